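"""Shared fixtures: phantom cohorts and a trained segmentation network.

Everything is generated programmatically and seeded; the expensive pieces
(segmentation training, the imaging cohort) are session-scoped so the unit
and acceptance tests share them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gliorisk.phantom import HazardCoeffs, PhantomConfig, _default_site_mix, generate_cohort, generate_phantom
from gliorisk.seg_encoder import SegTrainConfig, UNetConfig, train_segmentation


def clinical_only_config(seed: int) -> PhantomConfig:
    """Correctly specified clinical-only hazard (no tumor-volume term), with
    identical site intercepts so site is not a hidden confounder."""
    hc = HazardCoeffs(
        intercept=-3.8,
        log_volume=0.0,
        age_z=-0.6,
        resection={"GTR": -0.8, "STR": 0.3, "biopsy": 0.8, "NA": 0.0},
    )
    mix = {k: dataclasses.replace(v, intercept=-3.8) for k, v in _default_site_mix().items()}
    return PhantomConfig(seed=seed, hazard_coeffs=hc, site_mix=mix)


@pytest.fixture(scope="session")
def easy_phantoms():
    """48 high-contrast low-noise phantoms (vols, masks as arrays)."""
    cfg = PhantomConfig(noise_sd=0.02, bias_amplitude=0.05, tumor_contrast=2.0, seed=3)
    vols, masks = [], []
    for i in range(48):
        v, m, _ = generate_phantom(cfg, i)
        vols.append(v.voxels)
        masks.append(m.voxels)
    return vols, masks


@pytest.fixture(scope="session")
def trained_unet(easy_phantoms):
    """Desk-scale U-Net trained on the first 40 easy phantoms."""
    vols, masks = easy_phantoms
    model, loss_log = train_segmentation(
        vols[:40], masks[:40], UNetConfig.desk_scale(seed=5), SegTrainConfig(seed=5)
    )
    return model, loss_log


@pytest.fixture(scope="session")
def clinical_cohort():
    """n=600 clinical-only cohort under the correctly specified hazard."""
    _, table = generate_cohort(600, clinical_only_config(seed=0), with_images=False)
    return table


def multimodal_design_config(seed: int) -> PhantomConfig:
    """Designed cohort where tumor geometry (volume) and clinical covariates
    each carry an independent hazard signal: default imaging coefficient with
    the clinical coefficients of the clinical-only design."""
    hc = HazardCoeffs(
        intercept=-4.4,
        log_volume=0.9,
        age_z=-0.6,
        resection={"GTR": -0.8, "STR": 0.3, "biopsy": 0.8, "NA": 0.0},
    )
    return PhantomConfig(seed=seed, hazard_coeffs=hc)


@pytest.fixture(scope="session")
def imaging_cohort():
    """n=150 preprocessed imaging cohort with a trained encoder + features
    (shared by the modality-ordering and contract checks)."""
    from gliorisk.pipeline import ExperimentConfig, prepare_imaging_cohort, split_cohort
    from gliorisk.seg_encoder import extract_features

    cfg = ExperimentConfig(seed=11, phantom=multimodal_design_config(11))
    vols, masks, table = prepare_imaging_cohort(150, 11, cfg)
    plan = split_cohort(table, dev_frac=0.7, seed=11)
    table = table.set_index("id", drop=False)
    id_pos = {s: i for i, s in enumerate(table["id"])}
    dev_ids = plan.ids("dev")
    seg_model, _ = train_segmentation(
        [vols[id_pos[s]] for s in dev_ids[:30]],
        [masks[id_pos[s]] for s in dev_ids[:30]],
        UNetConfig.desk_scale(seed=11),
        SegTrainConfig(seed=11),
    )
    feats = np.stack([extract_features(seg_model, v).values for v in vols])
    return {
        "cfg": cfg,
        "vols": vols,
        "masks": masks,
        "table": table,
        "plan": plan,
        "id_pos": id_pos,
        "seg_model": seg_model,
        "feats": feats,
    }
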