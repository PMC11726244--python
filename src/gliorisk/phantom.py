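"""Synthetic T2-like tumor phantoms with a known discrete-time hazard.

The generator emulates the structure of a pooled two-site pediatric low-grade
glioma cohort: each subject gets a brain-shaped foreground, a perturbed
ellipsoidal tumor whose geometry drives recurrence hazard, clinical
covariates (age protective, gross total resection protective), and a
right-censored event time drawn natively in discrete time so that a
logistic-hazard survival model is correctly specified.

Event process
-------------
Each subject has a constant per-bin hazard

    h = sigmoid(beta0 + beta_v * log V + beta_a * age_z + beta_r[resection])

with V the tumor volume in millilitres and ``age_z = (age - 7) / 5`` a fixed
generator-internal standardization.  The event bin is geometric over
``n_bins_true`` bins of ``bin_width_months``; subjects event-free past the
last bin are administratively censored.  Random censoring: with probability
``censor_rate`` a subject draws an independent uniform censoring time over
the follow-up window (``censor_rate = 1`` is a boundary switch that censors
every subject).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import write_clinical_csv, write_nifti
from .types import ImageVolume, Subject, TumorMask

__all__ = [
    "SiteParams",
    "HazardCoeffs",
    "PhantomConfig",
    "generate_phantom",
    "generate_cohort",
    "save_cohort",
    "true_survival_at",
]

_AXIS_NAMES = ("axis0 (slice)", "axis1 (row)", "axis2 (col)")


@dataclass(frozen=True)
class HazardCoeffs:
    """Coefficients of the true discrete-time hazard linear predictor."""

    intercept: float = -4.4
    log_volume: float = 0.9
    age_z: float = -0.35
    resection: dict = field(
        default_factory=lambda: {"GTR": -0.6, "STR": 0.2, "biopsy": 0.5, "NA": 0.0}
    )


@dataclass(frozen=True)
class SiteParams:
    """Per-site demography and hazard-intercept override.

    Defaults follow the qualitative two-site contrast of the emulated study:
    site B is younger, has fewer gross total resections, more adjuvant
    chemotherapy, and a higher baseline event rate.
    """

    intercept: float
    age_mode: float
    age_range: tuple[float, float]
    resection_probs: tuple[float, float, float, float]  # GTR, STR, biopsy, NA
    chemo_p: float
    radiotherapy_p: float
    sex_p_male: float


def _default_site_mix() -> dict:
    return {
        "A": SiteParams(
            intercept=-4.4,
            age_mode=8.7,
            age_range=(0.4, 19.0),
            resection_probs=(0.61, 0.29, 0.09, 0.01),
            chemo_p=0.05,
            radiotherapy_p=0.04,
            sex_p_male=0.56,
        ),
        "B": SiteParams(
            intercept=-3.85,
            age_mode=5.7,
            age_range=(0.2, 19.4),
            resection_probs=(0.47, 0.33, 0.19, 0.01),
            chemo_p=0.25,
            radiotherapy_p=0.08,
            sex_p_male=0.52,
        ),
    }


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (16, 32, 32)
    voxel_spacing: tuple[float, float, float] = (3.0, 2.0, 2.0)
    tumor_radius_range: tuple[float, float] = (4.0, 10.0)
    tumor_irregularity: float = 0.15
    tumor_contrast: float = 1.5
    noise_sd: float = 0.05
    bias_amplitude: float = 0.2
    hazard_coeffs: HazardCoeffs = field(default_factory=HazardCoeffs)
    n_bins_true: int = 20
    bin_width_months: float = 6.0
    censor_rate: float = 0.3
    site_mix: dict = field(default_factory=_default_site_mix)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(g) <= 0 for g in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be positive, got {self.voxel_spacing}")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError(f"tumor_radius_range must be a nonempty positive interval, got {self.tumor_radius_range}")
        if self.tumor_irregularity < 0:
            raise ValueError("tumor_irregularity must be nonnegative")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError(f"censor_rate must be in [0,1], got {self.censor_rate}")
        if self.n_bins_true < 1 or self.bin_width_months <= 0:
            raise ValueError("n_bins_true >= 1 and bin_width_months > 0 required")
        if isinstance(self.hazard_coeffs, dict):
            self.hazard_coeffs = HazardCoeffs(**self.hazard_coeffs)

    @property
    def max_followup_months(self) -> float:
        return self.n_bins_true * self.bin_width_months

    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(g * s for g, s in zip(self.grid_shape, self.voxel_spacing))

    def for_site(self, site: str) -> "PhantomConfig":
        """Config with the site's hazard-intercept override applied."""
        pars = self.site_mix[site]
        hc = dataclasses.replace(self.hazard_coeffs, intercept=pars.intercept)
        return dataclasses.replace(self, hazard_coeffs=hc)


def _age_z(age_years: float) -> float:
    # fixed generator-internal standardization; models z-score from their own
    # training data and never see this
    return (age_years - 7.0) / 5.0


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def linear_predictor(cfg: PhantomConfig, log_volume: float, age_years: float, resection: str) -> float:
    hc = cfg.hazard_coeffs
    return (
        hc.intercept
        + hc.log_volume * log_volume
        + hc.age_z * _age_z(age_years)
        + hc.resection[resection]
    )


def true_survival_at(lp: float | np.ndarray, horizon_months: float, cfg: PhantomConfig) -> np.ndarray:
    """Closed-form survival S(horizon) implied by the generator's hazard."""
    h = 1.0 / (1.0 + np.exp(-np.asarray(lp, dtype=np.float64)))
    k = int(np.floor(horizon_months / cfg.bin_width_months + 1e-9))
    k = min(k, cfg.n_bins_true)
    return (1.0 - h) ** k


# ---------------------------------------------------------------------------
# geometry & image synthesis


def _tumor_geometry(cfg: PhantomConfig, rng: np.random.Generator):
    """Sample tumor center (mm), semi-axes (mm), and surface-perturbation coefs."""
    extent = np.array(cfg.extent_mm())
    lo, hi = cfg.tumor_radius_range
    r = float(rng.uniform(lo, hi))
    # anisotropy scales with the irregularity knob; zero -> exact sphere
    semi = r * (1.0 + cfg.tumor_irregularity * rng.uniform(-0.3, 0.3, size=3))
    for ax in range(3):
        if 2.0 * semi[ax] * (1.0 + cfg.tumor_irregularity) > extent[ax]:
            raise ValueError(
                f"tumor diameter {2 * semi[ax]:.1f} mm exceeds grid extent "
                f"{extent[ax]:.1f} mm along {_AXIS_NAMES[ax]}"
            )
    margin = semi * (1.0 + cfg.tumor_irregularity)
    center = np.array(
        [rng.uniform(margin[ax], extent[ax] - margin[ax]) for ax in range(3)]
    )
    # keep the tumor near the brain interior when there is slack
    mid, span = extent / 2.0, extent * 0.18
    center = np.clip(center, np.maximum(margin, mid - span), np.minimum(extent - margin, mid + span))
    coefs = rng.normal(0.0, 0.45, size=8)  # real l=1,2 harmonic basis weights
    return center, semi, coefs


def _harmonic_field(u: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Low-order angular perturbation from unit directions u (..., 3)."""
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    basis = np.stack(
        [x, y, z, x * y, x * z, y * z, x * x - y * y, 2 * z * z - x * x - y * y],
        axis=-1,
    )
    return basis @ coefs


def _render(cfg: PhantomConfig, rng: np.random.Generator, center, semi, coefs):
    shape = tuple(int(g) for g in cfg.grid_shape)
    spacing = np.array(cfg.voxel_spacing)
    idx = np.indices(shape, dtype=np.float64)
    pos = np.stack([idx[a] * spacing[a] for a in range(3)], axis=-1)  # mm

    extent = np.array(cfg.extent_mm())
    brain_c = extent / 2.0
    brain_a = 0.42 * extent
    brain = (np.sum(((pos - brain_c) / brain_a) ** 2, axis=-1) <= 1.0).astype(np.uint8)

    d = pos - center
    rho = np.sqrt(np.sum((d / semi) ** 2, axis=-1))
    norm = np.linalg.norm(d, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(norm[..., None] > 0, d / np.maximum(norm, 1e-12)[..., None], 0.0)
    boundary = 1.0 + cfg.tumor_irregularity * _harmonic_field(u, coefs)
    tumor = (rho <= np.maximum(boundary, 0.05)).astype(np.uint8)

    img = brain.astype(np.float64) + cfg.tumor_contrast * tumor
    if cfg.bias_amplitude > 0:
        g = np.zeros(shape)
        for _ in range(3):
            k = rng.uniform(0.5, 1.5, size=3) * rng.choice([-1.0, 1.0], size=3)
            phase = rng.uniform(0, 2 * np.pi)
            arg = sum(2 * np.pi * k[a] * idx[a] / shape[a] for a in range(3)) + phase
            g += np.cos(arg)
        img *= np.exp(cfg.bias_amplitude * g / 3.0)
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=shape)

    vol = ImageVolume(img, cfg.voxel_spacing)
    mask = TumorMask(tumor, cfg.voxel_spacing)
    return vol, mask, brain


# ---------------------------------------------------------------------------
# outcome simulation


def _draw_outcome(cfg: PhantomConfig, rng: np.random.Generator, lp: float):
    h = _sigmoid(np.clip(lp, -30.0, 30.0))
    maxT = cfg.max_followup_months
    draws = rng.random(cfg.n_bins_true)
    hit = np.nonzero(draws < h)[0]
    if hit.size:
        k = int(hit[0])
        t_event = (k + rng.random()) * cfg.bin_width_months
        event = 1
    else:
        t_event, event = maxT, 0
    if cfg.censor_rate >= 1.0:
        # boundary switch: censor everyone strictly before their event
        c = rng.uniform(0.0, min(t_event, maxT))
        return max(c, 1e-3), 0
    if cfg.censor_rate > 0 and rng.random() < cfg.censor_rate:
        c = max(rng.uniform(0.0, maxT), 1e-3)
        if c < t_event:
            return c, 0
    return max(min(t_event, maxT), 1e-3), event


def _draw_clinical(pars: SiteParams, rng: np.random.Generator):
    age = float(rng.triangular(pars.age_range[0], pars.age_mode, pars.age_range[1]))
    sex = "M" if rng.random() < pars.sex_p_male else "F"
    resection = ("GTR", "STR", "biopsy", "NA")[
        int(rng.choice(4, p=np.array(pars.resection_probs) / sum(pars.resection_probs)))
    ]
    chemo = bool(rng.random() < pars.chemo_p)
    rt = bool(rng.random() < pars.radiotherapy_p)
    return age, sex, resection, chemo, rt


def generate_phantom(
    config: PhantomConfig,
    subject_seed: int,
    site: str = "A",
    with_image: bool = True,
):
    """Generate one synthetic subject.

    Returns ``(ImageVolume | None, TumorMask | None, Subject)``; the image and
    mask are ``None`` when ``with_image=False`` (the tumor volume entering the
    hazard is then the analytic ellipsoid volume).  Deterministic given
    ``(config, subject_seed, site)``.
    """
    vol, mask, subject, _ = _generate_one(config, subject_seed, site, with_image)
    return vol, mask, subject


def _generate_one(config: PhantomConfig, subject_seed: int, site: str, with_image: bool):
    cfg = config.for_site(site)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(subject_seed)]))
    center, semi, coefs = _tumor_geometry(cfg, rng)
    age, sex, resection, chemo, rt = _draw_clinical(cfg.site_mix[site], rng)

    vol = mask = None
    if with_image:
        vol, mask, _ = _render(cfg, rng, center, semi, coefs)
        volume_ml = mask.volume_ml()
        if volume_ml <= 0:  # sub-voxel tumor on a coarse grid
            volume_ml = 4.0 / 3.0 * np.pi * float(np.prod(semi)) / 1000.0
    else:
        rng.random(2)  # keep stream layout comparable across modes
        volume_ml = 4.0 / 3.0 * np.pi * float(np.prod(semi)) / 1000.0

    lp = linear_predictor(cfg, float(np.log(volume_ml)), age, resection)
    time_months, event = _draw_outcome(cfg, rng, lp)

    subject = Subject(
        id=f"S{subject_seed:05d}",
        site=site,
        age_years=age,
        sex=sex,
        resection=resection,
        chemo=chemo,
        radiotherapy=rt,
        time_months=time_months,
        event=event,
        true_linear_predictor=lp,
    )
    return vol, mask, subject, volume_ml


def generate_cohort(n: int, config: PhantomConfig, with_images: bool = True):
    """Generate a two-site cohort.

    Returns ``(images, table)`` where ``images`` is a list of
    ``(ImageVolume, TumorMask)`` (or ``None`` when ``with_images=False``) and
    ``table`` a clinical DataFrame with generator-truth columns
    ``tumor_volume_ml`` and ``true_lp`` appended.
    """
    if n < 2:
        raise ValueError(f"cohort size must be >= 2, got {n}")
    site_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 987654321]))
    sites = np.array(["A"] * (n - n // 2) + ["B"] * (n // 2))
    site_rng.shuffle(sites)

    images = [] if with_images else None
    rows = []
    for i in range(n):
        vol, mask, subj, volume_ml = _generate_one(config, subject_seed=i, site=str(sites[i]), with_image=with_images)
        if with_images:
            images.append((vol, mask))
        rows.append(
            {
                "id": subj.id,
                "site": subj.site,
                "age_years": subj.age_years,
                "sex": subj.sex,
                "resection": subj.resection,
                "chemo": int(subj.chemo),
                "radiotherapy": int(subj.radiotherapy),
                "time_months": subj.time_months,
                "event": subj.event,
                "tumor_volume_ml": volume_ml,
                "true_lp": subj.true_linear_predictor,
            }
        )
    table = pd.DataFrame(rows)
    return images, table


def save_cohort(images, table: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write volumes/masks as NIfTI and the clinical table as CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if images is not None:
        for (vol, mask), sid in zip(images, table["id"]):
            write_nifti(vol, out_dir / f"{sid}_T2.nii.gz")
            write_nifti(mask, out_dir / f"{sid}_mask.nii.gz")
    write_clinical_csv(table[[c for c in table.columns if c not in ("tumor_volume_ml", "true_lp")]], out_dir / "clinical.csv")
    table.to_csv(out_dir / "clinical_with_truth.csv", index=False)
    return out_dir
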