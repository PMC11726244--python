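"""End-to-end orchestration: cohort splitting, cross-validation, the three
survival-model variants, evaluation, fine-tuning, and a from-scratch CNN
baseline.

The experiment mirrors the framework it emulates: a pooled two-site cohort is
split 70/30 into development and test sets stratified by (event status,
site); the development set is used for 3-fold cross-validation (whose pooled
out-of-fold risk scores fix the stratification threshold) and the final
model is refit on the full development set before one evaluation pass on the
held-out test set.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .metrics import (
    bootstrap_ci,
    ctd_index,
    ece_calibration,
    integrated_brier,
    stratify_median,
    step_lookup,
    td_auc,
)
from .phantom import PhantomConfig, generate_cohort
from .preprocess import PreprocessConfig, preprocess_volume
from .seg_encoder import (
    SegTrainConfig,
    UNetConfig,
    build_unet,
    encoder_hash,
    extract_features,
    train_segmentation,
)
from .survival import (
    ClinicalNormalizer,
    SurvTrainConfig,
    TimeGrid,
    build_survival_net,
    discretize,
    hazard_loss_grad,
    make_time_grid,
    predict_survival_matrix,
    train_survival,
)

__all__ = [
    "SplitPlan",
    "ExperimentConfig",
    "split_cohort",
    "run_experiment",
    "finetune_incremental",
    "scratch_baseline",
    "scratch_experiment",
    "external_site_finetune_experiment",
    "prepare_imaging_cohort",
    "ScratchCNN",
]

MODES = ("clinical", "image", "multimodal")


@dataclass
class SplitPlan:
    assignment: dict  # subject_id -> "dev" | "test"
    folds: dict       # subject_id -> 1..n_folds (dev subjects only)
    seed: int

    def ids(self, which: str) -> list[str]:
        return [sid for sid, a in self.assignment.items() if a == which]


def split_cohort(table: pd.DataFrame, dev_frac: float = 0.7, seed: int = 0,
                 n_folds: int = 3) -> SplitPlan:
    """Stratified development/test split plus CV fold assignment.

    Strata are (event, site); each must hold >= 2 subjects.  The development
    fraction is met within +-1 subject per stratum, and folds are balanced
    within +-1 inside each stratum.
    """
    rng = np.random.default_rng(seed)
    assignment, folds = {}, {}
    for (ev, site), grp in table.groupby(["event", "site"], sort=True):
        ids = grp["id"].tolist()
        if len(ids) < 2:
            raise ValueError(f"stratum (event={ev}, site={site}) has < 2 subjects")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n_dev = int(round(dev_frac * len(ids)))
        n_dev = min(max(n_dev, 1), len(ids) - 1)
        for j, sid in enumerate(ids):
            assignment[sid] = "dev" if j < n_dev else "test"
        for j, sid in enumerate(ids[:n_dev]):
            folds[sid] = 1 + j % n_folds
    return SplitPlan(assignment=assignment, folds=folds, seed=seed)


@dataclass
class ExperimentConfig:
    n_subjects: int = 150
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(
            target_spacing_mm=(3.0, 2.0, 2.0), input_size=(16, 32, 32), bias_smooth_mm=30.0
        )
    )
    unet: UNetConfig = field(default_factory=UNetConfig.desk_scale)
    seg_train: SegTrainConfig = field(default_factory=SegTrainConfig)
    n_seg_train: int = 30
    surv_train: SurvTrainConfig = field(default_factory=SurvTrainConfig)
    n_bins: int = 20
    bin_scheme: str = "equidistant"
    hidden: int = 32
    dropout: float = 0.1
    # image features are high-dimensional relative to the cohort size; the
    # trunk uses the classic heavy-dropout default for that regime
    dropout_image: float = 0.5
    horizon_months: float = 36.0
    n_boot: int = 200
    modes: tuple = MODES
    seed: int = 0

    def hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return float(o)
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _targets_for(table: pd.DataFrame, grid: TimeGrid):
    return [discretize(t, e, grid) for t, e in zip(table["time_months"], table["event"])]


def _train_one_mode(mode, feats, clin_tables, grid, cfg, seed):
    """Fit one survival model variant; returns (model, normalizer)."""
    table = clin_tables
    norm = ClinicalNormalizer.fit(table)
    X_clin, kept = norm.transform(table)
    if mode == "image":
        kept = table.index.to_numpy()
        X_clin = None
    tbl = table.loc[kept]
    X_img = None
    feat_mu = feat_sd = None
    if mode != "clinical" and feats is not None:
        X_img = feats[table.index.get_indexer(pd.Index(kept))]
        # feature standardization with training-set statistics only
        feat_mu = X_img.mean(axis=0)
        feat_sd = np.maximum(X_img.std(axis=0), 1e-8)
        X_img = (X_img - feat_mu) / feat_sd
    model = build_survival_net(
        mode,
        dims={"image": 0 if X_img is None else X_img.shape[1],
              "clinical": 0 if X_clin is None else X_clin.shape[1]},
        n_bins=grid.n_bins,
        seed=seed,
        hidden=cfg.hidden,
        dropout=cfg.dropout if mode == "clinical" else cfg.dropout_image,
    )
    tr = dataclasses.replace(cfg.surv_train, seed=seed)
    if mode != "clinical":
        tr = dataclasses.replace(tr, weight_decay=max(tr.weight_decay, 1e-2))
    train_survival(model, X_img, X_clin, _targets_for(tbl, grid), tr)
    model.feature_stats = {"normalizer": norm, "feat_mu": feat_mu, "feat_sd": feat_sd}
    return model, norm, kept


def _predict_mode(mode, model, norm, feats, table, grid):
    X_clin, kept = norm.transform(table)
    if mode == "image":
        kept = table.index.to_numpy()
        X_clin = None
    X_img = None
    if mode != "clinical" and feats is not None:
        X_img = feats[table.index.get_indexer(pd.Index(kept))]
        mu = model.feature_stats.get("feat_mu")
        if mu is not None:
            X_img = (X_img - mu) / model.feature_stats["feat_sd"]
    S = predict_survival_matrix(model, X_img, X_clin, grid)
    return S, kept


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Full pipeline on a synthetic cohort; returns the metrics report.

    Stages write their artifacts under ``out_dir`` (stamped with the config
    hash) and are skipped on rerun if the artifact already exists, making a
    partially failed run resumable.
    """
    run_dir = None
    if out_dir is not None:
        run_dir = Path(out_dir) / f"run_{config.hash()}"
        run_dir.mkdir(parents=True, exist_ok=True)

    # 1. cohort
    phantom_cfg = dataclasses.replace(config.phantom, seed=config.seed)
    images, table = generate_cohort(config.n_subjects, phantom_cfg, with_images=True)

    # 2. preprocessing + framing (images and truth masks share the window)
    framed_vols, framed_masks = [], []
    for (vol, mask) in images:
        pv, (pm,) = preprocess_volume(vol, config.preprocess, companions=[mask.voxels])
        framed_vols.append(pv.voxels.astype(np.float32))
        framed_masks.append(pm)

    # 3. split
    plan = split_cohort(table, dev_frac=0.7, seed=config.seed)
    table = table.set_index("id", drop=False)
    dev_ids, test_ids = plan.ids("dev"), plan.ids("test")
    id_pos = {sid: i for i, sid in enumerate(table["id"])}

    # 4. segmentation training on development subjects only
    feat_path = run_dir / "features.npz" if run_dir else None
    if feat_path is not None and feat_path.exists():
        with np.load(feat_path) as data:
            feats_all = data["feats"]
        seg_model = None
        enc_hash_before = enc_hash_after = None
    else:
        seg_ids = dev_ids[: config.n_seg_train]
        seg_model, _ = train_segmentation(
            [framed_vols[id_pos[s]] for s in seg_ids],
            [framed_masks[id_pos[s]] for s in seg_ids],
            dataclasses.replace(config.unet, seed=config.seed),
            dataclasses.replace(config.seg_train, seed=config.seed),
        )
        enc_hash_before = encoder_hash(seg_model)
        # 5. frozen-encoder features for everyone
        feats_all = np.stack(
            [extract_features(seg_model, v).values for v in framed_vols]
        )
        enc_hash_after = encoder_hash(seg_model)
        assert enc_hash_before == enc_hash_after, "encoder changed during feature extraction"
        if feat_path is not None:
            np.savez(feat_path, feats=feats_all)

    # 6. time grid from development outcomes only
    dev_tbl = table.loc[dev_ids]
    test_tbl = table.loc[test_ids]
    grid = make_time_grid(dev_tbl["time_months"].to_numpy(), config.n_bins, config.bin_scheme,
                          events=dev_tbl["event"].to_numpy())

    report = {"config_hash": config.hash(), "seed": config.seed, "n_dev": len(dev_ids),
              "n_test": len(test_ids), "grid_edges": grid.edges.tolist(), "modes": {}}
    horizon = config.horizon_months

    for mode in config.modes:
        # 3-fold CV on the development set: pooled out-of-fold risk scores
        oof_risk = {}
        cv_losses = []
        for fold in (1, 2, 3):
            tr_ids = [s for s in dev_ids if plan.folds[s] != fold]
            va_ids = [s for s in dev_ids if plan.folds[s] == fold]
            tr_tbl = table.loc[tr_ids]
            feats_tr = feats_all[[id_pos[s] for s in tr_ids]]
            model, norm, _ = _train_one_mode(mode, feats_tr, tr_tbl, grid, config,
                                             seed=config.seed * 13 + fold)
            va_tbl = table.loc[va_ids]
            feats_va = feats_all[[id_pos[s] for s in va_ids]]
            S_va, kept = _predict_mode(mode, model, norm, feats_va, va_tbl, grid)
            risk = 1.0 - step_lookup(grid.edges, S_va, horizon)
            for sid, r in zip(va_tbl.loc[kept, "id"], risk):
                oof_risk[sid] = float(r)
            # validation NLL from the predicted hazards h_j = 1 - S_{j+1}/S_j
            h_va = np.clip(1.0 - S_va[:, 1:] / np.maximum(S_va[:, :-1], 1e-12), 1e-7, 1 - 1e-7)
            kt = va_tbl.loc[kept]
            vk = np.array([discretize(t, e, grid).bin_index
                           for t, e in zip(kt["time_months"], kt["event"])])
            vd = kt["event"].to_numpy().astype(int)
            vloss, _ = hazard_loss_grad(np.log(h_va / (1 - h_va)), vk, vd)
            cv_losses.append(float(vloss))

        # refit on the full development set, evaluate once on test
        feats_dev = feats_all[[id_pos[s] for s in dev_ids]]
        model, norm, _ = _train_one_mode(mode, feats_dev, dev_tbl, grid, config,
                                         seed=config.seed * 13)
        feats_test = feats_all[[id_pos[s] for s in test_ids]]
        S_test, kept = _predict_mode(mode, model, norm, feats_test, test_tbl, grid)
        kept_tbl = test_tbl.loc[kept]
        times = kept_tbl["time_months"].to_numpy()
        events = kept_tbl["event"].to_numpy()
        risk_test = 1.0 - step_lookup(grid.edges, S_test, horizon)

        def ctd_stat(idx, S=S_test, t=times, e=events):
            return ctd_index(S[idx], grid.edges, t[idx], e[idx])

        ctd = bootstrap_ci(ctd_stat, len(times), n_boot=config.n_boot,
                           seed=config.seed, name=f"ctd_{mode}")
        try:
            auc = td_auc(risk_test, times, events, horizon=horizon)
        except ValueError:
            auc = float("nan")
        S_at_h = step_lookup(grid.edges, S_test, horizon)
        ece, _cal = ece_calibration(S_at_h, times, events, horizon=horizon)
        # integrate only inside the censoring-KM support
        from .metrics import censoring_km

        G = censoring_km(times, events)
        t_hi = min(grid.edges[-1], float(np.quantile(times, 0.9)))
        if G.event_times.size and G.S_hat[-1] <= 0:
            t_hi = min(t_hi, 0.999 * float(G.event_times[-1]))
        ibs_grid = np.linspace(0, t_hi, 10)[1:]
        try:
            ibs = integrated_brier(S_test, grid.edges, times, events, ibs_grid)
        except ValueError:
            ibs = float("nan")
        val_risks = np.array([oof_risk[s] for s in dev_ids if s in oof_risk])
        strat = stratify_median(val_risks, risk_test, times, events, horizon=horizon)

        report["modes"][mode] = {
            "mean_cv_loss": float(np.mean(cv_losses)),
            "ctd": ctd.as_dict(),
            "td_auc_36": float(auc),
            "ece": float(ece),
            "ibs": float(ibs),
            "stratification": {
                "threshold": strat["threshold"],
                "efs_at_horizon": {k: float(v) for k, v in strat["efs_at_horizon"].items()},
                "logrank_chi2": float(strat["chi2"]),
                "logrank_p": float(strat["p"]),
            },
            "risk_scores_test": {sid: float(r) for sid, r in zip(kept_tbl["id"], risk_test)},
        }

    if enc_hash_before is not None:
        report["encoder_hash"] = enc_hash_before
    if run_dir is not None:
        (run_dir / "metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# fine-tuning on external-site data


def finetune_incremental(base_model, grid: TimeGrid, X_img_ext, X_clin_ext, table_ext: pd.DataFrame,
                         fractions, seed: int = 0, epochs: int = 100, lr: float = 3e-3,
                         holdout_frac: float = 0.3) -> pd.DataFrame:
    """Fine-tune the survival head on growing fractions of an external site.

    The encoder stays frozen by construction (only survival-network weights
    are updated).  Fractions yielding fewer than 5 subjects are skipped with
    a warning; fraction 0 reports the base model unchanged.  Returns a table
    (fraction, n_finetune, ctd) on the fixed external holdout.
    """
    rng = np.random.default_rng(seed)
    n = len(table_ext)
    order = rng.permutation(n)
    n_hold = max(2, int(round(holdout_frac * n)))
    hold_idx, pool_idx = order[:n_hold], order[n_hold:]

    def subset(X, idx):
        return None if X is None else X[idx]

    times = table_ext["time_months"].to_numpy()
    events = table_ext["event"].to_numpy()
    targets_all = [discretize(t, e, grid) for t, e in zip(times, events)]

    rows = []
    for frac in fractions:
        n_ft = int(round(frac * len(pool_idx)))
        if frac > 0 and n_ft < 5:
            warnings.warn(f"fraction {frac} yields {n_ft} subjects (< 5); skipped")
            continue
        model = copy.deepcopy(base_model)
        if n_ft > 0:
            ft_idx = pool_idx[:n_ft]
            cfg = SurvTrainConfig(epochs=epochs, lr=lr, seed=seed, weight_decay=1e-3)
            train_survival(model, subset(X_img_ext, ft_idx), subset(X_clin_ext, ft_idx),
                           [targets_all[i] for i in ft_idx], cfg)
        S = predict_survival_matrix(model, subset(X_img_ext, hold_idx),
                                    subset(X_clin_ext, hold_idx), grid)
        ctd = ctd_index(S, grid.edges, times[hold_idx], events[hold_idx])
        rows.append({"fraction": float(frac), "n_finetune": int(n_ft), "ctd": float(ctd)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# from-scratch CNN baseline


class ScratchCNN:
    """Small 3D CNN with a logistic-hazard head, trained end-to-end."""

    def __init__(self, n_bins: int, base_channels: int = 4, n_blocks: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.convs = []
        c_prev = 1
        for b in range(n_blocks):
            c = base_channels * 2**b
            self.convs.append(nn.Conv3d(c_prev, c, rng))
            c_prev = c
        self.fc = nn.Linear(c_prev, n_bins, rng, dtype=np.float64)
        self.n_bins = n_bins
        self._cache = None

    def parameters(self):
        out = []
        for c in self.convs:
            out += c.parameters()
        return out + self.fc.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x.astype(np.float32)
        acts, pools = [], []
        for conv in self.convs:
            a = nn.relu(conv.forward(h))
            h, cache = nn.maxpool2(a)
            acts.append(a)
            pools.append(cache)
        gap = h.mean(axis=(1, 2, 3)).astype(np.float64)
        self._cache = (acts, pools, h.shape)
        return self.fc.forward(gap[None, :])

    def backward(self, dlogits: np.ndarray) -> None:
        acts, pools, h_shape = self._cache
        dgap = self.fc.backward(dlogits)[0]
        nvox = int(np.prod(h_shape[1:]))
        dh = (np.ones(h_shape, dtype=np.float32) / nvox) * dgap[:, None, None, None].astype(np.float32)
        for conv, a, cache in zip(reversed(self.convs), reversed(acts), reversed(pools)):
            da = nn.maxpool2_backward(dh, cache)
            dh = conv.backward(nn.relu_backward(da, a))


def scratch_baseline(volumes, times, events, grid: TimeGrid, epochs: int = 8,
                     lr: float = 3e-3, seed: int = 0, base_channels: int = 4):
    """Train the end-to-end CNN baseline; returns (model, predict_S, loss_log)."""
    vols = [np.asarray(v, dtype=np.float32) for v in volumes]
    vols = [v[None] if v.ndim == 3 else v for v in vols]
    ks = np.array([discretize(t, e, grid).bin_index for t, e in zip(times, events)])
    ds = np.asarray(events).astype(int)
    model = ScratchCNN(grid.n_bins, base_channels=base_channels, seed=seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    loss_log = []
    for _epoch in range(epochs):
        order = rng.permutation(len(vols))
        losses = []
        for i in order:
            logits = model.forward(vols[i])
            loss, grad = hazard_loss_grad(logits, ks[i : i + 1], ds[i : i + 1])
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        loss_log.append(float(np.mean(losses)))

    def predict_S(test_vols) -> np.ndarray:
        S = []
        for v in test_vols:
            v = np.asarray(v, dtype=np.float32)
            logits = model.forward(v[None] if v.ndim == 3 else v)
            z = np.clip(logits, -15, 15)
            h = 1.0 / (1.0 + np.exp(-z))
            S.append(np.concatenate([[1.0], np.cumprod(1 - h[0])]))
        return np.asarray(S)

    return model, predict_S, loss_log


# ---------------------------------------------------------------------------
# convenience experiments (desk scale)


def prepare_imaging_cohort(n: int, seed: int, config: ExperimentConfig | None = None):
    """Generate, preprocess and frame a phantom cohort; returns
    (framed volumes, framed truth masks, clinical table)."""
    cfg = config or ExperimentConfig(seed=seed)
    phantom_cfg = dataclasses.replace(cfg.phantom, seed=seed)
    images, table = generate_cohort(n, phantom_cfg, with_images=True)
    vols, masks = [], []
    for (vol, mask) in images:
        pv, (pm,) = preprocess_volume(vol, cfg.preprocess, companions=[mask.voxels])
        vols.append(pv.voxels.astype(np.float32))
        masks.append(pm)
    return vols, masks, table


def scratch_experiment(n: int = 120, seed: int = 0, n_train: int = 100,
                       config: ExperimentConfig | None = None,
                       scratch_epochs: int = 8) -> dict:
    """Transfer-feature image model vs end-to-end scratch CNN on one cohort.

    Both routes share the same training subjects, time grid, and held-out
    test set; returns their test-set Ctd values.
    """
    cfg = config or ExperimentConfig(seed=seed)
    if n_train > 0.85 * n:
        warnings.warn(f"n_train={n_train} leaves too few test subjects; capping at 70% of n={n}")
        n_train = int(round(0.7 * n))
    vols, masks, table = prepare_imaging_cohort(n, seed, cfg)
    plan = split_cohort(table, dev_frac=n_train / n, seed=seed)
    table = table.set_index("id", drop=False)
    id_pos = {sid: i for i, sid in enumerate(table["id"])}
    tr_ids, te_ids = plan.ids("dev"), plan.ids("test")
    tr_tbl, te_tbl = table.loc[tr_ids], table.loc[te_ids]
    grid = make_time_grid(tr_tbl["time_months"].to_numpy(), cfg.n_bins, cfg.bin_scheme,
                          events=tr_tbl["event"].to_numpy())
    te_times = te_tbl["time_months"].to_numpy()
    te_events = te_tbl["event"].to_numpy()

    # transfer route: frozen segmentation encoder -> image-mode survival net
    seg_ids = tr_ids[: cfg.n_seg_train]
    seg_model, _ = train_segmentation(
        [vols[id_pos[s]] for s in seg_ids],
        [masks[id_pos[s]] for s in seg_ids],
        dataclasses.replace(cfg.unet, seed=seed),
        dataclasses.replace(cfg.seg_train, seed=seed),
    )
    feats = np.stack([extract_features(seg_model, v).values for v in vols])
    model, norm, _ = _train_one_mode("image", feats[[id_pos[s] for s in tr_ids]],
                                     tr_tbl, grid, cfg, seed=seed)
    S_tr, _ = _predict_mode("image", model, norm, feats[[id_pos[s] for s in tr_ids]], tr_tbl, grid)
    S_te, _ = _predict_mode("image", model, norm, feats[[id_pos[s] for s in te_ids]], te_tbl, grid)
    ctd_transfer = ctd_index(S_te, grid.edges, te_times, te_events)

    # scratch route: end-to-end CNN with the logistic-hazard head
    _, predict_S, _ = scratch_baseline(
        [vols[id_pos[s]] for s in tr_ids],
        tr_tbl["time_months"].to_numpy(), tr_tbl["event"].to_numpy(),
        grid, epochs=scratch_epochs, seed=seed,
    )
    S_scratch = predict_S([vols[id_pos[s]] for s in te_ids])
    ctd_scratch = ctd_index(S_scratch, grid.edges, te_times, te_events)
    return {"n_train": len(tr_ids), "n_test": len(te_ids),
            "ctd_transfer": float(ctd_transfer), "ctd_scratch": float(ctd_scratch)}


def external_site_finetune_experiment(n: int = 150, seed: int = 0,
                                      fractions=(0.0, 0.25, 0.5, 1.0),
                                      config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Train a multimodal model on site A only, then fine-tune the survival
    head on growing fractions of site B and evaluate on a site-B holdout."""
    cfg = config or ExperimentConfig(seed=seed)
    vols, masks, table = prepare_imaging_cohort(n, seed, cfg)
    table = table.set_index("id", drop=False)
    id_pos = {sid: i for i, sid in enumerate(table["id"])}
    a_tbl = table[table["site"] == "A"]
    b_tbl = table[table["site"] == "B"]

    seg_ids = a_tbl["id"].tolist()[: cfg.n_seg_train]
    seg_model, _ = train_segmentation(
        [vols[id_pos[s]] for s in seg_ids],
        [masks[id_pos[s]] for s in seg_ids],
        dataclasses.replace(cfg.unet, seed=seed),
        dataclasses.replace(cfg.seg_train, seed=seed),
    )
    feats = np.stack([extract_features(seg_model, v).values for v in vols])
    grid = make_time_grid(a_tbl["time_months"].to_numpy(), cfg.n_bins, cfg.bin_scheme,
                          events=a_tbl["event"].to_numpy())
    model, norm, _ = _train_one_mode("multimodal", feats[[id_pos[s] for s in a_tbl["id"]]],
                                     a_tbl, grid, cfg, seed=seed)
    X_clin_b, kept_b = norm.transform(b_tbl)
    b_kept = b_tbl.loc[kept_b]
    X_img_b = feats[[id_pos[s] for s in b_kept["id"]]]
    return finetune_incremental(model, grid, X_img_b, X_clin_b, b_kept,
                                fractions, seed=seed)
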