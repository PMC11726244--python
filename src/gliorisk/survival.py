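"""Discrete-time logistic-hazard survival networks.

The model treats survival prediction as serial binary regressions over time
bins: a 3-layer fully connected network emits one logit per bin, the per-bin
hazard is ``h_j = sigmoid(logit_j)``, and the survival curve is the running
product ``S(edge_j) = prod_{m <= j} (1 - h_m)``.  Three variants share the
architecture: *clinical* (age z-score + resection one-hot as the sole input),
*image* (the frozen-encoder feature vector), and *multimodal* (image features
through the trunk, with the clinical vector concatenated onto the activations
entering the final layer).

The negative log-likelihood for a subject with event indicator ``d`` in bin
``k`` is::

    -[ sum_{j<k} log(1 - h_j) + d log h_k + (1 - d) log(1 - h_k) ]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .types import RESECTION_LEVELS

__all__ = [
    "TimeGrid",
    "DiscreteTarget",
    "SurvivalCurve",
    "RiskScore",
    "ClinicalNormalizer",
    "SurvTrainConfig",
    "SurvivalNet",
    "make_time_grid",
    "discretize",
    "logistic_hazard_loss",
    "hazard_loss_grad",
    "build_survival_net",
    "train_survival",
    "predict_survival",
    "predict_survival_matrix",
    "survival_at",
    "risk_score",
    "select_covariates",
    "clinical_matrix",
]

LOGIT_CLAMP = 15.0  # keeps hazards strictly inside (0, 1)


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing bin edges in months, starting at 0."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=np.float64)
        if edges[0] != 0:
            raise ValueError("first edge must be 0")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


@dataclass(frozen=True)
class DiscreteTarget:
    bin_index: int
    event: int


@dataclass
class SurvivalCurve:
    """Survival probabilities at the grid edges; step-constant in between
    (right-continuous: S(t) = S at the greatest edge <= t)."""

    edges: np.ndarray
    S: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=np.float64)
        if abs(S[0] - 1.0) > 1e-12:
            raise ValueError("S(0) must be 1")
        if np.any(np.diff(S) > 1e-12) or S.min() < -1e-12 or S.max() > 1 + 1e-12:
            raise ValueError("survival curve must be nonincreasing within [0, 1]")
        self.S = S
        self.edges = np.asarray(self.edges, dtype=np.float64)


@dataclass(frozen=True)
class RiskScore:
    value: float
    horizon_months: float = 36.0


def make_time_grid(times, n_bins: int, scheme: str = "equidistant", events=None) -> TimeGrid:
    """Build a time grid over the observed follow-up.

    ``equidistant``: uniform edges over [0, max(times)].  ``quantile``: edges
    at quantiles of the event times (all times if ``events`` is None),
    deduplicated; the last edge is max(times).
    """
    times = np.asarray(times, dtype=np.float64)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    tmax = float(times.max())
    if tmax <= 0:
        raise ValueError("max(times) must be > 0")
    if scheme == "equidistant":
        return TimeGrid(np.linspace(0.0, tmax, n_bins + 1))
    if scheme == "quantile":
        ref = times if events is None else times[np.asarray(events).astype(bool)]
        distinct = np.unique(ref)
        if n_bins > distinct.size:
            raise ValueError(
                f"quantile scheme needs >= n_bins distinct event times ({n_bins} > {distinct.size})"
            )
        qs = np.quantile(ref, np.linspace(0, 1, n_bins + 1)[1:-1])
        edges = np.unique(np.concatenate([[0.0], qs, [tmax]]))
        return TimeGrid(edges)
    raise ValueError(f"unknown scheme {scheme!r}")


def discretize(time_months: float, event: int, grid: TimeGrid) -> DiscreteTarget:
    """Assign a subject to the half-open interval (edge_j, edge_{j+1}].

    A time exactly on an interior edge belongs to the earlier bin; times past
    the last edge clamp into the last bin.
    """
    if time_months <= 0:
        raise ValueError(f"time must be positive, got {time_months}")
    k = int(np.searchsorted(grid.edges, time_months, side="left")) - 1
    k = min(max(k, 0), grid.n_bins - 1)
    return DiscreteTarget(bin_index=k, event=int(event))


def logistic_hazard_loss(h: np.ndarray, targets) -> float:
    """Mean negative log-likelihood over subjects.

    ``h``: (n, n_bins) hazards strictly inside (0, 1); ``targets``: sequence of
    :class:`DiscreteTarget` (or (k, d) pairs).
    """
    h = np.atleast_2d(np.asarray(h, dtype=np.float64))
    if np.any(h <= 0) or np.any(h >= 1) or not np.all(np.isfinite(h)):
        raise ValueError("hazards must lie strictly inside (0, 1); clamp logits upstream")
    total = 0.0
    for i, tgt in enumerate(targets):
        k, d = (tgt.bin_index, tgt.event) if isinstance(tgt, DiscreteTarget) else tgt
        total += -(np.log1p(-h[i, :k]).sum() + (np.log(h[i, k]) if d else np.log1p(-h[i, k])))
    return float(total / h.shape[0])


def hazard_loss_grad(logits: np.ndarray, ks: np.ndarray, ds: np.ndarray):
    """(loss, dloss/dlogits) for the mean NLL; closed-form gradient.

    For subject i with event bin k: dL/dz_j = h_j for j < k, ``h_k - d`` at
    j = k, and 0 beyond.
    """
    z = np.clip(np.atleast_2d(logits), -LOGIT_CLAMP, LOGIT_CLAMP)
    h = 1.0 / (1.0 + np.exp(-z))
    n, J = h.shape
    cols = np.arange(J)[None, :]
    before = cols < ks[:, None]
    at = cols == ks[:, None]
    ll = (np.log1p(-h) * before).sum() + (
        np.where(ds[:, None].astype(bool), np.log(h), np.log1p(-h)) * at
    ).sum()
    grad = (h * before + (h - ds[:, None]) * at) / n
    # clamp is active only where |logits| > LOGIT_CLAMP; gradient there is kept
    # (straight-through) so training can recover
    return float(-ll / n), grad


class SurvivalNet:
    """3-layer fully connected logistic-hazard network."""

    def __init__(self, mode: str, image_dim: int, clinical_dim: int, n_bins: int,
                 hidden: int = 128, dropout: float = 0.2, seed: int = 0):
        if mode not in ("clinical", "image", "multimodal"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode in ("image", "multimodal") and image_dim < 1:
            raise ValueError(f"{mode} mode requires image features")
        if mode in ("clinical", "multimodal") and clinical_dim < 1:
            raise ValueError(f"{mode} mode requires clinical inputs")
        self.mode, self.n_bins, self.hidden = mode, n_bins, hidden
        self.image_dim, self.clinical_dim = image_dim, clinical_dim
        rng = np.random.default_rng(seed)
        trunk_in = clinical_dim if mode == "clinical" else image_dim
        final_in = hidden + (clinical_dim if mode == "multimodal" else 0)
        self.fc1 = nn.Linear(trunk_in, hidden, rng)
        self.fc2 = nn.Linear(hidden, hidden, rng)
        self.fc3 = nn.Linear(final_in, n_bins, rng)
        self.drop1, self.drop2 = nn.Dropout(dropout), nn.Dropout(dropout)
        self._cache = None
        self.feature_stats: dict = {}  # training normalization stats

    def parameters(self):
        return self.fc1.parameters() + self.fc2.parameters() + self.fc3.parameters()

    def forward(self, X_img: Optional[np.ndarray], X_clin: Optional[np.ndarray],
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        if self.mode == "clinical":
            x = X_clin
        else:
            x = X_img
        if x is None or (self.mode == "multimodal" and X_clin is None):
            raise ValueError(f"mode {self.mode!r} missing required input")
        a1 = self.drop1.forward(nn.relu(self.fc1.forward(x)), rng)
        a2 = self.drop2.forward(nn.relu(self.fc2.forward(a1)), rng)
        if self.mode == "multimodal":
            a2full = np.concatenate([a2, X_clin], axis=1)
        else:
            a2full = a2
        self._cache = (a1, a2, a2full)
        return self.fc3.forward(a2full)

    def backward(self, dlogits: np.ndarray) -> None:
        a1, a2, _ = self._cache
        da2full = self.fc3.backward(dlogits)
        da2 = da2full[:, : self.hidden] if self.mode == "multimodal" else da2full
        da1 = self.fc2.backward(nn.relu_backward(self.drop2.backward(da2), a2))
        self.fc1.backward(nn.relu_backward(self.drop1.backward(da1), a1))


def build_survival_net(mode: str, dims: dict, n_bins: int, seed: int = 0,
                       hidden: int = 128, dropout: float = 0.2) -> SurvivalNet:
    """``dims``: {'image': int, 'clinical': int} as applicable to the mode."""
    return SurvivalNet(
        mode,
        image_dim=int(dims.get("image", 0)),
        clinical_dim=int(dims.get("clinical", 0)),
        n_bins=n_bins,
        hidden=hidden,
        dropout=dropout,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# clinical encoding


@dataclass
class ClinicalNormalizer:
    """Age z-scoring with training-set statistics + resection one-hot.

    Subjects with resection 'NA' are dropped by default (``impute=True``
    instead maps them to the training-set modal level).
    """

    age_mean: float = 0.0
    age_sd: float = 1.0
    modal_resection: str = "GTR"

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "ClinicalNormalizer":
        ages = table["age_years"].to_numpy(dtype=np.float64)
        res = table["resection"][table["resection"] != "NA"]
        modal = res.mode().iloc[0] if len(res) else "GTR"
        sd = float(ages.std())
        return cls(age_mean=float(ages.mean()), age_sd=sd if sd > 0 else 1.0, modal_resection=str(modal))

    def transform(self, table: pd.DataFrame, impute: bool = False):
        """Returns (X (n,4), kept row index). Columns: age_z, GTR, STR, biopsy."""
        tbl = table.copy()
        if impute:
            tbl.loc[tbl["resection"] == "NA", "resection"] = self.modal_resection
        else:
            tbl = tbl[tbl["resection"] != "NA"]
        X = np.zeros((len(tbl), 4))
        X[:, 0] = (tbl["age_years"].to_numpy(dtype=np.float64) - self.age_mean) / self.age_sd
        for j, lev in enumerate(RESECTION_LEVELS[:3]):
            X[:, 1 + j] = (tbl["resection"] == lev).to_numpy()
        return X, tbl.index.to_numpy()


def clinical_matrix(table: pd.DataFrame, normalizer: ClinicalNormalizer, impute: bool = False):
    return normalizer.transform(table, impute=impute)


# ---------------------------------------------------------------------------
# training / prediction


@dataclass
class SurvTrainConfig:
    epochs: int = 300
    lr: float = 1e-2
    batch_size: int = 64
    seed: int = 0
    weight_decay: float = 1e-3
    early_stop: bool = False
    val_fraction: float = 0.2
    patience: int = 30


def train_survival(model: SurvivalNet, X_img, X_clin, targets: Sequence[DiscreteTarget],
                   cfg: SurvTrainConfig):
    """Minimize the mean logistic-hazard NLL with Adam.

    Deterministic under ``cfg.seed``.  With ``early_stop`` a tail fraction of
    the training subjects is held out and the best-validation-epoch weights
    are restored.  Returns (model, loss_log).
    """
    n = len(targets)
    ks = np.array([t.bin_index for t in targets])
    ds = np.array([t.event for t in targets])
    if ds.sum() == 0:
        warnings.warn("no events in training data; model will predict near-zero hazards")
    rng = np.random.default_rng(cfg.seed)

    idx_all = rng.permutation(n)
    if cfg.early_stop and n >= 10:
        n_val = max(1, int(round(cfg.val_fraction * n)))
        val_idx, tr_idx = idx_all[:n_val], idx_all[n_val:]
    else:
        val_idx, tr_idx = np.array([], dtype=int), idx_all

    def take(X, idx):
        return None if X is None else X[idx]

    opt = nn.Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    loss_log = []
    best_val, best_state, since_best = np.inf, None, 0
    for _epoch in range(cfg.epochs):
        order = tr_idx[rng.permutation(len(tr_idx))]
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            bidx = order[start : start + cfg.batch_size]
            logits = model.forward(take(X_img, bidx), take(X_clin, bidx), rng=rng)
            loss, grad = hazard_loss_grad(logits, ks[bidx], ds[bidx])
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(bidx)
            n_seen += len(bidx)
        loss_log.append(epoch_loss / max(n_seen, 1))
        if cfg.early_stop and len(val_idx):
            vlogits = model.forward(take(X_img, val_idx), take(X_clin, val_idx), rng=None)
            vloss, _ = hazard_loss_grad(vlogits, ks[val_idx], ds[val_idx])
            if vloss < best_val - 1e-6:
                best_val, since_best = vloss, 0
                best_state = [p.copy() for p, _ in model.parameters()]
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
    if best_state is not None:
        for (p, _), saved in zip(model.parameters(), best_state):
            p[...] = saved
    return model, loss_log


def predict_hazard(model: SurvivalNet, X_img, X_clin) -> np.ndarray:
    logits = model.forward(X_img, X_clin, rng=None)
    z = np.clip(logits, -LOGIT_CLAMP, LOGIT_CLAMP)
    return 1.0 / (1.0 + np.exp(-z))


def predict_survival_matrix(model: SurvivalNet, X_img, X_clin, grid: TimeGrid) -> np.ndarray:
    """(n, n_bins+1) survival values at the grid edges, S(0) = 1."""
    h = predict_hazard(model, X_img, X_clin)
    if h.shape[1] != grid.n_bins:
        raise ValueError(f"model emits {h.shape[1]} bins but grid has {grid.n_bins}")
    S = np.cumprod(1.0 - h, axis=1)
    S = np.concatenate([np.ones((h.shape[0], 1)), S], axis=1)
    assert np.all(S >= -1e-12) and np.all(S <= 1 + 1e-12) and np.all(np.diff(S, axis=1) <= 1e-12)
    return S


def predict_survival(model: SurvivalNet, X_img, X_clin, grid: TimeGrid,
                     subject_ids: Optional[Sequence[str]] = None) -> list[SurvivalCurve]:
    S = predict_survival_matrix(model, X_img, X_clin, grid)
    ids = subject_ids if subject_ids is not None else [""] * S.shape[0]
    return [SurvivalCurve(edges=grid.edges, S=S[i], subject_id=str(ids[i])) for i in range(S.shape[0])]


def survival_at(edges: np.ndarray, S: np.ndarray, t: float) -> float:
    """Step-constant evaluation: S at the greatest edge <= t."""
    j = int(np.searchsorted(edges, t, side="right")) - 1
    j = min(max(j, 0), len(S) - 1)
    return float(S[j])


def risk_score(curve: SurvivalCurve, horizon: float = 36.0) -> RiskScore:
    """Risk = 1 - S(horizon); errors if the horizon is beyond the grid."""
    if horizon > curve.edges[-1] + 1e-9:
        raise ValueError(f"horizon {horizon} beyond last grid edge {curve.edges[-1]}")
    return RiskScore(value=1.0 - survival_at(curve.edges, curve.S, horizon), horizon_months=horizon)


def select_covariates(candidates: dict, times, events, p_threshold: float = 0.15):
    """Univariable Cox screen: keep covariates with Wald p < threshold.

    ``candidates``: name -> numeric value array.  Constant covariates are
    excluded with a warning.  Returns the retained names with their fits.
    """
    from .cohort_stats import cox_univariable

    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate covariates to screen")
    kept, fits = [], {}
    for name, values in candidates.items():
        values = np.asarray(values, dtype=np.float64)
        if np.ptp(values) == 0:
            warnings.warn(f"covariate {name!r} is constant; excluded from screening")
            continue
        fit = cox_univariable(values, times, events)
        fits[name] = fit
        if fit.p_wald < p_threshold:
            kept.append(name)
    return kept, fits
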