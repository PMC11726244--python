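"""Core domain containers shared across the package.

Conventions
-----------
Volumes are stored as ``(D, H, W)`` arrays with 0-based voxel indices; axis 0
is the slice (inferior-superior) axis.  World coordinates follow
``world = origin + index * spacing_mm`` per axis, so index 0 sits at the
origin.  Spacing is millimetres per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ImageVolume",
    "TumorMask",
    "Subject",
    "MetricResult",
]


@dataclass
class ImageVolume:
    """A 3D scalar image with voxel spacing metadata."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite intensities")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size spanned by the voxel grid along each axis."""
        return tuple(n * s for n, s in zip(self.voxels.shape, self.spacing_mm))


@dataclass
class TumorMask:
    """A binary mask aligned to a companion :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    def volume_ml(self) -> float:
        """Mask volume in millilitres (= cm^3)."""
        voxel_mm3 = float(np.prod(self.spacing_mm))
        return float(self.voxels.sum()) * voxel_mm3 / 1000.0


RESECTION_LEVELS = ("GTR", "STR", "biopsy", "NA")


@dataclass
class Subject:
    """Clinical covariates and right-censored outcome for one patient.

    ``true_linear_predictor`` holds the simulation's hazard linear predictor
    and is only populated for synthetic subjects; models never see it.
    """

    id: str
    site: str
    age_years: float
    sex: str
    resection: str
    chemo: bool
    radiotherapy: bool
    time_months: float
    event: int
    true_linear_predictor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError(f"time_months must be > 0, got {self.time_months}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event}")
        if self.site not in ("A", "B"):
            raise ValueError(f"site must be 'A' or 'B', got {self.site}")
        if self.resection not in RESECTION_LEVELS:
            raise ValueError(f"unknown resection level {self.resection!r}")


@dataclass
class MetricResult:
    """Point estimate with a bootstrap percentile confidence interval."""

    name: str
    point: float
    ci_low: float = field(default=float("nan"))
    ci_high: float = field(default=float("nan"))
    n_boot: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot > 0 and np.isfinite(self.ci_low):
            if not (self.ci_low <= self.point + 1e-12 and self.point - 1e-12 <= self.ci_high):
                raise ValueError(
                    f"{self.name}: point {self.point} outside CI [{self.ci_low}, {self.ci_high}]"
                )

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "point": float(self.point),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "n_boot": int(self.n_boot),
            "seed": int(self.seed),
        }
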