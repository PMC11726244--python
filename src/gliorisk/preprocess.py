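"""Single-sequence T2 preprocessing chain.

Stages: multiplicative bias-field correction (a log-domain smoothing
surrogate for N4), trilinear resampling to a target voxel spacing (default
1 x 1 x 3 mm, stored slice-axis-first as (3, 1, 1)), brain masking (Otsu +
largest component + hole fill, or an externally supplied mask passed through
unchanged), within-brain z-score normalization, and center-crop / zero-pad
framing to the network input size.

Rigid inter-scan registration is deliberately a no-op here: with a single
sequence per subject there is nothing to co-register.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import ImageVolume, TumorMask

__all__ = [
    "PreprocessConfig",
    "correct_bias",
    "resample",
    "extract_brain",
    "normalize_and_frame",
    "frame_array",
    "preprocess_volume",
]


@dataclass
class PreprocessConfig:
    target_spacing_mm: tuple[float, float, float] = (3.0, 1.0, 1.0)
    input_size: tuple[int, int, int] = (96, 192, 192)
    bias_smooth_mm: float = 30.0
    normalize: str = "zscore_in_mask"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")
        if any(int(n) <= 0 for n in self.input_size):
            raise ValueError("input size must be positive")


def correct_bias(vol: ImageVolume, brain: TumorMask, bias_smooth_mm: float = 30.0) -> ImageVolume:
    """Divide out a smooth multiplicative intensity field.

    The field is estimated as a heavy Gaussian smoothing of the log-intensity
    inside the brain mask (normalized convolution, which extrapolates the
    field smoothly outside the mask), then normalized so the within-mask mean
    intensity is preserved.
    """
    m = brain.voxels.astype(bool)
    if not m.any():
        raise ValueError("brain mask is empty")
    x = np.asarray(vol.voxels, dtype=np.float64)
    inside = x[m]
    if np.any(inside <= 0):
        raise ValueError("nonpositive intensities inside the brain mask; log-domain bias correction undefined")

    sigma_vox = [bias_smooth_mm / s for s in vol.spacing_mm]
    logx = np.where(m, np.log(x, where=x > 0, out=np.zeros_like(x)), 0.0)
    num = ndimage.gaussian_filter(logx * m, sigma=sigma_vox)
    den = ndimage.gaussian_filter(m.astype(np.float64), sigma=sigma_vox)
    smooth_log = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-8)
    # zero-mean the log-field inside the mask so the field is pure shape
    field = np.exp(smooth_log - smooth_log[m].mean())
    field = np.where(den > 1e-8, field, 1.0)

    corrected = x / field
    corrected *= inside.mean() / corrected[m].mean()  # exact mean preservation
    return ImageVolume(corrected, vol.spacing_mm, vol.origin)


def resample(vol: ImageVolume, target_spacing_mm) -> ImageVolume:
    """Trilinear resampling onto the target spacing.

    Grid convention: voxel i sits at ``origin + i * spacing``, so old and new
    grids share their first sample and the physical extent is preserved to
    within one voxel.  Returns the input voxels unchanged when the spacing
    already matches.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if any(s <= 0 for s in target):
        raise ValueError("target spacing must be positive")
    if any(n < 2 for n in vol.shape):
        raise ValueError(f"degenerate volume of shape {vol.shape} cannot be resampled")
    if np.allclose(target, vol.spacing_mm):
        return ImageVolume(vol.voxels.copy(), vol.spacing_mm, vol.origin)

    new_shape = tuple(
        max(1, int(round(n * s_old / s_new)))
        for n, s_old, s_new in zip(vol.shape, vol.spacing_mm, target)
    )
    coords = np.meshgrid(
        *[
            np.arange(m, dtype=np.float64) * s_new / s_old
            for m, s_old, s_new in zip(new_shape, vol.spacing_mm, target)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        np.asarray(vol.voxels, dtype=np.float64), np.stack(coords), order=1, mode="nearest"
    )
    return ImageVolume(out, target, vol.origin)


def extract_brain(vol: ImageVolume, external_mask: TumorMask | None = None) -> TumorMask:
    """Foreground (brain) mask: Otsu threshold, largest connected component,
    hole fill.  A precomputed external mask is passed through bit-identically."""
    if external_mask is not None:
        return external_mask
    x = np.asarray(vol.voxels, dtype=np.float64)
    if np.ptp(x) <= 0:
        raise ValueError("volume has no intensity contrast; cannot extract brain")
    from skimage.filters import threshold_otsu

    fg = x > threshold_otsu(x)
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    labels, nlab = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, nlab + 1))
    largest = (labels == (1 + int(np.argmax(sizes))))
    filled = ndimage.binary_fill_holes(largest)
    return TumorMask(filled.astype(np.uint8), vol.spacing_mm, vol.origin)


def frame_array(arr: np.ndarray, center_vox, size, fill=0.0) -> np.ndarray:
    """Crop/pad ``arr`` to ``size`` about ``center_vox`` (voxel coordinates).

    The crop window is clipped to the array bounds (maximizing retained
    content) and any shortfall is zero-padded symmetrically.
    """
    size = tuple(int(n) for n in size)
    out = np.full(size, fill, dtype=arr.dtype)
    src_slices, dst_slices = [], []
    for ax in range(3):
        n, m, c = arr.shape[ax], size[ax], float(center_vox[ax])
        start = int(round(c - m / 2.0 + 0.5))
        start = min(max(start, 0), max(n - m, 0)) if n >= m else 0
        if n >= m:
            src_slices.append(slice(start, start + m))
            dst_slices.append(slice(0, m))
        else:
            pad = (m - n) // 2
            src_slices.append(slice(0, n))
            dst_slices.append(slice(pad, pad + n))
    out[tuple(dst_slices)] = arr[tuple(src_slices)]
    return out


def normalize_and_frame(
    vol: ImageVolume,
    brain: TumorMask,
    input_size,
    companions: list[np.ndarray] | None = None,
):
    """Z-score within the brain mask, zero the background, and frame to
    ``input_size`` about the brain-mask centroid.

    ``companions`` (e.g. truth masks) are framed with the identical window and
    returned alongside.  Raises on an empty mask or zero within-mask variance.
    """
    m = brain.voxels.astype(bool)
    if not m.any():
        raise ValueError("brain mask is empty")
    x = np.asarray(vol.voxels, dtype=np.float64)
    mu, sd = x[m].mean(), x[m].std()
    if sd <= 1e-12:
        raise ValueError("zero intensity variance inside the brain mask")
    z = np.where(m, (x - mu) / sd, 0.0)
    centroid = ndimage.center_of_mass(m)
    framed = frame_array(z, centroid, input_size)
    out = ImageVolume(framed, vol.spacing_mm, vol.origin)
    if companions is None:
        return out
    framed_companions = [frame_array(np.asarray(c), centroid, input_size) for c in companions]
    return out, framed_companions


def preprocess_volume(
    vol: ImageVolume,
    cfg: PreprocessConfig,
    external_mask: TumorMask | None = None,
    companions: list[np.ndarray] | None = None,
):
    """Full chain: bias correction -> resampling -> brain mask -> normalize/frame.

    Companion arrays (e.g. tumor truth masks on the input grid) are resampled
    with nearest-equivalent thresholding and framed identically.
    """
    brain0 = extract_brain(vol, external_mask)
    corrected = correct_bias(vol, brain0, cfg.bias_smooth_mm)
    res = resample(corrected, cfg.target_spacing_mm)
    res_companions = None
    if companions is not None:
        res_companions = [
            (
                resample(ImageVolume(np.asarray(c, dtype=np.float64), vol.spacing_mm, vol.origin), cfg.target_spacing_mm).voxels
                > 0.5
            ).astype(np.uint8)
            for c in companions
        ]
    brain_mask_arr = (
        resample(
            ImageVolume(brain0.voxels.astype(np.float64), vol.spacing_mm, vol.origin),
            cfg.target_spacing_mm,
        ).voxels
        > 0.5
    ).astype(np.uint8)
    brain = TumorMask(brain_mask_arr, cfg.target_spacing_mm, vol.origin)
    return normalize_and_frame(res, brain, cfg.input_size, companions=res_companions)
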