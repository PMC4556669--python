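"""Per-timepoint ratiometric processing: red mask, green edit, SUM projections,
and the green/red ratio image.

The measurement logic: the red (converted Kaede) channel marks the axon, so a
binary mask derived from the red z-stack confines the green (newly synthesized
Kaede) signal to the axon before both channels are SUM-projected and divided.
Masking has two modes:

``restrict``
    green is retained only inside the red-positive mask (the analysis intent —
    ratios stay finite along the axon).  Default.
``literal_subtract``
    green minus (mask × max intensity), clamped at zero — faithful 8/16-bit
    image-calculator arithmetic, kept as an opt-in fidelity mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_isodata, threshold_otsu

__all__ = [
    "MaskVolume",
    "RatioMap",
    "binarize_red",
    "edit_green",
    "sum_project",
    "compute_ratio",
    "ratio_from_stack",
]


@dataclass
class MaskVolume:
    """Binary axon mask for one timepoint's red z-stack."""

    voxels: np.ndarray  # bool, (Z, Y, X)
    threshold_used: float
    method: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.dtype != bool:
            raise ValueError("mask voxels must be boolean")


@dataclass
class RatioMap:
    """2-D green/red ratio with a validity mask (ratio undefined where red is dim)."""

    values: np.ndarray  # float, NaN where invalid
    valid: np.ndarray  # bool
    timepoint_index: int = 0
    min_red_used: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must have the same shape")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite wherever valid")


def binarize_red(
    red_zstack: np.ndarray,
    method: str = "otsu",
    manual_threshold: float | None = None,
) -> MaskVolume:
    """Threshold the red z-stack into a binary axon mask.

    Foreground is every voxel ``>= threshold``.  ``method`` is ``"otsu"``,
    ``"isodata"`` or ``"manual"`` (requires ``manual_threshold``).  A constant
    volume contains no object and yields an empty foreground.
    """
    red = np.asarray(red_zstack)
    if red.size == 0:
        raise ValueError("empty stack")
    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual method requires manual_threshold")
        thr = float(manual_threshold)
    elif red.min() == red.max():
        # no contrast: nothing to segment
        thr = float(red.max()) + 1.0
    elif method == "otsu":
        # skimage thresholds are "foreground > thr"; our convention is >=,
        # so nudge up by half the smallest level gap for integer data.
        thr = float(threshold_otsu(red))
        thr = np.nextafter(thr, np.inf)
    elif method == "isodata":
        thr = float(threshold_isodata(red))
        thr = np.nextafter(thr, np.inf)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return MaskVolume(voxels=red >= thr, threshold_used=thr, method=method)


def edit_green(
    green_zstack: np.ndarray, mask: MaskVolume, mode: str = "restrict"
) -> np.ndarray:
    """Apply the red-derived mask to the green z-stack (see module docstring)."""
    green = np.asarray(green_zstack)
    if green.shape != mask.voxels.shape:
        raise ValueError(
            f"shape mismatch: green {green.shape} vs mask {mask.voxels.shape}"
        )
    if mode == "restrict":
        return np.where(mask.voxels, green, 0)
    if mode == "literal_subtract":
        max_int = np.iinfo(green.dtype).max if np.issubdtype(green.dtype, np.integer) else green.max()
        out = green.astype(np.int64) - mask.voxels.astype(np.int64) * int(max_int)
        return np.clip(out, 0, None).astype(green.dtype)
    raise ValueError(f"unknown edit mode {mode!r}")


def sum_project(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel sum over z in a widened dtype (no 16-bit overflow)."""
    z = np.asarray(zstack)
    if z.ndim != 3 or z.shape[0] < 1:
        raise ValueError("zstack must be 3-D with >= 1 slice")
    acc = np.int64 if np.issubdtype(z.dtype, np.integer) else np.float64
    return z.sum(axis=0, dtype=acc)


def compute_ratio(
    green_sum: np.ndarray,
    red_sum: np.ndarray,
    min_red: float = 1.0,
    timepoint_index: int = 0,
) -> RatioMap:
    """green/red per pixel where red >= ``min_red``; invalid (NaN) elsewhere."""
    if min_red <= 0:
        raise ValueError("min_red must be positive")
    g = np.asarray(green_sum, dtype=float)
    r = np.asarray(red_sum, dtype=float)
    if g.shape != r.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {r.shape}")
    valid = r >= min_red
    values = np.full(g.shape, np.nan)
    np.divide(g, r, out=values, where=valid)
    return RatioMap(values=values, valid=valid, timepoint_index=timepoint_index,
                    min_red_used=float(min_red))


def ratio_from_stack(
    stack,
    timepoint: int,
    threshold_method: str = "otsu",
    manual_threshold: float | None = None,
    mask_mode: str = "restrict",
    min_red: float = 1.0,
) -> RatioMap:
    """Full one-timepoint chain: mask red, edit green, SUM-project, divide."""
    red = stack.red(timepoint)
    green = stack.green(timepoint)
    mask = binarize_red(red, method=threshold_method, manual_threshold=manual_threshold)
    edited = edit_green(green, mask, mode=mask_mode)
    return compute_ratio(
        sum_project(edited), sum_project(red), min_red=min_red, timepoint_index=timepoint
    )
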