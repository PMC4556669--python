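"""Sampling the ratio image along the retrograde trace and binning it.

The trace is re-supplied per timepoint and anchored at the current growth-cone
tip (the tip advances during the assay).  The first 150 unit-spaced trace
pixels are read off the ratio image and averaged in 15 consecutive 10-pixel
bins; those 15 bin means are the unit of all downstream statistics.

Pixel positions are labelled 1-based in outputs (bins "1-10" ... "141-150")
to match the field's convention, while array indexing stays 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image_io import TracePath
from .ratio_pipeline import RatioMap

__all__ = [
    "TraceTooShortError",
    "IntensityProfile",
    "BinnedProfile",
    "resample_trace",
    "sample_profile",
    "bin_profile",
]

DEFAULT_N_PIXELS = 150
DEFAULT_BIN_WIDTH = 10


class TraceTooShortError(ValueError):
    """Raised when a trace cannot supply the requested number of unit-spaced pixels."""


@dataclass
class IntensityProfile:
    """Ratio values at unit arc-length steps along the trace, tip first.

    ``positions_px`` are 1-based labels 1..N (pixel 1 = growth-cone tip);
    invalid ratio pixels appear as NaN.
    """

    values: np.ndarray
    timepoint_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("profile values must be 1-D")

    @property
    def n_pixels(self) -> int:
        return len(self.values)

    @property
    def positions_px(self) -> np.ndarray:
        return np.arange(1, len(self.values) + 1)


@dataclass
class BinnedProfile:
    """Bin means of a profile (NaN where a bin has no valid pixel)."""

    bin_means: np.ndarray
    bin_ranges: list  # [(1, 10), (11, 20), ...] 1-based inclusive pixel labels
    valid_counts: np.ndarray
    timepoint_index: int = 0

    def __post_init__(self) -> None:
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.valid_counts = np.asarray(self.valid_counts, dtype=int)
        if not (len(self.bin_means) == len(self.bin_ranges) == len(self.valid_counts)):
            raise ValueError("bin arrays must have equal length")

    @property
    def n_bins(self) -> int:
        return len(self.bin_means)

    @property
    def bin_centers_px(self) -> np.ndarray:
        """Bin-centre positions in 1-based pixel units: 5.5, 15.5, ..., 145.5."""
        return np.array([(a + b) / 2.0 for a, b in self.bin_ranges])


def resample_trace(
    trace: TracePath, step_px: float = 1.0, n_pixels: int = DEFAULT_N_PIXELS
) -> TracePath:
    """Resample a polyline at exact unit arc-length spacing from the tip.

    Point 1 is the tip itself (arc length 0); points follow retrogradely at
    ``step_px`` spacing, truncated to ``n_pixels``.  The result depends only
    on the underlying piecewise-linear curve, not on vertex density.
    """
    if step_px <= 0:
        raise ValueError("step_px must be positive")
    pts = trace.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    needed = (n_pixels - 1) * step_px
    if s[-1] + 1e-9 < needed:
        raise TraceTooShortError(
            f"trace too short: {s[-1]:.3f} px available, "
            f"{needed:.3f} px needed for {n_pixels} points"
        )
    targets = np.arange(n_pixels) * step_px
    y = np.interp(targets, s, pts[:, 0])
    x = np.interp(targets, s, pts[:, 1])
    return TracePath(
        points=np.column_stack([y, x]),
        timepoint_index=trace.timepoint_index,
        oriented_retrograde=trace.oriented_retrograde,
    )


def _bilinear(values: np.ndarray, valid: np.ndarray, yy: np.ndarray, xx: np.ndarray):
    ny, nx = values.shape
    y0 = np.clip(np.floor(yy).astype(int), 0, ny - 1)
    x0 = np.clip(np.floor(xx).astype(int), 0, nx - 1)
    y1 = np.minimum(y0 + 1, ny - 1)
    x1 = np.minimum(x0 + 1, nx - 1)
    wy = yy - y0
    wx = xx - x0
    out = (
        values[y0, x0] * (1 - wy) * (1 - wx)
        + values[y0, x1] * (1 - wy) * wx
        + values[y1, x0] * wy * (1 - wx)
        + values[y1, x1] * wy * wx
    )
    ok = valid[y0, x0] & valid[y0, x1] & valid[y1, x0] & valid[y1, x1]
    return np.where(ok, out, np.nan)


def sample_profile(
    ratio: RatioMap, trace: TracePath, interpolation: str = "nearest"
) -> IntensityProfile:
    """Read the ratio at each (already resampled) trace point.

    ``nearest`` replicates literal pixel lookup (the faithful default);
    ``bilinear`` interpolates for sub-pixel traces.  Invalid ratio pixels
    yield NaN entries.
    """
    yy, xx = trace.points[:, 0], trace.points[:, 1]
    ny, nx = ratio.values.shape
    ry, rx = np.rint(yy).astype(int), np.rint(xx).astype(int)
    if (ry < 0).any() or (ry >= ny).any() or (rx < 0).any() or (rx >= nx).any():
        bad = int(np.argmax((ry < 0) | (ry >= ny) | (rx < 0) | (rx >= nx)))
        raise ValueError(
            f"trace point {bad} at ({yy[bad]:.2f}, {xx[bad]:.2f}) is outside the "
            f"{ny}x{nx} image"
        )
    if interpolation == "nearest":
        vals = np.where(ratio.valid[ry, rx], ratio.values[ry, rx], np.nan)
    elif interpolation == "bilinear":
        vals = _bilinear(ratio.values, ratio.valid, yy, xx)
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return IntensityProfile(values=vals, timepoint_index=trace.timepoint_index)


def bin_profile(profile: IntensityProfile, width: int = DEFAULT_BIN_WIDTH) -> BinnedProfile:
    """Average each run of ``width`` consecutive pixels (bins 1-10, 11-20, ...).

    Means are taken over valid pixels only; an all-invalid bin is NaN with
    valid_count 0.  A trailing remainder shorter than ``width`` is dropped
    with a warning.
    """
    if width < 1:
        raise ValueError("bin width must be >= 1")
    n = profile.n_pixels
    n_bins = n // width
    if n_bins == 0:
        raise ValueError(f"profile of {n} pixels shorter than one bin of {width}")
    if n % width:
        warnings.warn(
            f"dropping trailing {n % width} pixels not filling a bin of {width}",
            stacklevel=2,
        )
    chunks = profile.values[: n_bins * width].reshape(n_bins, width)
    counts = np.sum(np.isfinite(chunks), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        means = np.nanmean(chunks, axis=1)
    ranges = [(i * width + 1, (i + 1) * width) for i in range(n_bins)]
    return BinnedProfile(
        bin_means=means,
        bin_ranges=ranges,
        valid_counts=counts,
        timepoint_index=profile.timepoint_index,
    )
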