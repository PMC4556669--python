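"""The two-level gradient statistic and group comparisons.

Level 1 (per axon, per timepoint): ordinary least squares of the 15 bin means
against bin-centre position (pixels 5.5, 15.5, ..., 145.5 from the growth-cone
tip).  A negative slope means the green/red ratio is enriched at the growth
cone.

Level 2 (per axon): OLS of those spatial slopes against time (minutes after
photoconversion, 0..90 at defaults).  This "gradient rate" is the headline
per-axon statistic: a negative rate means growth-cone enrichment increases
over the timelapse, the signature of local synthesis.

Group inference: one-way ANOVA with Tukey HSD on region means (growth cone =
bin 1, proximal = bin 15) at a chosen timepoint, and an exact two-sided
Mann-Whitney U test on the per-axon gradient rates (+UTR vs −UTR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .trace_quant import BinnedProfile

__all__ = [
    "GradientPoint",
    "AxonGradientRate",
    "GroupTestResult",
    "fit_spatial_gradient",
    "fit_gradient_rate",
    "region_summary",
    "anova_tukey",
    "mann_whitney_exact",
    "EXACT_ENUMERATION_MAX_N",
]

#: exact Mann-Whitney enumeration is used up to this combined sample size
#: (chosen so the 6-vs-10 axon design is always exact).
EXACT_ENUMERATION_MAX_N = 16


@dataclass
class GradientPoint:
    """Spatial gradient of the binned ratio profile at one timepoint."""

    timepoint_min: float
    slope: float  # ratio units per pixel
    intercept: float
    r_squared: float
    n_bins_used: int


@dataclass
class AxonGradientRate:
    """Rate of change of the spatial gradient for one axon (ratio·px⁻¹·min⁻¹)."""

    axon_id: str
    condition: str
    rate: float
    intercept: float
    n_timepoints_used: int


@dataclass
class GroupTestResult:
    test_name: str
    statistic: float
    p_value: float
    groups: list = field(default_factory=list)  # (label, n, mean, sem)
    pairwise: list = field(default_factory=list)  # (pair, significant, p_adj)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r² by the closed form; r² = 0 for constant y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    syy = np.sum((y - ym) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    if sxx == 0:
        raise ValueError("degenerate regression: no variation in x")
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return float(slope), float(intercept), float(r2)


def fit_spatial_gradient(
    binned: BinnedProfile,
    timepoint_min: float | None = None,
    position_unit: str = "px",
    pixel_size_um: float | None = None,
) -> GradientPoint:
    """OLS of bin means vs bin-centre position; >= 3 non-missing bins required.

    Positions are bin centres in pixels by default; ``position_unit="um"``
    (with ``pixel_size_um``) rescales the axis — a linear change that only
    rescales the slope, so group inference is unaffected.
    """
    x = binned.bin_centers_px.astype(float)
    if position_unit == "um":
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required for position_unit='um'")
        x = x * pixel_size_um
    elif position_unit != "px":
        raise ValueError(f"unknown position unit {position_unit!r}")
    y = binned.bin_means
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 non-missing bins, got {int(ok.sum())}")
    slope, intercept, r2 = _ols(x[ok], y[ok])
    return GradientPoint(
        timepoint_min=float(timepoint_min) if timepoint_min is not None else float("nan"),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_bins_used=int(ok.sum()),
    )


def fit_gradient_rate(
    series: list[GradientPoint], condition: str = "", axon_id: str = ""
) -> AxonGradientRate:
    """OLS of spatial-gradient slope vs time (minutes) for one axon."""
    t = np.array([g.timepoint_min for g in series], dtype=float)
    y = np.array([g.slope for g in series], dtype=float)
    if len(t) < 3:
        raise ValueError(f"need >= 3 timepoints, got {len(t)}")
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate timepoints in gradient series")
    rate, intercept, _ = _ols(t, y)
    return AxonGradientRate(
        axon_id=axon_id,
        condition=condition,
        rate=rate,
        intercept=intercept,
        n_timepoints_used=len(t),
    )


def region_summary(
    binned_by_timepoint: list[BinnedProfile],
    region: str,
    frame_interval_min: float | None = None,
) -> np.ndarray:
    """Per-timepoint region mean: growth cone = bin 1, proximal = last bin.

    Returns the time series of region means in timepoint order; pair with
    ``frame_interval_min`` (if given the times are returned alongside as a
    second array).
    """
    idx = {"growth_cone": 0, "proximal": -1}
    if region not in idx:
        raise ValueError("region must be 'growth_cone' or 'proximal'")
    ordered = sorted(binned_by_timepoint, key=lambda b: b.timepoint_index)
    vals = np.array([b.bin_means[idx[region]] for b in ordered])
    if frame_interval_min is None:
        return vals
    times = np.array([b.timepoint_index * frame_interval_min for b in ordered])
    return np.column_stack([times, vals])


def anova_tukey(groups: dict, alpha: float = 0.05) -> GroupTestResult:
    """One-way ANOVA over >= 3 labelled groups with Tukey-Kramer HSD pairwise flags."""
    if len(groups) < 3:
        raise ValueError("need >= 3 groups for ANOVA + Tukey")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {label!r} has n < 2")
    f_stat, p = stats.f_oneway(*arrays.values())
    if not np.isfinite(f_stat):  # all groups identical and constant
        f_stat, p = 0.0, 1.0
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pair_index = [
        (i, j)
        for i in range(len(tk.groupsunique))
        for j in range(i + 1, len(tk.groupsunique))
    ]
    pairwise = [
        ((str(tk.groupsunique[i]), str(tk.groupsunique[j])), bool(r), float(pa))
        for (i, j), r, pa in zip(pair_index, tk.reject, tk.pvalues)
    ]
    summary = [
        (k, len(a), float(a.mean()), float(stats.sem(a)) if len(a) > 1 else float("nan"))
        for k, a in arrays.items()
    ]
    return GroupTestResult(
        test_name="one-way ANOVA + Tukey HSD",
        statistic=float(f_stat),
        p_value=float(min(max(p, 0.0), 1.0)),
        groups=summary,
        pairwise=pairwise,
    )


def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank assignments giving each U value, U = 0..n1*n2.

    Classic recurrence c(n1, n2, u) = c(n1-1, n2, u-n2) + c(n1, n2-1, u):
    the largest rank belongs either to sample 1 (contributing n2 to U) or to
    sample 2.  Total over u is C(n1+n2, n1).
    """
    table = {(0, 0): np.array([1.0])}
    for a in range(n1 + 1):
        for b in range(n2 + 1):
            if (a, b) in table:
                continue
            size = a * b + 1
            c = np.zeros(size)
            if a > 0:
                prev = table[(a - 1, b)]
                c[b : b + len(prev)] += prev[: max(size - b, 0)]
            if b > 0:
                prev = table[(a, b - 1)]
                c[: len(prev)] += prev[:size]
            table[(a, b)] = c
    return table[(n1, n2)]


def mann_whitney_exact(a, b, alternative: str = "two-sided") -> GroupTestResult:
    """Mann-Whitney U with an exact two-sided p for small tie-free samples.

    For combined n <= EXACT_ENUMERATION_MAX_N and no ties, the p-value is
    exact: the proportion of the C(n, n_a) equally likely rank assignments
    whose U is at least as far from the null mean n_a·n_b/2 as observed.
    Larger or tied samples fall back to the tie-corrected normal
    approximation (with continuity correction).  U reported is U of the
    first sample (number of (a, b) pairs with a > b, ties counting 1/2).
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) != len(pooled)
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 + n2 <= EXACT_ENUMERATION_MAX_N and not has_ties:
        counts = _u_counts(n1, n2)
        mu = n1 * n2 / 2.0
        dev = abs(u1 - mu)
        us = np.arange(len(counts))
        p = counts[np.abs(us - mu) >= dev - 1e-9].sum() / comb(n1 + n2, n1)
        method = "exact enumeration"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal approximation (tie-corrected)"

    summary = [
        ("a", n1, float(a.mean()), float(stats.sem(a)) if n1 > 1 else float("nan")),
        ("b", n2, float(b.mean()), float(stats.sem(b)) if n2 > 1 else float("nan")),
    ]
    return GroupTestResult(
        test_name=f"Mann-Whitney U ({method})",
        statistic=u1,
        p_value=float(min(p, 1.0)),
        groups=summary,
    )
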