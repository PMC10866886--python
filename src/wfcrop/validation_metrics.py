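"""Statistics for comparing two gridded datasets.

Used to benchmark one gridded product against another: the fraction of
cells with counterpart values (after excluding cells below a minimum,
50 mm for CWU comparisons), (area- or production-weighted) Pearson
correlation over the matching cells, and the median of grid-level
relative differences with respect to the reference dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ComparisonReport", "matching_cells", "pearson",
           "median_relative_difference", "percentile_clip", "compare_grids"]


@dataclass(frozen=True)
class ComparisonReport:
    matching_fraction_pct: float
    pearson_r: float
    weighted_pearson_r: float
    median_relative_difference_pct: float
    n_matching: int

    def to_dict(self):
        return asdict(self)


def matching_cells(ours, theirs, threshold: float = 0.0):
    """Boolean mask of cells defined and >= threshold in both datasets,
    plus the matching percentage relative to cells defined in ``ours``."""
    a = np.asarray(ours, dtype=float)
    b = np.asarray(theirs, dtype=float)
    if a.shape != b.shape:
        raise ValueError("grids must share a shape")
    ours_defined = np.isfinite(a) & (a >= threshold)
    match = ours_defined & np.isfinite(b) & (b >= threshold)
    n_ours = int(ours_defined.sum())
    fraction = 100.0 * match.sum() / n_ours if n_ours else 0.0
    return match, float(fraction)


def pearson(x, y, weights=None) -> float:
    """(Weighted) product-moment correlation coefficient.

    With equal weights this reduces to the ordinary Pearson r. Fewer than
    two pairs or zero variance yield NaN (reported as missing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        return float("nan")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    mx = np.average(x, weights=w)
    my = np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y - my) ** 2, weights=w)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(cov / np.sqrt(vx * vy))


def median_relative_difference(ours, theirs) -> float:
    """Median over cells of 100 x (ours - theirs) / theirs (%).

    Cells where the reference is zero are excluded. Invariant to scaling
    both datasets by a common positive constant.
    """
    a = np.asarray(ours, dtype=float).ravel()
    b = np.asarray(theirs, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(b) & (b != 0)
    if not ok.any():
        return float("nan")
    return float(np.median(100.0 * (a[ok] - b[ok]) / b[ok]))


def percentile_clip(values, lower: float = 1.0, upper: float = 99.0):
    """Mask extreme values outside the symmetric percentile band."""
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size == 0:
        return v
    lo, hi = np.percentile(finite, [lower, upper])
    out = v.copy()
    out[(v < lo) | (v > hi)] = np.nan
    return out


def compare_grids(ours, theirs, threshold: float = 0.0,
                  weights=None, clip_extremes: bool = False) -> ComparisonReport:
    """Full comparison of two same-grid datasets."""
    a = np.asarray(ours, dtype=float)
    b = np.asarray(theirs, dtype=float)
    if clip_extremes:
        a = percentile_clip(a)
        b = percentile_clip(b)
    match, fraction = matching_cells(a, b, threshold)
    x, y = a[match], b[match]
    w = None if weights is None else np.asarray(weights, dtype=float)[match]
    return ComparisonReport(
        matching_fraction_pct=fraction,
        pearson_r=pearson(x, y) if x.size >= 2 else float("nan"),
        weighted_pearson_r=pearson(x, y, w) if x.size >= 2 else float("nan"),
        median_relative_difference_pct=median_relative_difference(x, y),
        n_matching=int(match.sum()),
    )
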