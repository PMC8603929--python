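"""Per-VOI summaries and the statistical comparisons run on parametric maps.

Summaries are per-region mean/sd/median over valid voxels.  Cross-region and
longitudinal comparisons use Welch's unequal-variance two-tailed t-test
(Welch–Satterthwaite degrees of freedom); the association between mean
diffusivity and conductivity uses Pearson's r with the usual t-distributed
two-sided p-value.  Raw p-values are reported; Holm correction is available
but off by default.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .grids import ConductivityMap, MDMap, VOISet

SUMMARY_COLUMNS = ["region", "day", "map_name", "n_voxels", "mean", "sd", "median"]
TEST_COLUMNS = ["region", "map_name", "group_a", "group_b", "t", "dof", "p"]


def region_summary(
    parametric_map: ConductivityMap | MDMap,
    vois: VOISet,
    map_name: str = "map",
    day: int | None = None,
) -> pd.DataFrame:
    """Mean/sd/median of a map over each VOI (masked-invalid voxels excluded).

    Empty regions are reported with n_voxels = 0 and NaN statistics.  The sd
    uses the n−1 denominator.
    """
    if vois.labels.shape != parametric_map.values.shape:
        raise ValueError("map and VOI grids differ")
    rows = []
    day = day if day is not None else vois.day
    for lab_id in sorted(vois.label_names):
        name = vois.label_names[lab_id]
        sel = (vois.labels == lab_id) & parametric_map.mask
        vals = parametric_map.values[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            rows.append(
                (name, day, map_name, int(vals.size), float(vals.mean()),
                 float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                 float(np.median(vals)))
            )
        else:
            rows.append((name, day, map_name, 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def region_values(
    parametric_map: ConductivityMap | MDMap, vois: VOISet
) -> dict[str, np.ndarray]:
    """Valid voxel values of the map per region name."""
    out = {}
    for lab_id, name in sorted(vois.label_names.items()):
        sel = (vois.labels == lab_id) & parametric_map.mask
        vals = parametric_map.values[sel]
        out[name] = vals[np.isfinite(vals)]
    return out


def ttest_two_tailed(a, b) -> tuple[float, float, float]:
    """Welch's two-tailed t-test: returns (t, dof, p).

    Degrees of freedom by Welch–Satterthwaite; p two-sided from the Student-t
    survival function.  Zero variance in both samples with equal means gives
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, float(a.size + b.size - 2), 0.0
    sea, seb = va / a.size, vb / b.size
    dof = (sea + seb) ** 2 / (sea**2 / (a.size - 1) + seb**2 / (b.size - 1))
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(dof), float(res.pvalue)


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p via t = r√((n−2)/(1−r²))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_corr needs >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("pairs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def cross_region_tests(
    values_by_region: dict[str, np.ndarray],
    reference: str = "contralateral_cortex",
    map_name: str = "map",
) -> pd.DataFrame:
    """Welch tests of every region against the reference region."""
    rows = []
    ref_vals = values_by_region.get(reference)
    if ref_vals is None or ref_vals.size < 2:
        raise ValueError(f"reference region {reference!r} missing or too small")
    for name, vals in values_by_region.items():
        if name == reference or vals.size < 2:
            continue
        t, dof, p = ttest_two_tailed(vals, ref_vals)
        rows.append((name, map_name, name, reference, t, dof, p))
    return pd.DataFrame(rows, columns=TEST_COLUMNS)


def longitudinal_compare(
    values_by_day: dict[int, dict[str, np.ndarray]],
    map_name: str = "map",
) -> pd.DataFrame:
    """Welch tests between every pair of days, per region.

    ``values_by_day`` maps day → region → sample values.  A single day yields
    no records (warning).  The unit of analysis is whatever the caller pooled
    into the samples (animal means or voxels).
    """
    days = sorted(values_by_day)
    if len(days) < 2:
        warnings.warn("longitudinal comparison needs >= 2 days", stacklevel=2)
        return pd.DataFrame(columns=TEST_COLUMNS)
    rows = []
    regions = sorted({r for d in days for r in values_by_day[d]})
    for region in regions:
        for da, db in combinations(days, 2):
            va = values_by_day[da].get(region)
            vb = values_by_day[db].get(region)
            if va is None or vb is None or va.size < 2 or vb.size < 2:
                continue
            t, dof, p = ttest_two_tailed(va, vb)
            rows.append((region, map_name, f"day{da}", f"day{db}", t, dof, p))
    return pd.DataFrame(rows, columns=TEST_COLUMNS)


def holm_correction(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def md_sigma_correlation(
    md_values: dict[str, np.ndarray], sigma_values: dict[str, np.ndarray]
) -> tuple[float, float]:
    """Pearson correlation between region-pooled MD and conductivity.

    Pools the per-region samples (truncated to matched length per region,
    voxel order) across all regions, the grouping used for the global
    MD-vs-σ association.
    """
    xs, ys = [], []
    for name in md_values:
        if name not in sigma_values:
            continue
        n = min(md_values[name].size, sigma_values[name].size)
        if n == 0:
            continue
        xs.append(md_values[name][:n])
        ys.append(sigma_values[name][:n])
    return pearson_corr(np.concatenate(xs), np.concatenate(ys))
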