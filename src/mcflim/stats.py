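"""Descriptive statistics and non-parametric population comparison.

Group distributions of the FLIM parameters are summarized as mean +-
standard deviation and compared with the two-sample Kolmogorov-Smirnov
test (asymptotic p-values with the standard effective-sample-size
correction; p < 0.05 is flagged significant).  No multiple-testing
correction is applied; the number of flagged comparisons is reported so
callers can apply their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: FLIM parameters compared between populations
COMPARE_PARAMS = ("tau1", "tau2", "tau_m", "ratio", "asym", "intensity")

SCATTER_PAIRS = {
    "tau1_tau2": ("tau1", "tau2"),
    "tau1_ratio": ("tau1", "ratio"),
    "tau2_ratio": ("tau2", "ratio"),
    "tau2_asym": ("tau2", "asym"),
}


@dataclass
class SampleSummary:
    n: int
    mean: float
    sd: float

    @classmethod
    def of(cls, values) -> "SampleSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 1:
            raise ValueError("summary of an empty sample")
        return cls(n=int(v.size), mean=float(v.mean()), sd=float(v.std(ddof=1)) if v.size > 1 else 0.0)


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS statistic D = sup |Fx - Fy| and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("KS test needs at least two observations per sample")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def population_compare(cohort: pd.DataFrame, group_col: str, group_a, group_b,
                       params=COMPARE_PARAMS, alpha: float = 0.05) -> pd.DataFrame:
    """Compare two groups of a cohort parameter-by-parameter.

    Returns one row per parameter with group means +- SD, the KS statistic,
    p-value and a significance flag at ``alpha``.
    """
    a = cohort[cohort[group_col] == group_a]
    b = cohort[cohort[group_col] == group_b]
    if a.empty or b.empty:
        raise ValueError("both groups must be present in the cohort")
    rows = []
    for param in params:
        if param not in cohort.columns:
            raise ValueError(f"unknown parameter {param!r}")
        sa = SampleSummary.of(a[param])
        sb = SampleSummary.of(b[param])
        d, p = ks_two_sample(a[param], b[param])
        rows.append({
            "parameter": param,
            "group_a": group_a, "n_a": sa.n, "mean_a": sa.mean, "sd_a": sa.sd,
            "group_b": group_b, "n_b": sb.n, "mean_b": sb.mean, "sd_b": sb.sd,
            "ks_d": d, "p_value": p, "significant": bool(p < alpha),
        })
    out = pd.DataFrame(rows)
    out.attrs["n_significant"] = int(out["significant"].sum())
    return out


def segmentation_scatter(cohort: pd.DataFrame, pair: str,
                         group_col: str = "label3") -> dict:
    """Grouped 2-D coordinates plus centroid/covariance per group for one
    parameter pair used for 2-D segmentation plots."""
    if pair not in SCATTER_PAIRS:
        raise ValueError(f"unsupported pair {pair!r}; choose from {sorted(SCATTER_PAIRS)}")
    xcol, ycol = SCATTER_PAIRS[pair]
    out = {}
    for group, sub in cohort.groupby(group_col):
        pts = sub[[xcol, ycol]].to_numpy(dtype=float)
        entry = {"points": pts}
        if pts.shape[0] >= 1:
            entry["centroid"] = pts.mean(axis=0)
            entry["cov"] = (np.cov(pts.T) if pts.shape[0] > 1
                            else np.zeros((2, 2)))
        out[group] = entry
    return out
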