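"""Differential expression against the never-smoker baseline.

The analysis chain is: detection filtering (probe must be called detected in
at least 20% of samples of at least one group), exclusion of age-correlated
probes (simple regression on age, BH FDR 0.1), then a per-probe two-sample
t-test of a smoking group versus never smokers with Benjamini-Hochberg
correction and fold-change classification (over-expressed if the linear ratio
2^(mean difference of log2 values) exceeds 1.2, under-expressed below 0.8,
gated on the FDR threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, InputError, check_sample_table

__all__ = [
    "detection_filter",
    "welch_t",
    "bh_fdr",
    "age_exclusion",
    "DifferentialExpression",
    "DifferentialExpressionResults",
]


def detection_filter(x: ExpressionMatrix, samples: pd.DataFrame, frac: float = 0.2) -> pd.Index:
    """Probe ids detected in >= ``frac`` of samples of at least one group."""
    if x.detection is None:
        raise InputError("detection flags required for detection filtering")
    samples = check_sample_table(samples)
    det = x.detection[samples.index]
    keep = np.zeros(det.shape[0], dtype=bool)
    for _, members in samples.groupby("group").groups.items():
        frac_det = det[list(members)].mean(axis=1).to_numpy()
        keep |= frac_det >= frac
    return x.probes[keep]


def welch_t(a, b, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; Welch by default.

    Returns (t, df, p).  Two identical constant groups give (0, df, 1) rather
    than NaN so that flat probes never rank as significant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return 0.0, float(df), 1.0
        raise InputError("both groups constant with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _regress_on_covariate(values: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Two-sided p for the slope of each row of ``values`` on ``cov``."""
    n = cov.size
    cz = cov - cov.mean()
    sxx = float(cz @ cz)
    if sxx == 0:
        raise InputError("covariate is constant")
    yc = values - values.mean(axis=1, keepdims=True)
    syy = (yc * yc).sum(axis=1)
    sxy = yc @ cz
    # rows with zero variance: slope 0, p 1
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(syy > 0, sxy * sxy / (sxx * syy), 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        t2 = r2 * (n - 2) / np.maximum(1.0 - r2, np.finfo(float).tiny)
    p = 2.0 * stats.t.sf(np.sqrt(t2), df=n - 2)
    return np.clip(p, 0.0, 1.0)


def age_exclusion(x: ExpressionMatrix, samples: pd.DataFrame, fdr: float = 0.1) -> pd.Index:
    """Probes whose expression regresses on age at BH q <= ``fdr``.

    The returned probes are removed before differential expression so that a
    group-age confound (cancer patients are older) cannot masquerade as a
    smoking/cancer expression difference.
    """
    samples = check_sample_table(samples)
    if "age" not in samples.columns or samples["age"].isna().any():
        raise InputError("ages required for all samples")
    age = samples["age"].to_numpy(dtype=float)
    vals = x.values[samples.index].to_numpy(dtype=float)
    p = _regress_on_covariate(vals, age)
    q = bh_fdr(p)
    return x.probes[q <= fdr]


@dataclass
class DifferentialExpressionResults:
    """Per-probe test results; ``table`` columns: mean_baseline, mean_target,
    t, df, p, q, fold_change, de_class."""

    table: pd.DataFrame
    baseline: str
    target: str
    fdr: float
    n_filtered_detection: int
    n_filtered_age: int

    @property
    def n_significant(self) -> int:
        return int((self.table["q"] <= self.fdr).sum())

    @property
    def n_over(self) -> int:
        return int((self.table["de_class"] == "over").sum())

    @property
    def n_under(self) -> int:
        return int((self.table["de_class"] == "under").sum())

    def summary(self) -> str:
        lines = [
            f"Differential expression: {self.target} vs {self.baseline} (FDR {self.fdr})",
            f"  probes tested:        {len(self.table)}",
            f"  removed by detection: {self.n_filtered_detection}",
            f"  removed by age:       {self.n_filtered_age}",
            f"  significant (q<=fdr): {self.n_significant}",
            f"  over-expressed  (fc > 1.2): {self.n_over}",
            f"  under-expressed (fc < 0.8): {self.n_under}",
        ]
        return "\n".join(lines)


class DifferentialExpression:
    """Model object for group-vs-baseline differential expression.

    Parameters
    ----------
    x : ExpressionMatrix
    samples : DataFrame indexed by sample id with 'group' (and 'age' if age
        exclusion is requested).
    baseline, target : group labels; the fold change is target over baseline.
    equal_var : use the pooled-variance t-test instead of Welch.
    """

    def __init__(self, x: ExpressionMatrix, samples: pd.DataFrame,
                 baseline: str = "NS", target: str = "SNC", equal_var: bool = False):
        self.x = x
        self.samples = check_sample_table(samples)
        self.baseline = baseline
        self.target = target
        self.equal_var = equal_var
        for g in (baseline, target):
            if (self.samples["group"] == g).sum() < 2:
                raise InputError(f"group {g!r} needs at least 2 samples")

    def fit(self, fdr: float = 0.1, detection_frac: float | None = 0.2,
            age_fdr: float | None = 0.1,
            fc_over: float = 1.2, fc_under: float = 0.8) -> DifferentialExpressionResults:
        x = self.x
        n_det = n_age = 0
        if detection_frac is not None and x.detection is not None:
            keep = detection_filter(x, self.samples, detection_frac)
            n_det = len(x.probes) - len(keep)
            x = x.subset_probes(keep)
        if age_fdr is not None and "age" in self.samples.columns:
            drop = age_exclusion(x, self.samples, age_fdr)
            n_age = len(drop)
            x = x.subset_probes(x.probes.difference(drop, sort=False))

        grp = self.samples["group"]
        a = x.values[grp.index[grp == self.target]].to_numpy(dtype=float)
        b = x.values[grp.index[grp == self.baseline]].to_numpy(dtype=float)
        res = stats.ttest_ind(a, b, axis=1, equal_var=self.equal_var)
        t = np.asarray(res.statistic, dtype=float)
        df = np.asarray(res.df, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        flat = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0) \
            & (a.mean(axis=1) == b.mean(axis=1))
        t[flat], p[flat] = 0.0, 1.0
        q = bh_fdr(p)
        diff = a.mean(axis=1) - b.mean(axis=1)
        fc = np.exp2(diff)
        de_class = np.where(
            q <= fdr,
            np.where(fc > fc_over, "over", np.where(fc < fc_under, "under", "neither")),
            "neither",
        )
        table = pd.DataFrame(
            {
                "mean_baseline": b.mean(axis=1),
                "mean_target": a.mean(axis=1),
                "t": t,
                "df": df,
                "p": p,
                "q": q,
                "fold_change": fc,
                "de_class": de_class,
            },
            index=x.probes,
        )
        return DifferentialExpressionResults(table, self.baseline, self.target, fdr, n_det, n_age)
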