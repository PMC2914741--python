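"""Phenotype-facing tests and the three-way integration report.

Three association axes are combined per (SNP, probe) pair: cis-eQTL
(genotype -> expression, min-p corrected), logistic regression of cancer
status on expression (min-p corrected over the probe family), and Fisher's
exact test of the genotype-by-status table.  A pair where all three axes are
significant and the directions are mutually consistent (the
expression-raising genotype is enriched in the group whose status the higher
expression predicts) is the strongest, tier-1 evidence for a SNP acting on
disease through expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, InputError
from .expression import welch_t  # noqa: F401  (summary/raw consistency pair)

__all__ = [
    "fisher_exact",
    "summary_ttest",
    "genotype_status_fisher",
    "ExpressionStatus",
    "ExpressionStatusResults",
    "build_integration_report",
    "cohort_table",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fisher's exact test, r x c, probability-mass two-sided definition
# ---------------------------------------------------------------------------

def _enumerate_tables(row_sums, col_remaining, row_idx, current, out):
    """Recursively enumerate tables with the given margins."""
    r = len(row_sums)
    if row_idx == r - 1:
        last = list(col_remaining)
        if all(v >= 0 for v in last) and sum(last) == row_sums[-1]:
            out(current + [last])
        return
    _fill_row(row_sums[row_idx], col_remaining, [], 0,
              lambda row: _enumerate_tables(
                  row_sums,
                  tuple(c - v for c, v in zip(col_remaining, row)),
                  row_idx + 1, current + [row], out))


def _fill_row(remaining, col_remaining, row, j, cont):
    c = len(col_remaining)
    if j == c - 1:
        if 0 <= remaining <= col_remaining[-1]:
            cont(row + [remaining])
        return
    hi = min(remaining, col_remaining[j])
    for v in range(hi + 1):
        _fill_row(remaining - v, col_remaining, row + [v], j + 1, cont)


def _table_weight(cells) -> int:
    """Integer weight proportional to the conditional table probability:
    n! / prod(cell!)."""
    n = sum(cells)
    w = math.factorial(n)
    for v in cells:
        w //= math.factorial(v)
    return w


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for an r x c count table.

    The two-sided p is the probability-mass criterion: the sum, over all
    tables with the observed margins, of probabilities no larger than the
    observed table's.  2x2 tables use the hypergeometric closed form; larger
    tables are enumerated.  Rows/columns with zero margin are dropped (with a
    log message) before testing; a table left with a single row or column has
    p = 1.  Exact integer arithmetic throughout.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or (t < 0).any():
        raise InputError("table must be a 2-D array of non-negative counts")
    rs, cs = t.sum(axis=1), t.sum(axis=0)
    if (rs == 0).any() or (cs == 0).any():
        log.info("dropping empty rows/columns from contingency table")
        t = t[rs > 0][:, cs > 0]
        if t.size == 0 or min(t.shape) < 2:
            return 1.0
        rs, cs = t.sum(axis=1), t.sum(axis=0)
    if t.shape == (2, 2):
        r1, r2 = int(rs[0]), int(rs[1])
        c1 = int(cs[0])
        a_obs = int(t[0, 0])
        lo, hi = max(0, c1 - r2), min(r1, c1)
        weights = {a: math.comb(r1, a) * math.comb(r2, c1 - a)
                   for a in range(lo, hi + 1)}
        w_obs = weights[a_obs]
        num = sum(w for w in weights.values() if w <= w_obs)
        return float(Fraction(num, sum(weights.values())))

    w_obs = _table_weight(t.ravel().tolist())
    acc = {"num": 0, "den": 0}

    def collect(rows):
        w = _table_weight([v for row in rows for v in row])
        acc["den"] += w
        if w <= w_obs:
            acc["num"] += w

    _enumerate_tables(tuple(int(v) for v in rs), tuple(int(v) for v in cs),
                      0, [], collect)
    return float(Fraction(acc["num"], acc["den"]))


def genotype_status_fisher(dosage, status, collapse: str | None = None
                           ) -> tuple[pd.DataFrame, float]:
    """Fisher exact test of genotype counts against a binary status.

    ``collapse`` = None tests the 2 x 3 genotypic table; "dominant" collapses
    carriers (1 or 2 copies) against non-carriers; "recessive" collapses
    minor-allele homozygotes against the rest.  Returns (table, p).
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status)
    keep = ~np.isnan(dosage)
    dosage, status = dosage[keep], status[keep]
    levels = list(pd.unique(status))
    if len(levels) != 2:
        raise InputError("status must be binary")
    if collapse == "dominant":
        geno = (dosage > 0).astype(int)
        cols = ["0", "1/2"]
    elif collapse == "recessive":
        geno = (dosage == 2).astype(int)
        cols = ["0/1", "2"]
    elif collapse is None:
        geno = dosage.astype(int)
        cols = ["0", "1", "2"]
    else:
        raise ConfigError(f"unknown collapse mode {collapse!r}")
    tab = np.zeros((2, len(cols)), dtype=int)
    for i, lev in enumerate(levels):
        for j in range(len(cols)):
            tab[i, j] = int(((status == lev) & (geno == j)).sum())
    df = pd.DataFrame(tab, index=[str(l) for l in levels], columns=cols)
    return df, fisher_exact(tab)


# ---------------------------------------------------------------------------
# Welch t from summary statistics (Table-1-style comparisons)
# ---------------------------------------------------------------------------

def summary_ttest(mean1: float, sd1: float, n1: int,
                  mean2: float, sd2: float, n2: int) -> tuple[float, float, float]:
    """Welch t-test from group summary statistics: (t, df, two-sided p)."""
    if sd1 <= 0 or sd2 <= 0:
        raise InputError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise InputError("each group needs n >= 2")
    v1, v2 = sd1 * sd1 / n1, sd2 * sd2 / n2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


# ---------------------------------------------------------------------------
# Logistic regression of status on expression, min-p corrected
# ---------------------------------------------------------------------------

_SEP_BETA = 30.0  # |slope| beyond this on standardized x flags separation


def _logit_fit_rows(y01: np.ndarray, X: np.ndarray, max_iter: int = 40,
                    tol: float = 1e-9, ridge: float = 0.0):
    """Vectorised univariate logistic ML fit of y on each row of X.

    Returns (beta0, beta1, llf, converged).  ``ridge`` adds an L2 penalty on
    the slope (separation fallback).
    """
    G, n = X.shape
    b0 = np.zeros(G)
    b1 = np.zeros(G)
    ok = np.zeros(G, dtype=bool)
    from scipy.special import expit

    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * X
        mu = expit(eta)
        w = mu * (1 - mu)
        r = y01[None, :] - mu
        g0 = r.sum(axis=1)
        g1 = (r * X).sum(axis=1) - ridge * b1
        h00 = w.sum(axis=1)
        h01 = (w * X).sum(axis=1)
        h11 = (w * X * X).sum(axis=1) + ridge
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        step = np.clip(np.stack([db0, db1]), -5.0, 5.0)
        b0 += step[0]
        b1 += step[1]
        ok = (np.abs(g0) < tol * n) & (np.abs(g1) < tol * n)
        if ok.all():
            break
    eta = b0[:, None] + b1[:, None] * X
    llf = (y01[None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=1)
    if ridge > 0:
        llf -= 0.5 * ridge * b1 * b1
    return b0, b1, llf, ok


def _logistic_p_matrix(y01: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Likelihood-ratio p per row of X (standardised internally), with an L2
    fallback where the unpenalised fit separates."""
    Xz = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    Xz = Xz / sd
    pbar = y01.mean()
    n = y01.size
    ll0 = n * (pbar * np.log(pbar) + (1 - pbar) * np.log1p(-pbar)) \
        if 0 < pbar < 1 else 0.0
    _, b1, llf, ok = _logit_fit_rows(y01, Xz)
    sep = (~ok) | (np.abs(b1) > _SEP_BETA)
    if sep.any():
        _, b1p, llfp, _ = _logit_fit_rows(y01, Xz[sep], ridge=0.5)
        llf = llf.copy()
        llf[sep] = llfp
        b1 = b1.copy()
        b1[sep] = b1p
    lr = np.maximum(2 * (llf - ll0), 0.0)
    p = stats.chi2.sf(lr, df=1)
    return np.clip(p, 0.0, 1.0), b1 / sd.ravel(), sep


@dataclass
class ExpressionStatusResults:
    """Logistic expression-status results; ``table`` columns: beta, p,
    p_corrected, separation (indexed by probe)."""

    table: pd.DataFrame
    nperm: int

    def summary(self) -> str:
        sig = (self.table["p_corrected"] <= 0.05).sum()
        return (f"Logistic expression-status: {len(self.table)} probes, "
                f"{self.nperm} status permutations, "
                f"{sig} with corrected p <= 0.05")


class ExpressionStatus:
    """Logistic regression of cancer status on per-probe log2 expression.

    Parameters
    ----------
    x : ExpressionMatrix restricted to smokers.
    status : binary labels over x.samples (e.g. SC / SNC); the first level in
        ``case`` order is modelled as the event.
    case : label to model as the event (default: "SC" if present).
    """

    def __init__(self, x, status, case: str | None = None):
        self.x = x
        status = pd.Series(np.asarray(status), index=x.samples)
        levels = list(pd.unique(status))
        if len(levels) != 2:
            raise InputError("status must be binary")
        if case is None:
            case = "SC" if "SC" in levels else str(levels[0])
        self.case = case
        self.y01 = (status == case).to_numpy(dtype=float)
        if self.y01.sum() < 3 or (1 - self.y01).sum() < 3:
            raise InputError("each status needs at least 3 samples")

    def fit(self, nperm: int = 10_000, seed: int | None = None) -> ExpressionStatusResults:
        if nperm < 100:
            raise ConfigError("nperm < 100 gives unstable min-p tails")
        rng = np.random.default_rng(seed)
        X = self.x.values.to_numpy(dtype=float)
        p_obs, beta, sep = _logistic_p_matrix(self.y01, X)
        min_p = np.empty(nperm)
        for i in range(nperm):
            yp = rng.permutation(self.y01)
            pp, _, _ = _logistic_p_matrix(yp, X)
            min_p[i] = pp.min()
        corrected = (1 + (min_p[:, None] <= p_obs[None, :]).sum(axis=0)) / (nperm + 1)
        table = pd.DataFrame(
            {"beta": beta, "p": p_obs, "p_corrected": corrected,
             "separation": sep},
            index=self.x.probes,
        )
        return ExpressionStatusResults(table, nperm)


# ---------------------------------------------------------------------------
# Three-way integration
# ---------------------------------------------------------------------------

DIRECTION_NOTE = """\
Direction consistency: let b_e = eQTL slope (log2 expression per minor
allele), b_l = logistic slope (case log-odds per log2 expression unit) and
df = minor-allele frequency difference (cases - controls).  The minor allele
is predicted to shift case log-odds by sign(b_e * b_l); the configuration is
consistent when sign(df) equals that prediction (a risk-predicted allele is
more common in cases, a protective-predicted allele less common).  Zero
signs are inconsistent."""


def direction_consistent(beta_eqtl: float, beta_logit: float,
                         freq_diff: float) -> bool:
    pred = np.sign(beta_eqtl) * np.sign(beta_logit)
    return bool(pred != 0 and np.sign(freq_diff) == pred)


def build_integration_report(eqtl: pd.DataFrame, pheno: pd.DataFrame,
                             geno_pheno: pd.DataFrame,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Join the three association axes and assign evidence tiers.

    Parameters
    ----------
    eqtl : columns snp, probe, beta, p_corrected  (cis-eQTL results).
    pheno : columns probe, beta, p_corrected      (expression-status).
    geno_pheno : columns snp, p, maf_case, maf_control (genotype-status).
    alpha : significance level applied to corrected p-values.

    Tier 1: all three tests <= alpha and direction-consistent; tier 2: eQTL
    plus at least one phenotype test (or all three but direction-
    inconsistent); tier 3: eQTL only; pairs whose eQTL test fails alpha get
    no tier.  Sorted by tier then eQTL corrected p.
    """
    if len(eqtl) == 0:
        return pd.DataFrame(columns=["snp", "probe", "eqtl_p", "expr_status_p",
                                     "geno_status_p", "direction_consistent",
                                     "tier"])
    df = eqtl.rename(columns={"p_corrected": "eqtl_p", "beta": "eqtl_beta"})
    df = df.merge(pheno.rename(columns={"p_corrected": "expr_status_p",
                                        "beta": "logit_beta"}),
                  on="probe", how="left")
    df = df.merge(geno_pheno.rename(columns={"p": "geno_status_p"}),
                  on="snp", how="left")
    rows = []
    for r in df.itertuples():
        have_all = all(pd.notna(getattr(r, c, np.nan))
                       for c in ("eqtl_p", "expr_status_p", "geno_status_p"))
        consistent = False
        if have_all and pd.notna(getattr(r, "maf_case", np.nan)):
            consistent = direction_consistent(
                r.eqtl_beta, r.logit_beta, r.maf_case - r.maf_control)
        tier = np.nan
        if pd.notna(r.eqtl_p) and r.eqtl_p <= alpha:
            n_pheno = int(pd.notna(r.expr_status_p) and r.expr_status_p <= alpha) \
                + int(pd.notna(r.geno_status_p) and r.geno_status_p <= alpha)
            if n_pheno == 2 and consistent:
                tier = 1
            elif n_pheno >= 1:
                tier = 2
            else:
                tier = 3
        rows.append((r.snp, r.probe, r.eqtl_p,
                     getattr(r, "expr_status_p", np.nan),
                     getattr(r, "geno_status_p", np.nan), consistent, tier))
    out = pd.DataFrame(rows, columns=["snp", "probe", "eqtl_p", "expr_status_p",
                                      "geno_status_p", "direction_consistent",
                                      "tier"])
    out = out.sort_values(["tier", "eqtl_p"], na_position="last",
                          kind="stable").reset_index(drop=True)
    out.attrs["direction_note"] = DIRECTION_NOTE
    return out


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

def cohort_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-group demographic summary with SC-vs-SNC comparison column.

    Rows: age, pack-years (mean +/- SD), sex and race counts.  The SC/SNC
    comparisons use the Welch t-test from summary statistics for the
    continuous rows and Fisher's exact test for the categorical rows.
    """
    if len(samples) == 0:
        raise InputError("empty sample table")
    groups = [g for g in ("NS", "SNC", "SC") if (samples["group"] == g).any()]
    cols = {}
    for g in groups:
        sub = samples[samples["group"] == g]
        entry = {"n": len(sub)}
        for var, label in (("age", "age"), ("pack_years", "pack_years")):
            if var in sub.columns:
                entry[label] = f"{sub[var].mean():.1f}±{sub[var].std(ddof=1):.1f}" \
                    if len(sub) > 1 else f"{sub[var].mean():.1f}"
        if "sex" in sub.columns:
            vc = sub["sex"].value_counts()
            entry["sex_F:M"] = f"{vc.get('F', 0)}:{vc.get('M', 0)}"
        if "race" in sub.columns:
            vc = sub["race"].value_counts()
            entry["race"] = ":".join(f"{k}={v}" for k, v in sorted(vc.items()))
        cols[g] = entry
    table = pd.DataFrame(cols)
    comp = {}
    if "SC" in groups and "SNC" in groups:
        sc = samples[samples["group"] == "SC"]
        snc = samples[samples["group"] == "SNC"]
        for var in ("age", "pack_years"):
            if var in samples.columns and len(sc) > 1 and len(snc) > 1 \
                    and sc[var].std(ddof=1) > 0 and snc[var].std(ddof=1) > 0:
                _, _, p = summary_ttest(sc[var].mean(), sc[var].std(ddof=1), len(sc),
                                        snc[var].mean(), snc[var].std(ddof=1), len(snc))
                comp[var] = f"p={p:.2g} (t-test)"
        for var in ("sex", "race"):
            if var in samples.columns:
                tab = pd.crosstab(samples.loc[samples["group"].isin(["SC", "SNC"]),
                                              "group"], samples[var])
                comp_name = {"sex": "sex_F:M", "race": "race"}[var]
                comp[comp_name] = f"p={fisher_exact(tab.to_numpy()):.2g} (Fisher)"
    table["SC_vs_SNC"] = pd.Series(comp)
    return table
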