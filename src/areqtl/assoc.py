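"""Genotype QC, Hardy-Weinberg exact test, LD r2, and cis-eQTL mapping with
per-probe min-p permutation correction.

The association model is ordinary least squares of log2 expression on
additive minor-allele dosage (0/1/2).  Family-wise correction follows the
regional-association approach: for each probe, expression values are permuted
across samples, the minimum nominal p over the probe's cis-SNP family is
recorded per permutation, the corrected p of a SNP is the tail probability of
its observed nominal p under that min-p distribution, and the family
threshold is the empirical 5% quantile of the min-p distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, GenotypeMatrix, InputError

__all__ = [
    "hwe_exact",
    "genotype_qc",
    "ld_r2",
    "map_cis_pairs",
    "additive_regression",
    "minp_permutation",
    "CisEqtl",
    "CisEqtlResults",
]


def hwe_exact(n_aa_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided probability-mass).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities no larger than that of the observed
    configuration.  Computed in exact integer arithmetic, so ties in the
    probability-mass criterion are handled without floating error.
    """
    counts = (n_aa_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise InputError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise InputError("need at least one genotyped sample")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)  # orient to the rarer allele
    if n_minor == 0:
        return 1.0
    # het counts share parity with the minor-allele count
    hets = range(n_minor % 2, n_minor + 1, 2)
    weights = {}
    for h in hets:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        # P(h) ∝ n! / (hom_major! h! hom_minor!) * 2^h
        weights[h] = (math.factorial(n)
                      // (math.factorial(hom_major) * math.factorial(h)
                          * math.factorial(hom_minor))) * (1 << h)
    h_obs = n_het
    if h_obs not in weights:
        raise InputError("observed het count incompatible with allele counts")
    w_obs = weights[h_obs]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, sum(weights.values())))


def _genotype_counts(dosage_row: np.ndarray) -> tuple[int, int, int]:
    d = dosage_row[~np.isnan(dosage_row)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def genotype_qc(g: GenotypeMatrix, call_rate_min: float = 0.90,
                maf_min: float = 0.01, hwe_min: float = 0.001,
                analysis_maf: float = 0.05) -> pd.DataFrame:
    """Per-SNP QC report.

    Columns: call_rate, maf, hwe_p, pass_call_rate, pass_maf, pass_hwe,
    pass_qc, analysis_eligible (passes QC and MAF >= ``analysis_maf``).
    MAF and the HWE test use non-missing calls only; a SNP with no calls
    fails call rate and reports MAF/HWE as missing.
    """
    if g.dosage.shape[1] < 1:
        raise InputError("need at least one sample")
    arr = g.dosage.to_numpy(dtype=float)
    rows = []
    for i, snp in enumerate(g.snps):
        row = arr[i]
        called = ~np.isnan(row)
        call_rate = called.mean()
        if called.sum() == 0:
            rows.append((snp, 0.0, np.nan, np.nan, False, False, False, False, False))
            continue
        freq = row[called].sum() / (2 * called.sum())
        maf = min(freq, 1 - freq)
        hwe_p = hwe_exact(*_genotype_counts(row))
        ok_cr = call_rate >= call_rate_min
        ok_maf = maf >= maf_min
        ok_hwe = hwe_p >= hwe_min
        ok = ok_cr and ok_maf and ok_hwe
        rows.append((snp, call_rate, maf, hwe_p, ok_cr, ok_maf, ok_hwe, ok,
                     ok and maf >= analysis_maf))
    return pd.DataFrame(
        rows,
        columns=["snp", "call_rate", "maf", "hwe_p", "pass_call_rate",
                 "pass_maf", "pass_hwe", "pass_qc", "analysis_eligible"],
    ).set_index("snp")


def ld_r2(g1, g2, tol: float = 1e-12, max_iter: int = 1000) -> float:
    """Two-locus r2 from unphased dosages via EM haplotype frequencies.

    Double heterozygotes are ambiguous between the two phase resolutions; the
    EM iterates their expected split until the haplotype frequencies
    converge.  r2 = D^2 / (pA pa pB pb).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    keep = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[keep], g2[keep]
    n = g1.size
    if n < 2:
        raise InputError("need at least 2 jointly non-missing samples")
    pA = 1 - g1.sum() / (2 * n)  # freq of the 0-coded allele at locus 1
    pB = 1 - g2.sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise InputError("monomorphic locus: r2 undefined")
    # joint genotype counts
    cnt = np.zeros((3, 3))
    for a, b in zip(g1.astype(int), g2.astype(int)):
        cnt[a, b] += 1
    # unambiguous haplotype tallies; h = [AB, Ab, aB, ab] where A/B are the
    # 0-coded alleles.  Each individual contributes two haplotypes of known
    # phase unless double-heterozygous.
    h = np.zeros(4)
    contrib = {
        (0, 0): [(0, 2)], (0, 1): [(0, 1), (1, 1)], (0, 2): [(1, 2)],
        (1, 0): [(0, 1), (2, 1)], (1, 2): [(1, 1), (3, 1)],
        (2, 0): [(2, 2)], (2, 1): [(2, 1), (3, 1)], (2, 2): [(3, 2)],
    }
    for (a, b), parts in contrib.items():
        for hap, copies in parts:
            h[hap] += cnt[a, b] * copies
    n_dh = cnt[1, 1]
    total = 2 * n
    # EM over the double-het split, started from an even split
    f = (h + (n_dh / 2)) / total if n_dh else h / total
    for _ in range(max_iter):
        if n_dh == 0:
            break
        denom = f[0] * f[3] + f[1] * f[2]
        frac_cis = 0.5 if denom == 0 else f[0] * f[3] / denom
        new = h.copy()
        new[0] += n_dh * frac_cis
        new[3] += n_dh * frac_cis
        new[1] += n_dh * (1 - frac_cis)
        new[2] += n_dh * (1 - frac_cis)
        new /= total
        if np.max(np.abs(new - f)) < tol:
            f = new
            break
        f = new
    pA_hat = f[0] + f[1]
    pB_hat = f[0] + f[2]
    d = f[0] - pA_hat * pB_hat
    denom = pA_hat * (1 - pA_hat) * pB_hat * (1 - pB_hat)
    if denom <= 0:
        raise InputError("monomorphic locus after EM: r2 undefined")
    return float(np.clip(d * d / denom, 0.0, 1.0))


def map_cis_pairs(snp_meta: pd.DataFrame, regions: pd.DataFrame,
                  window: int = 10_000) -> pd.DataFrame:
    """(snp, probe) pairs with the SNP within ``window`` bp of the probe's
    gene region (inclusive bounds, same chromosome).

    ``regions`` columns: probe, chrom, start, end (1-based inclusive).
    """
    if (regions["start"] > regions["end"]).any():
        raise InputError("malformed region: start > end")
    out = []
    meta = snp_meta.reset_index().rename(columns={snp_meta.index.name or "index": "snp"})
    for reg in regions.itertuples():
        sel = meta[(meta["chrom"] == reg.chrom)
                   & (meta["pos"] >= reg.start - window)
                   & (meta["pos"] <= reg.end + window)]
        for snp in sel["snp"]:
            out.append((snp, reg.probe))
    return pd.DataFrame(out, columns=["snp", "probe"])


def additive_regression(y, g) -> tuple[float, float, float]:
    """OLS of expression on additive dosage: (beta, SE, two-sided p)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    y, g = y[keep], g[keep]
    if y.size < 3:
        raise InputError("need at least 3 non-missing sample pairs")
    if np.var(g) == 0:
        raise InputError("monomorphic in analysis subset")
    res = stats.linregress(g, y)
    return float(res.slope), float(res.stderr), float(res.pvalue)


def _p_from_corr(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1 - r * r, np.finfo(float).tiny))
    return np.clip(2 * stats.t.sf(np.abs(t), df), 0.0, 1.0)


def minp_permutation(y, family: pd.DataFrame, nperm: int = 10_000,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Min-p permutation correction over one probe's cis-SNP family.

    Parameters
    ----------
    y : expression values over samples.
    family : dosage DataFrame, SNPs in rows, samples in columns (aligned to y).
    nperm : number of expression permutations (>= 100).
    seed, rng : randomness; pass ``rng`` to share a stream across probes.

    Returns a DataFrame indexed by SNP with n, beta, se, p, p_corrected,
    family_threshold, significant.  Corrected p uses the (1+k)/(1+N)
    estimator; ``significant`` flags observed nominal p below the empirical
    5% quantile of the permuted min-p distribution.  Permutations shuffle the
    full expression vector and then apply each SNP's missingness mask, so all
    SNPs of the family share one permutation stream.
    """
    if nperm < 100:
        raise ConfigError("nperm < 100 gives unstable min-p tails")
    if family.shape[0] == 0:
        raise InputError("empty SNP family")
    if rng is None:
        rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    G = family.to_numpy(dtype=float)
    k, n = G.shape
    if y.size != n:
        raise InputError("y and family sample dimensions differ")

    perm_idx = np.argsort(rng.random((nperm, n)), axis=1)
    y_perm = y[perm_idx]  # (nperm, n)

    obs = np.full((k, 3), np.nan)  # beta, se, p
    perm_p = np.full((nperm, k), np.nan)
    valid = np.zeros(k, dtype=bool)
    for j in range(k):
        mask = ~np.isnan(G[j]) & ~np.isnan(y)
        nj = int(mask.sum())
        gj = G[j, mask]
        if nj < 3 or np.var(gj) == 0:
            continue
        valid[j] = True
        obs[j] = additive_regression(y[mask], gj)
        yp = y_perm[:, mask]
        gz = gj - gj.mean()
        gnorm = np.sqrt((gz * gz).sum())
        ypc = yp - yp.mean(axis=1, keepdims=True)
        ynorm = np.sqrt((ypc * ypc).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ypc @ gz) / np.where(ynorm > 0, ynorm * gnorm, np.nan)
        perm_p[:, j] = np.where(np.isnan(r), 1.0, _p_from_corr(r, nj - 2))
    if not valid.any():
        raise InputError("no analyzable SNP in family")

    min_p = np.nanmin(perm_p[:, valid], axis=1)
    threshold = float(np.quantile(min_p, 0.05))
    p_obs = obs[:, 2]
    corrected = np.full(k, np.nan)
    corrected[valid] = (1 + (min_p[:, None] <= p_obs[valid][None, :]).sum(axis=0)) \
        / (nperm + 1)
    out = pd.DataFrame(
        {
            "n": [int((~np.isnan(G[j]) & ~np.isnan(y)).sum()) for j in range(k)],
            "beta": obs[:, 0],
            "se": obs[:, 1],
            "p": p_obs,
            "p_corrected": corrected,
            "family_threshold": threshold,
            "significant": valid & (p_obs < threshold),
        },
        index=family.index,
    )
    return out


@dataclass
class CisEqtlResults:
    """Per-pair association results; ``table`` columns: snp, probe, n, beta,
    se, p, p_corrected, family_threshold, significant."""

    table: pd.DataFrame
    window: int
    nperm: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        sig = self.significant
        lines = [
            f"cis-eQTL scan: {self.table['probe'].nunique()} probes, "
            f"{self.table['snp'].nunique()} SNPs, window {self.window} bp, "
            f"{self.nperm} permutations",
            f"  pairs tested: {len(self.table)}",
            f"  significant (min-p corrected, 5% family threshold): {len(sig)} "
            f"pairs / {sig['snp'].nunique()} SNPs / {sig['probe'].nunique()} probes",
        ]
        return "\n".join(lines)


class CisEqtl:
    """cis-eQTL model: log2 expression ~ additive dosage, per-probe min-p
    permutation correction.

    Parameters
    ----------
    expr : ExpressionMatrix (probes x samples).
    geno : GenotypeMatrix (QC-filtered; samples must cover expr.samples).
    regions : DataFrame with probe, chrom, start, end (1-based inclusive).
    window : cis window in bp around the gene region.
    """

    def __init__(self, expr, geno: GenotypeMatrix, regions: pd.DataFrame,
                 window: int = 10_000):
        missing = expr.samples.difference(geno.samples)
        if len(missing):
            raise InputError(f"samples without genotypes: {list(missing)[:5]}")
        self.expr = expr
        self.geno = geno
        self.regions = regions
        self.window = window
        self.pairs = map_cis_pairs(geno.meta, regions, window)
        self.pairs = self.pairs[self.pairs["probe"].isin(expr.probes)]

    def fit(self, nperm: int = 10_000, seed: int | None = None) -> CisEqtlResults:
        rng = np.random.default_rng(seed)
        dosage = self.geno.dosage[self.expr.samples]
        frames = []
        for probe, grp in self.pairs.groupby("probe", sort=True):
            fam = dosage.loc[grp["snp"]]
            y = self.expr.values.loc[probe].to_numpy(dtype=float)
            res = minp_permutation(y, fam, nperm=nperm, rng=rng)
            res = res.reset_index(names="snp")
            res.insert(1, "probe", probe)
            frames.append(res)
        table = (pd.concat(frames, ignore_index=True)
                 if frames else pd.DataFrame(
                     columns=["snp", "probe", "n", "beta", "se", "p",
                              "p_corrected", "family_threshold", "significant"]))
        return CisEqtlResults(table, self.window, nperm)
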