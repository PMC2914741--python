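"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a 52-sample bronchoscopy cohort in three groups
(8 never smokers, 24 smokers without cancer, 20 smokers with cancer),
genotypes drawn from per-block haplotype pools (Hardy-Weinberg holds per SNP
by construction, linkage disequilibrium arises within blocks from shared pool
haplotypes), log2 expression with additive cis allelic effects and an
SNC-up / SC-down group shift on ARE-flagged genes, and motif-bearing
sequences with planted consensus sites and SNPs.  Every draw is reproducible
from the configured seed, and the planted truth is returned for parameter-
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (ConfigError, ExpressionMatrix, GenotypeMatrix,
                         GroundTruth, InputError)

__all__ = [
    "SimConfig",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_sequences",
    "gene_regions",
    "draw_individuals_from_pool",
    "simulate_integration_dataset",
]

# Per-group demographic moments of the emulated cohort:
# age mean/SD (years), pack-years mean/SD, P(female), race proportions.
_AGE = {"NS": (32.0, 9.0), "SNC": (53.0, 18.0), "SC": (68.0, 15.0)}
_PACK = {"NS": None, "SNC": (52.0, 53.0), "SC": (58.0, 28.0)}
_P_FEMALE = {"NS": 3 / 8, "SNC": 2 / 24, "SC": 4 / 20}
_RACE_LEVELS = ("AFA", "ASI", "CAU", "HIS", "OTH")
_RACE_P = {
    "NS": (0, 0, 6, 1, 1),
    "SNC": (6, 3, 13, 1, 1),
    "SC": (2, 0, 18, 0, 0),
}


@dataclass
class SimConfig:
    """Study-condition parameters of the generator.

    Effects are in log2 expression units; a_snc/b_sc are the group shifts of
    ARE-flagged genes in smokers without / with cancer relative to never
    smokers (defaults 2^0.58 ~ 1.5-fold up in SNC, 2^-0.74 ~ 0.6-fold down
    in SC, the magnitude of the MAFG-like pattern).
    """

    n_per_group: tuple[int, int, int] = (8, 24, 20)  # NS, SNC, SC
    n_genes: int = 200
    snps_per_gene: int = 6
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 3
    n_haplotypes_pool: int = 20
    beta_cis: float = 1.0
    frac_causal: float = 0.2
    a_snc: float = 0.58
    b_sc: float = -0.74
    noise_sd: float = 0.5
    n_are_genes: int = 25
    missing_rate: float = 0.0
    frac_undetected: float = 0.05
    # sequence simulation
    n_sequences: int = 5
    seq_length: int = 400
    sites_per_seq: int = 1
    snps_per_seq: int = 2
    seed: int = 1

    def __post_init__(self):
        if any(n <= 0 for n in self.n_per_group):
            raise ConfigError("group sizes must be positive")
        for name in ("n_genes", "snps_per_gene", "ld_block_size",
                     "n_haplotypes_pool", "n_sequences", "seq_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if not 0 <= self.frac_causal <= 1:
            raise ConfigError("frac_causal must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    # independent, reproducible stream per operation
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def _trunc_normal(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Sample table: group, age, pack_years, sex, race (index = sample id).

    Ages are group-specific normals truncated at 18 (SC older than SNC);
    pack-years are 0 for never smokers and truncated-at-zero normals for
    smokers; sex and race follow the per-group cohort proportions.
    """
    rng = _rng(config, 1)
    rows = []
    for group, n in zip(("NS", "SNC", "SC"), config.n_per_group):
        age = _trunc_normal(rng, *_AGE[group], lower=18.0, size=n)
        if _PACK[group] is None:
            pack = np.zeros(n)
        else:
            pack = _trunc_normal(rng, *_PACK[group], lower=0.0, size=n)
        sex = np.where(rng.random(n) < _P_FEMALE[group], "F", "M")
        race_p = np.asarray(_RACE_P[group], dtype=float)
        race = rng.choice(_RACE_LEVELS, size=n, p=race_p / race_p.sum())
        for i in range(n):
            rows.append((f"{group}{i + 1:02d}", group, age[i], pack[i],
                         sex[i], race[i]))
    df = pd.DataFrame(rows, columns=["sample", "group", "age", "pack_years",
                                     "sex", "race"]).set_index("sample")
    return df


def gene_regions(config: SimConfig) -> pd.DataFrame:
    """Gene/probe regions (probe, chrom, start, end; 1-based inclusive).

    One probe per gene; genes are spaced 100 kb apart so cis windows never
    overlap across genes.
    """
    rows = []
    for j in range(config.n_genes):
        chrom = f"chr{1 + j % 22}"
        start = 50_001 + 100_000 * (j // 22)
        rows.append((f"G{j:04d}", chrom, start, start + 1_999))
    return pd.DataFrame(rows, columns=["probe", "chrom", "start", "end"])


def _block_pool(rng, n_pool: int, freqs: np.ndarray) -> np.ndarray:
    """Haplotype pool (n_pool x n_snps) whose per-SNP minor-allele counts
    match round(freq * n_pool), clamped to keep every SNP polymorphic in the
    pool."""
    n_snps = freqs.size
    pool = np.zeros((n_pool, n_snps), dtype=np.int8)
    for s in range(n_snps):
        k = int(round(freqs[s] * n_pool))
        k = min(max(k, 1), n_pool - 1)
        carriers = rng.choice(n_pool, size=k, replace=False)
        pool[carriers, s] = 1
    return pool


def draw_individuals_from_pool(pool: np.ndarray, n: int,
                               rng: np.random.Generator) -> np.ndarray:
    """Dosage matrix (n x n_snps): each individual is the sum of two
    independently drawn pool haplotypes, so HWE holds per SNP exactly."""
    i1 = rng.integers(0, pool.shape[0], size=n)
    i2 = rng.integers(0, pool.shape[0], size=n)
    return (pool[i1] + pool[i2]).astype(float)


_BASES = np.array(list("ACGT"))


def simulate_genotypes(config: SimConfig,
                       samples: pd.DataFrame | None = None
                       ) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Genotypes for all samples plus the haplotype pools used.

    SNPs come in LD blocks of ``ld_block_size`` within each gene's cis
    region; each block has its own haplotype pool.  After generation the
    dosage is re-oriented so that 1 counts the globally minor allele
    (frequency ties broken by allele lexicographic order).
    """
    lo, hi = config.maf_range
    if lo == hi == 0:
        raise ConfigError("degenerate maf_range")
    if samples is None:
        samples = simulate_cohort(config)
    rng = _rng(config, 2)
    n = len(samples)
    regions = gene_regions(config)
    dosage_rows, meta_rows, snp_ids = [], [], []
    pools: dict[str, np.ndarray] = {}
    for gi, reg in enumerate(regions.itertuples()):
        k = config.snps_per_gene
        pos = np.sort(rng.choice(np.arange(reg.start - 9_000, reg.end + 9_000),
                                 size=k, replace=False))
        block_starts = range(0, k, config.ld_block_size)
        dos_gene = np.empty((n, 0))
        for bi, b0 in enumerate(block_starts):
            width = min(config.ld_block_size, k - b0)
            freqs = rng.uniform(lo, hi, size=width)
            pool = _block_pool(rng, config.n_haplotypes_pool, freqs)
            pools[f"{reg.probe}_b{bi}"] = pool
            dos_gene = np.hstack([dos_gene, draw_individuals_from_pool(pool, n, rng)])
        for s in range(k):
            snp_ids.append(f"rs{gi:04d}_{s}")
            ref, alt = rng.choice(4, size=2, replace=False)
            meta_rows.append((reg.chrom, int(pos[s]), _BASES[ref], _BASES[alt],
                              "simulated", reg.probe))
        dosage_rows.append(dos_gene)
    dosage = np.hstack(dosage_rows).T  # (snps, samples)
    meta = pd.DataFrame(meta_rows, columns=["chrom", "pos", "ref", "alt",
                                            "snp_class", "gene"],
                        index=pd.Index(snp_ids, name="snp"))
    # orient to the globally minor allele
    freq = dosage.mean(axis=1) / 2
    flip = (freq > 0.5) | ((freq == 0.5)
                           & (meta["alt"].to_numpy() < meta["ref"].to_numpy()))
    dosage[flip] = 2 - dosage[flip]
    meta.loc[flip, ["ref", "alt"]] = meta.loc[flip, ["alt", "ref"]].to_numpy()
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage = np.where(mask, np.nan, dosage)
    gm = GenotypeMatrix(pd.DataFrame(dosage, index=meta.index,
                                     columns=samples.index), meta)
    return gm, pools


def simulate_expression(config: SimConfig, geno: GenotypeMatrix,
                        samples: pd.DataFrame
                        ) -> tuple[ExpressionMatrix, GroundTruth]:
    """log2 expression: baseline + group shifts on ARE genes + cis effects.

    y_gene,i = mu_gene + a_snc*1[SNC] + b_sc*1[SC] (ARE genes only)
               + beta_cis * dosage_i (causal pairs) + Normal(0, noise_sd).
    Missing dosages contribute their expected value (2*MAF) so expression is
    always complete.  Detection flags mark a ``frac_undetected`` slice of
    genes as essentially undetected to exercise the detection filter.
    """
    if not geno.samples.equals(samples.index):
        raise InputError("genotype and sample table sample ids differ")
    rng = _rng(config, 3)
    regions = gene_regions(config)
    genes = list(regions["probe"])
    n = len(samples)
    group = samples["group"].to_numpy()
    snc = (group == "SNC").astype(float)
    sc = (group == "SC").astype(float)

    n_are = min(config.n_are_genes, config.n_genes)
    are_genes = list(rng.choice(genes, size=n_are, replace=False))
    n_causal = int(round(config.frac_causal * config.n_genes))
    causal_genes = rng.choice(genes, size=n_causal, replace=False)
    snp_by_gene = geno.meta.groupby("gene").groups

    mu = rng.uniform(6.0, 10.0, size=len(genes))
    vals = np.empty((len(genes), n))
    truth = GroundTruth(are_genes=are_genes)
    are_set = set(are_genes)
    causal_map = {}
    for g in causal_genes:
        snp = rng.choice(list(snp_by_gene.get(g, [])))
        causal_map[g] = snp
        truth.causal_pairs.append((str(snp), str(g), config.beta_cis))
    for i, g in enumerate(genes):
        y = np.full(n, mu[i])
        if g in are_set:
            y = y + config.a_snc * snc + config.b_sc * sc
        if g in causal_map:
            d = geno.dosage.loc[causal_map[g]].to_numpy(dtype=float)
            d = np.where(np.isnan(d), np.nanmean(d), d)
            y = y + config.beta_cis * d
        vals[i] = y + rng.normal(0.0, config.noise_sd, size=n)

    undet = rng.random(len(genes)) < config.frac_undetected
    det_p = np.where(undet[:, None], 0.05, 0.95)
    detection = rng.random(vals.shape) < det_p
    x = ExpressionMatrix(
        pd.DataFrame(vals, index=pd.Index(genes, name="probe"),
                     columns=samples.index),
        pd.DataFrame(detection, index=pd.Index(genes, name="probe"),
                     columns=samples.index),
    )
    return x, truth


def simulate_sequences(config: SimConfig, pwm) -> tuple[dict[str, str], GroundTruth]:
    """Random-background sequences with planted motif-consensus sites and
    SNPs inside/outside the sites; the plant positions, strands and alleles
    are recorded as ground truth."""
    from .motif import revcomp

    if pwm.width > config.seq_length:
        raise InputError("PWM wider than sequence length")
    rng = _rng(config, 4)
    w = pwm.width
    consensus = pwm.consensus
    seqs: dict[str, str] = {}
    truth = GroundTruth()
    for si in range(config.n_sequences):
        sid = f"seq{si + 1}"
        seq = list(rng.choice(list("ACGT"), size=config.seq_length))
        placed: list[tuple[int, int]] = []
        for _ in range(config.sites_per_seq):
            for _attempt in range(200):
                start = int(rng.integers(0, config.seq_length - w + 1))
                if all(start >= e + w or start + w <= s - w for s, e in placed):
                    break
            else:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            word = consensus if strand == "+" else revcomp(consensus)
            seq[start:start + w] = list(word)
            placed.append((start, start + w))
            truth.planted_sites.append((sid, start, start + w, strand))
        seq = "".join(seq)
        # SNPs: one inside the first site (if any), the rest well outside
        offsets = []
        if placed:
            s0, e0 = placed[0]
            offsets.append(int(rng.integers(s0, e0)))
        while len(offsets) < config.snps_per_seq:
            off = int(rng.integers(0, config.seq_length))
            if all(off < s - w or off >= e + w for s, e in placed) \
                    and off not in offsets:
                offsets.append(off)
        for off in offsets:
            ref = seq[off]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            inside = any(s <= off < e for s, e in placed)
            truth.planted_snps.append((sid, off, ref, alt, inside))
        seqs[sid] = seq
    return seqs, truth


# ---------------------------------------------------------------------------
# Planted-signal integration dataset
# ---------------------------------------------------------------------------

@dataclass
class IntegrationSim:
    """Bundle returned by :func:`simulate_integration_dataset`."""

    expr: ExpressionMatrix          # smokers only, gene-level
    geno: GenotypeMatrix            # cis SNPs of the causal gene + decoys
    status: pd.Series               # SC / SNC per smoker
    gene_sets: list                 # causal ARE set first, decoys after
    causal_snp: str
    causal_gene: str
    are_set_name: str
    regions: pd.DataFrame


def simulate_integration_dataset(seed: int, n_smokers: int = 44,
                                 n_genes: int = 150, n_are: int = 25,
                                 beta_cis: float = 2.0, maf: float = 0.35,
                                 n_decoy_sets: int = 10) -> IntegrationSim:
    """Smoker cohort where one cis SNP drives an ARE gene's expression and
    cancer status is sampled from a logistic model on that expression.

    ARE genes share a latent regulator f (the MAFG-like co-regulation), the
    causal gene additionally carries a strong cis effect, and
    logit P(SC) = -(0.9 f + 2.6 z) with z the standardised causal-gene
    expression, so SC sits low on the ARE axis.  Effect sizes were fixed by a
    power analysis: with n = 44 the genotype-status Fisher test is the
    weakest link and needs a marginal per-allele odds ratio around 10 to be
    reliably detectable once the latent-factor noise attenuates it.
    """
    from .enrichment import GeneSet

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    genes = [f"G{j:03d}" for j in range(n_genes)]
    are_genes = genes[:n_are]
    causal_gene = are_genes[0]

    # one LD block of cis SNPs for the causal gene + independent decoy SNPs
    n_cis = 6
    pool = _block_pool(rng, 20, np.full(n_cis, maf))
    cis_dos = draw_individuals_from_pool(pool, n_smokers, rng).T  # (snps, n)
    causal_idx = 0
    decoy_dos = np.stack([
        draw_individuals_from_pool(_block_pool(rng, 20, np.array([maf])),
                                   n_smokers, rng)[:, 0]
        for _ in range(6)
    ])
    sample_ids = pd.Index([f"S{i + 1:02d}" for i in range(n_smokers)],
                          name="sample")
    snp_ids = [f"cis{j}" for j in range(n_cis)] + [f"null{j}" for j in range(6)]
    dosage = pd.DataFrame(np.vstack([cis_dos, decoy_dos]),
                          index=pd.Index(snp_ids, name="snp"),
                          columns=sample_ids)
    causal_region_start = 50_001
    meta = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_cis + ["chr9"] * 6,
            "pos": ([causal_region_start + 500 * j for j in range(n_cis)]
                    + [1_000_000 + 50_000 * j for j in range(6)]),
            "ref": "A", "alt": "G", "snp_class": "simulated",
            "gene": [causal_gene] * n_cis + ["none"] * 6,
        },
        index=dosage.index,
    )
    geno = GenotypeMatrix(dosage, meta)

    f = rng.normal(size=n_smokers)  # latent ARE co-regulator
    mu = rng.uniform(6.0, 10.0, size=n_genes)
    vals = np.empty((n_genes, n_smokers))
    g_causal = cis_dos[causal_idx]
    are_set = set(are_genes)
    for i, g in enumerate(genes):
        y = np.full(n_smokers, mu[i])
        if g in are_set:
            # the causal gene loads less on f: its variance budget goes to
            # the cis effect, keeping the genotype-status link strong
            y = y + (0.5 if g == causal_gene else 0.9) * f
        if g == causal_gene:
            y = y + beta_cis * g_causal
        noise = 0.35 if g == causal_gene else 0.5
        vals[i] = y + rng.normal(0.0, noise, size=n_smokers)
    y_causal = vals[genes.index(causal_gene)]
    z = (y_causal - y_causal.mean()) / y_causal.std()
    logit = -(0.9 * f + 2.6 * z)
    status = np.where(rng.random(n_smokers) < 1 / (1 + np.exp(-logit)),
                      "SC", "SNC")
    status = pd.Series(status, index=sample_ids, name="group")

    expr = ExpressionMatrix(pd.DataFrame(vals, index=pd.Index(genes, name="probe"),
                                         columns=sample_ids))
    sets = [GeneSet("ARE_GENES", frozenset(are_genes))]
    non_are = genes[n_are:]
    for k in range(n_decoy_sets):
        members = rng.choice(non_are, size=n_are, replace=False)
        sets.append(GeneSet(f"DECOY_{k + 1}", frozenset(members)))
    regions = pd.DataFrame(
        [(causal_gene, "chr1", causal_region_start, causal_region_start + 1_999)],
        columns=["probe", "chrom", "start", "end"])
    return IntegrationSim(expr, geno, status, sets, snp_ids[causal_idx],
                          causal_gene, "ARE_GENES", regions)
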