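"""Gene-set enrichment analysis (weighted 2005 form).

Genes are ranked by a signal-to-noise statistic between two phenotype groups,
a weighted Kolmogorov-Smirnov-like running sum is walked down the ranking for
each gene set, and significance comes from phenotype-label permutation:
nominal p from the sign-matched tail of the permuted enrichment scores (ES),
NES by dividing each ES by the mean |permuted ES| of its sign, and FDR q from
the pooled positive/negative permuted-NES distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigError, ExpressionMatrix, InputError

__all__ = [
    "GeneSet",
    "read_gmt",
    "collapse_probes",
    "signal_to_noise",
    "rank_signal_to_noise",
    "enrichment_score",
    "Gsea",
    "GseaResults",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise InputError(f"gene set {self.name!r} is empty")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> description <tab> symbols...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            sets.append(GeneSet(name, frozenset(genes)))
    return sets


def collapse_probes(x: ExpressionMatrix, probe_to_gene) -> ExpressionMatrix:
    """Collapse probe-sets to genes, keeping the probe with the highest mean.

    ``probe_to_gene`` is a mapping or Series; unmapped probes are dropped with
    a warning.
    """
    import warnings

    mapping = pd.Series(probe_to_gene)
    unmapped = x.probes.difference(mapping.index)
    if len(unmapped):
        warnings.warn(f"dropping {len(unmapped)} unmapped probes")
    probes = x.probes.intersection(mapping.index, sort=False)
    vals = x.values.loc[probes]
    genes = mapping.loc[probes]
    means = vals.mean(axis=1)
    # highest-mean probe per gene
    best = means.groupby(genes.to_numpy()).idxmax()
    out = vals.loc[best.to_numpy()]
    out.index = pd.Index(best.index, name="gene")
    det = None
    if x.detection is not None:
        det = x.detection.loc[best.to_numpy()]
        det.index = out.index
    return ExpressionMatrix(out, det)


def signal_to_noise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise signal-to-noise (mu_a - mu_b)/(sd_a + sd_b) with the GSEA
    guard: each sd is floored at 0.2 * |mean| of its own group, and |mean| is
    itself floored at 0.2."""
    ma, mb = a.mean(axis=-1), b.mean(axis=-1)
    sa, sb = a.std(axis=-1, ddof=1), b.std(axis=-1, ddof=1)
    sa = np.maximum(sa, 0.2 * np.maximum(np.abs(ma), 0.2))
    sb = np.maximum(sb, 0.2 * np.maximum(np.abs(mb), 0.2))
    return (ma - mb) / (sa + sb)


def rank_signal_to_noise(x: ExpressionMatrix, labels,
                         group_a: str | None = None) -> pd.Series:
    """Signal-to-noise scores sorted descending (group A minus group B).

    ``labels`` is a Series/array over x.samples with exactly two distinct
    values; ``group_a`` selects the numerator group (default: the first
    distinct label encountered).  Swapping the two groups negates every
    score and reverses the ranking.
    """
    labels = pd.Series(np.asarray(labels), index=x.samples)
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise InputError("exactly two groups required")
    if group_a is not None and group_a not in uniq:
        raise InputError(f"group_a {group_a!r} not among labels")
    a_mask = (labels == (group_a if group_a is not None else uniq[0])).to_numpy()
    if a_mask.sum() < 3 or (~a_mask).sum() < 3:
        raise InputError("each group needs at least 3 samples")
    vals = x.values.to_numpy(dtype=float)
    scores = signal_to_noise(vals[:, a_mask], vals[:, ~a_mask])
    order = np.argsort(-scores, kind="stable")
    return pd.Series(scores[order], index=x.probes[order], name="score")


def enrichment_score(ranked: pd.Series, gene_set: GeneSet, weight: float = 1.0,
                     return_running: bool = False):
    """ES of ``gene_set`` in a descending-ranked score Series.

    Hits increment the running sum by |score|^weight normalised over hits;
    misses decrement by 1/(N - Nh).  ES is the running-sum value of largest
    magnitude (first occurrence on ties).
    """
    member = np.fromiter((g in gene_set.genes for g in ranked.index), dtype=bool,
                         count=len(ranked))
    running = _es_walk(ranked.to_numpy(dtype=float), member, weight)
    es = float(running[np.argmax(np.abs(running))])
    if return_running:
        return es, running
    return es


def _es_walk(scores: np.ndarray, member: np.ndarray, weight: float) -> np.ndarray:
    n = scores.size
    nh = int(member.sum())
    if nh == 0:
        raise InputError("gene set is disjoint from the ranked list")
    w = np.abs(scores) ** weight
    denom = w[member].sum()
    if denom == 0:  # all hit scores exactly zero: fall back to unweighted hits
        hit_step = member / nh
    else:
        hit_step = np.where(member, w / denom, 0.0)
    if nh == n:
        steps = hit_step
    else:
        steps = hit_step - (~member) / (n - nh)
    return np.cumsum(steps)


@dataclass
class GseaResults:
    """Enrichment results; ``table`` columns: size, es, nes, p, q (indexed by
    set name, sorted by NES descending)."""

    table: pd.DataFrame
    group_a: str
    group_b: str
    nperm: int

    def top(self) -> str:
        return str(self.table["nes"].idxmax())

    def summary(self) -> str:
        head = (f"GSEA {self.group_a} vs {self.group_b} "
                f"({self.nperm} phenotype permutations)")
        return head + "\n" + self.table.to_string(float_format=lambda v: f"{v:.4f}")


class Gsea:
    """GSEA model over a gene-level expression matrix.

    Parameters
    ----------
    x : ExpressionMatrix (gene-level; use :func:`collapse_probes` first if the
        rows are probe-sets).
    labels : two-group phenotype labels over x.samples.  Scores are group A
        minus group B where A is the first distinct label encountered.
    gene_sets : list of GeneSet; sets disjoint from the matrix are dropped.
    group_a : label treated as the numerator group (positive scores mean "up
        in group_a"); default: first distinct label encountered.
    """

    def __init__(self, x: ExpressionMatrix, labels, gene_sets: list[GeneSet],
                 weight: float = 1.0, group_a: str | None = None):
        self.x = x
        self.labels = pd.Series(np.asarray(labels), index=x.samples)
        uniq = list(pd.unique(self.labels))
        if len(uniq) != 2:
            raise InputError("exactly two groups required")
        if group_a is not None:
            if group_a not in (str(u) for u in uniq):
                raise InputError(f"group_a {group_a!r} not among labels")
            uniq = sorted(uniq, key=lambda u: str(u) != group_a)
        self.group_a, self.group_b = (str(u) for u in uniq)
        present = set(x.probes)
        self.gene_sets = [gs for gs in gene_sets if gs.genes & present]
        if not self.gene_sets:
            raise InputError("no gene set overlaps the expression matrix")
        self.weight = weight

    def fit(self, nperm: int = 1000, seed: int | None = None) -> GseaResults:
        if nperm < 100:
            raise ConfigError("nperm < 100 gives unstable permutation tails")
        rng = np.random.default_rng(seed)
        vals = self.x.values.to_numpy(dtype=float)
        genes = list(self.x.probes)
        a_mask = (self.labels.astype(str) == self.group_a).to_numpy()
        n_a = int(a_mask.sum())
        n = vals.shape[1]

        member = np.stack(
            [np.fromiter((g in gs.genes for g in genes), dtype=bool, count=len(genes))
             for gs in self.gene_sets]
        )  # (nsets, ngenes)

        es_obs = self._es_all(vals, a_mask, member)

        # phenotype permutations: redraw which samples sit in group A
        es_perm = np.empty((nperm, len(self.gene_sets)))
        for i in range(nperm):
            perm = rng.permutation(n)
            mask = np.zeros(n, dtype=bool)
            mask[perm[:n_a]] = True
            es_perm[i] = self._es_all(vals, mask, member)

        p, nes, nes_perm = _normalize(es_obs, es_perm)
        q = _fdr_q(nes, nes_perm)
        table = pd.DataFrame(
            {
                "size": member.sum(axis=1),
                "es": es_obs,
                "nes": nes,
                "p": p,
                "q": q,
            },
            index=pd.Index([gs.name for gs in self.gene_sets], name="set"),
        ).sort_values("nes", ascending=False)
        return GseaResults(table, self.group_a, self.group_b, nperm)

    def _es_all(self, vals: np.ndarray, a_mask: np.ndarray,
                member: np.ndarray) -> np.ndarray:
        scores = signal_to_noise(vals[:, a_mask], vals[:, ~a_mask])
        order = np.argsort(-scores, kind="stable")
        s_sorted = scores[order]
        out = np.empty(member.shape[0])
        for k in range(member.shape[0]):
            running = _es_walk(s_sorted, member[k][order], self.weight)
            out[k] = running[np.argmax(np.abs(running))]
        return out


def _normalize(es_obs: np.ndarray, es_perm: np.ndarray):
    """Sign-matched nominal p, NES and permuted NES (NaN-padded where a sign
    pool is empty)."""
    nsets = es_obs.size
    p = np.empty(nsets)
    nes = np.empty(nsets)
    nes_perm = np.full_like(es_perm, np.nan)
    for k in range(nsets):
        col = es_perm[:, k]
        pos, neg = col[col >= 0], col[col < 0]
        if es_obs[k] >= 0:
            pool = pos
            p[k] = (1 + (pool >= es_obs[k]).sum()) / (1 + pool.size) if pool.size else 1.0
        else:
            pool = neg
            p[k] = (1 + (pool <= es_obs[k]).sum()) / (1 + pool.size) if pool.size else 1.0
        mpos = pos.mean() if pos.size else np.nan
        mneg = np.abs(neg).mean() if neg.size else np.nan
        nes[k] = es_obs[k] / mpos if es_obs[k] >= 0 else es_obs[k] / mneg
        nes_perm[col >= 0, k] = col[col >= 0] / mpos
        nes_perm[col < 0, k] = col[col < 0] / mneg
    return p, nes, nes_perm


def _fdr_q(nes: np.ndarray, nes_perm: np.ndarray) -> np.ndarray:
    """Subramanian positive/negative-pool FDR q with monotonicity enforced."""
    flat = nes_perm[np.isfinite(nes_perm)]
    pos_perm, neg_perm = flat[flat >= 0], flat[flat < 0]
    obs = nes[np.isfinite(nes)]
    pos_obs, neg_obs = obs[obs >= 0], obs[obs < 0]
    q = np.empty_like(nes)
    for k, v in enumerate(nes):
        if not np.isfinite(v):
            q[k] = np.nan
            continue
        if v >= 0:
            num = (pos_perm >= v).mean() if pos_perm.size else 0.0
            den = (pos_obs >= v).mean() if pos_obs.size else 1.0
        else:
            num = (neg_perm <= v).mean() if neg_perm.size else 0.0
            den = (neg_obs <= v).mean() if neg_obs.size else 1.0
        q[k] = min(1.0, num / max(den, 1.0 / max(len(obs), 1)))
    # step-up style monotonicity within each sign pool: a more extreme NES
    # may take the smallest raw q among all cutoffs at or below its own
    for sign in (1, -1):
        idx = [k for k in range(len(nes)) if np.isfinite(nes[k])
               and (nes[k] >= 0) == (sign == 1)]
        idx.sort(key=lambda k: abs(nes[k]))  # least extreme first
        best = np.inf
        for k in idx:
            best = min(best, q[k])
            q[k] = best
    return q
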