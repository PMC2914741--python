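"""Small plotting helpers for association results.

Matplotlib is imported lazily so headless/batch use of the statistics never
pays for it.
"""

from __future__ import annotations

import numpy as np


def plot_genotype_expression(y, g, ax=None, group=None, title=None):
    """Strip plot of log2 expression by genotype with the additive trend line
    (the standard eQTL panel: one column per dosage 0/1/2).

    Parameters
    ----------
    y : expression values.
    g : dosage vector aligned with y (missing dropped).
    ax : existing matplotlib Axes, or None to create one.
    group : optional labels used to colour points (e.g. SC/SNC/NS).
    """
    import matplotlib.pyplot as plt

    from .assoc import additive_regression

    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    y, g = y[keep], g[keep]
    if ax is None:
        _, ax = plt.subplots(figsize=(3.2, 3.2))
    rng = np.random.default_rng(0)
    jitter = rng.uniform(-0.08, 0.08, size=g.size)
    if group is None:
        ax.scatter(g + jitter, y, s=18, alpha=0.8)
    else:
        group = np.asarray(group)[keep]
        for lab in np.unique(group):
            m = group == lab
            ax.scatter(g[m] + jitter[m], y[m], s=18, alpha=0.8, label=str(lab))
        ax.legend(frameon=False, fontsize=8)
    try:
        beta, _, p = additive_regression(y, g)
        xs = np.array([g.min(), g.max()])
        intercept = y.mean() - beta * g.mean()
        ax.plot(xs, intercept + beta * xs, color="0.3", lw=1.2)
        ax.set_title(title or f"beta={beta:.2f}, p={p:.2g}", fontsize=9)
    except Exception:
        if title:
            ax.set_title(title, fontsize=9)
    ax.set_xticks([0, 1, 2])
    ax.set_xlabel("minor-allele dosage")
    ax.set_ylabel("log2 expression")
    return ax


def plot_enrichment_running_sum(ranked, gene_set, weight=1.0, ax=None):
    """The ES running-sum walk for one gene set over a ranked list."""
    import matplotlib.pyplot as plt

    from .enrichment import enrichment_score

    es, running = enrichment_score(ranked, gene_set, weight, return_running=True)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.0, 2.4))
    ax.plot(running, lw=1.2)
    ax.axhline(0, color="0.6", lw=0.8)
    ax.set_xlabel("rank")
    ax.set_ylabel("running ES")
    ax.set_title(f"{gene_set.name}: ES={es:.3f}", fontsize=9)
    return ax
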