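"""Gene-set over-representation of differentially expressed mRNA lists.

The statistic is the hypergeometric upper tail (one-sided Fisher test): with
N universe genes of which K belong to a set, and n DE genes of which k fall
in the set, p = P(X >= k). The universe is the set of annotated mRNA genes
on the array, not the genome. P-values are Benjamini-Hochberg corrected
across sets and the 30 most significant terms are reported.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .study_io import GeneSetCollection


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed stably."""
    if not (0 <= k <= K <= N and k <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: list[float] | np.ndarray) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


@dataclass
class EnrichmentResult:
    set_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    p_adj: float


def enrich(
    de_genes: set[str],
    universe: set[str],
    sets: GeneSetCollection,
    top_n: int = 30,
) -> tuple[list[EnrichmentResult], pd.DataFrame]:
    """Over-representation of ``de_genes`` within ``universe`` for each set.

    Sets are intersected with the universe before counting; sets with no
    universe member are omitted. Returns results in input-set order plus the
    top-``top_n`` table sorted by adjusted p (ties by raw p then name).
    """
    if not universe:
        raise ValueError("empty universe")
    extra = de_genes - universe
    if extra:
        raise ValueError(
            f"{len(extra)} DE gene(s) outside the universe (e.g. {sorted(extra)[:3]})"
        )
    N = len(universe)
    n = len(de_genes)
    partial = []
    for gene_set in sets:
        members = gene_set.members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & de_genes)
        partial.append((gene_set.name, k, K, hypergeom_upper_tail(k, K, n, N)))
    adjusted = bh_adjust([p for _, _, _, p in partial])
    results = [
        EnrichmentResult(name, k, K, n, N, p, p_adj)
        for (name, k, K, p), p_adj in zip(partial, adjusted)
    ]
    table = pd.DataFrame(
        [(r.set_name, r.k, r.K, r.n, r.N, r.p, r.p_adj) for r in results],
        columns=["set_name", "k", "K", "n", "N", "p", "p_adj"],
    )
    top = table.sort_values(
        ["p_adj", "p", "set_name"], ascending=True, kind="stable"
    ).head(top_n).reset_index(drop=True)
    return results, top
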