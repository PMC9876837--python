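"""Over-representation analysis of gene lists against local gene sets.

For a query of n genes drawn from a measured universe of N genes, the
overlap k with a gene set of size K is tested against the hypergeometric
upper tail P(X ≥ k), X ~ Hypergeometric(N, K, n), evaluated in log space.
The universe is the collection of genes that survive probe collapsing —
conditioning on what was measured, the standard ORA background.
Benjamini-Hochberg FDR is applied within each gene-set category (BP, CC,
MF, KEGG) separately.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .deg import bh_adjust
from .io import GeneSetCollection

log = logging.getLogger(__name__)

ENRICH_COLUMNS = ["category", "term", "k", "n", "K", "N", "percent",
                  "p", "fdr", "genes"]


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X ≥ k).

    N genes in the universe, K in the set, n drawn (the query), k
    overlapping.  Computed as a log-space sum of the pmf for numerical
    stability; the result is clipped into (0, 1].
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    p = float(np.exp(logsumexp(logp)))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def enrich(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Test every gene set with ≥ 1 overlap against the query.

    Query genes outside the universe are ignored (warned); set members
    outside the universe do not count toward K.  FDR is BH within each
    category over all sets tested in that category.  Rows are sorted by p
    ascending.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        log.warning("%d query genes outside the universe ignored",
                    len(outside))
    query &= universe
    n, N = len(query), len(universe)

    rows = []
    for gs in collection:
        members = set(gs.genes) & universe
        overlap = sorted(query & members)
        if not overlap:
            continue
        k, K = len(overlap), len(members)
        rows.append({
            "category": gs.category,
            "term": gs.name,
            "k": k, "n": n, "K": K, "N": N,
            "percent": 100.0 * k / n if n else 0.0,
            "p": hypergeom_test(k, n, K, N),
            "genes": ",".join(overlap),
        })
    if not rows:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    for cat, idx in df.groupby("category").groups.items():
        df.loc[idx, "fdr"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return df[ENRICH_COLUMNS]
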