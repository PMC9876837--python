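"""Kim-Park feature scoring and metagene membership on an NMF basis matrix.

Each gene's loadings across the r metagenes are row-normalized into
contributions p(i, q) = W(i, q) / Σ_q' W(i, q'); the Kim-Park score

    S(i) = 1 + (1 / log2 r) · Σ_q p(i, q) · log2 p(i, q)     (0·log 0 := 0)

is 1 for a gene loading on exactly one metagene and 0 for a uniformly
loading (uninformative) gene.  Genes are selected as metagene features when
their score exceeds median(S) + 3·MAD(S) *and* their maximum loading
exceeds the median of all entries of W; each selected gene is assigned to
its argmax metagene (ties to the lowest index) while the full contribution
vector is preserved.  Metagenes retaining fewer than two members are
dropped.  Metagenes are ranked by activation — the sum of their members'
loadings — in descending order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

log = logging.getLogger(__name__)


@dataclass
class MetageneSet:
    """Selected metagene members with scores, plus activation ranking.

    ``members`` columns: gene, metagene, loading (W(i, q*)), contribution
    (p(i, q*)), score; ``activation`` maps metagene index to the sum of its
    members' loadings; ``order`` lists metagene indices by activation
    descending (ties to the lower index) once :func:`rank_metagenes` has
    run.
    """

    members: pd.DataFrame
    activation: pd.Series
    order: list[int] = field(default_factory=list)
    contributions: pd.DataFrame | None = None  # full p(i, q) for members

    @property
    def metagene_ids(self) -> list[int]:
        return sorted(self.activation.index)

    def genes_of(self, q: int) -> list[str]:
        sub = self.members[self.members["metagene"] == q]
        return list(sub["gene"])


def kim_park_scores(W: np.ndarray) -> np.ndarray:
    """Per-gene Kim-Park scores in [0, 1]; NaN for all-zero rows."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("W must be a matrix")
    if np.any(W < 0):
        raise ValueError("W must be nonnegative")
    r = W.shape[1]
    if r < 2:
        raise ValueError("need at least 2 metagenes (log2 r = 0 for r = 1)")
    rowsum = W.sum(axis=1)
    zero = rowsum == 0
    if zero.any():
        log.warning("%d all-zero rows of W: score undefined, excluded",
                    int(zero.sum()))
    p = np.divide(W, rowsum[:, None], out=np.zeros_like(W),
                  where=rowsum[:, None] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    s = 1.0 + plogp.sum(axis=1) / np.log2(r)
    s = np.clip(s, 0.0, 1.0)
    s[zero] = np.nan
    return s


def select_metagene_genes(W: np.ndarray, scores: np.ndarray,
                          gene_names=None,
                          mad_scale: str = "normal") -> MetageneSet:
    """Select metagene feature genes and assign them to metagenes.

    A gene is retained iff S(i) > median(S) + 3·MAD(S) and
    max_q W(i, q) > median(all entries of W), both strict.  ``mad_scale``
    is ``'normal'`` (MAD × 1.4826, the R convention) or ``'raw'``.
    Metagenes with fewer than two surviving members are excluded.
    """
    W = np.asarray(W, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(W.shape[0])]
    gene_names = list(gene_names)
    if len(gene_names) != W.shape[0] or scores.shape[0] != W.shape[0]:
        raise ValueError("W, scores and gene_names must align")
    scale = "normal" if mad_scale == "normal" else 1.0
    valid = ~np.isnan(scores)
    med = float(np.median(scores[valid]))
    mad = float(median_abs_deviation(scores[valid], scale=scale))
    threshold = med + 3.0 * mad
    w_median = float(np.median(W))
    max_load = W.max(axis=1)
    keep = valid & (scores > threshold) & (max_load > w_median)
    if not keep.any():
        log.warning("Kim-Park selection returned no genes "
                    "(threshold %.4g)", threshold)

    assigned = W.argmax(axis=1)  # argmax ties -> lowest index
    rowsum = W.sum(axis=1)
    rows, contrib_rows = [], []
    for i in np.flatnonzero(keep):
        q = int(assigned[i])
        rows.append({
            "gene": gene_names[i],
            "metagene": q,
            "loading": float(W[i, q]),
            "contribution": float(W[i, q] / rowsum[i]),
            "score": float(scores[i]),
        })
        contrib_rows.append(W[i] / rowsum[i])
    members = pd.DataFrame(rows, columns=["gene", "metagene", "loading",
                                          "contribution", "score"])

    # drop metagenes with < 2 members
    counts = members["metagene"].value_counts()
    small = counts.index[counts < 2]
    if len(small):
        log.info("excluding %d metagenes with < 2 members", len(small))
    keep_rows = ~members["metagene"].isin(small)
    contrib = (pd.DataFrame(np.array(contrib_rows)[keep_rows.to_numpy()],
                            index=members.loc[keep_rows, "gene"])
               if len(rows) else None)
    members = members.loc[keep_rows].reset_index(drop=True)

    activation = members.groupby("metagene")["loading"].sum()
    activation.name = "activation"
    return MetageneSet(members=members, activation=activation,
                       contributions=contrib)


def rank_metagenes(mset: MetageneSet, top: int = 15) -> MetageneSet:
    """Order metagenes by activation (descending, ties to the lower index)
    and sort members within each metagene by loading descending; the
    members table gains ``rank`` (metagene rank, 1-based) and
    ``member_rank`` columns, truncated to the ``top`` strongest members per
    metagene."""
    if mset.members.empty:
        raise ValueError("cannot rank an empty metagene set")
    act = mset.activation.sort_index()
    order = sorted(act.index, key=lambda q: (-act[q], q))
    rank_of = {q: i + 1 for i, q in enumerate(order)}

    members = mset.members.copy()
    members["rank"] = members["metagene"].map(rank_of)
    members = members.sort_values(
        ["rank", "loading", "gene"], ascending=[True, False, True],
        kind="mergesort").reset_index(drop=True)
    members["member_rank"] = members.groupby("metagene").cumcount() + 1
    members = members[members["member_rank"] <= top].reset_index(drop=True)
    return MetageneSet(members=members, activation=mset.activation,
                       order=order, contributions=mset.contributions)
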