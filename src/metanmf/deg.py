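"""Two-group differential expression on log2 intensity data.

The workflow mirrors standard microarray practice: drop low-intensity
probes, average duplicate probes per gene symbol, compute an
empirical-Bayes moderated t-statistic (pooled two-group variance shrunk
toward a common prior, Smyth-style), adjust p-values by Benjamini-Hochberg,
and select DEGs at p < 0.05 and |logFC| > 0.5 (strict inequalities).

logFC is the case-group mean minus the control-group mean on the log2
scale.  The DEG filter defaults to the *raw* p-value, with the adjusted
p-value reported alongside and available as the filter criterion via
``use_adjusted``.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import CASE, CONTROL, ExpressionDataset

log = logging.getLogger(__name__)

DEG_COLUMNS = ["gene", "logFC", "t", "p", "p_adj", "direction", "mean_expr"]


# ---------------------------------------------------------------------------
# probe-level preprocessing
# ---------------------------------------------------------------------------

def filter_low_expression(dataset: ExpressionDataset,
                          quantile: float = 0.2) -> ExpressionDataset:
    """Remove probes whose median log2 intensity is strictly below the given
    quantile of all probe medians.  Ties at the cutoff are retained."""
    if not 0 <= quantile < 1:
        raise ValueError("quantile must be in [0, 1)")
    medians = dataset.matrix.median(axis=1)
    cutoff = float(np.quantile(medians.to_numpy(), quantile))
    keep = medians >= cutoff
    if not keep.any():
        raise ValueError("low-expression filter would remove every probe")
    removed = int((~keep).sum())
    if removed:
        log.info("low-expression filter: removed %d of %d probes "
                 "(median < %.4g)", removed, len(medians), cutoff)
    return dataset.subset_probes(dataset.matrix.index[keep])


def collapse_probes(dataset: ExpressionDataset) -> ExpressionDataset:
    """Average duplicate probes per gene symbol; one row per symbol.

    Unannotated probes are dropped (count logged).  The returned dataset is
    keyed by gene symbol, with an identity annotation.
    """
    ann = dataset.annotation
    annotated = [p for p in dataset.matrix.index if p in ann.index]
    dropped = len(dataset.matrix.index) - len(annotated)
    if dropped:
        log.info("collapse: dropping %d unannotated probes", dropped)
    if not annotated:
        raise ValueError("no annotated probes to collapse")
    sub = dataset.matrix.loc[annotated]
    symbols = ann.loc[annotated]
    collapsed = sub.groupby(symbols.values, sort=True).mean()
    collapsed.index.name = "gene"
    identity = pd.Series(collapsed.index.values, index=collapsed.index.values,
                         name="gene_symbol")
    return ExpressionDataset(matrix=collapsed, groups=dataset.groups,
                             annotation=identity,
                             log2_applied=dataset.log2_applied)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    # Newton iteration for psi'(x) = y (monotone decreasing, convex).
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    return x


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink per-gene pooled variances toward a common prior.

    The prior (d0, s0^2) is fit by matching the first two moments of
    log s_g^2 under the scaled-F model (digamma/trigamma moment equations);
    the posterior variance is the df-weighted mix
    (d0*s0^2 + df*s2) / (d0 + df).

    Returns (posterior variances, d0, s0^2); d0 may be ``inf`` when the
    observed variances show no excess spread over chi-square sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all pooled variances are zero; cannot fit a prior")
    z = np.log(s2[positive])
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = e_mean + float(special.digamma(d0 / 2.0)) - np.log(d0 / 2.0)
    else:
        d0 = np.inf
        log_s0 = e_mean
    s0_sq = float(np.exp(log_s0))
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0, s0_sq


def moderated_t(dataset: ExpressionDataset,
                moderation: bool = True) -> pd.DataFrame:
    """Per-gene two-group (moderated) t-test; returns the full table without
    any thresholding, sorted by p ascending.

    With ``moderation=False`` this reduces to the ordinary equal-variance
    pooled two-sample t-test.
    """
    ctrl = dataset.samples_in_group(CONTROL)
    case = dataset.samples_in_group(CASE)
    n1, n2 = len(ctrl), len(case)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")
    x = dataset.matrix[ctrl].to_numpy(dtype=float)
    y = dataset.matrix[case].to_numpy(dtype=float)
    mean_ctrl, mean_case = x.mean(axis=1), y.mean(axis=1)
    logfc = mean_case - mean_ctrl
    df_resid = n1 + n2 - 2
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)

    if moderation:
        s2_post, d0, s0_sq = squeeze_variances(s2, df_resid)
        df_total = d0 + df_resid
        log.info("variance shrinkage: d0=%.4g, s0^2=%.4g", d0, s0_sq)
    else:
        if np.all(s2 == 0):
            raise ValueError(
                "all genes have zero within-group variance; "
                "the unmoderated t is undefined"
            )
        s2_post, df_total = s2, df_resid

    se = np.sqrt(s2_post) * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0),
                     np.where(logfc == 0, 0.0, np.sign(logfc) * np.inf))
    df_eff = df_total if np.isfinite(df_total) else 1e9
    p = 2.0 * stats.t.sf(np.abs(t), df_eff)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame({
        "gene": dataset.matrix.index,
        "logFC": logfc,
        "t": t,
        "p": p,
        "p_adj": bh_adjust(p),
        "direction": np.where(logfc > 0, "up", "down"),
        "mean_expr": dataset.matrix.mean(axis=1).to_numpy(),
    })
    return table.sort_values("p", kind="mergesort").reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(table: pd.DataFrame, p_cut: float = 0.05,
                lfc_cut: float = 0.5,
                use_adjusted: bool = False) -> pd.DataFrame:
    """Apply the DEG filter: p < p_cut and |logFC| > lfc_cut, both strict."""
    if p_cut <= 0 or lfc_cut < 0:
        raise ValueError("cuts must be positive")
    crit = table["p_adj"] if use_adjusted else table["p"]
    keep = (crit < p_cut) & (table["logFC"].abs() > lfc_cut)
    out = table.loc[keep].reset_index(drop=True)
    n_up = int((out["direction"] == "up").sum())
    n_down = int((out["direction"] == "down").sum())
    if out.empty:
        log.warning("DEG filter retained no genes")
    else:
        log.info("DEG filter: %d genes (%d up, %d down)", len(out), n_up, n_down)
    return out
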