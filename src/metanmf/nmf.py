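"""Nonnegative matrix factorization with knee-point rank selection.

``V ≈ W·H`` is fit by the classic multiplicative updates for the Frobenius
objective (the residual sum of squares, RSS = ‖V − WH‖²_F):

    H ← H ∘ (WᵀV) / (WᵀW H + ε)
    W ← W ∘ (V Hᵀ) / (W H Hᵀ + ε)        ε = 1e−12

These updates keep W and H nonnegative and never increase the objective.
The number of metagenes r is chosen by scanning a rank grid (default
3..30), recording the best-of-restarts RSS per rank, and locating the knee
of the RSS-vs-rank curve: after min-max scaling both axes to [0, 1], the
knee is the interior point with the maximum perpendicular distance to the
chord joining the curve's endpoints — a unit-invariant criterion, so the
chosen rank does not depend on the units of either axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

EPS = 1e-12


@dataclass
class Factorization:
    """Result of one multiplicative-update NMF run."""

    V: np.ndarray
    W: np.ndarray
    H: np.ndarray
    r: int
    rss: float
    n_iter: int
    seed: int
    converged: bool
    rss_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class RankCurve:
    """Best-of-restarts RSS over an ascending rank grid."""

    ranks: tuple[int, ...]
    rss_values: tuple[float, ...]
    chosen_rank: int | None = None
    factorizations: dict[int, Factorization] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ranks) != len(self.rss_values):
            raise ValueError("ranks and rss_values must be the same length")
        if any(b <= a for a, b in zip(self.ranks, self.ranks[1:])):
            raise ValueError("ranks must be strictly increasing")


# ---------------------------------------------------------------------------
# target construction
# ---------------------------------------------------------------------------

def build_target(dataset, genes, max_rank: int | None = None):
    """Restrict a symbol-keyed expression dataset to the DEG rows.

    Returns ``(V, gene_index, shift)``: V is the nonnegative genes × samples
    array (shifted by the global minimum if any entry is negative; the shift
    is logged and returned), gene_index the row labels.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("DEG list is empty")
    missing = [g for g in genes if g not in dataset.matrix.index]
    if missing:
        raise ValueError(f"genes absent from dataset: {missing[:5]}")
    if max_rank is not None and len(genes) < max_rank:
        raise ValueError(
            f"only {len(genes)} DEG rows but the rank grid extends to "
            f"{max_rank}; use a smaller grid"
        )
    v = dataset.matrix.loc[genes].to_numpy(dtype=float)
    shift = 0.0
    if v.min() < 0:
        shift = -float(v.min())
        v = v + shift
        log.info("build_target: shifted matrix by +%.4g to enforce "
                 "nonnegativity", shift)
    return v, list(genes), shift


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def nmf_fit(V: np.ndarray, r: int, seed: int = 0, max_iter: int = 2000,
            tol: float = 1e-5) -> Factorization:
    """Fit rank-r NMF by seeded multiplicative updates.

    Stops when the relative RSS decrease drops below ``tol`` or after
    ``max_iter`` iterations.  Deterministic for a fixed seed.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a matrix")
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    m, n = V.shape
    if not 1 <= r <= min(m, n):
        raise ValueError(f"rank {r} outside [1, {min(m, n)}]")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(float(V.mean()), EPS) / r)
    # uniform on (0, 1], scaled so W·H starts on the scale of V
    w = scale * (1.0 - rng.random((m, r)))
    h = scale * (1.0 - rng.random((r, n)))

    norm_v = float(np.einsum("ij,ij->", V, V))
    history = np.empty(max_iter + 1)
    rss = float(np.linalg.norm(V - w @ h) ** 2)
    history[0] = rss
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wtv = w.T @ V
        wtw = w.T @ w
        h *= wtv / (wtw @ h + EPS)
        hht = h @ h.T
        w *= (V @ h.T) / (w @ hht + EPS)
        if not (np.isfinite(w).all() and np.isfinite(h).all()):
            raise FloatingPointError("NMF update produced non-finite values")
        # RSS from cached Gram products at the (W_old, H_new) half-step:
        # ||V||^2 - 2 tr(H^T W^T V) + tr((W^T W)(H H^T)); each half-step is
        # non-increasing, so the recorded sequence stays monotone
        prev = rss
        rss = max(float(norm_v - 2.0 * np.einsum("ij,ij->", h, wtv)
                        + np.einsum("ij,ij->", wtw, hht)), 0.0)
        history[it] = rss
        if prev > 0 and abs(prev - rss) / prev < tol:
            converged = True
            break
    # exact residual of the factors actually returned
    rss = float(np.linalg.norm(V - w @ h) ** 2)
    history[it] = min(history[it], rss) if it else rss
    return Factorization(V=V, W=w, H=h, r=r, rss=rss, n_iter=it, seed=seed,
                         converged=converged, rss_history=history[: it + 1])


def rank_scan(V: np.ndarray, rank_grid, n_restarts: int = 10,
              base_seed: int = 0, max_iter: int = 2000, tol: float = 1e-5,
              keep_factors: bool = True) -> RankCurve:
    """Best-of-restarts RSS per rank over a grid (chosen rank left unset).

    Restart ``j`` of every rank uses seed ``base_seed + j``.
    """
    V = np.asarray(V, dtype=float)
    ranks = [int(r) for r in rank_grid]
    if len(ranks) < 2:
        raise ValueError("rank grid needs at least 2 points "
                         "(3 for knee selection)")
    lo, hi = min(ranks), max(ranks)
    if lo < 2 or hi > min(V.shape):
        raise ValueError(f"rank grid [{lo}, {hi}] outside [2, {min(V.shape)}]")
    if n_restarts < 1:
        raise ValueError("need at least one restart")

    rss_values: list[float] = []
    best_fits: dict[int, Factorization] = {}
    for r in ranks:
        best: Factorization | None = None
        for j in range(n_restarts):
            fit = nmf_fit(V, r, seed=base_seed + j, max_iter=max_iter, tol=tol)
            if best is None or fit.rss < best.rss:
                best = fit
        assert best is not None
        rss_values.append(best.rss)
        if keep_factors:
            best_fits[r] = best
        log.debug("rank %d: best RSS %.6g over %d restarts", r, best.rss,
                  n_restarts)
    return RankCurve(ranks=tuple(ranks), rss_values=tuple(rss_values),
                     factorizations=best_fits)


# ---------------------------------------------------------------------------
# knee location
# ---------------------------------------------------------------------------

def uik_knee(curve, distance: str = "perpendicular") -> int:
    """Locate the knee of an RSS-vs-rank curve (unit-invariant).

    Both axes are min-max scaled to [0, 1]; for each interior point the
    distance to the chord joining the first and last scaled points is
    computed (perpendicular by default, vertical via
    ``distance='vertical'``).  The knee is the abscissa of the maximum
    distance; ties break toward the smaller rank.  A flat or exactly linear
    curve has no knee and raises ``ValueError``.
    """
    if isinstance(curve, RankCurve):
        x = np.asarray(curve.ranks, dtype=float)
        y = np.asarray(curve.rss_values, dtype=float)
    else:
        x, y = (np.asarray(a, dtype=float) for a in curve)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 curve points")
    if np.ptp(y) == 0:
        raise ValueError("flat RSS curve has no knee")
    if distance not in ("perpendicular", "vertical"):
        raise ValueError(f"unknown distance {distance!r}")

    xs = (x - x[0]) / (x[-1] - x[0])
    ys = (y - y.min()) / np.ptp(y)
    # chord through the scaled endpoints
    p0 = np.array([xs[0], ys[0]])
    p1 = np.array([xs[-1], ys[-1]])
    d = p1 - p0
    interior = slice(1, -1)
    pts = np.column_stack([xs[interior], ys[interior]])
    if distance == "perpendicular":
        rel = pts - p0
        cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
        dist = np.abs(cross) / np.linalg.norm(d)
    else:
        chord_y = p0[1] + (pts[:, 0] - p0[0]) * d[1] / d[0]
        dist = np.abs(chord_y - pts[:, 1])
    dmax = float(dist.max())
    if dmax < 1e-12:
        raise ValueError("curve is linear: no knee")
    # first index within tolerance of the max -> smaller rank on ties
    idx = int(np.flatnonzero(dist >= dmax - 1e-12)[0]) + 1
    val = float(x[idx])
    return int(val) if val.is_integer() else val


def select_rank(V: np.ndarray, rank_grid=range(3, 31), n_restarts: int = 10,
                base_seed: int = 0, max_iter: int = 2000, tol: float = 1e-5,
                distance: str = "perpendicular") -> RankCurve:
    """Rank scan followed by knee selection; returns the curve with
    ``chosen_rank`` set and the best factorization per rank retained."""
    curve = rank_scan(V, rank_grid, n_restarts=n_restarts,
                      base_seed=base_seed, max_iter=max_iter, tol=tol)
    if len(curve.ranks) < 3:
        raise ValueError("knee selection needs at least 3 grid points")
    curve.chosen_rank = uik_knee(curve, distance=distance)
    log.info("rank selection: chose r=%d on grid [%d, %d]",
             curve.chosen_rank, curve.ranks[0], curve.ranks[-1])
    return curve
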