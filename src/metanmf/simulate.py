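"""Synthetic two-group expression studies with planted, recoverable structure.

The generator emulates a small case/control microarray study on the log2
intensity scale: a low-rank nonnegative signal (the "metagenes"), a per-gene
baseline, planted differential expression in both directions, duplicate
probes per gene symbol, a scale-free-ish interaction graph with planted hub
genes, and positive-control annotation tables (gene sets, gene-disease and
TF-target associations).  Every planted feature is returned as ground truth
so each downstream stage of the pipeline has a known answer.

Construction of the signal matrix.  The planted signal is exactly a
nonnegative rank-``r_true`` product ``W·H``:

* ``r_true − 2`` *content* metagenes: block-sparse columns of W (each
  metagene owns a disjoint core of genes plus ~5% overlap genes, since a
  gene may take part in more than one expression program) with activities
  in H whose group means are balanced, so they contribute no fold change;
* two *group* factors ``(B+U)·case^T`` and ``(B+D)·ctrl^T`` where B is the
  per-gene baseline (≥ 4 log2 units), U holds the up-regulation effects and
  D the down-regulation effects.  Because ``case^T + ctrl^T = 1^T`` these
  two nonnegative rank-1 terms encode both the baseline and an exact
  per-gene log2 fold change of ``U − D``.

Probe intensities are the gene signal plus i.i.d. Gaussian noise on the
log2 scale, truncated at zero (the truncation essentially never binds at a
baseline of ≥ 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    CASE,
    CONTROL,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
)

log = logging.getLogger(__name__)

DISEASE_LABELS = (
    "cognition disorder",
    "schizophrenia",
    "amyotrophic lateral sclerosis",
    "Alzheimer disease",
)

OVERLAP_FRACTION = 0.05

#: activation contrast of a content program: samples sit at 1 + amp,
#: 1 - amp or 1 (equal numbers of high and low per group)
ACTIVITY_AMPLITUDE = 0.9

#: lognormal sigma of program gene-loadings (heavy tail: a few strongly
#: committed genes per program) and the mean per-gene loading energy the
#: columns are equalized to
LOADING_SIGMA = 1.2
LOADING_ENERGY = 1.3


def _balanced_signs(m: int, rng: np.random.Generator) -> np.ndarray:
    """A random permutation of m//2 ones, m//2 minus-ones (and a zero when
    m is odd): exactly zero-mean within the group."""
    k = m // 2
    pattern = np.concatenate([np.ones(k), -np.ones(k), np.zeros(m - 2 * k)])
    return rng.permutation(pattern)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the stated synthetic world.

    Defaults emulate a small neurovascular case/control microarray design:
    5 control vs 6 case subjects in each of three cell types (15 vs 18
    samples), 218 planted up- and 780 down-regulated genes, a planted rank
    of 10, and effect sizes comfortably above the |logFC| > 0.5 selection
    threshold.
    """

    n_genes: int = 5000
    n_probes_per_gene: tuple[int, int] = (1, 3)
    n_samples_per_group: tuple[int, int] = (15, 18)
    n_de_up: int = 218
    n_de_down: int = 780
    de_logfc_range: tuple[float, float] = (0.6, 1.5)
    r_true: int = 10
    noise_sd: float = 0.3
    network_n_nodes: int = 1500
    network_planted_hub_degree: int = 30
    n_hubs: int = 6
    baseline_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.network_n_nodes <= 0 or self.n_hubs <= 0:
            raise ValueError("all counts must be positive")
        if min(self.n_samples_per_group) <= 0:
            raise ValueError("sample counts must be positive")
        if self.n_de_up < 0 or self.n_de_down < 0:
            raise ValueError("DE counts must be nonnegative")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError("n_de_up + n_de_down exceeds n_genes")
        if self.r_true < 2:
            raise ValueError("r_true must be at least 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        lo, hi = self.n_probes_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("n_probes_per_gene must be an increasing pair >= 1")
        if self.de_logfc_range[0] <= 0 or self.de_logfc_range[1] < self.de_logfc_range[0]:
            raise ValueError("de_logfc_range must be a positive interval")
        if self.baseline_range[0] < 4.0:
            raise ValueError("baseline offset must be at least 4 log2 units")

    @property
    def n_samples(self) -> int:
        return sum(self.n_samples_per_group)


@dataclass
class GroundTruth:
    """Planted structure of one simulated study."""

    de_genes_up: frozenset[str]
    de_genes_down: frozenset[str]
    metagene_membership: dict[str, tuple[int, ...]]  # gene -> content metagenes
    hub_genes: frozenset[str]
    gene_symbols: tuple[str, ...] = ()
    planted_w: np.ndarray | None = None  # genes × r_true
    planted_h: np.ndarray | None = None  # r_true × samples
    planted_logfc: dict[str, float] = field(default_factory=dict)

    def metagene_members(self, q: int) -> frozenset[str]:
        return frozenset(
            g for g, qs in self.metagene_membership.items() if q in qs
        )

    @property
    def n_content_metagenes(self) -> int:
        if not self.metagene_membership:
            return 0
        return 1 + max(q for qs in self.metagene_membership.values() for q in qs)


def _symbols(n: int) -> list[str]:
    return [f"SYG{i:05d}" for i in range(n)]


def simulate_expression(
    config: SimulationConfig,
    force_up: Sequence[str] = (),
    force_down: Sequence[str] = (),
) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a probe × sample log2 expression dataset plus ground truth.

    ``force_up`` / ``force_down`` name gene symbols that must be among the
    planted up/down-regulated sets (used to build dataset pairs sharing
    differentially expressed genes).
    """
    n1, n2 = config.n_samples_per_group
    n_samples = n1 + n2
    if config.r_true > min(config.n_genes, n_samples):
        raise ValueError(
            f"r_true={config.r_true} exceeds min(n_genes, n_samples)="
            f"{min(config.n_genes, n_samples)}"
        )
    rng = np.random.default_rng(config.seed)
    genes = _symbols(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # ---- differential expression assignment -----------------------------
    for sym in (*force_up, *force_down):
        if sym not in gene_pos:
            raise ValueError(f"forced DE gene {sym!r} not in gene universe")
    free = [g for g in genes if g not in set(force_up) | set(force_down)]
    perm = rng.permutation(len(free))
    it = iter(perm)
    up = list(force_up)
    while len(up) < config.n_de_up:
        up.append(free[next(it)])
    down = list(force_down)
    while len(down) < config.n_de_down:
        g = free[next(it)]
        if g not in up:
            down.append(g)
    up, down = up[: config.n_de_up], down[: config.n_de_down]

    lo, hi = config.de_logfc_range
    u_vec = np.zeros(config.n_genes)
    d_vec = np.zeros(config.n_genes)
    for g in up:
        u_vec[gene_pos[g]] = rng.uniform(lo, hi)
    for g in down:
        d_vec[gene_pos[g]] = rng.uniform(lo, hi)

    # ---- content metagenes ----------------------------------------------
    hubs = frozenset(up[: config.n_hubs]) if up else frozenset()

    r_content = config.r_true - 2
    w_content = np.zeros((config.n_genes, r_content))
    membership: dict[str, list[int]] = {}
    if r_content > 0:
        # planted hubs are kept out of the content programs: program
        # activity adds within-group variance, and the hubs' differential
        # expression must stay unambiguous (hubness and program membership
        # are separately planted features)
        eligible = np.array([i for i in range(config.n_genes)
                             if genes[i] not in hubs])
        order = rng.permutation(eligible)
        cores = np.array_split(order, r_content)
        # Loadings are heavy-tailed (lognormal), like real NMF basis
        # columns: a few strongly committed genes per program.  A high
        # loading coefficient of variation is also what keeps the planted
        # factors spectrally separable — near-constant positive loadings
        # would make every program's gene vector almost parallel to the
        # baseline, and the planted rank numerically undetectable.  Columns
        # are norm-equalized so programs carry comparable energy.
        for q, core in enumerate(cores):
            members = list(core)
            outside = np.setdiff1d(order, core, assume_unique=True)
            n_extra = min(max(1, int(round(OVERLAP_FRACTION * len(core)))),
                          len(outside))
            if n_extra > 0:
                members += list(rng.choice(outside, size=n_extra,
                                           replace=False))
            load = rng.lognormal(0.0, LOADING_SIGMA, len(members))
            load *= np.sqrt(LOADING_ENERGY * len(members)) / np.linalg.norm(load)
            for i, w in zip(members, load):
                w_content[i, q] = w
                membership.setdefault(genes[i], []).append(q)

    # content activities: each expression program is "on" in its own block
    # of samples (emulating cell-type / cell-state specific programs, with
    # blocks balanced across the two groups) and near zero elsewhere, so the
    # planted factors carry comparable energy.  Group means are balanced
    # multiplicatively so content metagenes add no fold change.
    # content activities: three-level activation 1 ± AMP (high / neutral /
    # low) with equal numbers of high and low samples inside each group.
    # The deviation patterns are then zero-mean within both groups, so the
    # content programs add no fold change, and they are mutually
    # near-orthogonal and orthogonal to the constant and to the group
    # indicators — keeping every planted factor's energy well separated
    # (without this, nonnegative activity rows are all strongly aligned
    # with the baseline factor and the planted rank becomes numerically
    # undetectable).
    h_content = np.empty((r_content, n_samples))
    for q in range(r_content):
        h_content[q] = 1.0 + ACTIVITY_AMPLITUDE * np.concatenate(
            [_balanced_signs(n1, rng), _balanced_signs(n2, rng)])

    # ---- group factors (baseline + DE) ----------------------------------
    baseline = rng.uniform(*config.baseline_range, size=config.n_genes)
    ctrl_ind = np.concatenate([np.ones(n1), np.zeros(n2)])
    case_ind = 1.0 - ctrl_ind
    w_full = np.column_stack([w_content, baseline + u_vec, baseline + d_vec])
    h_full = np.vstack([h_content, case_ind[None, :], ctrl_ind[None, :]])
    signal = w_full @ h_full

    # ---- probes ----------------------------------------------------------
    plo, phi = config.n_probes_per_gene
    n_probes = rng.integers(plo, phi + 1, size=config.n_genes)
    probe_gene_idx = np.repeat(np.arange(config.n_genes), n_probes)
    probe_ids = []
    counter = 0
    for gi, k in zip(range(config.n_genes), n_probes):
        for _ in range(k):
            probe_ids.append(f"P{counter:06d}_at")
            counter += 1
    values = signal[probe_gene_idx]
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
        values = np.maximum(values, 0.0)

    sample_ids = [f"CTRL_{i + 1:02d}" for i in range(n1)] + [
        f"CASE_{i + 1:02d}" for i in range(n2)
    ]
    matrix = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    groups = pd.Series(
        [CONTROL] * n1 + [CASE] * n2, index=sample_ids, name="group"
    )
    annotation = pd.Series(
        [genes[i] for i in probe_gene_idx], index=probe_ids, name="gene_symbol"
    )
    dataset = ExpressionDataset(matrix=matrix, groups=groups,
                                annotation=annotation)

    truth = GroundTruth(
        de_genes_up=frozenset(up),
        de_genes_down=frozenset(down),
        metagene_membership={g: tuple(sorted(qs)) for g, qs in membership.items()},
        hub_genes=hubs,
        gene_symbols=tuple(genes),
        planted_w=w_full,
        planted_h=h_full,
        planted_logfc={
            **{g: float(u_vec[gene_pos[g]]) for g in up},
            **{g: -float(d_vec[gene_pos[g]]) for g in down},
        },
    )
    log.info("simulated %d probes / %d genes, %d+%d samples, rank %d",
             len(probe_ids), config.n_genes, n1, n2, config.r_true)
    return dataset, truth


def simulate_network(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Generate a scale-free-ish undirected interactome containing the
    planted hubs, as an edge list with confidence scores in [0, 1].

    Preferential attachment yields the heavy-tailed degree distribution;
    each planted hub is then wired up to ``network_planted_hub_degree``
    neighbours.  Hub-incident edges receive scores ≥ 0.9 so they survive
    confidence filtering.
    """
    import networkx as nx

    rng = np.random.default_rng(config.seed + 1)
    genes = list(truth.gene_symbols)
    hubs = sorted(truth.hub_genes)
    de = sorted((truth.de_genes_up | truth.de_genes_down) - set(hubs))
    others = [g for g in genes if g not in truth.de_genes_up
              and g not in truth.de_genes_down]
    n_nodes = min(config.network_n_nodes, len(genes))
    nodes = list(hubs)
    nodes += de[: max(0, n_nodes - len(nodes))]
    if len(nodes) < n_nodes:
        extra = rng.choice(len(others), size=n_nodes - len(nodes), replace=False)
        nodes += [others[i] for i in sorted(extra)]
    if len(nodes) < 3:
        raise ValueError("network needs at least 3 nodes")

    m = min(3, len(nodes) - 1)
    g = nx.barabasi_albert_graph(len(nodes), m, seed=int(config.seed + 1))
    # place hubs at the early (high-degree) attachment positions
    mapping = {i: nodes[i] for i in range(len(nodes))}
    g = nx.relabel_nodes(g, mapping)

    non_hubs = [v for v in nodes if v not in truth.hub_genes]
    for h in hubs:
        need = config.network_planted_hub_degree - g.degree(h)
        if need > 0:
            candidates = [v for v in non_hubs if not g.has_edge(h, v)]
            pick = rng.choice(len(candidates), size=need, replace=False)
            for i in pick:
                g.add_edge(h, candidates[i])

    hub_set = set(hubs)
    rows = []
    for a, b in sorted((min(a, b), max(a, b)) for a, b in g.edges()):
        if a in hub_set or b in hub_set:
            score = rng.uniform(0.9, 1.0)
        else:
            score = rng.uniform(0.6, 1.0)
        rows.append((a, b, round(float(score), 4)))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    log.info("simulated interactome: %d nodes, %d edges", len(nodes), len(edges))
    return edges


def simulate_annotations(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[GeneSetCollection, pd.DataFrame, pd.DataFrame]:
    """Generate positive-control annotation tables.

    Returns a GMT-style gene-set collection in which one set per planted
    content metagene is exactly that metagene's members, a gene-disease
    association table linking every planted hub to the four neurological
    disease labels, and a TF-target table in which ≥ 5 TFs regulate hub
    genes.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = list(truth.gene_symbols)
    coll = GeneSetCollection()
    categories = ("BP", "CC", "MF", "KEGG")
    for q in range(truth.n_content_metagenes):
        members = tuple(sorted(truth.metagene_members(q)))
        if members:
            coll.add(GeneSet(name=f"MG{q:02d}_CORE",
                             category=categories[q % 4], genes=members))
    n_random = 30
    for j in range(n_random):
        size = int(rng.integers(15, 80))
        idx = rng.choice(len(genes), size=size, replace=False)
        coll.add(GeneSet(name=f"RANDSET{j:03d}",
                         category=categories[j % 4],
                         genes=tuple(sorted(genes[i] for i in idx))))

    hubs = sorted(truth.hub_genes)
    gda_rows = [
        (h, dis, round(float(rng.uniform(0.3, 0.9)), 3))
        for h in hubs
        for dis in DISEASE_LABELS
    ]
    decoys = rng.choice(len(genes), size=20, replace=False)
    for i in decoys:
        if genes[i] in truth.hub_genes:
            continue
        dis = f"decoy disorder {int(rng.integers(1, 6))}"
        gda_rows.append((genes[i], dis, round(float(rng.uniform(0.1, 0.5)), 3)))
    gda = pd.DataFrame(gda_rows, columns=["gene", "entity", "score"])
    gda = gda.drop_duplicates(subset=["gene", "entity"]).reset_index(drop=True)

    n_tfs = max(5, min(8, len(hubs) + 2))
    tf_rows = []
    for t in range(n_tfs):
        tf = f"TF{t:02d}"
        targets = [hubs[i] for i in
                   rng.choice(len(hubs), size=max(1, len(hubs) // 2),
                              replace=False)] if hubs else []
        extra = rng.choice(len(genes), size=3, replace=False)
        targets += [genes[i] for i in extra]
        for tgt in dict.fromkeys(targets):
            tf_rows.append((tgt, tf, round(float(rng.uniform(0.5, 1.0)), 3)))
    tf = pd.DataFrame(tf_rows, columns=["gene", "entity", "score"])
    tf = tf.drop_duplicates(subset=["gene", "entity"]).reset_index(drop=True)
    return coll, gda, tf


def write_study(
    config: SimulationConfig,
    outdir,
    prefix: str = "",
    force_up: Sequence[str] = (),
    with_network: bool = True,
    with_annotations: bool = True,
) -> tuple[dict[str, str], GroundTruth]:
    """Simulate a full study and write every input table the pipeline
    consumes; returns ({role: path}, truth)."""
    from pathlib import Path

    from .io import (
        write_association,
        write_edge_list,
        write_expression,
        write_gmt,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, truth = simulate_expression(config, force_up=force_up)
    paths = {
        "expression": str(outdir / f"{prefix}expression.tsv"),
        "groups": str(outdir / f"{prefix}groups.tsv"),
        "annotation": str(outdir / f"{prefix}annotation.tsv"),
    }
    write_expression(ds, paths["expression"], paths["groups"],
                     paths["annotation"])
    if with_network:
        paths["edges"] = str(outdir / f"{prefix}edges.tsv")
        write_edge_list(simulate_network(config, truth), paths["edges"])
    if with_annotations:
        coll, gda, tf = simulate_annotations(config, truth)
        paths["gene_sets"] = str(outdir / f"{prefix}gene_sets.gmt")
        paths["gene_disease"] = str(outdir / f"{prefix}gene_disease.tsv")
        paths["tf_targets"] = str(outdir / f"{prefix}tf_targets.tsv")
        write_gmt(coll, paths["gene_sets"])
        write_association(gda, paths["gene_disease"])
        write_association(tf, paths["tf_targets"])
    return paths, truth


def simulate_pair(
    config1: SimulationConfig, config2: SimulationConfig
) -> tuple[
    tuple[ExpressionDataset, GroundTruth],
    tuple[ExpressionDataset, GroundTruth],
]:
    """Simulate two studies over the same gene universe that share the first
    study's planted hub genes as up-regulated DEGs, for cross-dataset
    validation."""
    if config1.n_genes != config2.n_genes:
        raise ValueError("paired studies must share the gene universe")
    ds1, truth1 = simulate_expression(config1)
    ds2, truth2 = simulate_expression(
        config2, force_up=sorted(truth1.hub_genes)
    )
    return (ds1, truth1), (ds2, truth2)
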