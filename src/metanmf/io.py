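"""Readers and writers for the tab-separated tables the pipeline consumes.

Every on-disk format is plain UTF-8, tab-separated, with ``#`` comment lines
allowed; gzip-compressed variants (``*.gz``) are handled transparently by
pandas.  Formats:

* expression matrix — rows are probe (or gene) IDs, columns are sample IDs,
  first header row carries the sample names;
* sample-group table — columns ``sample``, ``group`` with group in
  {``control``, ``case``};
* probe annotation — columns ``probe_id``, ``gene_symbol``;
* GMT gene sets — ``name<TAB>category<TAB>member...`` (MSigDB dialect, the
  description slot carries the category tag);
* interaction edge list — columns ``node_a``, ``node_b``, ``score``;
* association tables — columns ``gene``, ``entity``, ``score``.

Gene symbols are compared case-sensitively after whitespace trimming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"
VALID_GROUPS = (CONTROL, CASE)

#: heuristic: a log2-intensity matrix should not exceed this value; anything
#: larger is assumed to be on the linear scale and is log2(x+1)-transformed.
LOG2_GUARD = 50.0

GENE_SET_CATEGORIES = ("BP", "CC", "MF", "KEGG")


class FormatError(ValueError):
    """Raised when an input table violates the expected dialect."""


# ---------------------------------------------------------------------------
# expression data
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """A log2 probe (or gene) × sample expression matrix with metadata.

    Parameters
    ----------
    matrix
        Probes × samples DataFrame of nonnegative log2 intensities.
    groups
        Series mapping sample ID to ``'control'`` or ``'case'``.
    annotation
        Series mapping probe ID to gene symbol; probes absent from the index
        are treated as unannotated.
    log2_applied
        True when :func:`read_expression` applied the log2 guard transform.
    """

    matrix: pd.DataFrame
    groups: pd.Series
    annotation: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    log2_applied: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        idx, cols = self.matrix.index, self.matrix.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe IDs: {dup[:5]}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dup[:5]}")
        missing = [s for s in cols if s not in self.groups.index]
        if missing:
            raise FormatError(f"samples without a group assignment: {missing}")
        bad = set(self.groups.loc[list(cols)]) - set(VALID_GROUPS)
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        if self.matrix.isna().any().any():
            raise FormatError("expression matrix contains missing entries")

    # -- convenience -------------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    def samples_in_group(self, group: str) -> list[str]:
        g = self.groups.loc[list(self.matrix.columns)]
        return list(g.index[g == group])

    def unannotated_probes(self) -> list[str]:
        return [p for p in self.matrix.index if p not in self.annotation.index]

    def subset_probes(self, probes: Iterable[str]) -> "ExpressionDataset":
        probes = list(probes)
        return replace(self, matrix=self.matrix.loc[probes])


def read_expression(
    matrix_path: str | Path,
    groups_path: str | Path,
    annotation_path: str | Path | None = None,
    na_action: str = "error",
) -> ExpressionDataset:
    """Load an expression matrix plus sample groups (and optional annotation).

    If the matrix maximum exceeds ``LOG2_GUARD`` the data are assumed linear
    and log2(x+1) is applied; the event is logged and recorded on the
    returned dataset.

    ``na_action``: ``'error'`` rejects missing entries, ``'impute'`` fills
    them with the probe median.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    matrix.index = matrix.index.astype(str).str.strip()
    matrix.columns = matrix.columns.astype(str).str.strip()

    if matrix.isna().any().any():
        if na_action == "impute":
            n_missing = int(matrix.isna().sum().sum())
            med = matrix.median(axis=1)
            matrix = matrix.apply(lambda row: row.fillna(med[row.name]), axis=1)
            log.warning("imputed %d missing entries with probe medians", n_missing)
        else:
            bad = matrix.index[matrix.isna().any(axis=1)].tolist()
            raise FormatError(f"missing entries in probes {bad[:5]}")

    log2_applied = False
    if matrix.size and float(matrix.to_numpy().max()) > LOG2_GUARD:
        log.info("matrix max %.1f > %.0f: applying log2(x+1)",
                 matrix.to_numpy().max(), LOG2_GUARD)
        matrix = np.log2(matrix + 1.0)
        log2_applied = True

    groups = read_groups(groups_path)
    annotation = (
        read_annotation(annotation_path) if annotation_path is not None
        else pd.Series(dtype=object)
    )
    ds = ExpressionDataset(matrix=matrix, groups=groups,
                           annotation=annotation, log2_applied=log2_applied)
    n_unann = len(ds.unannotated_probes())
    if annotation_path is not None and n_unann:
        log.warning("%d probes lack a gene-symbol annotation", n_unann)
    return ds


def read_groups(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise FormatError(
            f"{path}: expected columns 'sample', 'group', got {list(df.columns)}"
        )
    df["sample"] = df["sample"].str.strip()
    if df["sample"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample rows")
    return pd.Series(df["group"].str.strip().values, index=df["sample"].values,
                     name="group")


def read_annotation(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:2]) != ["probe_id", "gene_symbol"]:
        raise FormatError(
            f"{path}: expected columns 'probe_id', 'gene_symbol', "
            f"got {list(df.columns)}"
        )
    df = df.dropna(subset=["gene_symbol"])
    probe = df["probe_id"].str.strip()
    if probe.duplicated().any():
        raise FormatError(f"{path}: duplicate probe_id rows")
    return pd.Series(df["gene_symbol"].str.strip().values, index=probe.values,
                     name="gene_symbol")


def write_expression(ds: ExpressionDataset, matrix_path: str | Path,
                     groups_path: str | Path | None = None,
                     annotation_path: str | Path | None = None) -> None:
    ds.matrix.to_csv(matrix_path, sep="\t", index_label="probe_id")
    if groups_path is not None:
        write_groups(ds.groups, groups_path)
    if annotation_path is not None:
        write_annotation(ds.annotation, annotation_path)


def write_groups(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False)


def write_annotation(annotation: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"probe_id": annotation.index,
                  "gene_symbol": annotation.values}).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str  # BP / CC / MF / KEGG / NA
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets with a category tag per set."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise FormatError(f"set name mismatch: {name!r} vs {gs.name!r}")
            if not gs.genes:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise FormatError(f"duplicate gene-set name {gs.name!r}")
        if not gs.genes:
            raise FormatError(f"gene set {gs.name!r} has no members")
        self.sets[gs.name] = gs

    def by_category(self) -> dict[str, list[GeneSet]]:
        out: dict[str, list[GeneSet]] = {}
        for gs in self:
            out.setdefault(gs.category, []).append(gs)
        return out


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; the description column carries the category tag."""
    coll = GeneSetCollection()
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name, desc = fields[0], fields[1]
            members = tuple(f for f in fields[2:] if f)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            category = desc if desc in GENE_SET_CATEGORIES else "NA"
            coll.add(GeneSet(name=name, category=category, genes=members))
    if not coll.sets:
        log.warning("%s: no gene sets found (empty file)", path)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for gs in coll:
            fh.write("\t".join([gs.name, gs.category, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# edge lists and association tables
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read an interaction edge list; (a, b) and (b, a) are deduplicated.

    Returns a DataFrame with columns ``node_a``, ``node_b``, ``score`` in
    which each undirected pair appears once (lexicographically ordered).
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={0: str, 1: str})
    if list(df.columns[:3]) != ["node_a", "node_b", "score"]:
        raise FormatError(
            f"{path}: expected columns 'node_a', 'node_b', 'score', "
            f"got {list(df.columns)}"
        )
    if df.empty:
        log.warning("%s: empty edge list", path)
        return df
    if df[["node_a", "node_b", "score"]].isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: malformed line at data row {bad + 1}")
    a = df["node_a"].str.strip()
    b = df["node_b"].str.strip()
    swap = a > b
    lo, hi = a.where(~swap, b), b.where(~swap, a)
    out = pd.DataFrame({"node_a": lo, "node_b": hi,
                        "score": df["score"].astype(float)})
    out = out[out["node_a"] != out["node_b"]]  # drop self-loops
    out = out.drop_duplicates(subset=["node_a", "node_b"], keep="first")
    return out.reset_index(drop=True)


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges[["node_a", "node_b", "score"]].to_csv(path, sep="\t", index=False)


def read_association(path: str | Path) -> pd.DataFrame:
    """Read a (gene, entity, score) association table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    if list(df.columns[:3]) != ["gene", "entity", "score"]:
        raise FormatError(
            f"{path}: expected columns 'gene', 'entity', 'score', "
            f"got {list(df.columns)}"
        )
    if df.empty:
        log.warning("%s: empty association table", path)
        return df
    if df[["gene", "entity", "score"]].isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: malformed line at data row {bad + 1}")
    df["gene"] = df["gene"].str.strip()
    df["entity"] = df["entity"].str.strip()
    df["score"] = df["score"].astype(float)
    return df.drop_duplicates(subset=["gene", "entity"]).reset_index(drop=True)


def write_association(assoc: pd.DataFrame, path: str | Path) -> None:
    assoc[["gene", "entity", "score"]].to_csv(path, sep="\t", index=False)
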