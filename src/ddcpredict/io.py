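"""Containers and plain-text readers/writers for expression, gene-set and network data.

All formats are deliberately simple text formats: genes x samples TSV/CSV tables
(gene symbols in the first column, sample ids in the header), two-column label
files, GMT gene-set collections, and two-column edge lists (SIF relation column
tolerated).  Expression values are assumed already normalized and on log2 scale;
the package validates but never re-normalizes.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Alias: gene interaction networks are plain undirected simple graphs.
GeneNetwork = nx.Graph


@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x samples log2-expression table with per-sample group labels.

    Parameters
    ----------
    dataset_id : str
        Identifier of the dataset (e.g. a cohort accession).
    compartment : str
        Tissue compartment or platform tag, e.g. ``glomeruli``,
        ``tubulointerstitium``, ``blood`` or ``panel``.
    data : pandas.DataFrame
        Float matrix, genes as the index, sample ids as columns.
    labels : dict
        Map sample id -> group label (e.g. ``LN``/``control`` or
        ``responder``/``non-responder``).  Every sample must be labelled.
    allow_missing : bool
        Permit NaN cells (used for targeted-panel cohorts where a gene may be
        absent from one platform); disallowed for array-style matrices.
    """

    dataset_id: str
    compartment: str
    data: pd.DataFrame
    labels: dict
    allow_missing: bool = False

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        cols = self.data.columns
        if cols.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing_labels = [s for s in cols if s not in self.labels]
        if missing_labels:
            raise ValueError(f"sample {missing_labels[0]!r} has no group label")
        if not self.allow_missing and self.data.isna().any().any():
            raise ValueError("missing values are not allowed in this matrix")
        self.data = self.data.astype(float)

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> list:
        return list(self.data.index)

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def samples_in_group(self, group: str) -> list:
        return [s for s in self.data.columns if self.labels[s] == group]

    def values_for(self, group: str) -> pd.DataFrame:
        """Sub-matrix of the samples carrying a given label."""
        return self.data[self.samples_in_group(group)]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            self.dataset_id,
            self.compartment,
            self.data[sample_ids].copy(),
            {s: self.labels[s] for s in sample_ids},
            allow_missing=self.allow_missing,
        )

    def write(self, path, labels_path=None) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index_label="gene")
        if labels_path is not None:
            write_labels(dict(self.labels), labels_path)


@dataclasses.dataclass
class SignatureCollection:
    """Named gene sets (GMT-backed): the DDG signature, immune-cell sets, etc."""

    sets: dict
    descriptions: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name) -> list:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                desc = self.descriptions.get(name, "na")
                fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_labels(path) -> dict:
    """Read a two-column sample -> label table (header row optional)."""
    labels: dict = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {i}: expected two columns")
            sample, label = (p.strip() for p in parts)
            if i == 1 and sample.lower() in {"sample", "sample_id", "id"}:
                continue
            labels[sample] = label
    return labels


def write_labels(labels: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tlabel\n")
        for sample, label in labels.items():
            fh.write(f"{sample}\t{label}\n")


def read_expression_table(
    path,
    labels_path,
    dataset_id: str | None = None,
    compartment: str = "",
    allow_missing: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV plus a sample-label file.

    Duplicate gene rows are collapsed by their mean (first-occurrence order is
    preserved).  A non-numeric cell or an unlabelled sample is a hard error.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    stripped = raw.apply(lambda col: col.astype(str).str.strip())
    bad = numeric.isna() & raw.notna() & (stripped != "")
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ValueError(f"{path}: non-numeric cell at gene {gene!r}, sample {sample!r}")
    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("%s: collapsing %d duplicate gene rows by mean", path, n_dup)
        order = numeric.index.drop_duplicates()
        numeric = numeric.groupby(level=0, sort=False).mean().loc[order]
    labels = read_labels(labels_path)
    missing = [s for s in numeric.columns if s not in labels]
    if missing:
        raise ValueError(f"{labels_path}: missing label for sample {missing[0]!r}")
    return ExpressionMatrix(
        dataset_id=dataset_id or path.stem,
        compartment=compartment,
        data=numeric,
        labels={s: labels[s] for s in numeric.columns},
        allow_missing=allow_missing,
    )


def read_gmt(path) -> SignatureCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...`` per line."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {i}: GMT line needs >=3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            seen: dict = {}
            for g in genes:
                g = g.strip()
                if g and g not in seen:
                    seen[g] = None
            sets[name] = list(seen)
            descriptions[name] = desc
    return SignatureCollection(sets=sets, descriptions=descriptions)


def read_edge_list(path) -> GeneNetwork:
    """Read a 2-column edge list (a SIF-style third relation column is ignored).

    Self-loops and duplicate edges are dropped; the dropped counts are logged.
    """
    g = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) not in (2, 3):
                raise ValueError(f"{path}: line {i}: expected 2 (or 3) columns")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                n_self += 1
                g.add_node(a)
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if n_self or n_dup:
        logger.info("%s: dropped %d self-loops, %d duplicate edges", path, n_self, n_dup)
    return g


def write_edge_list(g: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(map(sorted, g.edges())):
            fh.write(f"{a}\t{b}\n")
        for node in sorted(n for n in g.nodes() if g.degree(n) == 0):
            # isolated nodes are not representable as edges; record degenerate rows
            fh.write(f"{node}\t{node}\n")
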