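"""Readers and writers for the pipeline's external formats.

Dialect: every table is TSV, UTF-8, with a mandatory header row, decimal
points and no thousands separators.  The supported formats are

* MaxQuant-style protein-groups tables (one ``LFQ intensity <run_id>``
  column per run, ``+``/empty flag columns),
* the sample-metadata table mapping runs to their experimental design,
* STRING-style weighted edge lists,
* an OBO subset (``is_a`` and ``relationship: part_of``) for the GO DAG,
* GAF-like two-column gene-to-term annotation tables,
* simple mapping / phenotype tables.

Loaders never silently drop rows: every exclusion is counted in a
:class:`LoadReport`.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .datasets import LFQDataset, PROTEIN_COLUMNS, RUN_COLUMNS

LFQ_PREFIX = "LFQ intensity "
FLAG_COLUMNS = {
    "flag_site_only": "Only identified by site",
    "flag_contaminant": "Potential contaminant",
    "flag_reverse": "Reverse",
}


@dataclasses.dataclass
class LoadReport:
    """Per-load accounting of rows read, kept and skipped."""

    n_read: int = 0
    n_kept: int = 0
    n_skipped: int = 0
    messages: list[str] = dataclasses.field(default_factory=list)

    def skip(self, msg: str) -> None:
        self.n_skipped += 1
        self.messages.append(msg)


# --------------------------------------------------------------------- #
# sample metadata and protein groups
# --------------------------------------------------------------------- #
def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the run-metadata TSV (columns ``run_id`` + the design fields)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"run_id", *RUN_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"metadata misses columns {sorted(missing)}")
    df = df.set_index("run_id")
    df["bio_rep"] = df["bio_rep"].astype(int)
    df["tech_rep"] = df["tech_rep"].astype(int)
    df["is_control"] = df["is_control"].str.lower().isin({"true", "1", "yes"})
    return df[list(RUN_COLUMNS)]


def write_sample_metadata(runs: pd.DataFrame, path: str | Path) -> None:
    out = runs.copy()
    out.insert(0, "run_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_protein_groups(path: str | Path, metadata_path: str | Path) -> LFQDataset:
    """Parse a MaxQuant-style protein-groups TSV against run metadata.

    Absent or zero LFQ cells load as the value 0; the distinction between
    "missing" and "zero" is introduced later by the zero-removal filter.
    """
    runs = read_sample_metadata(metadata_path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "protein_id" not in df.columns:
        raise ValueError("protein-groups table misses 'protein_id' column")
    if df["protein_id"].duplicated().any():
        dupes = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise ValueError(f"duplicate protein_id in table: {dupes}")

    proteins = pd.DataFrame(index=pd.Index(df["protein_id"], name="protein_id"))
    proteins["gene_name"] = df.get("gene_name", df["protein_id"]).to_numpy()
    for field, col in FLAG_COLUMNS.items():
        if col in df.columns:
            proteins[field] = (df[col].fillna("") == "+").to_numpy()
        else:
            proteins[field] = False

    cols = {}
    for run_id in runs.index:
        col = LFQ_PREFIX + run_id
        if col not in df.columns:
            raise ValueError(f"no LFQ intensity column for run {run_id!r}")
        # str -> float via the correctly-rounded Python parser so that
        # write/read round-trips bit-identically
        raw = df[col].fillna("").astype(str).str.strip()
        cols[run_id] = raw.where(raw != "", "0").astype(float).to_numpy()
    intensity = pd.DataFrame(cols, index=proteins.index)
    return LFQDataset(proteins=proteins, runs=runs, intensity=intensity)


def write_protein_groups(ds: LFQDataset, path: str | Path) -> None:
    """Write a dataset back to the MaxQuant-style dialect (raw scale)."""
    if ds.log2_scale:
        raise ValueError("protein-groups export expects the raw LFQ scale")
    cols: dict[str, np.ndarray] = {
        "protein_id": ds.proteins.index.to_numpy(),
        "gene_name": ds.proteins["gene_name"].to_numpy(),
    }
    for field, col in FLAG_COLUMNS.items():
        cols[col] = np.where(ds.proteins[field].astype(bool), "+", "")
    for run_id in ds.runs.index:
        cols[LFQ_PREFIX + run_id] = ds.intensity[run_id].fillna(0.0).to_numpy()
    pd.DataFrame(cols, index=ds.proteins.index).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- #
# weighted edge lists
# --------------------------------------------------------------------- #
def read_edge_list(path: str | Path, score_scale: str = "0-1") -> pd.DataFrame:
    """Read a STRING-style TSV (``node_a``, ``node_b``, ``score``).

    Returns an undirected, de-duplicated edge frame with scores on [0, 1]
    (a 0-1000 input is divided by 1000).  Duplicate undirected edges keep
    the maximum score; self-loops are dropped.
    """
    if score_scale not in {"0-1", "0-1000"}:
        raise ValueError(f"unknown score_scale {score_scale!r}")
    df = pd.read_csv(path, sep="\t", dtype={"node_a": str, "node_b": str})
    missing = {"node_a", "node_b", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"edge list misses columns {sorted(missing)}")
    score = df["score"].astype(float)
    hi = 1.0 if score_scale == "0-1" else 1000.0
    if ((score < 0) | (score > hi)).any():
        raise ValueError(f"scores outside declared scale {score_scale}")
    score = score / hi if score_scale == "0-1000" else score

    a = df["node_a"].to_numpy()
    b = df["node_b"].to_numpy()
    keep = a != b  # drop self-loops
    lo = np.minimum(a[keep], b[keep])
    hi_n = np.maximum(a[keep], b[keep])
    edges = pd.DataFrame({"node_a": lo, "node_b": hi_n, "score": score.to_numpy()[keep]})
    edges = (
        edges.groupby(["node_a", "node_b"], as_index=False)["score"].max()
    )
    return edges


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges[["node_a", "node_b", "score"]].to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- #
# ontology + annotations
# --------------------------------------------------------------------- #
@dataclasses.dataclass
class GODag:
    """GO DAG: nodes are term ids, directed edges run child -> parent with a
    ``relation`` attribute (``is_a`` or ``part_of``)."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology graph contains a cycle")

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def roots(self) -> list[str]:
        return [t for t in self.graph.nodes if self.graph.out_degree(t) == 0]

    def leaves(self) -> list[str]:
        return [t for t in self.graph.nodes if self.graph.in_degree(t) == 0]

    def parents(self, term: str) -> list[str]:
        return list(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)


#: gene -> set of term ids
AnnotationMap = dict


def read_obo(path: str | Path) -> GODag:
    """Load an OBO subset into a :class:`GODag` (acyclicity enforced)."""
    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, name=data.get("name", node), namespace=data.get("namespace", ""))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent, relation="is_a")
        elif key == "part_of":
            g.add_edge(child, parent, relation="part_of")
    return GODag(g)


def write_obo(dag: GODag, path: str | Path, ontology_name: str = "synthetic-go") -> None:
    """Write the DAG in minimal OBO syntax (id, name, namespace, is_a,
    relationship: part_of)."""
    lines = [f"format-version: 1.2", f"ontology: {ontology_name}", ""]
    for term in sorted(dag.graph.nodes):
        data = dag.graph.nodes[term]
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {data.get('name', term)}")
        if data.get("namespace"):
            lines.append(f"namespace: {data['namespace']}")
        for parent in sorted(dag.graph.successors(term)):
            rel = dag.graph.edges[term, parent].get("relation", "is_a")
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: part_of {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_gaf(path: str | Path, dag: GODag | None = None):
    """Read a GAF-like two-column TSV (``gene``, ``term``).

    Rows annotating a term absent from ``dag`` (when given) are skipped
    with a warning and counted in the returned :class:`LoadReport`.

    Returns
    -------
    (annotations, report) : (dict gene -> set of terms, LoadReport)
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene", "term"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table misses columns {sorted(missing)}")
    report = LoadReport(n_read=len(df))
    known = set(dag.graph.nodes) if dag is not None else None
    annotations: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        if known is not None and term not in known:
            report.skip(f"unknown term {term!r} for gene {gene!r}")
            continue
        annotations.setdefault(gene, set()).add(term)
        report.n_kept += 1
    if report.n_skipped:
        warnings.warn(
            f"skipped {report.n_skipped} annotation rows with unknown terms",
            stacklevel=2,
        )
    return annotations, report


def write_gaf(annotations: AnnotationMap, path: str | Path) -> None:
    rows = [
        {"gene": gene, "term": term}
        for gene in sorted(annotations)
        for term in sorted(annotations[gene])
    ]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- #
# small auxiliary tables
# --------------------------------------------------------------------- #
def read_mapping_table(path: str | Path) -> dict:
    """Static two-column id mapping (``from_id``, ``to_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"from_id", "to_id"} - set(df.columns)
    if missing:
        raise ValueError(f"mapping table misses columns {sorted(missing)}")
    return dict(zip(df["from_id"], df["to_id"]))


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Phenotype table: parameter rows x sample/group columns, first column
    ``parameter``."""
    df = pd.read_csv(path, sep="\t")
    if "parameter" not in df.columns:
        raise ValueError("phenotype table misses 'parameter' column")
    return df.set_index("parameter")


def write_matrix(mat: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    mat.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
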