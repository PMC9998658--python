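"""Orchestration: simulate -> filter -> functional -> semantic -> walk.

Each stage reads its inputs from the run directory, writes TSV artifacts
plus a log entry, and records row counts in a manifest.  Reruns with the
same config and seeds are identical (the manifest carries a hash of the
serialized config, and every stochastic stage derives its seed from the
run seed).  A failing stage halts the run with its name; artifacts of
completed stages are kept.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import apms_filter, go_functional, io_formats, random_walk, synthetic_data
from .datasets import LFQDataset, condition_label

STAGES = ("simulate", "filter", "collapse", "gsea", "semantic", "walk")


@dataclasses.dataclass
class RunConfig:
    """One reproducible run: stage toggles, per-module parameters, seeds."""

    out_dir: str
    seed: int = 0
    stages: dict = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    sim: dict = dataclasses.field(default_factory=dict)  # SimConfig overrides
    filter_params: dict = dataclasses.field(default_factory=dict)
    go: dict = dataclasses.field(
        default_factory=lambda: {"n_terms": 30, "max_depth": 4}
    )
    gsea_params: dict = dataclasses.field(
        default_factory=lambda: {"n_perm": 200, "min_size": 3}
    )
    network: dict = dataclasses.field(
        default_factory=lambda: {"n_nodes": 60, "mean_degree": 6, "n_effectors": 5}
    )
    walk: dict = dataclasses.field(
        default_factory=lambda: {
            "n_walks": 20_000,
            "bias_factor": 20.0,
            "min_freq": 1e-6,
            "top_k": 10,
            "n_conditions": 3,
            "n_targets": 3,
        }
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in fields})


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str, index_label="id"):
    df.to_csv(path, sep="\t", index_label=index_label)
    manifest["artifacts"].append(
        {"stage": stage, "path": path.name, "n_rows": int(df.shape[0])}
    )


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise StageError(
            stage,
            f"missing input {path.name!r}; run the {produced_by!r} stage first",
        )
    return path


# --------------------------------------------------------------------- #
# stages
# --------------------------------------------------------------------- #
def stage_simulate(config: RunConfig, out: Path, manifest: dict) -> None:
    sim_cfg = synthetic_data.SimConfig(**{"seed": config.seed, **config.sim})
    ds, truth = synthetic_data.simulate_lfq(sim_cfg)
    io_formats.write_protein_groups(ds, out / "lfq_protein_groups.tsv")
    io_formats.write_sample_metadata(ds.runs, out / "sample_metadata.tsv")
    manifest["artifacts"].append(
        {"stage": "simulate", "path": "lfq_protein_groups.tsv", "n_rows": ds.intensity.shape[0]}
    )
    manifest["artifacts"].append(
        {"stage": "simulate", "path": "sample_metadata.tsv", "n_rows": ds.runs.shape[0]}
    )

    truth_rows = [
        {"condition": condition_label(c), "protein_id": p}
        for c, prots in truth.true_interactors.items()
        for p in sorted(prots)
    ]
    _write(
        pd.DataFrame(truth_rows, columns=["condition", "protein_id"]),
        out / "true_interactors.tsv",
        manifest,
        "simulate",
    )

    net_cfg = config.network
    network = synthetic_data.simulate_network(
        n_nodes=min(net_cfg["n_nodes"], sim_cfg.n_proteins),
        mean_degree=net_cfg["mean_degree"],
        n_effectors=net_cfg["n_effectors"],
        seed=config.seed + 1,
        node_names=[f"P{i:04d}" for i in range(sim_cfg.n_proteins)],
    )
    io_formats.write_edge_list(network.to_edge_frame(), out / "ppi_edges.tsv")
    pd.DataFrame({"effector": sorted(network.effectors)}).to_csv(
        out / "effectors.tsv", sep="\t", index=False
    )
    manifest["artifacts"].append(
        {"stage": "simulate", "path": "ppi_edges.tsv", "n_rows": network.graph.number_of_edges()}
    )

    dag, annotations = synthetic_data.simulate_go(
        n_terms=config.go["n_terms"],
        max_depth=config.go["max_depth"],
        genes=list(ds.proteins["gene_name"]),
        seed=config.seed + 2,
    )
    io_formats.write_obo(dag, out / "go.obo")
    io_formats.write_gaf(annotations, out / "annotations.tsv")
    manifest["artifacts"].append(
        {"stage": "simulate", "path": "go.obo", "n_rows": len(dag.terms)}
    )

    pheno = synthetic_data.simulate_phenotype(seed=config.seed + 3)
    pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    manifest["artifacts"].append(
        {"stage": "simulate", "path": "phenotype.tsv", "n_rows": len(pheno)}
    )


def stage_filter(config: RunConfig, out: Path, manifest: dict) -> None:
    pg = _require(out / "lfq_protein_groups.tsv", "filter", "simulate")
    meta = _require(out / "sample_metadata.tsv", "filter", "simulate")
    ds = io_formats.read_protein_groups(pg, meta)
    params = apms_filter.FilterParams(**{"seed": config.seed, **config.filter_params})
    result = apms_filter.run_filter_pipeline(ds, params)

    _write(result.dataset.intensity, out / "merged_log2.tsv", manifest, "filter",
           index_label="protein_id")
    io_formats.write_sample_metadata(result.dataset.runs, out / "merged_metadata.tsv")
    _write(result.presence.astype(int), out / "presence.tsv", manifest, "filter",
           index_label="protein_id")
    calls = (
        pd.concat(result.calls.values())
        if result.calls
        else apms_filter._empty_calls(("", "", ""))
    )
    _write(calls, out / "interactor_calls.tsv", manifest, "filter",
           index_label="protein_id")
    _write(result.report.as_frame(), out / "filter_report.tsv", manifest, "filter")


def _load_filtered(out: Path, stage: str) -> tuple[LFQDataset, pd.DataFrame]:
    mat = io_formats.read_matrix(_require(out / "merged_log2.tsv", stage, "filter"))
    runs = io_formats.read_sample_metadata(
        _require(out / "merged_metadata.tsv", stage, "filter")
    )
    proteins = pd.DataFrame(
        {
            "gene_name": mat.index,
            "flag_site_only": False,
            "flag_contaminant": False,
            "flag_reverse": False,
        },
        index=pd.Index(mat.index, name="protein_id"),
    )
    mat.columns = list(runs.index)
    ds = LFQDataset(proteins=proteins, runs=runs, intensity=mat, log2_scale=True)
    return ds, mat


def _load_annotations(out: Path, stage: str):
    dag = io_formats.read_obo(_require(out / "go.obo", stage, "simulate"))
    direct, _ = io_formats.read_gaf(
        _require(out / "annotations.tsv", stage, "simulate"), dag
    )
    return dag, go_functional.propagate_annotations(dag, direct)


def stage_collapse(config: RunConfig, out: Path, manifest: dict) -> None:
    ds, _ = _load_filtered(out, "collapse")
    dag, annotations = _load_annotations(out, "collapse")
    tim = go_functional.collapse_to_terms(ds, annotations)
    _write(tim, out / "term_intensity.tsv", manifest, "collapse", index_label="term")

    design = ds.runs.loc[ds.sample_runs]
    scan = go_functional.term_anova_scan(tim[list(design.index)], design)
    long = (
        scan.p_adj.stack()
        .rename("p_adj")
        .to_frame()
        .join(scan.p_raw.stack().rename("p_raw"))
        .reset_index()
        .rename(columns={"level_0": "term", "level_1": "effect"})
    )
    _write(long.set_index("term"), out / "term_anova.tsv", manifest, "collapse",
           index_label="term")
    _write(scan.tukey, out / "term_tukey.tsv", manifest, "collapse")


def stage_gsea(config: RunConfig, out: Path, manifest: dict) -> None:
    calls = pd.read_csv(
        _require(out / "interactor_calls.tsv", "gsea", "filter"), sep="\t"
    )
    if calls.empty:
        raise StageError("gsea", "no interactor calls available")
    dag, annotations = _load_annotations(out, "gsea")
    gene_sets: dict[str, list[str]] = {}
    for gene, terms in annotations.items():
        for t in terms:
            gene_sets.setdefault(t, []).append(gene)

    conditions = sorted(calls["condition"].unique())[: config.walk["n_conditions"]]
    n_perm = config.gsea_params["n_perm"]
    for i, cond in enumerate(conditions):
        sub = calls[calls["condition"] == cond].set_index("protein_id")
        ranked = sub["log_fc"].astype(float)
        usable = {
            t: g
            for t, g in gene_sets.items()
            if 3 <= len(set(g) & set(ranked.index)) <= len(ranked) - 3
        }
        res = go_functional.gsea_scan(
            ranked, usable, n_perm=n_perm, seed=config.seed + 10 + i
        )
        _write(
            res.set_index("term") if len(res) else res,
            out / f"gsea_{cond}.tsv",
            manifest,
            "gsea",
            index_label="term",
        )


def stage_semantic(config: RunConfig, out: Path, manifest: dict) -> None:
    anova = pd.read_csv(
        _require(out / "term_anova.tsv", "semantic", "collapse"), sep="\t"
    )
    dag, _ = _load_annotations(out, "semantic")
    sig = sorted(anova.loc[anova["p_adj"] < 0.05, "term"].unique())
    if len(sig) < 2:  # fall back to every scanned term for the overview
        sig = sorted(anova["term"].unique())
    sim = go_functional.similarity_matrix(dag, sig)
    _write(sim, out / "similarity.tsv", manifest, "semantic", index_label="term")
    clustering = go_functional.binary_cut_cluster(sim)
    labels = pd.DataFrame(
        {"term": list(clustering.labels), "cluster": list(clustering.labels.values())}
    ).set_index("term")
    _write(labels, out / "clusters.tsv", manifest, "semantic", index_label="term")


def stage_walk(config: RunConfig, out: Path, manifest: dict) -> None:
    edges = io_formats.read_edge_list(
        _require(out / "ppi_edges.tsv", "walk", "simulate")
    )
    effectors = pd.read_csv(out / "effectors.tsv", sep="\t")["effector"].tolist()
    calls = pd.read_csv(
        _require(out / "interactor_calls.tsv", "walk", "filter"), sep="\t"
    )
    dag, annotations = _load_annotations(out, "walk")
    network = random_walk.build_network(edges, effectors, source="BAIT")
    wcfg = config.walk

    called = calls[calls["called"] == True]  # noqa: E712 (serialized bool)
    conditions = sorted(called["condition"].unique())[: wcfg["n_conditions"]]
    if not conditions:
        raise StageError("walk", "no condition has called interactors")

    # targets: network nodes annotated to the largest term
    gene_terms: dict[str, list[str]] = {}
    for gene, terms in annotations.items():
        for t in terms:
            gene_terms.setdefault(t, []).append(gene)
    nodes = set(network.graph.nodes)
    term, members = max(
        gene_terms.items(), key=lambda kv: (len(set(kv[1]) & nodes), kv[0])
    )
    targets = sorted(set(members) & nodes - set(effectors))[: wcfg["n_targets"]]
    if not targets:
        raise StageError("walk", "no annotated target reachable in the network")

    ranked_by_cond: dict[str, list] = {}
    edge_rows = []
    for i, cond in enumerate(conditions):
        evidence = frozenset(called.loc[called["condition"] == cond, "protein_id"])
        ranked_all: list = []
        for j, tgt in enumerate(targets):
            try:
                spec = random_walk.WalkSpec(
                    target=tgt,
                    n_walks=wcfg["n_walks"],
                    bias_factor=wcfg["bias_factor"],
                    evidence=evidence,
                    seed=config.seed + 100 + 17 * i + j,
                )
                pe = random_walk.run_walks(network, spec)
            except ValueError:
                continue
            ranked = random_walk.filter_and_rank_paths(
                pe, min_freq=wcfg["min_freq"], k=wcfg["top_k"]
            )
            ranked_all.extend(ranked)
            path_rows = [
                {"target": tgt, "path": "->".join(p), "frequency": f}
                for p, f in ranked
            ]
            pd.DataFrame(path_rows, columns=["target", "path", "frequency"]).to_csv(
                out / f"paths_{cond}_{tgt}.tsv", sep="\t", index=False
            )
        ranked_by_cond[cond] = ranked_all
        for (u, v), w in sorted(
            random_walk.condition_network(ranked_all, source="BAIT").items()
        ):
            edge_rows.append({"condition": cond, "node_a": u, "node_b": v, "weight": w})

    _write(
        pd.DataFrame(edge_rows, columns=["condition", "node_a", "node_b", "weight"]),
        out / "condition_edges.tsv",
        manifest,
        "walk",
    )
    traversal = random_walk.effector_traversal_matrix(ranked_by_cond, sorted(effectors))
    _write(traversal, out / "effector_traversal.tsv", manifest, "walk",
           index_label="effector")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "collapse": stage_collapse,
    "gsea": stage_gsea,
    "semantic": stage_semantic,
    "walk": stage_walk,
}


def run_all(config: RunConfig) -> dict:
    """Run the enabled stages in order and write ``manifest.json``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stage_order": [],
        "artifacts": [],
    }
    for stage in STAGES:
        if not config.stages.get(stage, False):
            continue
        try:
            _STAGE_FUNCS[stage](config, out, manifest)
        except StageError:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        except Exception as exc:  # halt with the failing stage named
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(stage, str(exc)) from exc
        manifest["stage_order"].append(stage)
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
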