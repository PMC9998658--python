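"""Synthetic data with the statistical structure the pipeline assumes.

Generators for (a) LFQ datasets with bead-control background,
condition-specific spiked interactors and MNAR/MAR dropout, (b) weighted
PPI networks with a bait source and source-adjacent effectors, (c) rooted
GO DAGs with gene annotations, and (d) phenotype tables.  Every generator
is fully determined by its seed, and each returns the ground truth needed
for recovery tests.

The default :class:`SimConfig` mirrors the study design: 4 genetic contexts
x 11 culture contexts (unstimulated + 5 stimuli x 2 doses), 3 biological
x 2 technical replicates (44 conditions, 264 sample runs) plus one
bead-only control group.  Intensities are log2-normal background shared
with the bead controls; true interactors of a condition are spiked by
``enrichment_logfc`` (log2 units) in that condition's sample runs only.
MNAR dropout is intensity-dependent (logistic in -log2 intensity,
calibrated to the requested overall rate); MAR dropout is uniform.
Dropped cells are written as 0, as a MaxQuant export would show them.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import (
    CONTROL_SENTINEL,
    Condition,
    GENETIC_CONTEXTS,
    LFQDataset,
    condition_label,
    default_culture_grid,
    make_run_table,
)
from .io_formats import GODag


@dataclasses.dataclass
class SimConfig:
    """Parameters of the LFQ simulation (log2 units unless noted)."""

    n_proteins: int = 300
    genetic_contexts: Sequence[str] = GENETIC_CONTEXTS
    culture_grid: Sequence[tuple[str, str]] = dataclasses.field(
        default_factory=default_culture_grid
    )
    n_bio: int = 3
    n_tech: int = 2
    frac_true_interactors: float = 0.05
    enrichment_logfc: float = 3.0
    sigma_bio: float = 0.5
    sigma_tech: float = 0.25
    mnar_rate: float = 0.15
    mar_rate: float = 0.05
    baseline_mu: float = 25.0
    baseline_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mnar_rate", "mar_rate", "frac_true_interactors"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_bio", "sigma_tech", "baseline_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.frac_true_interactors > 0 and (
            round(self.frac_true_interactors * self.n_proteins) < 1
        ):
            raise ValueError(
                "frac_true_interactors * n_proteins < 1: no interactor can be planted"
            )

    def conditions(self) -> list[Condition]:
        return [
            (g, cu, co)
            for g in self.genetic_contexts
            for cu, co in self.culture_grid
        ]


@dataclasses.dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    true_interactors: dict  # Condition -> set of protein ids
    mnar_mask: pd.DataFrame  # bool, proteins x runs
    mar_mask: pd.DataFrame  # bool, proteins x runs (disjoint from mnar)
    planted_go_effects: dict = dataclasses.field(default_factory=dict)


def _mnar_midpoint(values: np.ndarray, rate: float, width: float) -> float:
    """Bisection for the logistic midpoint giving overall dropout ``rate``.

    Dropout probability is ``1 / (1 + exp((x - x0) / width))`` -- a
    decreasing function of the log2 intensity ``x``.
    """
    lo, hi = values.min() - 20.0, values.max() + 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp((values - mid) / width))
        if p.mean() < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_lfq(config: SimConfig) -> tuple[LFQDataset, GroundTruth]:
    """Generate an LFQ dataset (with bead-control runs) plus ground truth."""
    rng = np.random.default_rng(config.seed)
    prot_ids = [f"P{i:04d}" for i in range(config.n_proteins)]
    conditions = config.conditions()

    # run table: every condition x bio x tech, then one bead-control group
    rows = []
    for cond in conditions:
        g, cu, co = cond
        for b in range(1, config.n_bio + 1):
            for t in range(1, config.n_tech + 1):
                rows.append(
                    dict(
                        run_id=f"{condition_label(cond)}_{b}_{t}",
                        genetic_context=g,
                        culture_context=cu,
                        concentration=co,
                        bio_rep=b,
                        tech_rep=t,
                        is_control=False,
                    )
                )
    for b in range(1, config.n_bio + 1):
        for t in range(1, config.n_tech + 1):
            rows.append(
                dict(
                    run_id=f"beads_{b}_{t}",
                    genetic_context=CONTROL_SENTINEL,
                    culture_context=CONTROL_SENTINEL,
                    concentration="none",
                    bio_rep=b,
                    tech_rep=t,
                    is_control=True,
                )
            )
    runs = make_run_table(rows)
    n_runs = len(runs)

    baseline = rng.normal(config.baseline_mu, config.baseline_sigma, config.n_proteins)
    log2_vals = np.tile(baseline[:, None], (1, n_runs))

    # biological effects shared across the technical replicates of a bio rep
    run_meta = runs.reset_index()
    group_key = [
        (r.genetic_context, r.culture_context, r.concentration, r.bio_rep)
        for r in run_meta.itertuples()
    ]
    for key in set(group_key):
        cols = [i for i, k in enumerate(group_key) if k == key]
        log2_vals[:, cols] += rng.normal(0.0, config.sigma_bio, config.n_proteins)[:, None]
    log2_vals += rng.normal(0.0, config.sigma_tech, (config.n_proteins, n_runs))

    # condition-specific true interactors
    n_true = round(config.frac_true_interactors * config.n_proteins)
    run_cond = {
        run_id: (r.genetic_context, r.culture_context, r.concentration)
        for run_id, r in zip(runs.index, run_meta.itertuples())
        if not r.is_control
    }
    true_interactors: dict[Condition, set[str]] = {}
    prot_pos = {p: i for i, p in enumerate(prot_ids)}
    for cond in conditions:
        chosen = set(rng.choice(prot_ids, size=n_true, replace=False)) if n_true else set()
        true_interactors[cond] = chosen
        cols = [j for j, rid in enumerate(runs.index) if run_cond.get(rid) == cond]
        for p in chosen:
            log2_vals[prot_pos[p], cols] += config.enrichment_logfc

    # dropout: MNAR (intensity-dependent) then MAR on the remainder
    mnar = np.zeros_like(log2_vals, dtype=bool)
    if config.mnar_rate > 0:
        x0 = _mnar_midpoint(log2_vals, config.mnar_rate, width=1.0)
        p_mnar = 1.0 / (1.0 + np.exp((log2_vals - x0) / 1.0))
        mnar = rng.random(log2_vals.shape) < p_mnar
    mar = np.zeros_like(log2_vals, dtype=bool)
    if config.mar_rate > 0:
        mar = (~mnar) & (rng.random(log2_vals.shape) < config.mar_rate)

    raw = np.power(2.0, log2_vals)
    raw[mnar | mar] = 0.0

    proteins = pd.DataFrame(
        {
            "gene_name": prot_ids,
            "flag_site_only": False,
            "flag_contaminant": False,
            "flag_reverse": False,
        },
        index=pd.Index(prot_ids, name="protein_id"),
    )
    ds = LFQDataset(
        proteins=proteins,
        runs=runs,
        intensity=pd.DataFrame(raw, index=proteins.index, columns=runs.index),
    )
    truth = GroundTruth(
        true_interactors=true_interactors,
        mnar_mask=pd.DataFrame(mnar, index=proteins.index, columns=runs.index),
        mar_mask=pd.DataFrame(mar, index=proteins.index, columns=runs.index),
    )
    return ds, truth


# --------------------------------------------------------------------- #
# PPI network
# --------------------------------------------------------------------- #
def simulate_network(
    n_nodes: int,
    mean_degree: float,
    n_effectors: int,
    seed: int,
    source: str = "BAIT",
    node_names: Sequence[str] | None = None,
):
    """Random connected PPI graph with a bait source and effector layer.

    Preferential-attachment topology, edge confidence scores Uniform(0.5, 1)
    so that a 0.7 confidence filter removes a substantial fraction.  Returns
    an :class:`~apmsnet.random_walk.EffectorNetwork` whose source connects to
    every effector by a directed edge.
    """
    from .random_walk import EffectorNetwork

    if n_effectors >= n_nodes:
        raise ValueError("n_effectors must be < n_nodes")
    rng = np.random.default_rng(seed)
    m = max(1, round(mean_degree / 2))
    g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31 - 1)))
    if node_names is not None:
        if len(node_names) < n_nodes:
            raise ValueError("node_names shorter than n_nodes")
        mapping = {i: str(node_names[i]) for i in g.nodes}
    else:
        mapping = {i: f"N{i:04d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    for u, v in g.edges:
        g.edges[u, v]["score"] = float(rng.uniform(0.5, 1.0))
    effectors = sorted(
        str(x) for x in rng.choice(sorted(g.nodes), size=n_effectors, replace=False)
    )
    return EffectorNetwork(graph=g, source=source, effectors=set(effectors))


# --------------------------------------------------------------------- #
# GO DAG + annotations
# --------------------------------------------------------------------- #
def simulate_go(
    n_terms: int,
    max_depth: int,
    genes: Sequence[str],
    seed: int,
    part_of_frac: float = 0.2,
):
    """Random rooted DAG plus gene annotations.

    Term 0 is the root; each new term attaches below 1-2 existing terms at
    depth < ``max_depth``.  Each gene receives 1-5 annotations to leaf terms.
    """
    if n_terms < 2:
        raise ValueError("need at least a root and one child term")
    rng = np.random.default_rng(seed)
    ids = [f"GO:{i:07d}" for i in range(n_terms)]
    g = nx.DiGraph()
    depth = {ids[0]: 0}
    g.add_node(ids[0], name="root process", namespace="biological_process")
    for i in range(1, n_terms):
        candidates = [t for t in ids[:i] if depth[t] < max_depth]
        if not candidates:
            candidates = [ids[0]]
        k = min(len(candidates), int(rng.integers(1, 3)))
        parents = rng.choice(candidates, size=k, replace=False)
        g.add_node(ids[i], name=f"process {i}", namespace="biological_process")
        for p in parents:
            rel = "part_of" if rng.random() < part_of_frac else "is_a"
            g.add_edge(ids[i], str(p), relation=rel)
        depth[ids[i]] = 1 + max(depth[str(p)] for p in parents)
    dag = GODag(g)
    leaves = dag.leaves() or ids[1:]
    annotations: dict[str, set[str]] = {}
    for gene in genes:
        k = min(len(leaves), int(rng.integers(1, 6)))
        annotations[gene] = set(str(t) for t in rng.choice(leaves, size=k, replace=False))
    return dag, annotations


# --------------------------------------------------------------------- #
# phenotype table
# --------------------------------------------------------------------- #
def simulate_phenotype(
    parameters: Sequence[str] = ("cell_density", "glucose_uptake", "lactate_release", "atp_pool"),
    genetic: Sequence[str] = ("WT", "G12D", "G12C"),
    culture: Sequence[str] = ("unstim", "DMOG", "IL6"),
    times: Sequence[int] = (24, 48, 72),
    n_rep: int = 3,
    effect_size: float = 1.0,
    sigma: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format phenotype measurements with culture/genetic/time factors.

    Each parameter gets its own random main effects per factor level so the
    three-way ANOVA has signal to find; replicate noise is N(0, sigma).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for param in parameters:
        eff_g = {g: rng.normal(0, effect_size) for g in genetic}
        eff_c = {c: rng.normal(0, effect_size) for c in culture}
        eff_t = {t: rng.normal(0, effect_size) for t in times}
        for g, c, t in itertools.product(genetic, culture, times):
            for r in range(1, n_rep + 1):
                rows.append(
                    dict(
                        parameter=param,
                        genetic_context=g,
                        culture_context=c,
                        time=t,
                        replicate=r,
                        value=10.0 + eff_g[g] + eff_c[c] + eff_t[t] + rng.normal(0, sigma),
                    )
                )
    return pd.DataFrame(rows)
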