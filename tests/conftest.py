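import os
import sys

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from apmsnet.datasets import LFQDataset, make_run_table
from apmsnet.random_walk import EffectorNetwork
from apmsnet.synthetic_data import SimConfig

REDUCED_GRID = [("unstim", "none"), ("DMOG", "20"), ("IL6", "200")]


@pytest.fixture
def reduced_config():
    """Desk-scale study design: 2 genetic x 3 culture contexts."""
    return SimConfig(
        n_proteins=200,
        genetic_contexts=("WT", "G12D"),
        culture_grid=REDUCED_GRID,
        seed=0,
    )


def build_dataset(values, conditions, n_control=0, log2_scale=False, flags=None):
    """Small LFQDataset from a dict {condition_tuple: n_runs} layout.

    ``values`` is an array (proteins x total runs); run order follows the
    conditions dict then the control runs (bio reps split evenly, 2 tech
    reps per bio rep when counts allow; otherwise 1 tech rep each).
    """
    rows = []
    for cond, n_runs in conditions.items():
        g, cu, co = cond
        for i in range(n_runs):
            b, t = divmod(i, 2)
            rows.append(
                dict(
                    run_id=f"{g}_{cu}_{co}_{b + 1}_{t + 1}",
                    genetic_context=g,
                    culture_context=cu,
                    concentration=co,
                    bio_rep=b + 1,
                    tech_rep=t + 1,
                    is_control=False,
                )
            )
    for i in range(n_control):
        b, t = divmod(i, 2)
        rows.append(
            dict(
                run_id=f"beads_{b + 1}_{t + 1}",
                genetic_context="control",
                culture_context="control",
                concentration="none",
                bio_rep=b + 1,
                tech_rep=t + 1,
                is_control=True,
            )
        )
    runs = make_run_table(rows)
    values = np.asarray(values, dtype=float)
    pids = [f"P{i:03d}" for i in range(values.shape[0])]
    proteins = pd.DataFrame(
        {
            "gene_name": pids,
            "flag_site_only": False,
            "flag_contaminant": False,
            "flag_reverse": False,
        },
        index=pd.Index(pids, name="protein_id"),
    )
    if flags is not None:
        for col, mask in flags.items():
            proteins[col] = mask
    intensity = pd.DataFrame(values, index=proteins.index, columns=runs.index)
    return LFQDataset(proteins=proteins, runs=runs, intensity=intensity, log2_scale=log2_scale)


def toy_network(edges, effectors, source="SRC"):
    """EffectorNetwork from (u, v, score) triples."""
    g = nx.Graph()
    for u, v, s in edges:
        g.add_edge(u, v, score=s)
    return EffectorNetwork(graph=g, source=source, effectors=set(effectors))


@pytest.fixture
def diamond_network():
    """Source -> effector A, then a diamond A-B-D / A-C-D."""
    return toy_network(
        [("A", "B", 0.9), ("A", "C", 0.9), ("B", "D", 0.9), ("C", "D", 0.9)],
        effectors={"A"},
    )
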