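"""Functional analysis of interactomes against a GO-style ontology.

Two complementary routes:

* **GSEA** -- a weighted Kolmogorov-Smirnov running-sum enrichment of a
  gene set in a ranked gene list, with a gene-label permutation null and
  BH correction across terms.
* **Intensity collapse** -- per sample, LFQ intensities of all identified
  proteins annotated to a term are summed (true-path rule applied first),
  then each term's profile is tested with a three-way factorial ANOVA
  (genetic context, culture context, concentration); the term x effect
  p-values are corrected collectively with Hommel, and significant terms
  are followed up with Tukey HSD whose p-values are BH-corrected
  collectively.

Semantic structure of the significant terms comes from Wang's graph-based
term-term similarity (edge-weight-propagated S-values over common
ancestors) clustered by recursive binary cut.  Radar normalisation and
Pearson phenotype-vs-term correlation support the comparison of term
intensity sums with measured cell phenotypes.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import stats_core
from .io_formats import AnnotationMap, GODag

WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


# --------------------------------------------------------------------- #
# annotation propagation and intensity collapse
# --------------------------------------------------------------------- #
def propagate_annotations(dag: GODag, direct: AnnotationMap) -> AnnotationMap:
    """True-path rule: annotate every gene to all ancestors of its direct
    terms.  Idempotent."""
    anc_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        full: set[str] = set()
        for t in terms:
            if t not in anc_cache:
                anc_cache[t] = nx.descendants(dag.graph, t) | {t}
            full |= anc_cache[t]
        out[gene] = full
    return out


def collapse_to_terms(
    ds, annotations: AnnotationMap, use_gene_names: bool = True
) -> pd.DataFrame:
    """Sum raw-scale LFQ intensities of annotated, identified proteins per
    term per sample.

    Proteins annotated to k terms contribute to all k; a protein missing
    in a sample contributes 0 there.  Terms without any identified protein
    are absent from the result.  Returns a terms x samples frame; term
    protein counts are stored in ``DataFrame.attrs['n_proteins']``.
    """
    raw = ds.from_log2() if ds.log2_scale else ds
    gene_of = (
        raw.proteins["gene_name"].astype(str)
        if use_gene_names
        else pd.Series(raw.proteins.index, index=raw.proteins.index)
    )
    term_members: dict[str, list[str]] = {}
    for pid, gene in gene_of.items():
        for term in annotations.get(gene, ()):  # unannotated proteins drop out
            term_members.setdefault(term, []).append(pid)
    if not term_members:
        return pd.DataFrame(columns=raw.intensity.columns)
    mat = raw.intensity.fillna(0.0)
    rows = {term: mat.loc[pids].sum(axis=0) for term, pids in term_members.items()}
    tim = pd.DataFrame(rows).T
    tim = tim.loc[sorted(tim.index)]
    tim.attrs["n_proteins"] = {t: len(p) for t, p in term_members.items()}
    return tim


# --------------------------------------------------------------------- #
# per-term factorial ANOVA scan
# --------------------------------------------------------------------- #
@dataclasses.dataclass
class TermScanResult:
    """Hommel-corrected per-term ANOVA scan with Tukey follow-up."""

    p_raw: pd.DataFrame  # terms x effects
    p_adj: pd.DataFrame  # terms x effects, Hommel across all entries
    anovas: dict  # term -> AnovaResult
    tukey: pd.DataFrame  # long frame: term, factor, level_a, level_b, diff, p, p_adj
    excluded: list[str]


def term_anova_scan(
    tim: pd.DataFrame,
    design: pd.DataFrame,
    factors: Sequence[str] = ("genetic_context", "culture_context", "concentration"),
    alpha: float = 0.05,
    min_proteins: int = 3,
    log_transform: bool = True,
    include_interactions: bool = True,
) -> TermScanResult:
    """Three-way ANOVA per term with collective Hommel correction.

    ``design`` is indexed by the samples (columns of ``tim``) and carries
    the factor columns.  Terms backed by fewer than ``min_proteins``
    annotated identified proteins (from ``tim.attrs['n_proteins']``) are
    excluded and reported.  For terms with any Hommel-adjusted effect
    p < ``alpha``, Tukey HSD tables are computed for the significant main
    effects and BH-corrected collectively.
    """
    factors = list(factors)
    counts = tim.attrs.get("n_proteins", {})
    excluded = [t for t in tim.index if counts and counts.get(t, 0) < min_proteins]
    terms = [t for t in tim.index if t not in set(excluded)]

    anovas: dict[str, stats_core.AnovaResult] = {}
    records: dict[str, dict[str, float]] = {}
    for term in terms:
        vals = tim.loc[term, design.index].to_numpy(dtype=float)
        if log_transform:
            vals = np.log2(vals + 1.0)
        if np.allclose(vals, vals[0]):
            continue  # constant profile: nothing to test
        frame = design[factors].copy()
        frame["value"] = vals
        res = stats_core.factorial_anova(
            frame, factors, include_interactions=include_interactions
        )
        anovas[term] = res
        records[term] = {e: res.table.loc[e, "p"] for e in res.table.index}

    p_raw = pd.DataFrame(records).T
    if p_raw.empty:
        empty = pd.DataFrame(
            columns=["term", "factor", "level_a", "level_b", "diff", "ci_low", "ci_high", "p", "p_adj"]
        )
        return TermScanResult(p_raw, p_raw.copy(), anovas, empty, excluded)

    flat = p_raw.stack(future_stack=True).dropna()
    adj = stats_core.adjust_hommel(flat.to_numpy())
    p_adj = pd.Series(adj, index=flat.index).unstack()
    p_adj = p_adj.reindex(index=p_raw.index, columns=p_raw.columns)

    tukey_rows = []
    for term in p_adj.index:
        for factor in factors:
            if factor in p_adj.columns and p_adj.loc[term, factor] < alpha:
                tab = stats_core.tukey_hsd(anovas[term], factor, alpha=alpha)
                tab.insert(0, "factor", factor)
                tab.insert(0, "term", term)
                tukey_rows.append(tab)
    if tukey_rows:
        tukey = pd.concat(tukey_rows, ignore_index=True)
        tukey["p_adj"] = stats_core.adjust_bh(tukey["p"].to_numpy())
    else:
        tukey = pd.DataFrame(
            columns=["term", "factor", "level_a", "level_b", "diff", "ci_low", "ci_high", "p", "p_adj"]
        )
    return TermScanResult(p_raw, p_adj, anovas, tukey, excluded)


# --------------------------------------------------------------------- #
# GSEA
# --------------------------------------------------------------------- #
@dataclasses.dataclass
class EnrichmentResult:
    term: str
    es: float
    nes: float
    p_perm: float
    fdr: float
    leading_edge: list[str]


def _running_es(scores: np.ndarray, hit: np.ndarray, p: float) -> tuple[float, int]:
    """Signed max deviation of the weighted KS running sum, and its argmax."""
    w = np.abs(scores) ** p
    hit_w = np.where(hit, w, 0.0)
    denom_hit = hit_w.sum()
    n_miss = (~hit).sum()
    if denom_hit == 0 or n_miss == 0:
        return 0.0, 0
    run = np.cumsum(hit_w / denom_hit - (~hit).astype(float) / n_miss)
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def gsea(
    ranked: pd.Series,
    gene_set: Sequence[str],
    term: str = "",
    p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted KS enrichment of ``gene_set`` in a score-ranked gene list.

    ``ranked`` maps gene -> score; it is sorted by decreasing score
    internally.  The null permutes gene labels: ``n_perm`` random sets of
    the same size.  ``p_perm = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1)``;
    NES divides ES by the mean |ES_perm| of the same sign.
    """
    ranked = ranked.sort_values(ascending=False)
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    n = len(genes)
    in_set = np.isin(genes, np.asarray(list(gene_set)))
    k = int(in_set.sum())
    if k == n:  # degenerate: the set is the whole universe
        return EnrichmentResult(term, 0.0, 0.0, 1.0, 1.0, [])
    if k < 3 or k > n - 3:
        raise ValueError(f"gene set size {k} outside [3, {n - 3}]")

    es, peak = _running_es(scores, in_set, p)
    rng = np.random.default_rng(seed)
    es_perm = np.empty(n_perm)
    for j in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=k, replace=False)] = True
        es_perm[j], _ = _running_es(scores, perm_hit, p)
    p_perm = (1.0 + np.sum(np.abs(es_perm) >= abs(es))) / (n_perm + 1.0)
    same_sign = es_perm[np.sign(es_perm) == np.sign(es)] if es != 0 else es_perm
    nes = es / np.mean(np.abs(same_sign)) if len(same_sign) else 0.0

    if es >= 0:
        leading = list(genes[: peak + 1][in_set[: peak + 1]])
    else:
        leading = list(genes[peak:][in_set[peak:]])
    return EnrichmentResult(term, es, float(nes), float(p_perm), float("nan"), leading)


def gsea_scan(
    ranked: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """GSEA over many terms, with BH FDR across terms."""
    rows = []
    rng = np.random.default_rng(seed)
    for term, gset in gene_sets.items():
        sub_seed = int(rng.integers(2**31 - 1))
        try:
            r = gsea(ranked, gset, term=term, p=p, n_perm=n_perm, seed=sub_seed)
        except ValueError:
            continue
        rows.append(
            {
                "term": r.term,
                "es": r.es,
                "nes": r.nes,
                "p_perm": r.p_perm,
                "leading_edge": ",".join(r.leading_edge),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = stats_core.adjust_bh(out["p_perm"].to_numpy())
    return out


# --------------------------------------------------------------------- #
# Wang semantic similarity + binary cut clustering
# --------------------------------------------------------------------- #
def _svalues(dag: GODag, term: str, weights: Mapping[str, float]) -> dict[str, float]:
    """Edge-weight-propagated S-values of ``term`` over its ancestors.

    S(term) = 1; for an ancestor a, S(a) is the maximum over parent edges
    from already-scored nodes of w_edge * S(child).
    """
    nodes = nx.descendants(dag.graph, term) | {term}
    sub = dag.graph.subgraph(nodes)
    s = {term: 1.0}
    for node in nx.topological_sort(sub):  # children before parents
        if node == term:
            continue
        best = 0.0
        for child in sub.predecessors(node):
            if child in s:
                w = weights.get(sub.edges[child, node].get("relation", "is_a"), 0.8)
                best = max(best, w * s[child])
        s[node] = best
    return s


def wang_similarity(
    dag: GODag,
    term1: str,
    term2: str,
    w_is_a: float = 0.8,
    w_part_of: float = 0.6,
) -> float:
    """Wang graph-based similarity of two terms in [0, 1]."""
    if term1 == term2:
        return 1.0
    weights = {"is_a": w_is_a, "part_of": w_part_of}
    s1 = _svalues(dag, term1, weights)
    s2 = _svalues(dag, term2, weights)
    common = set(s1) & set(s2)
    num = sum(s1[c] + s2[c] for c in common)
    denom = sum(s1.values()) + sum(s2.values())
    return num / denom if denom > 0 else 0.0


def similarity_matrix(
    dag: GODag, terms: Sequence[str], w_is_a: float = 0.8, w_part_of: float = 0.6
) -> pd.DataFrame:
    """Symmetric Wang similarity matrix with unit diagonal."""
    weights = {"is_a": w_is_a, "part_of": w_part_of}
    svals = {t: _svalues(dag, t, weights) for t in terms}
    sums = {t: sum(svals[t].values()) for t in terms}
    n = len(terms)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s1, s2 = svals[terms[i]], svals[terms[j]]
            common = set(s1) & set(s2)
            denom = sums[terms[i]] + sums[terms[j]]
            val = sum(s1[c] + s2[c] for c in common) / denom if denom > 0 else 0.0
            sim[i, j] = sim[j, i] = val
    return pd.DataFrame(sim, index=list(terms), columns=list(terms))


@dataclasses.dataclass
class SemanticClustering:
    similarity: pd.DataFrame
    labels: dict  # term -> cluster id (1-based)
    sizes: dict  # cluster id -> size


def _coherence(sim: np.ndarray, idx: np.ndarray) -> float:
    """Mean pairwise similarity of a term subset (diagonal included)."""
    block = sim[np.ix_(idx, idx)]
    return float(block.mean())


def _two_split(sim: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic hierarchical 2-group split of a similarity submatrix."""
    block = sim[np.ix_(idx, idx)]
    dist = 1.0 - block
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    # cut_tree splits by merge order, so tied heights still give two groups
    assign = hierarchy.cut_tree(z, n_clusters=2).ravel()
    left = idx[assign == 0]
    right = idx[assign != 0]
    return left, right


def binary_cut_cluster(
    sim: pd.DataFrame, cut_score_threshold: float = 0.85
) -> SemanticClustering:
    """Recursive binary-cut clustering of a term similarity matrix.

    A term subset stays one cluster when its coherence (mean of the
    similarity submatrix) reaches ``cut_score_threshold``; otherwise it is
    split in two by average-linkage hierarchical clustering and both
    halves are recursed on.  Fully deterministic.
    """
    terms = list(sim.index)
    mat = sim.to_numpy(dtype=float)
    labels: dict[str, int] = {}
    next_id = [1]

    def recurse(idx: np.ndarray) -> None:
        if len(idx) == 1 or _coherence(mat, idx) >= cut_score_threshold:
            cid = next_id[0]
            next_id[0] += 1
            for i in idx:
                labels[terms[i]] = cid
            return
        left, right = _two_split(mat, idx)
        if len(left) == 0 or len(right) == 0:  # split failed: accept as one
            cid = next_id[0]
            next_id[0] += 1
            for i in idx:
                labels[terms[i]] = cid
            return
        recurse(left)
        recurse(right)

    recurse(np.arange(len(terms)))
    sizes: dict[int, int] = {}
    for cid in labels.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    return SemanticClustering(similarity=sim, labels=labels, sizes=sizes)


# --------------------------------------------------------------------- #
# radar normalisation and phenotype correlation
# --------------------------------------------------------------------- #
def radar_normalize(ls_means: pd.DataFrame) -> pd.DataFrame:
    """Divide each parameter row by its maximum so values lie in [0, 1]."""
    vals = ls_means.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("radar normalisation is defined for non-negative values")
    row_max = vals.max(axis=1, keepdims=True)
    if (row_max == 0).any():
        raise ValueError("a parameter row is all zero; cannot normalise")
    return pd.DataFrame(
        vals / row_max, index=ls_means.index, columns=ls_means.columns
    )


def phenotype_correlation(
    pheno: pd.DataFrame, term_sums: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r of each phenotype parameter against each term's intensity
    sums over the shared group columns."""
    groups = [g for g in pheno.columns if g in set(term_sums.columns)]
    if len(groups) < 3:
        raise ValueError("need at least three shared groups for correlation")
    P = pheno[groups].to_numpy(dtype=float)
    T = term_sums[groups].to_numpy(dtype=float)
    Pz = (P - P.mean(axis=1, keepdims=True)) / P.std(axis=1, keepdims=True)
    Tz = (T - T.mean(axis=1, keepdims=True)) / T.std(axis=1, keepdims=True)
    r = (Pz @ Tz.T) / len(groups)
    return pd.DataFrame(r, index=pheno.index, columns=term_sums.index)
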