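"""Independent brute-force references used by the test suite only."""

from itertools import combinations

import numpy as np


def bh_reference(p):
    """Benjamini-Hochberg by the definitional formula:
    p_adj(i) = min over j with p_(j) >= p_(i) of min(1, n * p_(j) / rank_j)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    sorted_p = p[order]
    for i in range(n):
        candidates = [n * sorted_p[j] / (j + 1) for j in range(i, n)]
        adj[order[i]] = min(1.0, min(candidates))
    return adj


def simes_p(p_subset):
    ps = np.sort(np.asarray(p_subset, dtype=float))
    m = len(ps)
    return float(np.min(m * ps / np.arange(1, m + 1)))


def hommel_reference(p):
    """Hommel via exhaustive closed testing with Simes local tests:
    p_adj(i) = max over subsets S containing i of Simes p-value of S.
    Exponential; use only for n <= 8."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    adj = np.zeros(n)
    idx = list(range(n))
    for r in range(1, n + 1):
        for subset in combinations(idx, r):
            sp = simes_p(p[list(subset)])
            for i in subset:
                adj[i] = max(adj[i], sp)
    return np.minimum(adj, 1.0)


def wang_reference(dag, term, weights):
    """All-paths S-values: S(ancestor) = max over upward paths from
    ``term`` of the product of edge weights along the path."""
    s = {term: 1.0}
    stack = [(term, 1.0)]
    while stack:
        node, val = stack.pop()
        for parent in dag.graph.successors(node):
            w = weights[dag.graph.edges[node, parent].get("relation", "is_a")]
            cand = val * w
            if cand > s.get(parent, 0.0):
                s[parent] = cand
                stack.append((parent, cand))
    return s


def wang_similarity_reference(dag, t1, t2, w_is_a=0.8, w_part_of=0.6):
    weights = {"is_a": w_is_a, "part_of": w_part_of}
    if t1 == t2:
        return 1.0
    s1 = wang_reference(dag, t1, weights)
    s2 = wang_reference(dag, t2, weights)
    common = set(s1) & set(s2)
    denom = sum(s1.values()) + sum(s2.values())
    return sum(s1[c] + s2[c] for c in common) / denom if denom else 0.0


def ancestor_closure_reference(dag, term):
    """Ancestors by naive repeated expansion."""
    out = set()
    frontier = {term}
    while frontier:
        nxt = set()
        for t in frontier:
            for parent in dag.graph.successors(t):
                if parent not in out:
                    out.add(parent)
                    nxt.add(parent)
        frontier = nxt
    return out
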