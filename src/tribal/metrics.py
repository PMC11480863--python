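"""Evaluation metrics for lineage trees, labelings and transition matrices.

All logarithms are natural.  Where a method returns several co-optimal
solutions, callers average the per-solution metric before pooling (see
:func:`mean_over_solutions`).
"""

from __future__ import annotations

import math
from typing import Dict, Hashable, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .model import LineageTree, TransitionMatrix, hamming_distance

Node = Hashable


# ---------------------------------------------------------------------------
# Transition matrix accuracy
# ---------------------------------------------------------------------------

def kl_divergence_rows(P_hat: TransitionMatrix, P: TransitionMatrix) -> np.ndarray:
    """Per-starting-state KL divergence D(p_hat_s || p_s), inferred row first.

    Uses the convention 0 log(0/x) = 0; raises if the inferred row puts mass
    where the reference row has none.
    """
    if P_hat.r != P.r:
        raise ValueError(f"state counts differ: {P_hat.r} vs {P.r}")
    out = np.zeros(P.r)
    for s in range(P.r):
        ph, p = P_hat.probs[s], P.probs[s]
        acc = 0.0
        for t in range(P.r):
            if ph[t] > 0.0:
                if p[t] <= 0.0:
                    raise ValueError(
                        f"support violation at (s={s + 1}, t={t + 1}): "
                        f"inferred {ph[t]:g} but reference is 0"
                    )
                acc += ph[t] * math.log(ph[t] / p[t])
        out[s] = acc
    return out


# ---------------------------------------------------------------------------
# Topology accuracy
# ---------------------------------------------------------------------------

def _bipartitions(T: LineageTree) -> set:
    """Non-trivial unrooted bipartitions of the leaf set, canonicalized."""
    leaves = frozenset(T.leaves())
    n = len(leaves)
    out = set()
    for v, cl in T.clusters().items():
        if v == T.root or T.is_leaf(v):
            continue
        if len(cl) < 2 or len(cl) > n - 2:
            continue
        other = leaves - cl
        a, b = sorted((tuple(sorted(map(str, cl))), tuple(sorted(map(str, other)))))
        out.add((a, b))
    return out


def normalized_rf(T: LineageTree, T_hat: LineageTree) -> float:
    """Robinson-Foulds distance on unrooted bipartitions, normalized by the
    total bipartition count of both trees; 0 when both sets are equal
    (including two star trees)."""
    if set(T.leaves()) != set(T_hat.leaves()):
        raise ValueError("leaf-set mismatch")
    b1, b2 = _bipartitions(T), _bipartitions(T_hat)
    denom = len(b1) + len(b2)
    if denom == 0:
        return 0.0
    return len(b1 ^ b2) / denom


# ---------------------------------------------------------------------------
# Ancestral sequence accuracy
# ---------------------------------------------------------------------------

def _mrca_table(T: LineageTree) -> Dict[Tuple[Node, Node], Node]:
    """MRCA of every unordered leaf pair (keys sorted by str)."""
    parent = {v: T.parent(v) for v in T.nodes()}
    depth: Dict[Node, int] = {T.root: 0}
    for v in T.preorder():
        for c in T.children(v):
            depth[c] = depth[v] + 1
    leaves = sorted(T.leaves(), key=str)
    table: Dict[Tuple[Node, Node], Node] = {}
    for i, u in enumerate(leaves):
        for v in leaves[i + 1:]:
            a, b = u, v
            while a != b:
                if depth[a] >= depth[b]:
                    a = parent[a]
                else:
                    b = parent[b]
            table[(u, v)] = a
    return table


def mrca_distance(T: LineageTree, T_hat: LineageTree) -> float:
    """Mean per-site Hamming distance between the MRCA sequences of every
    unordered leaf pair in the truth vs the inferred tree."""
    for t in (T, T_hat):
        if t.alpha is None:
            raise ValueError("both trees must carry sequence labelings")
    leaves = sorted(T.leaves(), key=str)
    if set(leaves) != set(T_hat.leaves()):
        raise ValueError("leaf-set mismatch")
    n = len(leaves)
    if n < 2:
        raise ValueError("need at least two leaves")
    m = len(T.alpha[T.root])
    mr_t = _mrca_table(T)
    mr_h = _mrca_table(T_hat)
    total = 0
    for pair, anc in mr_t.items():
        total += hamming_distance(T.alpha[anc], T_hat.alpha[mr_h[pair]])
    return 2.0 * total / (n * (n - 1) * m)


# ---------------------------------------------------------------------------
# Isotype accuracy
# ---------------------------------------------------------------------------

def _switches_to_leaves(T: LineageTree) -> Dict[Node, int]:
    if T.beta is None:
        raise ValueError("tree must carry an isotype labeling")
    switches: Dict[Node, int] = {T.root: 0}
    for v in T.preorder():
        for c in T.children(v):
            switches[c] = switches[v] + (T.beta[c] != T.beta[v])
    return {v: switches[v] for v in T.leaves()}


def csr_error(truth: LineageTree, inferred: LineageTree) -> Dict[Node, int]:
    """Per cell: absolute difference between the number of class switches on
    the root-to-cell path in the truth vs the inferred labeled tree."""
    st = _switches_to_leaves(truth)
    si = _switches_to_leaves(inferred)
    if set(st) != set(si):
        raise ValueError("leaf-set mismatch")
    return {cell: abs(st[cell] - si[cell]) for cell in st}


def mean_over_solutions(per_solution: Sequence[Dict[Node, float]]) -> Dict[Node, float]:
    """Average a per-cell metric over a method's co-optimal solution set."""
    if not per_solution:
        raise ValueError("no solutions")
    cells = per_solution[0].keys()
    return {c: float(np.mean([d[c] for d in per_solution])) for c in cells}


def avg_isotype_clade_entropy(
    T: LineageTree, b: Dict[Node, int]
) -> Optional[float]:
    """Mean entropy of leaf-isotype distributions over all non-trivial clades
    (internal nodes other than the root); ``None`` when no such clade exists
    (for example a star tree)."""
    clades = [
        cl for v, cl in T.clusters().items()
        if v != T.root and not T.is_leaf(v)
    ]
    if not clades:
        return None
    ents = []
    for cl in clades:
        labels = [b[leaf] for leaf in cl]
        _, counts = np.unique(labels, return_counts=True)
        p = counts / counts.sum()
        ents.append(float(-(p * np.log(p)).sum()))
    return float(np.mean(ents))


def invalid_transition_stats(T: LineageTree) -> Tuple[int, float, bool]:
    """Count of edges whose isotypes decrease (invalid under CSR), the
    fraction of edges they represent, and whether any exist."""
    if T.beta is None:
        raise ValueError("tree must carry an isotype labeling")
    n_edges = T.n_edges()
    bad = sum(1 for u, v in T.graph.edges if T.beta[u] > T.beta[v])
    return bad, (bad / n_edges if n_edges else 0.0), bad > 0
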