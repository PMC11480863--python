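"""Domain types and objective functions for B cell lineage inference.

A clonal lineage is modeled as a rooted tree whose root is the naive
(germline) B cell.  Two evolutionary processes act along its edges:

* somatic hypermutation (SHM) of the concatenated heavy+light variable-region
  DNA sequence, scored by unweighted parsimony (sum of Hamming distances), and
* class switch recombination (CSR) of the heavy-chain isotype, an irreversible
  Markov process on the linearly ordered isotype states ``1..r`` governed by an
  upper-triangular row-stochastic transition matrix ``P``.

This module holds the data containers (:class:`IsotypeAlphabet`,
:class:`TransitionMatrix`, :class:`Clonotype`, :class:`LineageTree`,
:class:`LineageForest`, :class:`RefinementMap`) and the two objectives
(:func:`shm_score`, :func:`csr_log_likelihood`) together with structural
validation helpers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterable, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

#: Explicit sentinel for a zero-probability (impossible) labeling.
NEG_INF = float("-inf")

ROW_SUM_TOL = 1e-9

Node = Hashable


# ---------------------------------------------------------------------------
# Isotype alphabet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotypeAlphabet:
    """Ordered isotype states.

    Ordinal 1 is always the naive IgM/IgD state; ordinals increase along the
    heavy-chain constant-region locus, so class switching can only increase
    the ordinal.
    """

    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("alphabet needs at least one isotype label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("isotype labels must be unique")

    @property
    def r(self) -> int:
        return len(self.labels)

    def ordinal(self, label: str) -> int:
        """1-based ordinal of ``label``."""
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise KeyError(f"unknown isotype label {label!r}") from None

    def label(self, ordinal: int) -> str:
        if not 1 <= ordinal <= self.r:
            raise KeyError(f"isotype ordinal {ordinal} outside [1..{self.r}]")
        return self.labels[ordinal - 1]


#: Human heavy-chain constant-region order (r = 8).
HUMAN_ISOTYPES = IsotypeAlphabet(
    ("IgM/IgD", "IgG3", "IgG1", "IgA1", "IgG2", "IgG4", "IgE", "IgA2")
)

#: Mouse heavy-chain constant-region order (r = 7).
MOUSE_ISOTYPES = IsotypeAlphabet(
    ("IgM/IgD", "IgG3", "IgG1", "IgG2b", "IgG2c", "IgE", "IgA")
)


# ---------------------------------------------------------------------------
# Transition matrix
# ---------------------------------------------------------------------------

class TransitionMatrix:
    """Upper-triangular row-stochastic isotype transition probabilities.

    ``p[s][t]`` (1-based states) is the probability that a daughter cell has
    isotype ``t`` given parent isotype ``s``.  Irreversibility of CSR forces
    ``p[s][t] = 0`` for ``s > t``.
    """

    def __init__(self, probs: np.ndarray) -> None:
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != probs.shape[1]:
            raise ValueError(f"transition matrix must be square, got {probs.shape}")
        self.probs = probs

    @property
    def r(self) -> int:
        return self.probs.shape[0]

    def p(self, s: int, t: int) -> float:
        """Probability of transition ``s -> t`` (1-based states)."""
        return float(self.probs[s - 1, t - 1])

    def log_probs(self) -> np.ndarray:
        """r x r natural-log matrix with ``-inf`` at zero entries."""
        with np.errstate(divide="ignore"):
            return np.where(self.probs > 0.0, np.log(np.maximum(self.probs, 1e-300)), NEG_INF)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TransitionMatrix(r={self.r})"


def validate_transition_matrix(P: TransitionMatrix) -> List[str]:
    """Return a list of violation messages (empty list means valid).

    Checks non-negativity, irreversibility (zero strictly below the diagonal)
    and row-stochasticity within ``1e-9``.
    """
    violations: List[str] = []
    probs = P.probs
    r = P.r
    neg = np.argwhere(probs < 0)
    for s, t in neg:
        violations.append(f"negative entry p[{s + 1}][{t + 1}] = {probs[s, t]:g}")
    for s in range(r):
        for t in range(s):
            if probs[s, t] != 0.0:
                violations.append(
                    f"reversibility: p[{s + 1}][{t + 1}] = {probs[s, t]:g} with s > t"
                )
    sums = probs.sum(axis=1)
    for s in range(r):
        if abs(sums[s] - 1.0) > ROW_SUM_TOL:
            violations.append(f"row-stochastic: row {s + 1} sums to {sums[s]:.12g}")
    return violations


# ---------------------------------------------------------------------------
# Clonotype
# ---------------------------------------------------------------------------

@dataclass
class Clonotype:
    """One clonal family: aligned sequences and observed isotypes.

    The alignment consists of the germline (naive) root sequence plus one
    aligned sequence per sequenced cell.  The root isotype is always ordinal 1.
    """

    id: str
    germline: str
    sequences: Dict[str, str]          # cell id -> aligned sequence
    isotypes: Dict[str, int]           # cell id -> isotype ordinal in [1..r]
    alphabet: IsotypeAlphabet

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"clonotype {self.id}: needs at least one cell")
        m = len(self.germline)
        for cell, seq in self.sequences.items():
            if len(seq) != m:
                raise ValueError(
                    f"clonotype {self.id}: ragged alignment, cell {cell} has length "
                    f"{len(seq)} but germline has length {m}"
                )
        for cell in self.sequences:
            if cell not in self.isotypes:
                raise ValueError(f"clonotype {self.id}: cell {cell} has no isotype")
            iso = self.isotypes[cell]
            if not 1 <= iso <= self.alphabet.r:
                raise ValueError(
                    f"clonotype {self.id}: isotype {iso} of cell {cell} outside "
                    f"[1..{self.alphabet.r}]"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def m(self) -> int:
        return len(self.germline)

    @property
    def cell_ids(self) -> List[str]:
        return sorted(self.sequences)


# ---------------------------------------------------------------------------
# Lineage tree
# ---------------------------------------------------------------------------

class LineageTree:
    """Rooted tree with optional per-node sequence (alpha) and isotype (beta).

    Topology is held in a :class:`networkx.DiGraph` with edges directed from
    parent to child.  Leaves are identified with cell ids.  Child order is
    non-semantic; serialization applies a canonical order (lexicographic by
    smallest descendant leaf id).
    """

    def __init__(
        self,
        graph: nx.DiGraph,
        root: Node,
        alpha: Optional[Dict[Node, str]] = None,
        beta: Optional[Dict[Node, int]] = None,
    ) -> None:
        if root not in graph:
            raise ValueError(f"root {root!r} not in graph")
        roots = [v for v in graph if graph.in_degree(v) == 0]
        if roots != [root] and set(roots) != {root}:
            raise ValueError(f"graph must have exactly one root; found {roots}")
        if not nx.is_tree(graph.to_undirected(as_view=True)):
            raise ValueError("graph is not a tree")
        self.graph = graph
        self.root = root
        self.alpha = alpha
        self.beta = beta

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Tuple[Node, Node]],
        root: Node,
        alpha: Optional[Dict[Node, str]] = None,
        beta: Optional[Dict[Node, int]] = None,
    ) -> "LineageTree":
        g = nx.DiGraph()
        g.add_node(root)
        g.add_edges_from(edges)
        return cls(g, root, alpha=alpha, beta=beta)

    def copy(self) -> "LineageTree":
        return LineageTree(
            self.graph.copy(),
            self.root,
            alpha=dict(self.alpha) if self.alpha is not None else None,
            beta=dict(self.beta) if self.beta is not None else None,
        )

    # -- topology accessors --------------------------------------------------

    def nodes(self) -> List[Node]:
        return list(self.graph.nodes)

    def edges(self) -> List[Tuple[Node, Node]]:
        return list(self.graph.edges)

    def children(self, u: Node) -> List[Node]:
        return list(self.graph.successors(u))

    def parent(self, u: Node) -> Optional[Node]:
        preds = list(self.graph.predecessors(u))
        return preds[0] if preds else None

    def leaves(self) -> List[Node]:
        return [v for v in self.graph if self.graph.out_degree(v) == 0]

    def is_leaf(self, u: Node) -> bool:
        return self.graph.out_degree(u) == 0

    def postorder(self) -> List[Node]:
        return list(nx.dfs_postorder_nodes(self.graph, self.root))

    def preorder(self) -> List[Node]:
        return list(nx.dfs_preorder_nodes(self.graph, self.root))

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def clusters(self) -> Dict[Node, frozenset]:
        """Leaf-descendant set of every node."""
        out: Dict[Node, frozenset] = {}
        for v in self.postorder():
            kids = self.children(v)
            if not kids:
                out[v] = frozenset([v])
            else:
                acc: set = set()
                for c in kids:
                    acc |= out[c]
                out[v] = frozenset(acc)
        return out

    def path_to_root(self, v: Node) -> List[Node]:
        path = [v]
        while path[-1] != self.root:
            path.append(self.parent(path[-1]))
        return path

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LineageTree(root={self.root!r}, n_leaves={len(self.leaves())}, "
            f"n_nodes={self.graph.number_of_nodes()})"
        )


@dataclass
class LineageForest:
    """Candidate trees for one clonotype, all over the same leaf set."""

    clonotype_id: str
    trees: List[LineageTree]
    shm_scores: Optional[List[int]] = None
    source: str = "parsimony-input"

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError(f"forest for {self.clonotype_id}: empty tree list")
        leaf_sets = {frozenset(t.leaves()) for t in self.trees}
        if len(leaf_sets) != 1:
            raise ValueError(
                f"forest for {self.clonotype_id}: trees do not share a leaf set"
            )

    def __len__(self) -> int:
        return len(self.trees)


@dataclass
class RefinementMap:
    """Mapping sigma from nodes of a refined tree T' onto the original T.

    Contracting every edge of T' whose endpoints share the same image yields a
    tree isomorphic to T (respecting leaf labels).
    """

    sigma: Dict[Node, Node]


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

def hamming_distance(x: str, y: str) -> int:
    """Number of differing positions between two equal-length sequences.

    Comparison is case-insensitive; the gap character ``-`` and the ambiguity
    code ``N`` are treated as ordinary characters (unit-cost parsimony
    semantics, any mismatch counts 1).
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    x = x.upper()
    y = y.upper()
    return sum(a != b for a, b in zip(x, y))


def shm_score(T: LineageTree) -> int:
    """SHM parsimony score: sum of Hamming distances over all edges."""
    if T.alpha is None:
        raise ValueError("tree has no sequence labeling")
    total = 0
    for u, v in T.graph.edges:
        for node in (u, v):
            if node not in T.alpha:
                raise ValueError(f"node {node!r} has no sequence label")
        total += hamming_distance(T.alpha[u], T.alpha[v])
    return total


def csr_log_likelihood(T: LineageTree, P: TransitionMatrix) -> float:
    """Log-likelihood of the isotype labeling under transition matrix ``P``.

    Returns the :data:`NEG_INF` sentinel if any edge has zero probability
    (in particular any edge violating CSR irreversibility).
    """
    if T.beta is None:
        raise ValueError("tree has no isotype labeling")
    total = 0.0
    for u, v in T.graph.edges:
        for node in (u, v):
            if node not in T.beta:
                raise ValueError(f"node {node!r} has no isotype label")
        p = P.p(T.beta[u], T.beta[v])
        if p <= 0.0:
            return NEG_INF
        total += math.log(p)
    return total


def forest_csr_log_likelihood(trees: Sequence[LineageTree], P: TransitionMatrix) -> float:
    """Sum of :func:`csr_log_likelihood` over a list of labeled trees."""
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree list")
    total = 0.0
    for t in trees:
        ll = csr_log_likelihood(t, P)
        if ll == NEG_INF:
            return NEG_INF
        total += ll
    return total


# ---------------------------------------------------------------------------
# Structural checks
# ---------------------------------------------------------------------------

def is_valid_lineage_tree(T: LineageTree, c: Clonotype) -> List[str]:
    """Check Definition-style validity of a fully labeled lineage tree.

    Verifies that leaves agree with the clonotype's sequences/isotypes, the
    root carries the germline sequence and isotype 1, and isotypes are
    non-decreasing along every edge.  Returns violation messages.
    """
    violations: List[str] = []
    leaves = set(T.leaves())
    if leaves != set(c.cell_ids):
        violations.append(
            f"leaf set {sorted(map(str, leaves))} does not match cells "
            f"{c.cell_ids}"
        )
        return violations
    if T.alpha is not None:
        if T.alpha.get(T.root) != c.germline:
            violations.append("root sequence differs from germline")
        for cell in leaves:
            if T.alpha.get(cell) != c.sequences[cell]:
                violations.append(f"leaf sequence: {cell} differs from alignment")
    if T.beta is not None:
        if T.beta.get(T.root) != 1:
            violations.append(f"root isotype is {T.beta.get(T.root)}, expected 1")
        for cell in leaves:
            if T.beta.get(cell) != c.isotypes[cell]:
                violations.append(
                    f"leaf isotype: {cell} labeled {T.beta.get(cell)}, observed "
                    f"{c.isotypes[cell]}"
                )
        for u, v in T.graph.edges:
            if u in T.beta and v in T.beta and T.beta[u] > T.beta[v]:
                violations.append(
                    f"irreversibility: edge ({u!r},{v!r}) has isotypes "
                    f"{T.beta[u]} > {T.beta[v]}"
                )
    return violations


def _cluster_chains(T: LineageTree) -> Dict[frozenset, List[Node]]:
    """Group nodes by cluster; each group is a root-to-leaf-ordered chain."""
    clusters = T.clusters()
    depth: Dict[Node, int] = {T.root: 0}
    for v in T.preorder():
        for c in T.children(v):
            depth[c] = depth[v] + 1
    chains: Dict[frozenset, List[Node]] = {}
    for v, cl in clusters.items():
        chains.setdefault(cl, []).append(v)
    for cl in chains:
        chains[cl].sort(key=lambda v: depth[v])
    return chains


def is_refinement(Tprime: LineageTree, T: LineageTree) -> Optional[RefinementMap]:
    """Certify that ``Tprime`` is obtainable from ``T`` by expand operations.

    A rooted tree T' on the same leaf set refines T exactly when every
    cluster (leaf-descendant set) of T occurs in T' with at least the same
    multiplicity (nodes sharing a cluster always form a unary chain).  On
    success the returned map sigma sends each node of T' to a node of T such
    that contracting all sigma-internal edges of T' recovers T; returns
    ``None`` when T' is not a refinement.
    """
    if set(Tprime.leaves()) != set(T.leaves()):
        raise ValueError("leaf-set mismatch between trees")
    chains_t = _cluster_chains(T)
    chains_tp = _cluster_chains(Tprime)
    for cl, chain in chains_t.items():
        if len(chains_tp.get(cl, [])) < len(chain):
            return None
    # smallest T-cluster containing each T'-cluster (containing clusters form
    # a chain, so "smallest" is well defined)
    by_size = sorted(chains_t.items(), key=lambda kv: len(kv[0]))
    sigma: Dict[Node, Node] = {}
    for cl, chain_tp in chains_tp.items():
        target: Optional[List[Node]] = None
        target_cl: Optional[frozenset] = None
        for cu, chain_u in by_size:
            if cl <= cu:
                target, target_cl = chain_u, cu
                break
        if target is None:
            return None
        if cl == target_cl:
            # align chain tops; surplus T' nodes collapse onto the last T node
            for i, vprime in enumerate(chain_tp):
                sigma[vprime] = target[min(i, len(target) - 1)]
        else:
            # strictly inside the expansion of the deepest chain node
            for vprime in chain_tp:
                sigma[vprime] = target[-1]
    # definitive check: the quotient of T' by sigma-internal edges must have
    # T's cluster multiset (which determines a leaf-labeled rooted tree up to
    # isomorphism)
    from collections import Counter

    comp = nx.Graph()
    comp.add_nodes_from(Tprime.nodes())
    comp.add_edges_from(
        (u, v) for u, v in Tprime.graph.edges if sigma[u] == sigma[v]
    )
    rep = {}
    for group in nx.connected_components(comp):
        leader = min(group, key=str)
        for v in group:
            rep[v] = leader
    q = nx.DiGraph()
    q.add_nodes_from(set(rep.values()))
    for u, v in Tprime.graph.edges:
        if sigma[u] != sigma[v]:
            q.add_edge(rep[u], rep[v])
    if not nx.is_tree(q.to_undirected(as_view=True)):
        return None
    # leaves of the quotient must be exactly the original leaves: relabel each
    # component containing a leaf by that leaf
    leaf_rep = {}
    for leaf in Tprime.leaves():
        leaf_rep[rep[leaf]] = leaf
    q = nx.relabel_nodes(q, leaf_rep)
    quotient = LineageTree(q, leaf_rep.get(rep[Tprime.root], rep[Tprime.root]))
    if Counter(quotient.clusters().values()) != Counter(T.clusters().values()):
        return None
    return RefinementMap(sigma)


def contract_edges(T: LineageTree, edges: Iterable[Tuple[Node, Node]]) -> LineageTree:
    """Contract internal edges: for each (u, v), remove v and attach v's
    children to u.  Leaf set is preserved; labels of removed nodes dropped."""
    edge_set = set(edges)
    leaves = set(T.leaves())
    for u, v in edge_set:
        if v in leaves or u in leaves:
            raise ValueError(f"cannot contract edge ({u!r},{v!r}) incident to a leaf")
        if not T.graph.has_edge(u, v):
            raise ValueError(f"edge ({u!r},{v!r}) not in tree")
    g = T.graph.copy()
    alpha = dict(T.alpha) if T.alpha is not None else None
    beta = dict(T.beta) if T.beta is not None else None
    # contracting (u, v) removes v; chains contract correctly because the
    # current parent is looked up at removal time
    for _, v in edge_set:
        parent = next(iter(g.predecessors(v)))
        for c in list(g.successors(v)):
            g.add_edge(parent, c)
        g.remove_node(v)
        if alpha is not None:
            alpha.pop(v, None)
        if beta is not None:
            beta.pop(v, None)
    return LineageTree(g, T.root, alpha=alpha, beta=beta)


# ---------------------------------------------------------------------------
# Canonical ordering / serialization support
# ---------------------------------------------------------------------------

def canonical_children(T: LineageTree) -> Dict[Node, List[Node]]:
    """Children of every node ordered lexicographically by the smallest
    descendant leaf id, making serialized output byte-stable."""
    clusters = T.clusters()
    mins = {v: min(map(str, cl)) for v, cl in clusters.items()}
    return {
        u: sorted(T.children(u), key=lambda c: mins[c])
        for u in T.nodes()
        if not T.is_leaf(u)
    }
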