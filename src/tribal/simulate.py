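"""Synthetic data generation for benchmarking lineage inference.

Ground-truth isotype transition matrices are drawn under two class-switch
models: in the *direct* model a switching cell jumps to any downstream
isotype with similar probability, while in the *sequential* model it strongly
prefers the next contiguous isotype.  Isotypes are then evolved down
ground-truth lineage topologies, and candidate forests are produced by
degrading (contracting random internal edges of) the truth tree, emulating
the polytomies and ambiguity of maximum-parsimony input forests.

The lineage/sequence generator is a deliberately lightweight stand-in for a
full germinal-center simulator: uniform-attachment bifurcating topologies and
iid per-site substitutions, with no selection, indels or codon structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Optional, Tuple

import networkx as nx
import numpy as np

from .model import (
    Clonotype,
    IsotypeAlphabet,
    LineageForest,
    LineageTree,
    MOUSE_ISOTYPES,
    TransitionMatrix,
    contract_edges,
)
from .infer import _sankoff_sequences

Node = Hashable


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class CSRModelParams:
    """Ground-truth transition-matrix generator settings.

    ``transition_prob_choices`` are the admissible total switching
    probabilities ``1 - theta``; per-entry Gaussian noise ``N(mu, sd)`` is
    added and every admissible entry is floored at ``tau`` before row
    normalization, so all upper-triangular entries stay strictly positive.
    """

    model: str = "direct"                     # "direct" | "sequential"
    r: int = 7
    transition_prob_choices: Tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35)
    noise_mean: float = 0.05
    noise_sd: float = 0.025
    floor: float = 0.01

    def __post_init__(self) -> None:
        if self.model not in ("direct", "sequential"):
            raise ValueError(f"unknown CSR model {self.model!r}")
        if self.floor <= 0:
            raise ValueError("floor tau must be positive")
        if any(not 0 < c <= 0.5 for c in self.transition_prob_choices):
            raise ValueError("switching probabilities must lie in (0, 0.5]")


@dataclass
class LineageSimParams:
    """Stand-in lineage generator settings.

    ``mutation_rate`` is the per-site per-edge substitution probability;
    ``degradation`` is the fraction of internal edges contracted to produce
    each candidate tree; ``forest_size`` caps the number of distinct degraded
    candidates per clonotype.
    """

    n_cells: int = 35
    seq_length: int = 150
    mutation_rate: float = 0.0025
    degradation: float = 0.2
    forest_size: int = 4

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.seq_length < 1 or self.forest_size < 1:
            raise ValueError("sizes must be positive")
        if not 0 <= self.degradation <= 1:
            raise ValueError("degradation fraction must be in [0, 1]")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# Transition matrix simulation
# ---------------------------------------------------------------------------

def simulate_transition_matrix(
    params: CSRModelParams, rng: np.random.Generator
) -> TransitionMatrix:
    """Draw a ground-truth transition matrix under the direct or sequential
    class-switch model (noisy template, floored at tau, row-normalized)."""
    r = params.r
    one_minus_theta = rng.choice(params.transition_prob_choices)
    theta = 1.0 - one_minus_theta
    tau = params.floor
    P = np.zeros((r, r))

    def noisy(base: float) -> float:
        eps = rng.normal(params.noise_mean, params.noise_sd)
        return max(base + eps, tau)

    for s in range(r - 1):
        P[s, s] = noisy(theta)
        if params.model == "direct":
            for t in range(s + 1, r):
                P[s, t] = noisy(one_minus_theta / (r - s - 1))
        else:
            P[s, s + 1] = noisy(one_minus_theta)
            for t in range(s + 2, r):
                P[s, t] = tau
        P[s, s:] /= P[s, s:].sum()
    P[r - 1, r - 1] = 1.0
    return TransitionMatrix(P)


def evolve_isotypes(
    T: LineageTree, P: TransitionMatrix, rng: np.random.Generator
) -> Dict[Node, int]:
    """Evolve isotypes down the tree: root state 1, each child drawn from the
    parent-state row of ``P``.  Irreversibility holds by construction."""
    beta: Dict[Node, int] = {T.root: 1}
    r = P.r
    for v in T.preorder():
        row = P.probs[beta[v] - 1]
        for c in T.children(v):
            beta[c] = int(rng.choice(r, p=row)) + 1
    return beta


# ---------------------------------------------------------------------------
# Lineage / sequence simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_lineage_tree(
    params: LineageSimParams,
    rng: np.random.Generator,
    clonotype_id: str = "sim",
    alphabet: IsotypeAlphabet = MOUSE_ISOTYPES,
) -> Tuple[LineageTree, Clonotype]:
    """Random bifurcating lineage with sequences mutated from a naive root.

    Topology grows by uniform attachment (each new cell splits a uniformly
    random existing edge); each edge substitutes every site independently
    with probability ``mutation_rate``.  Isotypes default to all-naive; the
    experiment driver overwrites them via :func:`evolve_isotypes`.
    """
    n, m = params.n_cells, params.seq_length
    g = nx.DiGraph()
    root = "naive"
    cells = [f"cell{i + 1}" for i in range(n)]
    g.add_edge(root, cells[0])
    n_internal = 0
    for leaf in cells[1:]:
        edges = list(g.edges)
        u, v = edges[rng.integers(len(edges))]
        n_internal += 1
        w = f"n{n_internal}"
        g.remove_edge(u, v)
        g.add_edge(u, w)
        g.add_edge(w, v)
        g.add_edge(w, leaf)
    tree = LineageTree(g, root)

    root_seq = "".join(rng.choice(_BASES, size=m))
    seq_idx: Dict[Node, np.ndarray] = {root: np.searchsorted(_BASES, list(root_seq))}
    alpha: Dict[Node, str] = {root: root_seq}
    for v in tree.preorder():
        for c in tree.children(v):
            child = seq_idx[v].copy()
            hits = rng.random(m) < params.mutation_rate
            if hits.any():
                # substitute to a uniformly random *different* base
                shift = rng.integers(1, 4, size=int(hits.sum()))
                child[hits] = (child[hits] + shift) % 4
            seq_idx[c] = child
            alpha[c] = "".join(_BASES[child])
    tree.alpha = alpha
    tree.beta = {v: 1 for v in tree.nodes()}

    clonotype = Clonotype(
        id=clonotype_id,
        germline=root_seq,
        sequences={cell: alpha[cell] for cell in cells},
        isotypes={cell: 1 for cell in cells},
        alphabet=alphabet,
    )
    return tree, clonotype


def _internal_edges(T: LineageTree) -> List[Tuple[Node, Node]]:
    return [(u, v) for u, v in T.graph.edges if not T.is_leaf(v)]


def _degrade(
    T: LineageTree, fraction: float, rng: np.random.Generator
) -> LineageTree:
    """One degraded candidate: contract every internal edge without sequence
    support plus a random fraction of the supported ones.

    An internal edge whose endpoint sequences are identical carries no
    substitutions, so no parsimony method could resolve it from the leaf
    sequences alone -- keeping it would leak truth topology into the
    candidates.  The extra random contractions emulate the residual
    ambiguity of a maximum-parsimony search.
    """
    from .model import hamming_distance

    internal = sorted(_internal_edges(T), key=str)
    zero = [e for e in internal if hamming_distance(T.alpha[e[0]], T.alpha[e[1]]) == 0]
    supported = [e for e in internal if e not in zero]
    k = int(round(fraction * len(supported)))
    extra: List[Tuple[Node, Node]] = []
    if k:
        idx = rng.choice(len(supported), size=min(k, len(supported)), replace=False)
        extra = [supported[i] for i in sorted(idx)]
    chosen = zero + extra
    return contract_edges(T, chosen) if chosen else T.copy()


def make_candidate_forest(
    T_true: LineageTree,
    params: LineageSimParams,
    rng: np.random.Generator,
    clonotype_id: str = "sim",
) -> LineageForest:
    """Degraded candidate forest standing in for a maximum-parsimony forest.

    Every candidate is a contraction of the truth (so the truth is always a
    refinement of it) in which all internal edges without substitution
    support are collapsed -- a parsimony method cannot resolve them -- along
    with a random fraction of the supported edges; candidates are distinct
    and relabeled with minimum-SHM ancestral sequences.
    """
    if T_true.alpha is None:
        raise ValueError("truth tree must carry sequences")
    from collections import Counter

    leaf_seqs = {v: T_true.alpha[v] for v in T_true.leaves()}
    root_seq = T_true.alpha[T_true.root]
    from .model import shm_score

    trees: List[LineageTree] = []
    seen: List[Counter] = []
    attempts = 0
    while len(trees) < params.forest_size and attempts < 8 * params.forest_size:
        attempts += 1
        cand = _degrade(T_true, params.degradation, rng)
        key = Counter(cand.clusters().values())
        if key in seen:
            continue
        cand.beta = None
        cand.alpha = _sankoff_sequences(cand, root_seq, leaf_seqs)
        trees.append(cand)
        seen.append(key)
    scores = [shm_score(t) for t in trees]
    return LineageForest(
        clonotype_id=clonotype_id, trees=trees, shm_scores=scores, source="simulated"
    )


# ---------------------------------------------------------------------------
# Full replicate
# ---------------------------------------------------------------------------

@dataclass
class SimulatedClonotype:
    clonotype: Clonotype
    truth: LineageTree                        # alpha and beta set
    forest: LineageForest


@dataclass
class Replicate:
    model: str
    transitions: TransitionMatrix             # ground truth P
    clonotypes: List[SimulatedClonotype]
    alphabet: IsotypeAlphabet = MOUSE_ISOTYPES


def simulate_experiment(
    k: int,
    n: int,
    model: str,
    rng: np.random.Generator,
    sim_params: Optional[LineageSimParams] = None,
    csr_params: Optional[CSRModelParams] = None,
    alphabet: IsotypeAlphabet = MOUSE_ISOTYPES,
) -> Replicate:
    """One replicate: a ground-truth transition matrix plus ``k`` clonotypes
    of ``n`` cells each with truth trees, isotypes and candidate forests."""
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    csr_params = csr_params or CSRModelParams(model=model, r=alphabet.r)
    if csr_params.model != model:
        raise ValueError("csr_params.model disagrees with model")
    sim_params = sim_params or LineageSimParams(n_cells=n)
    if sim_params.n_cells != n:
        raise ValueError("sim_params.n_cells disagrees with n")
    P = simulate_transition_matrix(csr_params, rng)
    out: List[SimulatedClonotype] = []
    for j in range(k):
        cid = f"clonotype{j + 1}"
        tree, clonotype = simulate_lineage_tree(sim_params, rng, clonotype_id=cid,
                                                alphabet=alphabet)
        beta = evolve_isotypes(tree, P, rng)
        tree.beta = beta
        clonotype = Clonotype(
            id=cid,
            germline=clonotype.germline,
            sequences=clonotype.sequences,
            isotypes={cell: beta[cell] for cell in clonotype.sequences},
            alphabet=alphabet,
        )
        forest = make_candidate_forest(tree, sim_params, rng, clonotype_id=cid)
        out.append(SimulatedClonotype(clonotype=clonotype, truth=tree, forest=forest))
    return Replicate(model=model, transitions=P, clonotypes=out, alphabet=alphabet)
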