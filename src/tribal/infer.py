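"""Coordinate-ascent inference of lineage trees and transition probabilities.

The joint problem is solved lexicographically: candidate trees already
minimize the SHM parsimony score, and refinement (which preserves SHM score
by copying sequences onto expanded nodes) then maximizes the CSR likelihood.
Because clonotypes are conditionally independent given the transition matrix
``P``, inference alternates between

1. refining every candidate tree of every clonotype under the current ``P``
   (MPTR) and keeping the best refinement per clonotype, and
2. re-estimating ``P`` by (pseudocount-regularized) maximum likelihood from
   the isotype-labeled winners,

with multiple restarts over the initial stay probability ``theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    NEG_INF,
    Clonotype,
    LineageForest,
    LineageTree,
    RefinementMap,
    TransitionMatrix,
    validate_transition_matrix,
)
from .refine import MPTRSolution, sankoff_isotypes, solve_mptr

Node = Hashable

#: Character order used for ancestral sequence reconstruction; index order is
#: alphabetical so that plain argmin implements the alphabetical tie-break.
SEQ_CHARS = "-ACGNT"
_CHAR_INDEX = {c: i for i, c in enumerate(SEQ_CHARS)}


# ---------------------------------------------------------------------------
# Configuration / results
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Tuning knobs of the coordinate-ascent fit.

    Defaults follow the published protocol: restarts over
    theta in {0.55, ..., 0.95}, at most 10 iterations per restart, absolute
    convergence threshold 0.5 on the summed CSR log-likelihood, and at most
    50 candidate trees sampled per clonotype per iteration (the previous
    winner is always re-included so the objective cannot regress).
    """

    theta_grid: Tuple[float, ...] = (0.55, 0.65, 0.75, 0.85, 0.95)
    max_iterations: int = 10
    convergence_threshold: float = 0.5
    forest_sample_cap: int = 50
    mode: str = "tribal"                      # "tribal" | "tribal-nr"
    seed: int = 0
    engine: str = "dp"                        # MPTR engine: "dp" | "ilp"
    tie_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.convergence_threshold <= 0:
            raise ValueError("convergence threshold must be positive")
        if self.forest_sample_cap < 1:
            raise ValueError("forest sample cap must be >= 1")
        if self.mode not in ("tribal", "tribal-nr"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ClonotypeFit:
    """Co-optimal refined (or relabeled) trees for one clonotype."""

    clonotype_id: str
    solutions: List[MPTRSolution]             # all candidates tying the best
    objective: float
    shm_score: Optional[int] = None


@dataclass
class FitResult:
    transitions: TransitionMatrix
    fits: Dict[str, ClonotypeFit]
    theta: float
    objective: float
    traces: Dict[float, List[float]]          # per-restart objective trace
    mode: str


# ---------------------------------------------------------------------------
# Initialization and MLE update of P
# ---------------------------------------------------------------------------

def init_transition_probs(theta: float, r: int) -> TransitionMatrix:
    """Initial transition matrix: stay probability ``theta`` on the diagonal
    (1 for the last state), remaining mass uniform over higher states."""
    if not 0.5 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0.5, 1], got {theta}")
    P = np.zeros((r, r))
    for s in range(r - 1):
        P[s, s] = theta
        for t in range(s + 1, r):
            P[s, t] = (1.0 - theta) / (r - s - 1)
    P[r - 1, r - 1] = 1.0
    return TransitionMatrix(P)


def transition_counts(trees: Sequence[LineageTree], r: int) -> np.ndarray:
    """Edge counts N[s-1][t-1] of parent state s over child state t."""
    N = np.zeros((r, r))
    for tree in trees:
        if tree.beta is None:
            raise ValueError("tree has no isotype labeling")
        for u, v in tree.graph.edges:
            s, t = tree.beta[u], tree.beta[v]
            if s > t:
                raise ValueError(
                    f"invalid labeling: edge ({u!r},{v!r}) has isotypes {s} > {t}"
                )
            N[s - 1, t - 1] += 1
    return N


def mle_transition_probs(trees: Sequence[LineageTree], r: int) -> TransitionMatrix:
    """Maximum-likelihood transition probabilities with pseudocount 1 on every
    admissible (upper-triangular) cell, so unobserved transitions stay
    possible in the next refinement round."""
    N = transition_counts(trees, r)
    P = np.zeros((r, r))
    for s in range(r):
        row = N[s, s:] + 1.0
        P[s, s:] = row / row.sum()
    return TransitionMatrix(P)


# ---------------------------------------------------------------------------
# Ancestral sequence reconstruction (unit-cost Sankoff per column)
# ---------------------------------------------------------------------------

def _encode(seq: str, m: int, context: str) -> np.ndarray:
    seq = seq.upper()
    if len(seq) != m:
        raise ValueError(f"{context}: length {len(seq)} != alignment length {m}")
    try:
        return np.array([_CHAR_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"{context}: unexpected character {exc.args[0]!r}") from None


def _sankoff_sequences(
    T: LineageTree, root_seq: str, leaf_seqs: Dict[Node, str]
) -> Dict[Node, str]:
    """Unit-cost small parsimony over {A,C,G,T,-,N} per alignment column with
    the root fixed; ties break alphabetically."""
    m = len(root_seq)
    K = len(SEQ_CHARS)
    root_idx = _encode(root_seq, m, "root")
    cost: Dict[Node, np.ndarray] = {}
    for v in T.postorder():
        kids = T.children(v)
        if not kids:
            if v not in leaf_seqs:
                raise ValueError(f"leaf {v!r} has no sequence")
            idx = _encode(leaf_seqs[v], m, f"leaf {v!r}")
            vec = np.full((m, K), np.inf)
            vec[np.arange(m), idx] = 0.0
            cost[v] = vec
        else:
            vec = np.zeros((m, K))
            for c in kids:
                cc = cost[c]
                vec += np.minimum(cc, cc.min(axis=1, keepdims=True) + 1.0)
            cost[v] = vec
    alpha: Dict[Node, str] = {}
    choice: Dict[Node, np.ndarray] = {T.root: root_idx}
    alpha[T.root] = root_seq.upper()
    for v in T.preorder():
        pc = choice[v]
        for c in T.children(v):
            if T.is_leaf(c):
                alpha[c] = leaf_seqs[c].upper()
                choice[c] = _encode(leaf_seqs[c], m, f"leaf {c!r}")
                continue
            total = cost[c] + 1.0
            total[np.arange(m), pc] -= 1.0
            idx = np.argmin(total, axis=1)        # lowest index = alphabetical
            choice[c] = idx
            alpha[c] = "".join(SEQ_CHARS[i] for i in idx)
    return alpha


def ancestral_sequences(T: LineageTree, c: Clonotype) -> Dict[Node, str]:
    """Minimum-SHM internal sequence labeling of ``T`` with the root fixed to
    the germline and leaves fixed to the clonotype's aligned sequences."""
    leaves = set(T.leaves())
    missing = leaves - set(c.sequences)
    if missing:
        raise ValueError(f"leaves not mapped to cells: {sorted(map(str, missing))}")
    return _sankoff_sequences(T, c.germline, c.sequences)


# ---------------------------------------------------------------------------
# Candidate sampling and per-clonotype refinement
# ---------------------------------------------------------------------------

def sample_candidate_trees(
    forest: LineageForest,
    cap: int,
    previous_best: Optional[LineageTree],
    rng: np.random.Generator,
) -> List[LineageTree]:
    """Uniform sample (without replacement) of at most ``cap`` candidate
    trees, always force-including ``previous_best`` when given."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    trees = forest.trees
    if len(trees) <= cap:
        return list(trees)
    idx = rng.choice(len(trees), size=cap, replace=False)
    sample = [trees[i] for i in idx]
    if previous_best is not None and not any(t is previous_best for t in sample):
        sample[0] = previous_best
    return sample


def _copy_alpha(sol: MPTRSolution, source: LineageTree) -> None:
    """Sequence labeling of a refinement: expanded copies inherit the original
    node's sequence, so the SHM score is preserved exactly."""
    if source.alpha is None:
        return
    sol.tree.alpha = {
        v: source.alpha[sol.sigma.sigma[v]] for v in sol.tree.nodes()
    }


def refine_clonotype(
    trees: Sequence[LineageTree],
    b: Dict[Node, int],
    P: TransitionMatrix,
    mode: str = "tribal",
    engine: str = "dp",
    tie_tol: float = 1e-9,
) -> Tuple[List[MPTRSolution], List[int], float]:
    """Best CSR objective over a set of candidate trees.

    Mode ``tribal`` solves MPTR for every candidate; mode ``tribal-nr``
    labels the unrefined candidates by weighted Sankoff with costs
    ``-log p``.  Returns all co-optimal solutions (within ``tie_tol``), the
    indices of the candidates that produced them, and the objective.
    """
    if not trees:
        raise ValueError("empty candidate set")
    single_state = all(v == 1 for v in b.values())
    log_p11 = math.log(P.p(1, 1)) if P.p(1, 1) > 0 else NEG_INF
    solutions: List[MPTRSolution] = []
    for T in trees:
        if single_state:
            # every labeling is all-1s; the objective is |E| log p11
            beta = {v: 1 for v in T.nodes()}
            tree = LineageTree(T.graph.copy(), T.root, beta=beta)
            sigma = RefinementMap({v: v for v in T.nodes()})
            solutions.append(MPTRSolution(tree, sigma, T.n_edges() * log_p11))
        elif mode == "tribal":
            solutions.append(solve_mptr(T, b, P, engine=engine))
        else:
            W = -P.log_probs()
            beta, cost = sankoff_isotypes(T, b, W)
            tree = LineageTree(T.graph.copy(), T.root, beta=beta)
            sigma = RefinementMap({v: v for v in T.nodes()})
            solutions.append(MPTRSolution(tree, sigma, -cost))
    best = max(s.objective for s in solutions)
    winners, idx = [], []
    for i, s in enumerate(solutions):
        if s.objective >= best - tie_tol:
            _copy_alpha(s, trees[i])
            winners.append(s)
            idx.append(i)
    return winners, idx, best


# ---------------------------------------------------------------------------
# Coordinate ascent
# ---------------------------------------------------------------------------

def fit(
    clonotypes: Sequence[Clonotype],
    forests: Sequence[LineageForest],
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Jointly infer shared transition probabilities and per-clonotype trees.

    For each restart value theta: initialize ``P``, then alternate candidate
    sampling, per-clonotype refinement under the current ``P`` and
    pseudocount-MLE update of ``P`` until the summed log-objective changes by
    less than the convergence threshold (or the iteration cap is hit).  The
    restart with the highest final objective wins; ties go to the smaller
    theta.
    """
    config = config or FitConfig()
    if not clonotypes:
        raise ValueError("empty clonotype list")
    if len(clonotypes) != len(forests):
        raise ValueError("need exactly one forest per clonotype")
    r = clonotypes[0].alphabet.r
    for c in clonotypes:
        if c.alphabet.r != r:
            raise ValueError("clonotypes must share one isotype alphabet")

    # candidate trees must carry ancestral sequences so refinements can copy
    # them (SHM preservation) and outputs are fully labeled
    for c, forest in zip(clonotypes, forests):
        for T in forest.trees:
            if T.alpha is None:
                T.alpha = ancestral_sequences(T, c)

    rng = np.random.default_rng(config.seed)
    best_restart = None
    traces: Dict[float, List[float]] = {}
    for theta in config.theta_grid:
        P = init_transition_probs(theta, r)
        prev_obj: Optional[float] = None
        prev_best: Dict[str, Optional[LineageTree]] = {c.id: None for c in clonotypes}
        trace: List[float] = []
        fits: Dict[str, ClonotypeFit] = {}
        P_used = P
        for _ in range(config.max_iterations):
            P_used = P
            total = 0.0
            fits = {}
            mle_input: List[LineageTree] = []
            for c, forest in zip(clonotypes, forests):
                sample = sample_candidate_trees(
                    forest, config.forest_sample_cap, prev_best[c.id], rng
                )
                b = dict(c.isotypes)
                winners, idx, obj = refine_clonotype(
                    sample, b, P, mode=config.mode,
                    engine=config.engine, tie_tol=config.tie_tol,
                )
                total += obj
                prev_best[c.id] = sample[idx[0]]
                mle_input.append(winners[0].tree)
                fits[c.id] = ClonotypeFit(c.id, winners, obj)
            trace.append(total)
            if prev_obj is not None and abs(total - prev_obj) < config.convergence_threshold:
                break
            prev_obj = total
            P = mle_transition_probs(mle_input, r)
        traces[theta] = trace
        final = trace[-1]
        # report the matrix the final refinement was performed under
        if best_restart is None or final > best_restart[0] + 1e-12:
            best_restart = (final, theta, P_used, fits)
    final, theta, P, fits = best_restart
    assert not validate_transition_matrix(P)
    return FitResult(
        transitions=P,
        fits=fits,
        theta=theta,
        objective=final,
        traces=traces,
        mode=config.mode,
    )
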