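"""Most Parsimonious Tree Refinement (MPTR).

Given a (possibly multifurcating) candidate tree ``T`` whose leaves carry
observed isotypes ``b`` and an isotype transition matrix ``P``, MPTR asks for
a refinement ``T'`` of ``T`` (obtained by zero or more node-expand
operations) together with an isotype labeling ``beta'`` that maximizes the
CSR log-likelihood.  The search space is captured exactly by the *expansion
graph*: a layered DAG over (tree node, isotype state) pairs whose valid
subtrees -- rooted at ``(v0, 1)``, using exactly one copy of every original
tree edge -- correspond one-to-one to refinements with *transitory* isotype
labelings (every edge either switches state or joins copies of distinct
original nodes).

Three solvers are provided:

* :func:`solve_mptr_ilp` -- the multi-commodity-flow integer linear program
  (one flow commodity per leaf) solved with ``scipy.optimize.milp`` (HiGHS);
* :func:`solve_mptr_dp` -- an exact dynamic program over the expansion graph,
  exponential only in the number of isotype states ``r`` (the problem is
  NP-hard when ``r`` grows with the input, via Set Cover; for fixed ``r`` the
  DP is polynomial and orders of magnitude faster than the ILP);
* :func:`solve_mptr_bruteforce` -- exhaustive enumeration of valid subtrees,
  used as an independent oracle on tiny instances.

All three agree on the objective; solution trees may differ under ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Hashable, List, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .model import (
    NEG_INF,
    LineageTree,
    RefinementMap,
    TransitionMatrix,
    contract_edges,
    csr_log_likelihood,
)

Node = Hashable

try:  # optional JIT acceleration; the pure-Python path is identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not args else args[0]


# ---------------------------------------------------------------------------
# Expansion graph (Definition: layered DAG over (node, state) pairs)
# ---------------------------------------------------------------------------

@dataclass
class ExpansionGraph:
    """Layered DAG over (tree node, isotype state) pairs; states 1-based."""

    slices: Dict[Node, List[int]]                      # X(u)
    edges: List[Tuple[Tuple[Node, int], Tuple[Node, int]]]
    root: Tuple[Node, int]

    @property
    def nodes(self) -> List[Tuple[Node, int]]:
        return [(u, s) for u, states in self.slices.items() for s in states]

    def n_nodes(self) -> int:
        return sum(len(v) for v in self.slices.values())


def build_expansion_graph(T: LineageTree, b: Dict[Node, int], r: int) -> ExpansionGraph:
    """Construct the expansion graph of ``T`` with leaf isotypes ``b``.

    ``X(leaf) = {b_leaf}``; ``X(internal u) = {1..max leaf isotype below u}``.
    Edges: one copy of every tree edge for each state pair ``s <= t``, plus
    within-slice edges ``(u,s) -> (u,t)`` for ``s < t`` (expand operations).
    """
    for leaf in T.leaves():
        if leaf not in b:
            raise ValueError(f"leaf {leaf!r} is missing an isotype")
        if not 1 <= b[leaf] <= r:
            raise ValueError(f"leaf {leaf!r} isotype {b[leaf]} outside [1..{r}]")
    maxstate: Dict[Node, int] = {}
    for v in T.postorder():
        kids = T.children(v)
        if not kids:
            maxstate[v] = b[v]
        else:
            maxstate[v] = max(maxstate[c] for c in kids)
    slices: Dict[Node, List[int]] = {}
    for v in T.nodes():
        if T.is_leaf(v):
            slices[v] = [b[v]]
        else:
            slices[v] = list(range(1, maxstate[v] + 1))
    edges: List[Tuple[Tuple[Node, int], Tuple[Node, int]]] = []
    for u, v in T.graph.edges:
        for s in slices[u]:
            for t in slices[v]:
                if s <= t:
                    edges.append(((u, s), (v, t)))
    for u, states in slices.items():
        for s in states:
            for t in states:
                if s < t:
                    edges.append(((u, s), (u, t)))
    return ExpansionGraph(slices=slices, edges=edges, root=(T.root, 1))


@dataclass
class MPTRSolution:
    """A refined tree with transitory isotype labeling and its objective."""

    tree: LineageTree              # beta set on all nodes
    sigma: RefinementMap           # refined node -> original node
    objective: float


# ---------------------------------------------------------------------------
# Exact dynamic program
# ---------------------------------------------------------------------------
#
# In any valid subtree the copies used within one slice X(u) form a small
# arborescence rooted at the unique entry copy (the endpoint of the single
# selected copy of the tree edge into u), with strictly increasing states
# along its edges and at most one copy per state.  Conditioning on the entry
# state s of node u, the optimum decomposes over (i) the subset D of extra
# states used in the slice, (ii) a minimum-cost parent choice for every extra
# state, and (iii) an independent best attachment state in D for every child
# subtree.  g[u][s] below is the best objective of the subtree of u given
# entry state s; subsets D are enumerated as bitmasks over (s, maxstate(u)].


def _kernel_impl(order, child_ptr, child_idx, leaf_state, maxstate, logP):
    V = order.shape[0]
    r = logP.shape[0]
    g = np.full((V, r), -np.inf)
    choice = np.zeros((V, r), dtype=np.int64)
    H = np.empty((0, 0))
    for oi in range(V):
        u = order[oi]
        nc = child_ptr[u + 1] - child_ptr[u]
        if nc == 0:
            continue
        mu = maxstate[u]
        H = np.full((nc, r), -np.inf)
        for ci in range(nc):
            c = child_idx[child_ptr[u] + ci]
            if child_ptr[c + 1] == child_ptr[c]:           # leaf child
                bc = leaf_state[c]
                for a in range(bc + 1):
                    H[ci, a] = logP[a, bc]
            else:
                mc = maxstate[c]
                for a in range(mc + 1):
                    best = -np.inf
                    for t in range(a, mc + 1):
                        val = logP[a, t] + g[c, t]
                        if val > best:
                            best = val
                    H[ci, a] = best
        for s in range(mu + 1):
            k = mu - s
            nmask = 1 << k
            intcost = np.zeros(nmask)
            bh = np.empty((nc, nmask))
            best_obj = 0.0
            for ci in range(nc):
                bh[ci, 0] = H[ci, s]
                best_obj += H[ci, s]
            best_mask = 0
            for mask in range(1, nmask):
                top = 0
                tmp = mask
                while tmp > 1:
                    tmp >>= 1
                    top += 1
                rest = mask ^ (1 << top)
                st = s + 1 + top
                mp = logP[s, st]
                tmp = rest
                bit = 0
                while tmp > 0:
                    if tmp & 1:
                        cand = logP[s + 1 + bit, st]
                        if cand > mp:
                            mp = cand
                    tmp >>= 1
                    bit += 1
                intcost[mask] = intcost[rest] + mp
                tot = intcost[mask]
                for ci in range(nc):
                    v = bh[ci, rest]
                    hv = H[ci, st]
                    if hv > v:
                        v = hv
                    bh[ci, mask] = v
                    tot += v
                if tot > best_obj:                 # strict: smallest mask wins ties
                    best_obj = tot
                    best_mask = mask
            g[u, s] = best_obj
            choice[u, s] = best_mask
    return g, choice


if _HAVE_NUMBA:
    _kernel = _njit(cache=False)(_kernel_impl)
else:  # pragma: no cover
    _kernel = _kernel_impl


def _tree_arrays(T: LineageTree, b: Dict[Node, int]):
    """Flatten the tree into CSR arrays (0-based states) for the DP kernel."""
    nodes = list(T.postorder())
    index = {v: i for i, v in enumerate(nodes)}
    V = len(nodes)
    child_ptr = np.zeros(V + 1, dtype=np.int64)
    kids: List[List[int]] = []
    for v in nodes:
        ch = sorted(T.children(v), key=str)
        kids.append([index[c] for c in ch])
        child_ptr[index[v] + 1] = len(ch)
    child_ptr = np.cumsum(child_ptr).astype(np.int64)
    child_idx = np.zeros(child_ptr[-1], dtype=np.int64)
    for v in nodes:
        i = index[v]
        child_idx[child_ptr[i]: child_ptr[i + 1]] = kids[i]
    leaf_state = np.full(V, -1, dtype=np.int64)
    maxstate = np.zeros(V, dtype=np.int64)
    for v in nodes:  # postorder: children first
        i = index[v]
        ch = kids[i]
        if not ch:
            leaf_state[i] = b[v] - 1
            maxstate[i] = b[v] - 1
        else:
            maxstate[i] = max(maxstate[c] for c in ch)
    order = np.array([index[v] for v in nodes], dtype=np.int64)
    return nodes, index, order, child_ptr, child_idx, leaf_state, maxstate


def _fresh_name(base: str, used: Set[Node]) -> str:
    name = base
    while name in used:
        name = name + "'"
    used.add(name)
    return name


def solve_mptr_dp(T: LineageTree, b: Dict[Node, int], P: TransitionMatrix) -> MPTRSolution:
    """Solve MPTR exactly by dynamic programming over the expansion graph."""
    logP = P.log_probs()
    nodes, index, order, child_ptr, child_idx, leaf_state, maxstate = _tree_arrays(T, b)
    g, choice = _kernel(order, child_ptr, child_idx, leaf_state, maxstate, logP)
    ri = index[T.root]
    objective = float(g[ri, 0])
    if objective == NEG_INF:
        raise ValueError("no valid refinement under P (zero-probability structure)")

    # backtrace ------------------------------------------------------------
    edges: List[Tuple[Node, Node]] = []
    beta: Dict[Node, int] = {}
    sigma: Dict[Node, Node] = {}
    used: Set[Node] = set(nodes)

    def h_val(ci_node: int, a: int) -> float:
        if child_ptr[ci_node + 1] == child_ptr[ci_node]:
            bc = leaf_state[ci_node]
            return logP[a, bc] if a <= bc else -np.inf
        best = -np.inf
        for t in range(a, maxstate[ci_node] + 1):
            v = logP[a, t] + g[ci_node, t]
            if v > best:
                best = v
        return best

    stack: List[Tuple[int, int, Node]] = [(ri, 0, T.root)]
    beta[T.root] = 1
    sigma[T.root] = T.root
    while stack:
        ui, s, entry_name = stack.pop()
        u = nodes[ui]
        mask = int(choice[ui, s])
        D = [s] + [s + 1 + j for j in range(maxstate[ui] - s) if mask >> j & 1]
        copy_of: Dict[int, Node] = {s: entry_name}
        for d in D[1:]:
            name = _fresh_name(f"{u}.{d + 1}", used)
            copy_of[d] = name
            beta[name] = d + 1
            sigma[name] = u
        # within-slice arborescence: each extra state hangs off its best
        # lower parent in D (ties -> lowest state)
        for d in D[1:]:
            best_p, best_v = None, -np.inf
            for p in D:
                if p < d and logP[p, d] > best_v:
                    best_v, best_p = logP[p, d], p
            edges.append((copy_of[best_p], copy_of[d]))
        # children: best attachment state in D (ties -> lowest), then best
        # entry state for the child (ties -> lowest)
        for ci in range(child_ptr[ui], child_ptr[ui + 1]):
            c = int(child_idx[ci])
            cnode = nodes[c]
            best_a, best_v = D[0], h_val(c, D[0])
            for a in D[1:]:
                v = h_val(c, a)
                if v > best_v:
                    best_v, best_a = v, a
            if child_ptr[c + 1] == child_ptr[c]:           # leaf
                edges.append((copy_of[best_a], cnode))
                beta[cnode] = leaf_state[c] + 1
                sigma[cnode] = cnode
            else:
                best_t, best_tv = None, -np.inf
                for t in range(best_a, maxstate[c] + 1):
                    v = logP[best_a, t] + g[c, t]
                    if v > best_tv:
                        best_tv, best_t = v, t
                edges.append((copy_of[best_a], cnode))
                beta[cnode] = best_t + 1
                sigma[cnode] = cnode
                stack.append((c, best_t, cnode))

    tree = LineageTree.from_edges(edges, T.root, beta=beta)
    return MPTRSolution(tree=tree, sigma=RefinementMap(sigma), objective=objective)


# ---------------------------------------------------------------------------
# Integer linear program (multi-commodity flow)
# ---------------------------------------------------------------------------

def solve_mptr_ilp(T: LineageTree, b: Dict[Node, int], P: TransitionMatrix) -> MPTRSolution:
    """Solve MPTR via the multi-commodity-flow MILP on the expansion graph.

    One unit of flow is routed from the root copy ``(v0, 1)`` to every leaf
    copy; binary edge indicators ``x`` pay ``log p`` and exactly one copy of
    every original tree edge must be selected, which guarantees the selected
    subgraph is a refinement with transitory labeling.  Edges whose
    transition probability is zero are omitted, keeping the program
    well-posed.
    """
    r = P.r
    G = build_expansion_graph(T, b, r)
    logP = P.log_probs()
    edges = [
        ((u, s), (v, t))
        for (u, s), (v, t) in G.edges
        if logP[s - 1, t - 1] > NEG_INF
    ]
    nE = len(edges)
    leaves = sorted(T.leaves(), key=str)
    nQ = len(leaves)
    leaf_pos = {q: i for i, q in enumerate(leaves)}
    edge_pos = {e: i for i, e in enumerate(edges)}
    out_edges: Dict[Tuple[Node, int], List[int]] = {}
    in_edges: Dict[Tuple[Node, int], List[int]] = {}
    for i, (a, bb) in enumerate(edges):
        out_edges.setdefault(a, []).append(i)
        in_edges.setdefault(bb, []).append(i)

    nvar = nE + nE * nQ                      # x block then f block
    def fvar(i: int, qi: int) -> int:
        return nE + qi * nE + i

    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    lb: List[float] = []
    ub: List[float] = []
    nrow = 0

    def add_row(entries: List[Tuple[int, float]], lo: float, hi: float) -> None:
        nonlocal nrow
        for c, v in entries:
            rows.append(nrow)
            cols.append(c)
            vals.append(v)
        lb.append(lo)
        ub.append(hi)
        nrow += 1

    internal_tree_nodes = {v for v in T.nodes() if not T.is_leaf(v)}
    # (5) flow conservation at every internal-node copy except the root copy
    for gnode in G.nodes:
        u, s = gnode
        if u not in internal_tree_nodes or gnode == G.root:
            continue
        for qi in range(nQ):
            ent = [(fvar(i, qi), 1.0) for i in out_edges.get(gnode, [])]
            ent += [(fvar(i, qi), -1.0) for i in in_edges.get(gnode, [])]
            if ent:
                add_row(ent, 0.0, 0.0)
    # (6) each leaf copy receives one unit of its own commodity
    for q in leaves:
        qi = leaf_pos[q]
        sink = (q, b[q])
        ent = [(fvar(i, qi), 1.0) for i in in_edges.get(sink, [])]
        if not ent:
            raise ValueError("no valid refinement under P (leaf unreachable)")
        add_row(ent, 1.0, 1.0)
    # (7) the root copy emits one unit of every commodity
    for qi in range(nQ):
        ent = [(fvar(i, qi), 1.0) for i in out_edges.get(G.root, [])]
        add_row(ent, 1.0, 1.0)
    # (8) flow only on selected edges
    for i in range(nE):
        for qi in range(nQ):
            add_row([(fvar(i, qi), 1.0), (i, -1.0)], -np.inf, 0.0)
    # (9) exactly one copy of every original tree edge
    for (tu, tv) in T.graph.edges:
        ent = [
            (edge_pos[((u, s), (v, t))], 1.0)
            for ((u, s), (v, t)) in edges
            if u == tu and v == tv
        ]
        if not ent:
            raise ValueError("no valid refinement under P (tree edge has no copy)")
        add_row(ent, 1.0, 1.0)

    c = np.zeros(nvar)
    for i, ((u, s), (v, t)) in enumerate(edges):
        c[i] = -logP[s - 1, t - 1]           # minimize -(sum x log p)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(nrow, nvar))
    integrality = np.zeros(nvar)
    integrality[:nE] = 1
    bounds = Bounds(np.zeros(nvar), np.ones(nvar))
    res = milp(
        c,
        constraints=LinearConstraint(A, np.array(lb), np.array(ub)),
        integrality=integrality,
        bounds=bounds,
    )
    if res.status != 0:
        raise RuntimeError(f"MILP solver failed: status={res.status} ({res.message})")

    x = res.x[:nE]
    f = res.x[nE:].reshape(nQ, nE)
    carries = f.max(axis=0) > 1e-6
    chosen = [edges[i] for i in range(nE) if x[i] > 0.5 and carries[i]]
    # assemble the refined tree from the flow-carrying selected subgraph
    parent_of: Dict[Tuple[Node, int], Tuple[Node, int]] = {}
    for a, bb in chosen:
        if bb in parent_of:
            raise RuntimeError("degenerate MILP solution: node with two parents")
        parent_of[bb] = a
    used: Set[Node] = set(T.nodes())
    name_of: Dict[Tuple[Node, int], Node] = {G.root: T.root}
    beta: Dict[Node, int] = {T.root: 1}
    sigma: Dict[Node, Node] = {T.root: T.root}
    # entry copy of each slice keeps the original node name
    entry: Dict[Node, Tuple[Node, int]] = {T.root: G.root}
    for (a, bb) in chosen:
        if a[0] != bb[0]:
            entry[bb[0]] = bb
    for gnode in sorted(parent_of, key=lambda nd: (str(nd[0]), nd[1])):
        u, s = gnode
        if entry.get(u) == gnode:
            name = u
        else:
            name = _fresh_name(f"{u}.{s}", used)
        name_of[gnode] = name
        beta[name] = s
        sigma[name] = u
    tree_edges = [(name_of[parent_of[nd]], name_of[nd]) for nd in parent_of]
    tree = LineageTree.from_edges(tree_edges, T.root, beta=beta)
    if set(tree.leaves()) != set(T.leaves()):
        raise RuntimeError("degenerate MILP solution: leaf set mismatch")
    tree, beta2, sigma = contract_non_transitory(tree, beta, sigma)
    objective = csr_log_likelihood(tree, P)
    milp_obj = -float(res.fun)
    if not math.isclose(objective, milp_obj, rel_tol=0, abs_tol=1e-6 * max(1.0, abs(milp_obj))):
        raise RuntimeError(
            f"extracted objective {objective} differs from MILP optimum {milp_obj}"
        )
    return MPTRSolution(tree=tree, sigma=RefinementMap(sigma), objective=objective)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def solve_mptr_bruteforce(
    T: LineageTree,
    b: Dict[Node, int],
    P: TransitionMatrix,
    limit: int = 80,
) -> MPTRSolution:
    """Exhaustively enumerate valid subtrees of the expansion graph.

    Per internal node and entry state this enumerates every subset of extra
    slice states, every parent function on the subset, every child attachment
    and every child entry state -- no optimization shortcuts -- and returns
    the maximum.  Intended as an independent oracle; refuses instances whose
    expansion graph exceeds ``limit`` nodes.
    """
    G = build_expansion_graph(T, b, P.r)
    if G.n_nodes() > limit:
        raise ValueError(f"instance too large for brute force: {G.n_nodes()} > {limit}")
    logP = P.log_probs()
    maxstate: Dict[Node, int] = {}
    for v in T.postorder():
        kids = T.children(v)
        maxstate[v] = b[v] if not kids else max(maxstate[c] for c in kids)

    # plan: (D tuple, parents dict, {child: (attach, entry)})
    def best(u: Node, s: int) -> Tuple[float, Optional[dict]]:
        kids = sorted(T.children(u), key=str)
        extra = list(range(s + 1, maxstate[u] + 1))
        best_obj, best_plan = -np.inf, None
        for mask in range(1 << len(extra)):
            D = [s] + [extra[j] for j in range(len(extra)) if mask >> j & 1]
            for parents in _parent_functions(D):
                base = sum(logP[p - 1, d - 1] for d, p in parents.items())
                obj = base
                assign: Dict[Node, Tuple[int, int]] = {}
                for c in kids:
                    cb, ca = -np.inf, None
                    if T.is_leaf(c):
                        for a in D:
                            if a <= b[c] and logP[a - 1, b[c] - 1] > cb:
                                cb, ca = logP[a - 1, b[c] - 1], (a, b[c])
                    else:
                        for a in D:
                            for t in range(a, maxstate[c] + 1):
                                sub, _ = _memo_best(c, t)
                                v = logP[a - 1, t - 1] + sub
                                if v > cb:
                                    cb, ca = v, (a, t)
                    obj += cb
                    if ca is not None:
                        assign[c] = ca
                if obj > best_obj:
                    best_obj = obj
                    best_plan = {"D": tuple(D), "parents": dict(parents), "assign": assign}
        return best_obj, best_plan

    # exhaustive recursion; memo only caches full exhaustive results per
    # (node, entry) so complexity stays the enumeration above
    memo: Dict[Tuple[Node, int], Tuple[float, Optional[dict]]] = {}

    def _memo_best(u: Node, s: int) -> Tuple[float, Optional[dict]]:
        key = (u, s)
        if key not in memo:
            memo[key] = best(u, s)
        return memo[key]

    objective, _ = _memo_best(T.root, 1)
    if objective == -np.inf:
        raise ValueError("no valid refinement under P")

    # assemble winner
    edges: List[Tuple[Node, Node]] = []
    beta: Dict[Node, int] = {T.root: 1}
    sigma: Dict[Node, Node] = {T.root: T.root}
    used: Set[Node] = set(T.nodes())
    stack = [(T.root, 1, T.root)]
    while stack:
        u, s, entry_name = stack.pop()
        _, plan = _memo_best(u, s)
        copy_of = {s: entry_name}
        for d in plan["D"][1:]:
            name = _fresh_name(f"{u}.{d}", used)
            copy_of[d] = name
            beta[name] = d
            sigma[name] = u
        for d, p in plan["parents"].items():
            edges.append((copy_of[p], copy_of[d]))
        for c, (a, t) in plan["assign"].items():
            if T.is_leaf(c):
                edges.append((copy_of[a], c))
                beta[c] = b[c]
                sigma[c] = c
            else:
                edges.append((copy_of[a], c))
                beta[c] = t
                sigma[c] = c
                stack.append((c, t, c))
    tree = LineageTree.from_edges(edges, T.root, beta=beta)
    return MPTRSolution(tree=tree, sigma=RefinementMap(sigma), objective=float(objective))


def _parent_functions(D: Sequence[int]):
    """All ways to give each non-minimum member of D a strictly lower parent in D."""
    rest = list(D[1:])
    if not rest:
        yield {}
        return

    def rec(i: int, current: Dict[int, int]):
        if i == len(rest):
            yield dict(current)
            return
        d = rest[i]
        for p in D:
            if p < d:
                current[d] = p
                yield from rec(i + 1, current)
                del current[d]

    yield from rec(0, {})


# ---------------------------------------------------------------------------
# Sankoff small parsimony on isotypes
# ---------------------------------------------------------------------------

def sankoff_isotypes(
    T: LineageTree,
    b: Dict[Node, int],
    W: np.ndarray,
) -> Tuple[Dict[Node, int], float]:
    """Weighted small parsimony for isotypes on a fixed tree.

    ``W[s-1][t-1]`` is the cost of a parent state ``s`` over child state ``t``
    (``+inf`` forbids).  Leaves are fixed to ``b`` and the root to state 1.
    Returns a minimum-cost full labeling (deterministic tie-break: lowest
    state ordinal) and its total cost.
    """
    W = np.asarray(W, dtype=float)
    r = W.shape[0]
    cost: Dict[Node, np.ndarray] = {}
    for v in T.postorder():
        kids = T.children(v)
        if not kids:
            vec = np.full(r, np.inf)
            vec[b[v] - 1] = 0.0
            cost[v] = vec
        else:
            vec = np.zeros(r)
            for c in kids:
                # min over child states t of W[s,t] + cost[c][t], per s
                with np.errstate(invalid="ignore"):
                    vec += np.min(W + cost[c][None, :], axis=1)
            cost[v] = vec
    total = float(cost[T.root][0])             # root fixed to state 1
    if not np.isfinite(total):
        raise ValueError("no feasible labeling (all-infinite root cost)")
    beta: Dict[Node, int] = {T.root: 1}
    for v in T.preorder():
        s = beta[v]
        for c in T.children(v):
            cand = W[s - 1, :] + cost[c]
            t = int(np.argmin(cand))           # ties -> lowest ordinal
            beta[c] = t + 1
    return beta, total


def unit_switch_costs(r: int, literal: bool = False) -> np.ndarray:
    """Minimum-switches Sankoff weights: 0 on the diagonal, 1 for s < t,
    forbidden for s > t.  ``literal=True`` yields the swapped variant
    (1 if s = t, 0 if s < t) for comparison purposes."""
    W = np.full((r, r), np.inf)
    for s in range(r):
        W[s, s] = 1.0 if literal else 0.0
        for t in range(s + 1, r):
            W[s, t] = 0.0 if literal else 1.0
    return W


# ---------------------------------------------------------------------------
# Transitory normalization
# ---------------------------------------------------------------------------

def contract_non_transitory(
    Tprime: LineageTree,
    beta: Dict[Node, int],
    sigma: Optional[Dict[Node, Node]] = None,
) -> Tuple[LineageTree, Dict[Node, int], Dict[Node, Node]]:
    """Contract every edge whose endpoints share both state and origin.

    Removes zero-cost self-edges (state unchanged within one original node),
    leaving the objective unchanged.  When ``sigma`` is ``None`` all
    equal-state edges between internal nodes are considered same-origin.
    Returns the normalized tree, labeling and origin map.
    """
    if sigma is None:
        sigma = {v: v for v in Tprime.nodes()}
    tree = Tprime
    beta = dict(beta)
    sigma = dict(sigma)
    while True:
        target = None
        for u, v in tree.graph.edges:
            if beta[u] == beta[v] and sigma[u] == sigma[v]:
                target = (u, v)
                break
        if target is None:
            break
        u, v = target
        if not tree.is_leaf(v):
            tree = contract_edges(tree, [(u, v)])
            beta.pop(v)
            sigma.pop(v)
        else:
            # merge the parent into the grandparent so the leaf survives
            if u == tree.root:
                raise ValueError("cannot contract root-leaf self-edge")
            gp = tree.parent(u)
            tree = contract_edges(tree, [(gp, u)])
            beta.pop(u)
            sigma.pop(u)
    new_tree = LineageTree(tree.graph, tree.root, alpha=tree.alpha, beta=beta)
    return new_tree, beta, sigma


# ---------------------------------------------------------------------------
# Set-Cover reduction (hardness-style correctness tests)
# ---------------------------------------------------------------------------

def setcover_reduction(
    U: Sequence[str],
    S: Sequence[Set[str]],
    eps: float,
) -> Tuple[LineageTree, Dict[Node, int], TransitionMatrix]:
    """Encode a Set Cover instance as an MPTR instance.

    States (1-based): 1 = TOP, then one per subset, then one per element,
    then BOTTOM; the optimum MPTR objective equals ``(|U| + k + 1) log eps``
    where ``k`` is the minimum cover size.
    """
    U = list(U)
    S = [set(s) for s in S]
    if set().union(*S) != set(U):
        raise ValueError("subsets do not cover the universe")
    nS, nU = len(S), len(U)
    r = nS + nU + 2
    if not 0 < eps <= 1.0 / (nS + nU + 1):
        raise ValueError(f"eps must be in (0, 1/{nS + nU + 1}]")
    # state map R: TOP = 1, subset S_i -> i+1, element u_q -> |S|+q+1 (1-based
    # indices), BOTTOM = r; python 0-based loop indices shift by one
    R_top = 1
    R_set = {i: i + 2 for i in range(nS)}
    R_elem = {q: nS + q + 2 for q in range(nU)}
    R_bot = r

    # tree: root v0 with children vbar0 and the TOP leaf; elements under vbar0
    top_leaf = f"v{nU + 1}"
    edges = [("v0", "vbar0"), ("v0", top_leaf)]
    b: Dict[Node, int] = {top_leaf: R_top}
    for q in range(nU):
        leaf = f"v{q + 1}"
        edges.append(("vbar0", leaf))
        b[leaf] = R_elem[q]
    tree = LineageTree.from_edges(edges, "v0")

    Pm = np.zeros((r, r))
    # row TOP
    Pm[R_top - 1, R_top - 1] = eps
    for i in range(nS):
        Pm[R_top - 1, R_set[i] - 1] = eps
    Pm[R_top - 1, R_bot - 1] = 1 - (1 + nS) * eps
    # rows R(S_i)
    for i in range(nS):
        s = R_set[i] - 1
        for j in range(nS):
            if i < j:
                Pm[s, R_set[j] - 1] = eps
        for q in range(nU):
            if U[q] in S[i]:
                Pm[s, R_elem[q] - 1] = eps
        Pm[s, R_bot - 1] = 1 - (nS - (i + 1) + len(S[i])) * eps
    # rows R(u_q)
    for q in range(nU):
        Pm[R_elem[q] - 1, R_bot - 1] = 1.0
    Pm[R_bot - 1, R_bot - 1] = 1.0
    return tree, b, TransitionMatrix(Pm)


def min_cover_size(U: Sequence[str], S: Sequence[Set[str]]) -> int:
    """Exhaustive minimum set-cover search (oracle for the reduction)."""
    from itertools import combinations

    Uset = set(U)
    for k in range(1, len(S) + 1):
        for combo in combinations(range(len(S)), k):
            if set().union(*(S[i] for i in combo)) == Uset:
                return k
    raise ValueError("subsets do not cover the universe")


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------

def solve_mptr(
    T: LineageTree,
    b: Dict[Node, int],
    P: TransitionMatrix,
    engine: str = "dp",
) -> MPTRSolution:
    """Solve an MPTR instance with the selected engine (``dp``, ``ilp`` or
    ``brute``); all engines return the same optimal objective."""
    if engine == "dp":
        return solve_mptr_dp(T, b, P)
    if engine == "ilp":
        return solve_mptr_ilp(T, b, P)
    if engine == "brute":
        return solve_mptr_bruteforce(T, b, P)
    raise ValueError(f"unknown MPTR engine {engine!r}")
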