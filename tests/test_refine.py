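"""Expansion graph, MPTR solvers, Sankoff labeling and the hardness gadget."""

import math

import numpy as np
import pytest

from tribal.model import (
    LineageTree,
    TransitionMatrix,
    csr_log_likelihood,
    is_refinement,
    shm_score,
    validate_transition_matrix,
)
from tribal.refine import (
    build_expansion_graph,
    contract_non_transitory,
    min_cover_size,
    sankoff_isotypes,
    setcover_reduction,
    solve_mptr_bruteforce,
    solve_mptr_dp,
    solve_mptr_ilp,
    unit_switch_costs,
)

from conftest import (
    assert_transitory,
    random_mptr_instance,
    random_multifurcating_tree,
    random_transition_matrix,
)


# ---------------------------------------------------------------------------
# Expansion graph structure
# ---------------------------------------------------------------------------

def test_expansion_graph_slices_match_definition():
    # root with leaf l3 (isotype 1) and internal vbar with leaves l1 (2), l2 (3)
    T = LineageTree.from_edges(
        [("v0", "l3"), ("v0", "vbar"), ("vbar", "l1"), ("vbar", "l2")], "v0"
    )
    G = build_expansion_graph(T, {"l1": 2, "l2": 3, "l3": 1}, r=3)
    assert G.slices == {
        "l1": [2], "l2": [3], "l3": [1],
        "vbar": [1, 2, 3], "v0": [1, 2, 3],
    }
    assert G.root == ("v0", 1)
    # within-slice edges exist iff s < t
    within = {(a, b) for a, b in G.edges if a[0] == b[0]}
    for u in ("v0", "vbar"):
        for s in (1, 2, 3):
            for t in (1, 2, 3):
                assert (((u, s), (u, t)) in within) == (s < t)


def test_expansion_graph_all_naive_is_isomorphic_to_tree():
    T = LineageTree.from_edges(
        [("r", "m"), ("m", "a"), ("m", "b"), ("r", "c")], "r"
    )
    G = build_expansion_graph(T, {"a": 1, "b": 1, "c": 1}, r=5)
    assert all(states == [1] for states in G.slices.values())
    assert G.n_nodes() == len(T.nodes())
    assert len(G.edges) == T.n_edges()


def test_expansion_graph_missing_isotype_raises():
    T = LineageTree.from_edges([("r", "a"), ("r", "b")], "r")
    with pytest.raises(ValueError, match="'b'"):
        build_expansion_graph(T, {"a": 1}, r=3)


# ---------------------------------------------------------------------------
# Solver agreement and solution invariants
# ---------------------------------------------------------------------------

def test_solvers_agree_and_solutions_are_valid(rng):
    """DP, ILP and exhaustive oracle agree; every solution is a transitory
    refinement whose recomputed likelihood equals the reported objective."""
    for _ in range(40):
        T, b, P = random_mptr_instance(rng)
        dp = solve_mptr_dp(T, b, P)
        bf = solve_mptr_bruteforce(T, b, P)
        ilp = solve_mptr_ilp(T, b, P)
        assert dp.objective == pytest.approx(bf.objective, abs=1e-6)
        assert ilp.objective == pytest.approx(bf.objective, abs=1e-6)
        for sol in (dp, bf, ilp):
            assert is_refinement(sol.tree, T) is not None
            assert_transitory(sol, T, b)
            assert csr_log_likelihood(sol.tree, P) == pytest.approx(sol.objective)


def test_mptr_trivial_instances(rng):
    P = random_transition_matrix(3, rng)
    single = LineageTree.from_edges([("r", "a")], "r")
    sol = solve_mptr_dp(single, {"a": 2}, P)
    assert sol.objective == pytest.approx(math.log(P.p(1, 2)))
    allone = LineageTree.from_edges([("r", "a"), ("r", "b"), ("r", "c")], "r")
    sol = solve_mptr_dp(allone, {"a": 1, "b": 1, "c": 1}, P)
    assert sol.objective == pytest.approx(3 * math.log(P.p(1, 1)))


def test_mptr_groups_same_isotype_leaves_under_sharp_matrix():
    """A root polytomy over isotypes [1,2,2,3] refines so that both
    isotype-2 leaves share one expanded node when staying is much more
    likely than switching."""
    T = LineageTree.from_edges(
        [("r", "a"), ("r", "b"), ("r", "c"), ("r", "d")], "r"
    )
    b = {"a": 1, "b": 2, "c": 2, "d": 3}
    M = np.array([
        [0.90, 0.05, 0.05],
        [0.00, 0.80, 0.20],
        [0.00, 0.00, 1.00],
    ])
    P = TransitionMatrix(M)
    sol = solve_mptr_dp(T, b, P)
    bf = solve_mptr_bruteforce(T, b, P)
    assert sol.objective == pytest.approx(bf.objective, abs=1e-9)
    parents = {v: sol.tree.parent(v) for v in ("b", "c")}
    assert parents["b"] == parents["c"] != "r"
    assert sol.tree.beta[parents["b"]] == 2


def test_mptr_refinement_objective_dominates_unrefined_labeling(rng):
    """Optimum over refinements >= best labeling of the unrefined tree."""
    for _ in range(25):
        T, b, P = random_mptr_instance(rng)
        refined = solve_mptr_dp(T, b, P).objective
        _, cost = sankoff_isotypes(T, b, -P.log_probs())
        assert refined >= -cost - 1e-9


def test_mptr_infeasible_raises():
    T = LineageTree.from_edges([("r", "a")], "r")
    P = TransitionMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]))  # cannot reach 2
    with pytest.raises((ValueError, RuntimeError), match="refinement|unreachable"):
        solve_mptr_dp(T, {"a": 2}, P)
    with pytest.raises((ValueError, RuntimeError)):
        solve_mptr_ilp(T, {"a": 2}, P)


def test_bruteforce_size_limit():
    T = random_multifurcating_tree(12, np.random.default_rng(0))
    b = {leaf: 7 for leaf in T.leaves()}
    P = random_transition_matrix(7, np.random.default_rng(1))
    with pytest.raises(ValueError, match="too large"):
        solve_mptr_bruteforce(T, b, P, limit=10)


# ---------------------------------------------------------------------------
# Proposition: refinements preserve the SHM score under copy-labeling
# ---------------------------------------------------------------------------

def test_refinement_preserves_shm_score_under_copy_labeling(rng):
    for _ in range(20):
        T, b, P = random_mptr_instance(rng)
        # random sequences on the original tree
        T.alpha = {
            v: "".join(rng.choice(list("ACGT"), size=12)) for v in T.nodes()
        }
        sol = solve_mptr_dp(T, b, P)
        sol.tree.alpha = {
            v: T.alpha[sol.sigma.sigma[v]] for v in sol.tree.nodes()
        }
        assert shm_score(sol.tree) == shm_score(T)


# ---------------------------------------------------------------------------
# Sankoff isotype labeling
# ---------------------------------------------------------------------------

def _exhaustive_sankoff(T, b, W):
    """Enumerate all labelings with fixed leaves and root state 1."""
    import itertools

    internal = [v for v in T.nodes() if not T.is_leaf(v) and v != T.root]
    r = W.shape[0]
    best = np.inf
    for combo in itertools.product(range(1, r + 1), repeat=len(internal)):
        beta = {T.root: 1, **dict(zip(internal, combo)), **b}
        cost = sum(W[beta[u] - 1, beta[v] - 1] for u, v in T.graph.edges)
        best = min(best, cost)
    return best


def test_sankoff_matches_exhaustive_enumeration(rng):
    for _ in range(15):
        T = random_multifurcating_tree(int(rng.integers(3, 6)), rng)
        r = int(rng.integers(2, 5))
        b = {leaf: int(rng.integers(1, r + 1)) for leaf in T.leaves()}
        P = random_transition_matrix(r, rng)
        W = -P.log_probs()
        beta, cost = sankoff_isotypes(T, b, W)
        assert cost == pytest.approx(_exhaustive_sankoff(T, b, W))
        recomputed = sum(W[beta[u] - 1, beta[v] - 1] for u, v in T.graph.edges)
        assert recomputed == pytest.approx(cost)


def test_sankoff_unit_costs_all_naive():
    T = LineageTree.from_edges([("r", "m"), ("m", "a"), ("m", "b"), ("r", "c")], "r")
    b = {"a": 1, "b": 1, "c": 1}
    beta, cost = sankoff_isotypes(T, b, unit_switch_costs(4))
    assert cost == 0 and set(beta.values()) == {1}


def test_sankoff_forced_switch_path():
    T = LineageTree.from_edges([("r", "m"), ("m", "a"), ("m", "b")], "r")
    b = {"a": 1, "b": 3}
    W = unit_switch_costs(3)
    beta, cost = sankoff_isotypes(T, b, W)
    # one switch 1 -> 3 somewhere below the root
    assert cost == 1 and beta["r"] == 1 and beta["m"] == 1


def test_sankoff_infeasible_raises():
    T = LineageTree.from_edges([("r", "a")], "r")
    W = np.full((2, 2), np.inf)
    with pytest.raises(ValueError, match="feasible"):
        sankoff_isotypes(T, {"a": 2}, W)


# ---------------------------------------------------------------------------
# Transitory normalization
# ---------------------------------------------------------------------------

def test_contract_non_transitory():
    # chain u -> u' with equal state and equal origin collapses
    T = LineageTree.from_edges([("r", "x"), ("x", "y"), ("y", "a"), ("y", "b")], "r")
    beta = {"r": 1, "x": 2, "y": 2, "a": 2, "b": 3}
    sigma = {"r": "r", "x": "v", "y": "v", "a": "a", "b": "b"}
    tree, beta2, _ = contract_non_transitory(T, beta, sigma)
    assert "y" not in tree.nodes() and set(tree.children("x")) == {"a", "b"}
    # objective unchanged: removed edges contribute log p_{s,s}
    P = TransitionMatrix(np.array([[0.6, 0.2, 0.2], [0, 0.7, 0.3], [0, 0, 1.0]]))
    before = sum(
        math.log(P.p(beta[u], beta[v])) for u, v in T.graph.edges
    )
    after = csr_log_likelihood(tree, P)
    assert before == pytest.approx(after + math.log(P.p(2, 2)))
    # already-transitory labelings are unchanged
    tree2, _, _ = contract_non_transitory(T, beta, {v: v for v in T.nodes()})
    assert set(tree2.edges()) == set(T.edges())


# ---------------------------------------------------------------------------
# Set-Cover reduction
# ---------------------------------------------------------------------------

def test_setcover_reduction_structure():
    U = ["u1", "u2", "u3"]
    S = [{"u1"}, {"u2", "u3"}, {"u1", "u3"}]
    tree, b, P = setcover_reduction(U, S, eps=0.05)
    assert len(tree.nodes()) == len(U) + 3
    assert tree.n_edges() == len(U) + 2
    assert validate_transition_matrix(P) == []
    assert P.probs.sum(axis=1) == pytest.approx(np.ones(P.r))


def test_setcover_reduction_example_objective():
    U = ["u1", "u2"]
    S = [{"u1"}, {"u1", "u2"}]
    tree, b, P = setcover_reduction(U, S, eps=0.1)
    k = min_cover_size(U, S)
    assert k == 1
    sol = solve_mptr_dp(tree, b, P)
    assert sol.objective == pytest.approx((len(U) + k + 1) * math.log(0.1))


def test_setcover_reduction_eps_range():
    with pytest.raises(ValueError, match="eps"):
        setcover_reduction(["u1"], [{"u1"}], eps=0.9)
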