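import numpy as np
import pytest

from tribal.model import LineageTree, TransitionMatrix, contract_edges


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_transition_matrix(r, rng, low=0.05):
    """Random valid upper-triangular row-stochastic matrix with positive
    admissible entries."""
    M = np.triu(rng.uniform(low, 1.0, size=(r, r)))
    return TransitionMatrix(M / M.sum(axis=1, keepdims=True))


def random_binary_tree(n_leaves, rng, prefix="L"):
    """Uniform-attachment random bifurcating topology (root has one child)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_edge("root", f"{prefix}0")
    for i in range(1, n_leaves):
        edges = list(g.edges)
        u, v = edges[rng.integers(len(edges))]
        w = f"i{i}"
        g.remove_edge(u, v)
        g.add_edge(u, w)
        g.add_edge(w, v)
        g.add_edge(w, f"{prefix}{i}")
    return LineageTree(g, "root")


def random_multifurcating_tree(n_leaves, rng, contract_prob=0.4):
    T = random_binary_tree(n_leaves, rng)
    internal = [(u, v) for u, v in T.graph.edges if not T.is_leaf(v)]
    chosen = [e for e in internal if rng.random() < contract_prob]
    return contract_edges(T, chosen) if chosen else T


def random_mptr_instance(rng, max_leaves=6, max_r=4):
    """Small random (tree, leaf isotypes, P) instance for solver cross-checks."""
    n = int(rng.integers(3, max_leaves + 1))
    r = int(rng.integers(2, max_r + 1))
    T = random_multifurcating_tree(n, rng)
    b = {leaf: int(rng.integers(1, r + 1)) for leaf in T.leaves()}
    P = random_transition_matrix(r, rng)
    return T, b, P


def assert_transitory(sol, T, b):
    """Definition check of a transitory labeling for an MPTR solution."""
    tree, beta, sigma = sol.tree, sol.tree.beta, sol.sigma.sigma
    assert beta[tree.root] == 1
    for leaf in tree.leaves():
        assert beta[leaf] == b[leaf], f"leaf {leaf} changed isotype"
        assert sigma[leaf] == leaf
    for u, v in tree.graph.edges:
        assert beta[u] <= beta[v], "labeling violates irreversibility"
        if beta[u] == beta[v]:
            assert sigma[u] != sigma[v], "non-transitory self-edge"
    # every refined node maps onto an original node
    assert set(sigma.values()) <= set(T.nodes())
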