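# Methods

## Model

A clonotype is a set of B cells descending from one naive B cell. Its history
is a rooted lineage tree `T` whose root is the naive cell; each node `v`
carries a concatenated heavy+light variable-region DNA sequence `α(v)` and an
isotype `β(v) ∈ {1..r}` (`r = 8` human, `r = 7` mouse, ordered along the
heavy-chain constant locus; ordinal 1 is IgM/IgD). Two processes act on the
edges:

* **Somatic hypermutation (SHM)** is scored by unweighted parsimony,
  `SHM(T, α) = Σ_(u,v)∈E D(α(u), α(v))` with `D` the Hamming distance.
  Sequences are short and mutation counts low, so unit-cost parsimony is an
  adequate sequence model. Gaps (`-`) and `N` are treated as ordinary fifth
  and sixth characters, and comparison is case-insensitive: any character
  mismatch costs 1. This is the simplest reproducible rule and matches
  unit-cost parsimony semantics; no installed convention for parsimony with
  ambiguity codes is assumed.
* **Class switch recombination (CSR)** is an irreversible Markov chain on
  isotypes: an `r × r` row-stochastic matrix `P` with `p_st = 0` for `s > t`
  shared by all clonotypes of an experiment, giving the likelihood
  `CSR(T, β, P) = Π_(u,v)∈E p_β(u),β(v)`. Log-likelihoods use natural logs;
  an impossible labeling yields an explicit `-inf` sentinel, never a floating
  exception.

The joint problem is lexicographic: first minimize total SHM parsimony, then
maximize the product of CSR likelihoods. Because any *refinement* of a tree
(splitting nodes and redistributing children — the inverse of contracting
edges) can copy the split node's sequence onto its copies without changing
the SHM score, the lexicographic optimum is a refinement of some tree in each
clonotype's maximum-parsimony forest. Inference therefore takes candidate
forests as given and only refines them.

## Most parsimonious tree refinement (MPTR)

For one candidate tree `T` with leaf isotypes `b` and fixed `P`, the optimal
refinement plus isotype labeling is found on the **expansion graph**: nodes
are pairs `(u, s)` with `s` ranging from 1 to the maximum leaf isotype below
`u` (leaves keep their observed state); edges are all copies
`((u,s),(v,t))` of tree edges with `s ≤ t` plus within-slice edges
`((u,s),(u,t))` with `s < t` representing expand operations. Valid subtrees —
rooted at `(v₀, 1)` and using exactly one copy of every original tree edge —
correspond one-to-one to refinements with *transitory* labelings (every edge
either changes state or joins copies of distinct original nodes), and the
maximum-weight valid subtree under edge weights `log p_st` solves MPTR.

Three solvers are provided and cross-checked:

* **ILP** (`solve_mptr_ilp`): the multi-commodity-flow formulation — one unit
  of flow from the root copy to every leaf, binary edge indicators, flow only
  on selected edges, exactly one copy per original edge — solved with HiGHS
  via `scipy.optimize.milp`. Edges with `p = 0` are omitted rather than given
  infinite cost, keeping the program well-posed; during coordinate ascent the
  pseudocount MLE keeps all admissible entries positive, so omission only
  matters for user-supplied matrices.
* **Dynamic program** (`solve_mptr_dp`): in a valid subtree the copies used
  within one slice form an arborescence rooted at the slice's unique entry
  copy, with strictly increasing states. Conditioning on the entry state, the
  optimum decomposes over (i) the subset of extra states used in the slice
  (enumerated as bitmasks, at most `2^(r-1)`), (ii) a best lower parent per
  extra state, and (iii) an independent best attachment state per child
  subtree. This is exact, exponential only in `r` (the problem is NP-hard via
  Set Cover when `r` grows with the input) and orders of magnitude faster
  than the ILP at `r ≤ 8`; it is the default engine inside the fit loop. A
  numba JIT accelerates the kernel when available; the pure-Python path is
  identical.
* **Brute force** (`solve_mptr_bruteforce`): exhaustive enumeration of valid
  subtrees (every state subset, every parent function, every child
  attachment), used as the independent oracle on small instances.

Ties are broken deterministically (smallest expansion, lowest states); the
objective value is unique even when the optimal tree is not. After solving,
any zero-cost same-state/same-origin edges are contracted
(`contract_non_transitory`), which provably leaves the objective unchanged.
The Set Cover gadget (`setcover_reduction`) builds the hardness instance —
`r = |S| + |U| + 2` states, transition probabilities parameterized by
`ε ≤ 1/(|S|+|U|+1)` — whose MPTR optimum is `(|U|+k+1)·log ε` with `k` the
minimum cover size; it is used purely as a correctness harness.

## Coordinate ascent

Clonotypes are conditionally independent given `P`, so the fit alternates:

1. **Refine.** For every clonotype, sample up to 50 candidate trees
   (uniformly, without replacement, always re-including the previous winner
   so the per-clonotype objective cannot regress) and solve MPTR for each
   under the current `P`; keep all candidates tying the best objective within
   1e-9. In the no-refinement variant (`tribal-nr`) the candidates are
   instead labeled by weighted Sankoff small parsimony with costs `−log p`.
   Clonotypes whose cells are all IgM/IgD skip the solver: every labeling is
   all-ones and the objective is `|E|·log p₁₁` (a pure optimization with an
   identical result).
2. **Update.** `P` is re-estimated from the winning labeled trees by maximum
   likelihood with a pseudocount of 1 on every admissible (upper-triangular)
   cell: `p*_st = (N_st + 1) / Σ_{t'≥s} (N_st' + 1)`. The pseudocount keeps
   unobserved transitions possible in later iterations. When several
   solutions tie, the canonically first one feeds the counts.

Iteration stops when the absolute change of the summed log-likelihood falls
below 0.5 (a threshold on the log scale — the product form of the joint
likelihood makes 0.5 dimensionally sensible there) or after 10 iterations.
Restarts run over initial stay probabilities
`θ ∈ {0.55, 0.65, 0.75, 0.85, 0.95}`, where the initial matrix has `θ` on the
diagonal (1 for the last state) and the remaining mass uniform over higher
states; the restart with the highest final objective wins, ties going to the
smaller `θ`. The reported matrix is the one the final refinement was
performed under. Because the pseudocount regularizes the update, monotonicity
of the objective trace is not a theorem; with a few hundred labeled edges the
regularization is negligible and the trace is non-decreasing in practice (the
suite asserts this at the simulated sizes used).

Candidate trees without internal sequences are labeled by per-column
unit-cost Sankoff over `{A,C,G,T,-,N}` with the root fixed to the germline
(`ancestral_sequences`); ties break alphabetically, making outputs
deterministic. Refined trees copy the originating node's sequence onto
expanded copies, preserving the SHM score exactly.

## Synthetic data

The generator emulates the study conditions at desk scale; it is a
lightweight stand-in, not a germinal-center simulator.

* **Ground-truth matrices** (`simulate_transition_matrix`): draw a switching
  probability `1−θ ∈ {0.10, 0.15, …, 0.35}`; build a template in which a cell
  *stays* with probability `θ` and otherwise switches — under the **direct**
  model uniformly over all downstream isotypes, under the **sequential**
  model to the next isotype (all longer jumps at the floor); add Gaussian
  noise `N(0.05, 0.025)` per entry, floor every admissible entry at
  `τ = 0.01` (the floor prevents negative entries and keeps the support
  full), and normalize each row over `t ≥ s`. The last row is the point mass
  on itself.
* **Lineages** (`simulate_lineage_tree`): topologies grow by uniform
  attachment (each new cell splits a uniformly random existing edge),
  giving a bifurcating tree whose root (the naive cell) has one child; the
  root sequence is uniform random DNA of length 150 and every edge
  substitutes each site independently with probability 0.0025 to a uniformly
  random different base. There are no indels (the alignment is trivial), no
  affinity selection, no codon structure and no carrying-capacity dynamics —
  so passing benchmarks demonstrate correct behavior of the inference under
  the stated model, not performance on real repertoires.
* **Isotypes** (`evolve_isotypes`): the root is naive; each child's state is
  drawn from its parent's row of the ground-truth matrix.
* **Candidate forests** (`make_candidate_forest`): each of (by default) 4
  distinct candidates is a contraction of the truth tree in which *all*
  internal edges without substitution support are collapsed — an edge whose
  endpoint sequences are identical cannot be resolved by any parsimony
  method, and keeping it would leak truth topology the real pipeline could
  never recover — plus a random 20% of the supported internal edges,
  emulating residual parsimony ambiguity. Candidates are relabeled with
  minimum-SHM ancestral sequences. By construction the truth is a refinement
  of every candidate. Because candidates are contractions of the truth
  rather than genuinely wrong topologies from a parsimony search, the
  no-refinement baseline is stronger here than on real parsimony forests;
  comparisons against full-scale published magnitudes are scaled-down.

## Metrics

All logs natural. KL divergence is computed per starting state as
`D(p̂_s ‖ p_s)` with the *inferred* row first (the convention printed with
the metric's definition), erroring on support violations; the last row is
trivially zero. Normalized Robinson–Foulds treats both trees as unrooted and
divides the symmetric difference of non-trivial bipartitions by the total
bipartition count (star vs anything resolved gives 1; two stars give 0). MRCA
distance averages, over unordered leaf pairs, the Hamming distance between
the pair's MRCA sequences in truth vs inference, normalized by
`n(n−1)m/2`. CSR error is, per cell, the absolute difference in the number of
state changes on the root-to-cell path between the truth and the inferred
labeled tree; with several co-optimal solutions the per-cell mean across
solutions is pooled before quartiles. Average isotype clade entropy is the
mean leaf-label entropy over internal nodes other than the root and returns
an explicit "undefined" (`None`) for star trees rather than 0.

## Benchmark protocol

`tribal.benchmark.run_benchmark` simulates 5 replicates per CSR model with
k = 75 clonotypes of n = 35 cells each (one ground-truth matrix per
replicate), fits with and without refinement, and pools per-row KL values
(7 states × 5 replicates) and per-cell CSR errors (75 × 35 × 5 per model).
These problem sizes are the package's benchmark conditions; the whole run
takes a few minutes on one CPU. `scripts/acceptance.py --seed N --out F`
recomputes everything from scratch and writes the five summary statistics.

## Numerical choices and edge cases

* Objective tie tolerance across candidate trees: 1e-9 (co-optimal set).
* Row-stochasticity tolerance: 1e-9; written matrices absorb the 6-decimal
  rounding residual into each row's largest entry so files re-parse to rows
  summing to 1.
* The written transition matrix, trees (canonical child order: lexicographic
  by smallest descendant leaf id) and logs are byte-stable for a fixed seed.
* `is_refinement` certifies refinements via cluster multisets (nodes sharing
  a cluster form unary chains, which are aligned top-down) and verifies the
  quotient tree explicitly; it returns the contraction map σ.
* Sankoff labelings break ties toward the lowest state; the sequence solver
  toward the alphabetically first character.
* The degenerate unit-cost isotype weight matrix is 0 on the diagonal, 1 for
  upward switches and forbidden downward; a `literal` flag exposes the
  swapped variant for comparison.

## Known limitations

* One shared transition matrix per experiment; no per-clonotype matrices.
* No codon-model sequence likelihoods, no branch lengths in time units, no
  indel-aware SHM, no clonotyping/V(D)J preprocessing (inputs are the
  outputs of such pipelines).
* The ILP returns one optimal refinement per candidate tree; co-optimality
  is tracked across candidates, not within a single tree's solution pool.
* The stand-in simulator understates the difficulty of real parsimony
  forests (see above), so absolute error levels on real data will be higher
  than the benchmark's.
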