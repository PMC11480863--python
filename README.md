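# tribal-lineage

Isotype-aware inference of B cell clonal lineage trees from single-cell
BCR sequencing data.

During an adaptive immune response B cells evolve by two coupled processes:
**somatic hypermutation (SHM)** introduces point mutations into the BCR
variable region, and **class switch recombination (CSR)** irreversibly
switches the expressed antibody class (isotype) — IgM/IgD first, then the
downstream classes in genomic order. Reconstructing a clonotype's lineage
tree from sequences alone is badly underdetermined: maximum-parsimony methods
return many tied trees, riddled with polytomies. This package resolves that
uncertainty with the isotype calls that single-cell experiments provide
anyway, for immunologists and computational biologists studying affinity
maturation, vaccine responses and antibody discovery.

## Model

For each clonotype `j` with aligned sequences `A_j` (germline root plus one
row per cell) and observed isotypes `b_j ∈ {1..r}`, a lineage tree `T_j`
labels every node `v` with a sequence `α(v)` and isotype `β(v)`, subject to
`β(u) ≤ β(v)` along every edge (CSR is irreversible). The objectives are
lexicographic:

1. minimize `Σ_j SHM(T_j, α_j)`, with `SHM(T, α) = Σ_(u,v)∈E D(α(u), α(v))`
   (Hamming distance, unit-cost parsimony), then
2. maximize `Π_j CSR(T_j, β_j, P)`, with
   `CSR(T, β, P) = Π_(u,v)∈E p_β(u),β(v)` under an upper-triangular
   row-stochastic isotype transition matrix `P` shared by all clonotypes.

Stage 1 is delegated to existing maximum-parsimony tools, which provide a
candidate forest per clonotype. Stage 2 is this package: any tree in the
forest may be *refined* (polytomies split) without changing its parsimony
score, so the method solves the **most parsimonious tree refinement (MPTR)**
problem — find the refinement and transitory isotype labeling maximizing
`log CSR` — for every candidate, inside a coordinate-ascent loop that
alternates refinement with maximum-likelihood re-estimation of `P`
(pseudocount 1 on admissible cells), over restarts of the initial stay
probability `θ ∈ {0.55, …, 0.95}`.

MPTR is NP-hard (by reduction from Set Cover) and is solved exactly on the
*expansion graph* over (node, isotype) pairs, either by the
multi-commodity-flow integer linear program (HiGHS via
`scipy.optimize.milp`) or by an equivalent dynamic program that is
exponential only in the number of isotypes (the default engine; both are
cross-checked against an exhaustive oracle in the test suite). A
no-refinement variant (`tribal-nr`) labels the unrefined candidates by
weighted Sankoff parsimony with costs `−log p` instead.

See `docs/methods.md` for the full model, numerical choices and limitations.

## Worked example

Simulate a small cohort (5 clonotypes × 10 cells, sequential class-switch
model), fit, and evaluate against the ground truth:

```sh
tribal simulate --model sequential --clonotypes 5 --cells 10 --seed 11 --out demo/sim
tribal fit --alignments demo/sim/replicate1/alignments \
           --isotypes   demo/sim/replicate1/isotypes.tsv \
           --forests    demo/sim/replicate1/forests \
           --encoding   demo/sim/replicate1/encoding.txt \
           --seed 1 --out demo/fit
tribal evaluate --truth demo/sim/replicate1 --inferred demo/fit --out demo/report.tsv
```

The fit prints one objective trace (summed CSR log-likelihood) per restart —
non-decreasing within each restart — and the winning restart:

```
theta*=0.55 objective=-50.8884
  restart theta=0.55: -64.54 -> -52.76 -> -50.89 -> -50.89
  restart theta=0.65: -60.71 -> -52.76 -> -50.89 -> -50.89
  ...
```

`demo/fit/` then contains `transitions.tsv` (the inferred matrix `P`, rows =
parent isotype; the first row below says an IgM/IgD cell keeps its class with
probability 0.52 and switches to IgG3 with probability 0.20):

```
        IgM/IgD  IgG3      IgG1      IgG2b  ...
IgM/IgD 0.520000 0.200000  0.040000  0.120000 ...
IgG3    0.000000 0.636362  0.181818  0.045455 ...
```

plus one newick tree and node table (isotype and ancestral sequence per
node) per clonotype, and `fit_log.jsonl` with the iteration traces. The
evaluation reports per-clonotype and median metrics; on this example:

```
"normalized_rf": 0.6, "csr_error_mean": 0.0, "mrca_distance": 0.0,
"kl_median": 0.2099...
```

i.e. the inferred trees make no class-switch-count errors on any cell and
recover all ancestral sequences, while topology (RF) stays partly
unresolved — expected for 10-cell clonotypes — and the transition matrix is
estimated to a median per-row KL divergence of 0.21 nats from just 5
clonotypes (it tightens quickly with more; see the benchmark).

The same pipeline is available as a library: `tribal.simulate_experiment`,
`tribal.fit`, `tribal.solve_mptr`, `tribal.kl_divergence_rows`, etc.

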