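# Methods

## Model

The method treats disease-gene discovery as a proximity query on a weighted
undirected PPI network G. Edge weights are integer interaction confidences
on the STRING scale (150–999); the walker's transition probability from
node j to neighbor i is w(j, i) divided by the weighted degree of j, so the
transition operator W is column-stochastic and the iteration

p_{i+1} = (1 − r) · W · p_i + r · p_0

conserves probability mass at every step. Because r ∈ (0, 1] and W is a
nonnegative column-stochastic matrix, the map is an L1 contraction with
factor (1 − r): the fixed point p = (1 − r) W p + r p_0 is unique and the
power iteration converges geometrically (for r = 0.8 and tolerance 1e−6,
at most ~10 iterations). Components of the fixed point measure how much
restart mass diffuses from the seeds to each gene.

An alternative formulation that applies the transpose of a column-normalized
adjacency matrix does not conserve mass on weighted graphs with asymmetric
degrees; this package deliberately implements the mass-conserving
column-stochastic propagation standard in the network-propagation
literature. Components disconnected from every seed receive probability 0 —
the model has no uniform teleportation term.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| restart probability r | 0.8 | — | strong restart keeps the ranking local to the seed neighborhood |
| convergence tolerance | 1e−6 | L1 mass | stopping rule on successive iterates |
| max iterations | 1000 | — | safety valve; never binding at r = 0.8 |
| score threshold | 1e−5 | probability | selects "RWR genes" (strictly larger than) |
| n permutations | 1000 | — | FDR resolution 0.001 |
| FDR threshold | 0.05 | — | conventional significance cutoff (strictly smaller than) |
| MIS threshold | 900 | STRING score | STRING "highest confidence" band (≥) |
| MFS threshold | 0.9 | cosine | strong functional agreement (see boundary note) |
| min edge score | 150 | STRING score | keep the full STRING range by default |
| background N | "auto" | genes | hypergeometric universe; auto = union of annotated genes |

Seeds are excluded from all outputs by default: they are validated disease
genes, not discoveries (a diagnostic flag restores them). Random seed sets
for the permutation test are drawn uniformly from **all** network nodes and
may overlap the real seeds; exceedance uses a strict ">" so ties never
count against a gene. Every null run reuses the real run's walk parameters.

## Numerical choices

* The hypergeometric upper tail Σ_{k=m}^{min(n,M)} C(M,k)C(N−M,n−k)/C(N,n)
  is evaluated in log space with exact log-binomials (gammaln) combined by
  logsumexp, so it remains accurate for genome-scale N ≈ 20,000 where the
  direct sum underflows. Tail probabilities are floored at 1e−300, capping
  enrichment scores at 300. Zero overlap (m = 0) is defined as score 0.
* Empty-max conventions: MIS = 0 for a gene with no seed edge; cosine
  similarity = 0 when either enrichment vector is all-zero. Both make the
  filters conservative.
* MFS boundary: the selection rule is "larger than 0.9", but values are
  reported to three decimals, so the comparison is performed at 3-decimal
  precision — a stored 0.900 passes. This keeps reported tables and the
  stated rule mutually consistent.
* Ranking ties are broken lexicographically by gene identifier; the final
  report is sorted by descending MFS. Together with a single user-supplied
  RNG seed driving all permutations, two identical runs produce
  byte-identical reports (the run manifest records the resolved config and
  input checksums, and deliberately contains no timestamps).
* GO terms and KEGG pathways are concatenated into one enrichment vector
  (one GMT catalog); per-term p-values are raw tails, with no
  multiple-testing correction and no ontology-hierarchy propagation — the
  vector is a functional fingerprint, not an inference.

## Synthetic benchmark

Real inputs are genome-scale downloads, so testing uses a generated
benchmark with known truth: an Erdős–Rényi background (600 nodes, edge
probability 0.02, scores 150–700) containing a planted 30-gene module
(edge probability 0.6, scores 800–999), 10 module members as seeds and the
other 20 held out; 40 annotation terms of 10–30 genes, half of them
"disease" terms drawing 50% of their members from the module, the rest
uniform. The module is forced internally connected (a spanning chain is
added across any random split) so walk mass can reach every held-out
member; isolated nodes are dropped. The number of enriched terms and the
term-size range are the generator's own choices — they give enriched and
background genes clearly distinct functional fingerprints at a size where
exact enumeration oracles are still feasible.

What the benchmark does **not** emulate: STRING's heavy-tailed degree
distribution, its evidence channels, correlated annotations from the GO
hierarchy, or genome-scale N. Passing tests therefore demonstrate
correctness of the algorithmics and strong recovery under the planted-module
idealization, not expected performance on real interactomes. Analyses are
run at desk scale (600 nodes, 100 permutations in tests) — chosen so exact
oracles (dense linear solves, exhaustive hypergeometric enumeration,
brute-force exceedance recounts) can verify every stage.

## Known limitations

* The permutation null permutes seed labels only; degree-preserving edge
  rewiring is out of scope, so topology-driven biases shared by all seed
  sets are not controlled.
* Identifier spaces are opaque: no Ensembl↔symbol resolution is attempted,
  and mismatched identifier conventions across the three inputs surface as
  a consistency error, not an automatic mapping.
* With very small permutation counts the FDR resolution (1/n) is coarse;
  FDRs below resolution are reported as a "<1/n" bound rather than 0.
* Alternative normalizations (symmetric Laplacian), multi-network walks and
  approximate push-based solvers are out of scope.
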