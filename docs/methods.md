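# Methods

## Model

The walk operates on the undirected bipartite graph of miRNAs and target
genes. The transition matrix is built from the symmetric, unweighted
adjacency A of that graph, column-normalized by degree:
W′[i, j] = A[i, j] / deg(v_j), so W′ is column-stochastic and the update
p_{t+1} = (1 − γ) W′ p_t + γ p_0 conserves probability mass at every step.
Row- rather than column-normalization is an equally defensible convention
for RWR; we use column normalization so that mass conservation holds
exactly, which in turn gives the geometric convergence guarantee below.
On degree-heterogeneous networks the two conventions produce different
rankings; the package commits to one and documents it here.

Two seed distributions are supported. Heterogeneous seeding places
α/|S_m| on each known disease miRNA and (1 − α)/|S_g| on each gene targeted
by at least one of them; miRNA-only seeding is the α → 1 limit (uniform on
S_m), used both by the similarity-network baseline and as an internal
diagnostic (`loocv(..., method="mirna_only")`).

### Convergence

The norm in the stopping rule is L1 with threshold 10⁻⁶. Because W′ is
column-stochastic, consecutive residuals contract at least geometrically:
‖p_{t+1} − p_t‖₁ ≤ (1 − γ)‖p_t − p_{t−1}‖₁, so the iteration count is
bounded by ⌈log(tol/2)/log(1 − γ)⌉ (≈ 131 steps at γ = 0.1, tol = 10⁻⁶);
the default cap of 1000 iterations is never the binding constraint for
γ ≥ 0.1. γ = 1 is permitted as the degenerate case where the stationary
vector is the seed vector itself. A converged vector differs from the true
stationary distribution by at most tol·(1 − γ)/γ in L1; tests that need
exact stationarity use tol = 10⁻¹², and the closed-form solve
γ(I − (1 − γ)W′)⁻¹p_0 (dense, capped at 2000 nodes) serves as the
independent oracle.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| γ | restart probability per step | 0.5 | swept over 0.1–0.9 (step 0.1) |
| α | seed mass on miRNAs vs their targets | 0.5 | swept over {0.1, 0.3, 0.5, 0.7, 0.9}; (0, 1) open |
| tol | L1 convergence threshold | 10⁻⁶ | |
| max_iter | iteration cap | 1000 | safety net only |

Both grids and both defaults follow the published parameter study for this
method family; α weighting toward miRNAs reflects that known disease
miRNAs carry more disease information than their (noisier) predicted
targets.

## Baseline

The homogeneous baseline projects the bipartite graph onto miRNA–miRNA
similarities: weight(i, j) = |targets(i) ∩ targets(j)| (default), or the
Jaccard index of the target sets. The same restart walk runs on the
column-normalized weighted adjacency with miRNA-only seeding. miRNAs that
share no target with any other miRNA are isolated there; they are kept in
the ranking with score exactly 0 (ranked last, ties by id) so both methods
rank the same candidate pool. The original baseline's normalization of the
similarity matrix is not fully specified in the literature; column
normalization is used for consistency with the main method.

## Evaluation

LOOCV holds out each known disease miRNA in turn; seeds are the remaining
known miRNAs and the candidate set is every network miRNA except those
seeds (the held-out miRNA included). The AUC estimator is the mean per-fold
rank percentile,

    percentile = (#strictly below + 0.5 · #tied) / (n_candidates − 1),

which equals the probability that the held-out miRNA outscores a uniformly
chosen non-seed miRNA, with half credit for ties — a perfect ranker scores
exactly 1 and a constant scorer exactly 0.5. The pooled ROC curve
(`roc_points`) thresholds on rank k: TPR(k) is the fraction of folds ranked
within the top k and FPR(k) pools the remaining selections against the mean
candidate count; its trapezoidal area matches the mean percentile to within
1/min(n_candidates) (the discretization of one rank step). A test
cross-checks the estimator against scikit-learn's pairwise AUC on the same
fold scores. The held-out miRNA competes against *all* non-seed miRNAs, not
a sampled control set. The transition matrix is built once per network and
reused across folds — seeding changes, topology does not — which is purely
an optimization with bit-identical results.

## Synthetic benchmark

The generator plants a disease module in an otherwise random bipartite
graph: `n_module_mirna` = 12 of 60 miRNAs and `n_module_gene` = 40 of 200
genes; module miRNA × module gene pairs carry an edge with p_in = 0.35, all
other pairs with p_bg = 0.02, and 8 module miRNAs are reported as known for
the synthetic disease `SYN1`. Any node left with degree 0 receives one
uniformly chosen edge (module-respecting for module nodes), so every node
is normalizable. Edges are independent Bernoulli draws — the simplest
mechanism exhibiting the modular structure the walk exploits; no degree
correction is attempted at this scale. These sizes keep a full LOOCV at
~20 ms, so medians over 10 generator seeds and the full 45-cell sweep run
in seconds.

What the generator does *not* emulate: the heavy-tailed target-count
distributions of real miRNA-target databases, correlated (non-independent)
edges, multiple diseases sharing miRNAs, and annotation noise in the known
associations. Passing the planted-module checks therefore shows that the
implementation recovers modular disease signal under the model's own
assumption (disease miRNAs cluster around shared targets), not that it
reproduces performance figures on any specific public dataset — those
depend on external downloads and are out of scope here. On this benchmark
the shared-target baseline is nearly as strong as the heterogeneous walk,
because a Bernoulli module produces many shared targets; the advantage of
walking on the bipartite graph is expected to grow with target sparsity
and degree heterogeneity, which the generator deliberately does not model.

## Interfaces and I/O

Edge lists and association tables are TSV or CSV, auto-detected from the
first line; an optional header row is recognized by common column-name
tokens, and a first row whose miRNA column matches the standard miRBase
naming pattern is always treated as data. Identifier matching is
case-insensitive after trimming, since capitalisation conventions differ
across public databases; disease ids are opaque strings (OMIM-style ids are
typical but not validated). Rankings, LOOCV reports and sweep grids are
written as TSV with run metadata in `#` comment lines; result graphs are
exported as GraphML or SIF-plus-node-attributes with `node_class`,
`rank`/`score` and `edge_class` attributes replacing visual styling (known
vs candidate disease associations are distinguished by `edge_class`, the
analogue of solid vs dashed edges).

PubMed evidence is strict co-occurrence — one esearch query
`("<mirna>"[All Fields]) AND ("<disease>"[All Fields])` per miRNA — with
the fetcher injectable so the test suite runs fully offline; the live
NCBI E-utilities client (stdlib urllib) rate-limits itself and is never
exercised by tests. The REST facade implements the four automation
endpoints (`diseaseList`, `diseaseList/{name}`, `rank`, `getRank/{limit}`)
over the standard-library HTTP server behind a plain `RankingService`
class, stateful in the POST-then-GET style with a single most-recent
ranking slot; the CLI and the facade share one ranking code path, so their
outputs are byte-identical.

## Numerical and design notes

- Ties in stationary score are broken lexicographically by
  (case-normalized) miRNA id, making rankings fully deterministic.
- Candidate lists that overlap the seed set are accepted; overlapping
  entries are excluded with a warning and counted in the result. A
  candidate list with no network member is an error.
- Seeds with no target gene cannot use heterogeneous seeding (S_g = ∅);
  the error message points to miRNA-only seeding. This cannot happen for
  networks defined by edge lists, where every miRNA has ≥ 1 target.
- Nodes exist only via edges: isolated nodes are unrepresentable in the
  bipartite network type, which guarantees a normalizable transition
  matrix. The similarity projection is the one place isolation can appear,
  handled as described above.
- `stationary_direct` is intended for testing and small networks only; the
  production path is the sparse power iteration.

## Known limitations

- Single-network ranking only: no multi-network integration, no directed
  or weighted miRNA→gene edges, no teleport-vector variants beyond the two
  seeding schemes.
- The evidence search counts co-occurrence, not curated relations; a hit
  means both terms appear in a PubMed record, nothing more.
- LOOCV ranks held-out miRNAs against all non-seed miRNAs, including those
  associated with other diseases; with dense association tables this is a
  conservative choice.
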