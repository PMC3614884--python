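# Methods

## Model and objective

A genetic-interaction screen is modeled as a signed weighted graph: genes
are vertices, the epistasis score of an assayed pair is the edge weight,
and unassayed pairs have weight zero. A between-pathway module (BPM) is a
pair of disjoint gene sets whose between-set weights are predominantly
negative (aggravating — each pathway backs the other up) and whose
within-set weights are positive (alleviating). Writing side labels as
spins x ∈ {±1}ⁿ, a candidate pathway pair is a bipartition making

    Φ(x) = Σ_cross w − Σ_within w = −½ xᵀWx

as negative as possible. Exact minimization is weighted max-cut and
NP-hard; the method instead samples many *local* optima. A bipartition is
stable (a local max-cut) when every vertex's imbalance
h(v) = x_v (Wx)_v — same-side minus other-side weight sum — is
non-negative: flipping v changes Φ by exactly 2·h(v), so stability means no
single-vertex move improves the cut. The test suite verifies this move
identity against brute force, and verifies that every search output lies in
the exhaustively enumerated stable set on small graphs.

## Search procedure and numerical choices

* **Restarts.** M independent uniform-random bipartitions, seeded
  `base_seed + i` for restart i; the ensemble is therefore fully determined
  by (base_seed, M) and invariant to the worker count used to parallelize
  the restarts (results are collected by restart index).
* **Sweep schedule.** Vertices are visited in a per-restart seeded random
  order, reshuffled each sweep; any vertex with h(v) < −ε flips
  immediately (asynchronous updates). A sweep with no flips terminates. The
  visit order and asynchronous policy are genuinely open choices — they
  select *which* local optimum a start reaches, not whether the output is
  stable — and randomizing the order avoids systematic bias from the
  lexicographic gene order.
* **Tolerance.** ε = 1e−9 (absolute). Stability is declared at
  h(v) ≥ −ε; a flip is only taken when it lowers Φ by more than 2ε, which
  guarantees termination with real-valued (possibly tied) weights. The
  sweep limit 10·n is a safety valve; exceeding it raises an error carrying
  the partial state rather than silently truncating.
* **Degenerate inputs.** Self-pairs are dropped (the graph has no loops);
  duplicate unordered pairs are merged by averaging (both orientations
  commonly appear in screen matrices) with a warning; blank/non-finite
  scores are dropped, not imputed. Genes appearing in no surviving record
  never enter the graph, so there are no zero-degree vertices.

## Module extraction and pruning

For each gene g, the fraction of the M stable cuts placing each gene u on
g's side is computed; module 1 collects genes with fraction ≥ C (including
g), module 2 genes with fraction ≤ 1 − C. "At least C of the time" is read
inclusively, and the opposite-side criterion is the exact complement since
each cut places u either with or against g. C must exceed 0.5, which makes
the two criteria mutually exclusive and the modules disjoint by
construction; membership is monotone non-increasing in C. A gene whose
opposing module is empty contributes no BPM.

Pruning runs size-first: modules outside [min_size, max_size] are removed
before overlap pruning, so an oversized (to-be-deleted) BPM cannot shadow a
valid one. Overlap pruning is a canonical greedy pass: candidates ranked by
descending total gene count (ties by the lexicographically smallest
generating gene, then module content), each kept iff its flattened-set
Jaccard index with every already-kept BPM is strictly below J. Largest-
first keeps the most informative representative of each redundant family
and makes the output independent of candidate order; identical module
pairs generated by different genes collapse to one (Jaccard 1).

Defaults M = 250, C = 0.9, J = 0.66, min_size = 3, max_size = 25. Smaller
M or C increases run-to-run variability of the randomized algorithm;
lowering C (e.g. to 0.8) is the intended lever for admitting more, noisier
BPMs. Tests and the acceptance script run at M = 15–100 on 20–60-gene
synthetic tables — ensemble concentration sets in well below M = 250 at
these sizes, and the stability, determinism and pruning guarantees being
checked are size-independent.

## Enrichment

Each module is tested against every annotation term restricted to the
*genespace* (background gene universe; by default the genes of the input
screen) with the one-sided hypergeometric tail P(X ≥ k) for k annotated
genes in a module of n from a genespace of N with K term genes. Multiple-
testing correction follows the resampling semantics of simulation-based
enrichment services: for each module size, draw random same-size genespace
subsets, record each draw's minimum raw p over all terms, and set

    p_corr = (1 + #{draws with min-p ≤ p_raw}) / (1 + n_draws) ,

a Westfall–Young-style family-wise correction that is valid (conservative)
by construction; the suite checks ≤ 8% of null modules reach corrected
p ≤ 0.05. The draw count defaults to min(10000, max(1000, number of
modules)) with two modules per BPM — the floor exists because small
simulation counts make the corrected p-values too variable. Corrected
p-values from this offline procedure are not numerically comparable to any
particular web service's output. No GO-graph propagation is performed:
annotations are taken as given, and the remote-service integration is
deliberately reduced to a request-shaping function with no network code.

## Synthetic data

The generator plants pathway-pair structure directly in score space: every
within-module pair of a planted (a, b) pair receives within_weight + noise
and every between-module pair between_weight + noise
(defaults +1/−1, noise sd 0.1); background genes receive zero-mean noise
edges among themselves with probability edge_density (default 0.15).
Defaults are one 5+5 pair and 40 background genes. Background noise edges
connect background genes only, so the planted pairs are the only
systematic structure; a background gene that draws no edge stays out of
the table. Recovery is scored side-aware — the mean of the two module-wise
Jaccard indices under the better of the two module alignments, maximized
over predictions — since BPM side labels are arbitrary.

What passing these tests shows, and what it does not: the generator
reproduces the *signature* the algorithm searches for (anti-correlated
blocks in a sparse noisy background), so recovery tests validate the
search, extraction and pruning machinery end-to-end. It does not emulate
E-MAP/SGA measurement-error structure, batch effects, missing-value
patterns, hub genes, or overlapping real pathways; performance on real
screens depends on those features and on parameter choice.

## Known limitations

* Local, not global, optima: only the M random restarts guard against bad
  basins; there is no annealing or guided restart.
* Which member of an overlapping BPM family survives pruning depends on
  the (documented) greedy rule; other rules would differ at the margins.
* Candidate extraction recomputes co-occurrence fractions per gene
  (O(M·n²) overall), fine for screen-sized inputs but the dominant cost on
  dense matrices.
* Exclusion lists are the only treatment of essential genes; no per-BPM
  significance score is computed beyond GO enrichment.
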