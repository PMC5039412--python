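# Methods

## Problem setting

Given (a) a binary drug × side-effect incidence table, (b) a weighted
symptom-based disease–disease similarity network, and (c) a curated
chemical–disease association table with marks
`M` (marker/mechanism), `T` (therapeutic), `M&T`, `inferred` or `none`,
the pipeline ranks drug–disease pairs by how strongly a pair is supported
by the curated associations of its neighbors inside dense network
modules. No gene annotation is used anywhere, which is the point: drugs
and diseases with few or no known genes remain scorable.

## Similarity networks

Each incidence `W_ij ∈ {0,1}` (side effect `i`, drug `j`) is reweighted
as `w_ij = W_ij · ln(N / n_i)`, with `N` the number of drugs and `n_i`
the number of drugs displaying side effect `i`. The logarithm base is
deliberately unspecified in this construction's usual presentation; any
base rescales all weights of a feature by the same constant, which
cancels in the cosine, so the choice cannot affect the network. We use
natural log and test the invariance explicitly. A feature present in
every entity gets weight 0 everywhere; an entity whose *every* feature is
ubiquitous has an all-zero vector, an undefined cosine, and is excluded
from the network with a warning (raising would abort real corpora over a
degenerate handful of rows).

Edges are kept when cosine ≥ cutoff; the comparison is inclusive, i.e.
edges *strictly below* the cutoff are discarded. Nodes left without an
edge drop out of the network — the substantial node shrinkage seen on
real pharmacovigilance corpora at cutoff 0.4 comes from this rule.
Defaults: 0.4 for the drug network, 0.5 for the (already weighted)
disease network.

## Module detection

We detect overlapping dense modules with a greedy cohesiveness clusterer
of the neighborhood-expansion family. The objective for a node set `S` is

    coh(S) = w_in(S) / (w_in(S) + w_bound(S) + α·|S|)

with `w_in` the internal edge weight, `w_bound` the weight crossing the
boundary, and size penalty `α = 2` modeling unobserved edges. Seeds are
visited in descending weighted-degree order (ties lexicographic),
skipping nodes already absorbed; from each seed the set greedily applies
the best single-node addition *or removal* until no move improves the
objective (the shrink step matters: growth can overshoot a dense core).
Candidate sets with pairwise overlap `|A∩B|²/(|A||B|) ≥ 0.8` are unioned
(connected components of the overlap graph); survivors below 3 nodes or
weighted density 0.5 are discarded. All four parameters are exposed.

Because the procedure's outcome depends on these internal heuristics, the
module *counts* obtained by any particular external clustering release on
the real corpora are treated as soft reference points; the suite instead
verifies structural guarantees — every reported module is a local optimum
of the objective, detection is deterministic, and planted cliques
(sizes 4–8, intra-weights U(0.8, 1.0), ≤6 per network, sparse noise
bridges below 0.2) are recovered exactly with no false merges.

Module significance is a one-sided Mann–Whitney U test of internal
against boundary edge weights (alternative: internal stochastically
larger). Small samples without ties use the exact U distribution;
otherwise the normal approximation with tie correction applies. A module
with no boundary (an isolated component) or no internal edges offers no
contrast and is assigned p = 1 rather than an artificially small value.

## Module linking

With `M_ij` the number of curated associations crossing drug module `i`
and disease module `j`, and `N(i)`, `N(j)` the module sizes, the default
pair strength is

    w(i, j) = M_ij / (N(i) · N(j))

— the only normalization by both printed size quantities that is bounded
in [0, 1]; `M/(N_i+N_j)` and `M/√(N_i·N_j)` are available behind a config
switch for users probing alternative published scales. Curated marks
counted toward `M_ij` default to the full curated set {M, T, M&T};
restricted variants {T, M&T} and {M, M&T} are selectable, since both
appear in circulation as the qualifying set. Pairs with score ≥ 0.2
(inclusive) are retained and the top-3 taken forward, matching the
reference analysis; ties break on module ids so ranking is deterministic.

## Path similarity and cross-module propagation

**Step 1 (within module).** For nodes `a, b` of one module and each path
length `i`, let `avg(path_i)` be the per-edge average weight
`sum(path_i)/i` of the best simple path with exactly `i` edges, 0 when
none exists; then `sim(a,b) = Σ_{i=1..n−1} avg(path_i)`. Two decisions
were genuinely open and are resolved as follows:

* *Multiple paths of one length.* We take the maximum-weight simple path
  per length (config: mean over all simple paths of that length). Max is
  order-independent, bounded by the largest edge weight, and reduces to
  `sim = edge weight` for adjacent pairs in a two-node module.
* *Simple paths only.* Walks revisiting nodes would make the
  length-indexed sum divergent on weighted cycles.

No normalization by the number of contributing lengths is applied; the
published per-pair scores on the real corpora (≈3.7–8.8) are consistent
with unnormalized sums. The production implementation is a dynamic
program over (visited-node-subset, endpoint) states — exact for both
aggregation modes, `O(2^n · n · deg)` — which is cheap because observed
modules have about a dozen nodes; inputs beyond 26 nodes are rejected
rather than silently approximated. The test suite checks it against an
independent exhaustive `all_simple_paths` enumeration on 200+ random
subgraphs of ≤10 nodes, exact to 1e-12.

**Step 2 (across modules).** For disease `v` and drug `w` in a linked
module pair, with `N_DI(v)` the neighbors of `v` inside the disease
module that carry ≥1 curated link into the drug module (and `N_DR(w)`
symmetrically),

    corr(v, w) =   Σ_{p ∈ N_DI(v)} sim(v, p) · 1[(w, p) curated]
                 + Σ_{q ∈ N_DR(w)} sim(w, q) · 1[(q, v) curated]

This two-sided neighbor-propagation sum is the minimal expression built
from exactly the defined quantities; one-sided variants and an optional
direct-link bonus are config switches. Curated cells are *not* excluded
from ranking — known and novel associations are ranked together, and the
evaluation step merely labels them. Precision@n is the fraction of the
top n cells whose mark is M, T or M&T; `inferred` and `none` count as
candidates. The score is monotone: adding a curated link or increasing
any similarity never lowers any cell's score (tested), and removing a
link only perturbs cells sharing one of its endpoints (tested).

## Synthetic corpora

The generator plants `k` drug modules (each sharing a block of 8
module-exclusive side effects; members additionally pick up common-pool
side effects with probability 0.05), `k` disease modules (cliques with
intra-weights U(0.8, 1.0), inter-module noise edges at density 0.1 with
weights U(0.05, 0.2)), and pairs module `k` with module `k` by planting
the complete bipartite set of cross links, of which a `link_coverage`
fraction (default 0.5) is exposed with mark `M&T` — the rest is held out
in a ground-truth manifest. Module sizes default to U{4..8}; 20
background drugs each carry 4 private side effects plus one common-pool
draw, which bounds any background–background cosine far below the 0.4
cutoff (shared support is at most the single common feature). Everything
derives from one integer seed through a single `numpy` generator.

What the fixture does **not** emulate: real mark composition (everything
exposed is `M&T`), heavy-tailed side-effect marginals, reporting bias,
synonymy between drug names, or partially overlapping modules in the
ground truth. Passing the recovery benchmarks therefore shows the
machinery is correct and well-calibrated on block-structured inputs, not
that real-corpus precision is guaranteed.

Recovery of held-out links is scored over every (drug module, disease
module) combination — pairs without curated support contribute the
all-zero negative cells — with exposed cells excluded (they are inputs);
held-out cells missed by module detection score 0, so weak clustering is
penalized rather than hidden. At 50% coverage the AUROC exceeds 0.9 on
each of 10 seeded corpora, and its mean is nondecreasing in coverage.

## Evaluation fixtures

Four published top-20 ranking lists (three module-pair lists plus the
top-20 list of the PREDICT similarity-fusion baseline) ship as typed TSV
fixtures under `pdcim/data/` with their curated marks; `evaluate_precision`
reproduces their published precisions (0.90, 0.80, 0.90 and 0.25). Drug
name casing is preserved exactly as printed (identifiers are opaque
case-sensitive strings throughout; synonym resolution, e.g.
chlorpromazine/thorazine, is deliberately out of scope).

## Parameter summary

| parameter | default | where | meaning |
|---|---|---|---|
| drug network cutoff | 0.4 | `build_similarity_network` | min cosine for an edge |
| disease network cutoff | 0.5 | `filter_network` | min weight kept |
| penalty α | 2.0 | `detect_modules` | cohesiveness size penalty |
| min_size | 3 | `detect_modules` | smallest reportable module |
| min_density | 0.5 | `detect_modules` | weighted-density floor |
| merge_overlap | 0.8 | `detect_modules` | overlap score for merging |
| pair formula | product | `module_pair_score` | `M/(N_i·N_j)` |
| min_score / top_k | 0.2 / 3 | `rank_module_pairs` | pair retention |
| aggregate | max | `path_similarity` | per-length path aggregation |
| side / direct_bonus | both / off | `cross_module_score` | propagation variant |
| link_coverage ρ | 0.5 | `FixtureSpec` | curated fraction of planted links |

## Known limitations

* The method cannot distinguish therapeutic from adverse (marker)
  direction in a predicted association; both inflate `corr`.
* Module detection heuristics differ across clustering implementations;
  exact module counts on a given corpus are implementation-sensitive.
* Path similarity grows with module size (up to `n−1` terms), so `corr`
  values are comparable within a module pair, not across pairs.
* Cross-layer identifiers must match between the occurrence table and
  the curated table verbatim; no vocabulary mapping is attempted.
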