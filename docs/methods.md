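# Methods

This note documents the models implemented in `selenet`, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical conventions that make results
reproducible.

## Graph model

All networks are undirected, simple and unweighted. Interaction
direction, detection method and confidence scores present in source
files are ignored; self-loops are dropped (and counted) at merge time;
duplicate unordered pairs collapse with their source-provenance sets
unioned. Gene symbols are normalised by trimming and uppercasing; no
alias resolution is attempted unless the caller supplies a synonym
table. Merging is therefore idempotent and order-invariant, and the
merged edge count never exceeds the number of input records.

Global statistics follow the usual conventions: density 2E/(N(N−1)),
mean degree 2E/N, heterogeneity = coefficient of variation of the degree
distribution (population sd; 0 iff regular). The characteristic path
length is the mean shortest-path distance over *connected* unordered
pairs — disconnected pairs are excluded and the component count is
reported instead, so the statistic stays finite on fragmented networks.
Graphs up to `path_length_exact_limit` (default 2000) nodes use exact
all-sources BFS; above that, BFS from a seeded uniform sample of sources
(default 1000) estimates the same mean, with method, sample size and
seed recorded in the result.

## Centrality measures

Definitions follow the conventions of the Cytoscape hub-scoring
ecosystem; each constant is a parameter recorded in output metadata.

* **MNC / DMNC** — induce the subgraph on N(v) (v excluded); MNC is the
  node count of its largest connected component, DMNC that component's
  E/V^ε with ε = 1.7 (default), defined 0 when MNC ≤ 1.
* **MCC** — sum of (|C|−1)! over maximal cliques C containing v
  (`networkx.find_cliques`). Maximal 2-cliques contribute 1 each, so a
  node with an edgeless neighborhood scores its degree; size-1 cliques
  (isolated nodes) contribute nothing, so an isolated node scores 0.
  Enumeration aborts with a resource error beyond a configurable clique
  budget (default 2×10⁶).
* **EPC** — per realization, each edge draws an independent
  Uniform(0,1) weight and one Uniform(0,1) threshold is drawn; edges
  with weight ≥ threshold survive and each node contributes the size of
  its surviving component. EPC is the mean over K = 1000 realizations
  (seeded; same seed ⇒ identical scores). For a single edge the
  survival probability is P(weight ≥ threshold) = 1/2, so each
  endpoint's expected score is 2·(1/2) + 1·(1/2) = 1.5, which the test
  suite checks to within three Monte-Carlo standard errors.
* **BottleNeck** — one BFS shortest-path tree per source; a node scores
  +1 for a source when its tree descendants exceed a quarter of the
  nodes reachable from that source. The tree is made deterministic by
  choosing the lexicographically smallest parent among equally close
  candidates. This tie-break guarantees reproducibility but can split
  exact symmetry where several shortest-path trees exist (e.g. on even
  cycles the antipodal node's parent choice favours smaller labels);
  reproducibility was judged more important than exact symmetry in
  those degenerate cases.
* **Shortest-path family** — closeness is the harmonic form Σ 1/d
  (unreachable nodes contribute 0, so isolated nodes score 0);
  eccentricity is the maximum distance within the node's component (0
  for singleton components); radiality is Σ_w (Δ+1−d(v,w))/(n_c−1) with
  Δ the component diameter and n_c the component size; betweenness is
  the unnormalised Brandes statistic over unordered pairs (endpoints
  excluded); stress counts shortest paths with the node strictly
  interior (computed by a Brandes-style dependency accumulation, halved
  to count each unordered pair once).

**Consensus hubs.** Each measure contributes a top-k list (k = 10):
descending score, except eccentricity which ranks ascending because a
small maximum distance means central — nodes in singleton components
(eccentricity 0 by convention) are ranked last there rather than first.
Ties break on the symbol. Nodes present in at least `min_measures` = 6
lists form the consensus, ordered by membership count (descending), mean
rank across their lists (ascending), then symbol. The membership-count
rule with these defaults is this package's construction; alternative
combination schemes (rank products, score averaging) would be equally
defensible, which is why both k and the threshold are exposed.

## Expression analysis

Group profiles are arithmetic means of linear-scale values (ratios of
mean expression, not means of log ratios). Fold-change selection uses
log2((mean_case + c)/(mean_ref + c)) with pseudocount c = 0 by default —
zero means then yield an "undefined" status and a warning rather than an
arbitrary value; a small pseudocount is available for count-like data.
The default significance cutoff is |log2FC| ≥ 1 (a two-fold change),
applied both to qPCR fold changes and to network gene selection.
Cross-dataset consensus calls a gene up (down) only when at least
`min_agreement` tables agree and *no* table reports the opposite
direction; opposing calls give "discordant".

ΔΔCq quantification averages replicate Cq values per (sample, gene),
then per group; ΔCq = mean Cq(target) − mean Cq(housekeeping) per group,
ΔΔCq = ΔCq_case − ΔCq_ref, fold change 2^−ΔΔCq. One PCR cycle is one
doubling, so these identities are exact closed forms when jitter is
zero. Replicate-variance testing (t-tests on ΔCq) is deliberately out of
scope; significance is the ±1 log2 rule.

## Sub-network extraction

"1st/2nd order" neighborhoods are hop-distance ≤ 1 or ≤ 2 from the
mapped seed set with *induced* edges (every parent edge between selected
nodes is kept) — the neighborhood-selection semantics of Cytoscape.
Seeds absent from the parent are reported, not fatal; duplicates
collapse. Hub-to-seed connection paths enumerate all distinct shortest
paths up to length 2 (configurable), sorted lexicographically, and a
verification helper re-checks every reported path against BFS distances.

## Synthetic-data generators

Each generator returns its dataset plus a `SyntheticTruth` sidecar
(planted parameters, seed, generator settings), and is fully determined
by its integer seed.

* **Interactome.** A preferential-attachment backbone (default
  `attach` = 3, union mean degree ≈ 6–7) reproduces the heavy-tailed
  degree distribution of curated interactomes at desk scale. Planted
  hubs are the highest-degree backbone nodes, each wired to an
  *additional* 20% of all nodes, so hub identity is unambiguous ground
  truth rather than an accident of the backbone draw. Edges are split
  over sources uniformly, with a chosen fraction duplicated into a
  second source to emulate partially redundant databases. Not emulated:
  literature bias, false-positive edges, confidence scores.
* **Expression.** Values are baseline × 2^(log2FC·case) × exp(ε) with
  ε ~ N(0, noise_sd·ln 2): positivity is guaranteed and log2FC errors
  are symmetric. noise_sd = 0.25 (log2 units) is used in the operating-
  characteristic studies — a conservative per-sample spread for
  normalised expression panels. Not emulated: count noise, batch
  effects, normalisation artefacts.
* **qPCR.** Target Cq baselines are uniform in 22–30 cycles, the
  housekeeping gene fixed at 18; case reactions are shifted by −log2FC
  cycles; replicate jitter is Gaussian (default sd 0.15 cycles — the
  magnitude of replicate scatter is a convention, not a reported value).
* **IHC.** Two latent scores per patient from a standard bivariate
  normal with correlation `latent_rho`; grade-3 patients (2/3 of the
  cohort, matching a 10/20 grade split) have `grade_shift` added to both
  latents; thresholds discretise each latent into 1/2/3. The defaults
  — thresholds (−1.8, 1.3), grade_shift 2.58 — are a probit fit to
  grade-wise marginals in which grade 2 is predominantly moderate and
  ~90% of grade 3 is strong. With those fixed, `latent_rho` = 0.70 was
  calibrated once by Monte-Carlo scan so that the *ordinal* Pearson
  correlation of the two intensity scores averages ≈ 0.77 over
  30-patient cohorts (discretization attenuates the latent correlation;
  the shared grade shift partially offsets it). Ki67 is Gaussian per
  grade (means 28.9/44.9%, sd 13.3/15.8%), clipped to [0, 100].
  A sampling-theory consequence worth stating: at true correlation 0.77
  and n = 30, two-sided p < 10⁻⁴ requires sample r ≥ 0.650, an event of
  probability ≈ 0.91 even for *continuous* bivariate-normal data, and
  slightly less for 3-level ordinal scores. A single observed cohort
  with r = 0.77 has p ≈ 6×10⁻⁷, but no generator at that effect size can
  make p < 10⁻⁴ near-certain across replicate cohorts.
* **Survival.** Two correlated expression values per patient; the
  package's own combined z-score/median split defines the high/low
  groups (so the split operation recovers the truth exactly); event
  times are exponential with the low-group median at 36 months and the
  high-group rate multiplied by the planted hazard ratio; censoring
  replaces a patient's time by an independent uniform fraction of the
  event time at the chosen rate. Not emulated: covariate effects,
  non-proportional hazards, administrative censoring patterns.

Because the generators are simplifications, passing tests demonstrate
that the *estimators* recover what was planted under these noise models
— not that real CCLE/LINCS/TCGA data would yield the same gene lists,
hubs or survival curves.

## Numerical conventions and degenerate inputs

Direction calls use a relative tolerance (default 1e−9) for "equal".
Combined-split median ties go to "low", counted and reported;
essentially constant combined scores (e.g. perfectly anti-correlated
genes of equal variance) trigger a degenerate-split warning. Zero
variance makes Pearson correlation and z-scoring errors, not NaNs.
Log-rank p-values come from a χ²₁ tail; identical groups give exactly
χ² = 0, p = 1. p-values are reported at full precision; conventional
star thresholds are left to presentation. Study sizes used by the test
suite and the acceptance script (100-node hub graphs, 500 expression or
IHC replicates, 200 survival replicates of 200 patients) were chosen as
the smallest sizes at which the Monte-Carlo standard errors are well
inside the asserted margins.

## Known limitations

* No alias/ortholog mapping; symbol normalisation is purely
  typographical.
* MCC is exact but enumeration-bounded; very dense graphs need
  decomposition first.
* The consensus-hub rule is one defensible construction among several;
  rankings near the k-boundary are sensitive to k.
* DMNC systematically disfavours high-degree hubs (their neighborhoods
  are large and relatively sparse), so a genuine hub typically reaches
  10 of the 11 top-k lists.
* The survival generator plants group membership through the same
  combined-score rule the analysis uses; it validates the split/test
  machinery, not the biological claim that the signature is prognostic.
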