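# Methods

## Scope and data model

The package works at two resolutions.

*Measured karyograms* hold, per chromosome pair of one taxon, the relative
length (RL, percent of total haploid karyotype length, mean ± sd across
metaphase plates) and, where measured, the centromeric index (CI, percent of
chromosome length taken by the short arm, range 0–50). Pairs are ranked
1..n by decreasing mean RL. Validation enforces what printed morphometric
tables can actually promise: RL non-increasing with rank up to a 0.35
percentage-point rounding tolerance (printed columns contain ties), and an
RL column sum within [98, 102] (one-decimal rounding accumulates; fixture
columns are never renormalised — one of the packaged columns sums to 101.7
exactly as printed).

*Abstract karyotype states* keep only the haploid counts of the four Levan
morphology classes (m, sm, st, t). This is the unit the rearrangement engine
evolves: chromosome sizes are deliberately discarded because size homology
across genera is not established by banding-level cytogenetics, and the
published comparative argument operates on karyogram shape alone.

## Levan classification

CI thresholds are 12.5 (t/st), 25.0 (st/sm) and 37.5 (sm/m), the arm-ratio
scheme expressed on the short-arm scale; 25.0 being the st/sm transition
only makes sense on this scale, which fixes the convention. A CI exactly on
a threshold returns an explicit two-class token rather than being silently
rounded — the measured *B. antongilensis* pair 1 (CI 25.0) is reported
`st/sm`, as such boundary chromosomes are reported in practice. Boundary
comparisons use a 1e-9 absolute tolerance so grid values arriving through
float arithmetic still hit the token. For arm counting (FN) every
non-telocentric, including boundary tokens, contributes two arms; this
convention reproduces the published FN values (2n = 36 with 4 biarmed pairs
→ FN 44; with 2 → FN 40). When a karyogram is collapsed to an abstract
state, boundary pairs are tallied as the lower flanking class (st) by
default; the choice is configurable and affects only the class label, never
2n or FN.

## Event model

Four whole-chromosome events, each with a positive cost:

* centric (Robertsonian) fusion, t + t → one biarmed (n −1, diploid FN
  conserved); the product class is a parameter (default m);
* centric fission, the reverse (n +1, FN conserved);
* pericentric inversion, reclassifying one chromosome between any two
  classes (n conserved, diploid FN −2/0/+2);
* centromere repositioning, the same state change by a different mechanism.

Count-level cytogenetic data cannot distinguish inversion from
repositioning, so whenever their costs are equal the two are merged into
one move (reported `inv/repo`); with unequal costs they are enumerated
separately. There is no NOR-translocation event: NOR and heterochromatin
observations are carried as inert annotations only.

Default costs are fusion = inversion = repositioning = 1, fission = 5. The
fission penalty encodes the squamate prior that high chromosome numbers are
ancestral, so descent proceeds by fusions rather than ascent by fissions;
it is an analysis choice, versioned with the fixtures and fully
configurable. Under all-equal costs the reconstructed root of the case
study drops from 2n = 42 to 2n = 40 — the package treats this cost
sensitivity as part of the result.

## Distances and reconstruction

The minimal event cost between two states is computed by uniform-cost
(Dijkstra) search over the implicit state graph, bounded by a maximal
haploid number (`max_n`, default 30); one optimal path is returned. With
symmetric costs the distance is symmetric and satisfies the triangle
inequality; raising any single event cost never decreases a distance. The
test suite pins these properties and checks the search against an
independent Bellman–Ford oracle on every state pair with n ≤ 6.

Ancestral reconstruction is exact Sankoff dynamic programming. The
candidate state space is enumerated explicitly: every state within a
configurable number of single events (`state_radius`, default 6) of any
known tip state. All-pairs directional transition costs over that space are
computed by running Dijkstra from every state on the one-event graph
(scipy.sparse.csgraph). The up-pass yields the minimal total cost and all
minimal root states; a down-pass identifies, for every node, every state
occurring in at least one globally optimal labeling. If any such state lies
on the radius boundary the reconstruction raises instead of answering,
since the true optimum could then lie outside the enumerated space.
Unknown tips (taxa without karyotype data) contribute zero cost for every
state; they never change the total cost.

Ties are broken deterministically: among optimal states the designated
labeling prefers the largest haploid number (the ancestral-condition prior
again), then the lexicographically smallest (m, sm, st, t) vector. Reports
are therefore byte-identical across runs.

### The case-study optimum vs the narrative scenario

On the packaged tree and tip states with the default costs, the unique
minimum-cost root is `{m:1, t:20}` (2n = 42 with one metacentric), total
cost 11. The classical narrative — an all-telocentric 2n = 42 ancestor —
costs exactly 12: carrying one metacentric at the root saves one event on
the stem of the *Geckolepis* + *Homopholis* clade (one fusion instead of
fusion + inversion) and on the *B. sakalava* / *B. antongilensis* side,
at the price of a single m → t inversion on the branch towards
*B. boivini*. The fission penalty enforces the "many chromosomes ancestral"
half of the usual prior but not the "telocentric chromosomes ancestral"
half, because inversions can delete biarmed elements without fissions. The
engine reports both numbers (`ReconstructionResult.root_costs` holds the
total cost for any forced root), and the package deliberately does not
reweight costs to force the narrative root. Descendant-branch structure is
shared by both solutions: 3 inversions to *G. typica*, 2 fusions to the
*Homopholis* ancestor, 2 inversions to *H. fasciata*.

Note also that the narrative "two centric fusions reducing 2n = 42 to
2n = 40" is arithmetically impossible (each fusion removes one pair); the
engine's consistent decomposition of that step is one fusion plus one
inversion — two events, different labels.

## Synthetic data

`simulate_history` evolves a root state down a tree: per branch the event
count is Poisson with mean equal to the summed per-kind rates, kinds are
multinomial by rate, and an inapplicable sampled kind (e.g. fission with no
biarmed chromosome) is resampled among the applicable kinds, rate-weighted;
if nothing is applicable the event is dropped and logged. Branch lengths
are ignored — rates are per branch, which matches how the engine treats the
topology-only fixture tree. The full truth (node states, branch event
lists) is returned so tests can assert, e.g., that the parsimony total
never exceeds the true event count.

`simulate_measurements` emulates scoring metaphase plates: per cell,
chromosome lengths are base · (1 + N(0, length_cv)) truncated positive
(non-positive multipliers are redrawn), with base proportional to the true
RL; biarmed pairs get a short-arm fraction N(ci_mean, ci_sd)/100 clipped to
[0, 0.5]; telocentric pairs get short arm 0. Gaussian noise is a modelling
choice — the source tables publish only means ± sd. Because any computed RL
vector sums to exactly 100 while printed RL columns carry rounding,
zero-noise recovery is exact on the renormalised scale (100·rl/Σrl), which
coincides with the printed values whenever the printed column sums to 100.0
(true for the *B. antongilensis* column used in the round-trip tests).

What the simulators do *not* emulate: real metaphase spreads have
correlated condensation artefacts, rank misassignments near size ties, and
non-Gaussian measurement error; simulated recovery rates therefore bound
idealised, not real, performance. Likewise the history simulator draws
event kinds independently of chromosome identity, so it cannot model
lineage-specific hotspots.

## Frozen stochastic thresholds and problem sizes

Stochastic assertions were calibrated once with the seeded generators and
then frozen:

* root recovery at low rates (fusion 0.1 + inversion 0.1 per branch, no
  fissions, seeds 0–14): true root among minimal Sankoff roots in 14/15
  replicates; asserted ≥ 13/15.
* metacentric-pair recovery under study-scale noise (10 cells, 10% length
  cv, CI sd 3.5 — the printed spread of the relevant pair, seeds 0–9): the
  highest-CI pair classified m in 8/10 replicates (the true CI, 38.4, sits
  0.9 points above the sm/m boundary); asserted ≥ 8/10. The pair is located
  by highest CI, not printed rank, because 10-cell length noise can swap
  adjacent near-equal ranks.
* classification recovery is asserted non-increasing across the noise
  ladder (0, 0), (0.05, 2), (0.1, 3.5), (0.2, 8) with seeds 0–4.
* the parsimony-lower-bound check runs 40 seeded replicates at fusion 0.3 +
  inversion 0.3 per branch; the bound is a theorem given the state space
  covers the truth, so the replicate count only controls runtime.

## Numerical and degenerate-input choices

Costs are compared with 1e-9 tolerances throughout (they are small sums of
configured reals). Dijkstra uses an insertion counter to keep heap entries
comparable. Empty karyograms, non-contiguous ranks, RL inversions beyond
tolerance, negative counts, unknown morphologies in FN/summaries, cells
with differing chromosome complements, polytomous or duplicate-label trees,
and states exceeding `max_n` all raise immediately with messages naming the
violated constraint. Sample standard deviations use ddof = 1, defined as 0
for a single cell.

## Known limitations

* The engine evolves class counts, not chromosome identities: it cannot
  distinguish which pair fused, and homology of individual pairs across
  taxa is outside the model.
* Parsimony only; no rates, branch lengths, or likelihoods. The fixed costs
  are priors in disguise and should be varied (the CLI makes this cheap).
* The explicit state space grows quickly with radius; the default radius 6
  is ample for the packaged data (optimum ≤ 3 events from a tip state) but
  deep, event-dense trees need a larger radius and correspondingly more
  time/memory.
* Sex chromosomes, NOR translocations and heterochromatin dynamics are not
  modelled; their observations ride along as annotations.
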