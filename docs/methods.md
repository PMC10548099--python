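# Methods

`paleoranges` implements a complete quantitative workflow for the
historical biogeography of a fossil-rich clade: filtered occurrence data
are clustered into discrete areas, taxa are coded into those areas, six
likelihood models of geographic range evolution are fitted to a dated
phylogeny (with and without distance-based dispersal constraints),
ancestral coordinates are estimated independently under Brownian motion,
and dispersal events extracted from the fitted models are tested for a
skew in transoceanic crossings between saltwater-tolerant and -intolerant
clades.  This note records the models, their assumptions, the tunable
parameters, and the design decisions taken where the methodology was
genuinely open.

## Occurrence handling

Occurrence records carry present-day and palaeorotated coordinates, an
age interval in Ma, and a habitat flag.  Records are deduplicated on
(taxon, coordinates, age interval); longitudes are wrapped into
(−180, 180].  Two filters are applied before any spatial analysis:
primarily marine taxa (habitat column, optionally an explicit exclusion
list) and open-nomenclature identifications, detected by the rank
qualifier tokens ` sp.`, ` cf.`, ` aff.`, ` indet.` in the taxon name.
Both filters are idempotent and never add rows.

Records are pooled into four epoch-level bins — Early Cretaceous, Late
Cretaceous, Palaeogene, Neogene + Quaternary — before clustering, using
ICS boundaries (145, 100.5, 66, 23.03, 0 Ma).  An interval is binned by
its midpoint; records whose midpoint predates 145 Ma are flagged
unbinnable rather than forced into a bin, since pre-Cretaceous occurrence
densities are too low for meaningful clustering.

All point arithmetic happens on the unit sphere: a record maps to a 3D
unit vector, the geographic midpoint of a taxon is the renormalized
arithmetic mean of its vectors, and distances are haversine great circles
with Earth radius 6371.0088 km.  The midpoint is undefined (and raises)
when the mean vector is numerically zero — an antipodal configuration.

## Bioregionalization (k-means + PVE)

Area delineation uses k-means on the unit-sphere Cartesian coordinates of
the palaeocoordinates in each epoch bin.  Clustering in 3D rather than on
raw (lat, lon) avoids date-line and polar artifacts; k-means++
initialization with best-of-`restarts` Lloyd runs (default 100 restarts;
configurable upward — the selection stabilizes far below classic
10 000-replicate protocols at these data sizes) is provided by
scikit-learn.  The quality of a cluster count k is the proportion of
variance explained, PVE = BCSS/TSS; k is chosen as the smallest value in
[5, 15] whose PVE reaches 0.98, and the full PVE-by-k table is always
returned so that judgement (consistency across epochs, conformity to
known provinces) can override the rule — an override map is accepted when
linking clusters across epochs.  Cross-epoch linkage is greedy
closest-centroid pairing; on small centroid shifts it coincides with the
Hungarian optimum (property-tested).

Taxa are coded into areas by nearest area midpoint per occurrence
(great-circle; ties broken toward the lowest area index), and a taxon's
range is the union over its occurrences.  Ranges are written in the
standard geography-file layout (`n_taxa n_areas (labels)` header, one
binary presence string per taxon).

## Time strata, distance multipliers, connectivity

The distance-constrained analyses use seven time bins — 0–30, 30–60,
60–90, 90–120, 120–150, 150–180, 180–230 Ma — each with its own area
midpoints.  All pairwise midpoint distances, across all strata, are
divided by the single global minimum off-diagonal distance, so the
closest recorded pair of areas has relative distance exactly 1; the
dispersal multiplier is the reciprocal of relative distance,
m_ij = 1/d̃_ij ∈ (0, 1], with unit diagonal.  Proportionality of
dispersal probability to inverse distance fixes the constant so that the
nearest pair is unpenalized.  Land connectivity is a separate boolean
layer (direct links per stratum plus their transitive closure via
Floyd–Warshall); it never enters the likelihood and is used only to
classify inferred dispersal events.

## Range-evolution models

Ranges are non-empty subsets of n areas (bit-encoded; all subset sizes by
default, restrictable via `max_range_size`).  Anagenesis is a CTMC:
range gains R → R∪{a} at rate d·Σ_{i∈R} m_ia and losses R → R∖{i} at
rate e; the empty range is absorbing (global extirpation), participates
in anagenesis only, and is excluded at tips and cladogenesis.
Cladogenesis follows DEC (narrow sympatry, subset sympatry, narrow
vicariance), DIVALIKE (narrow sympatry, vicariance with splits of any
size), or BAYAREALIKE (exact full-range copy).  Founder-event speciation
(+J) adds, for each area b outside the ancestor range R, the ordered
daughter pairs (R, {b}) and ({b}, R).  Ordered events carry per-event
weights y = s = v = (3−j)/3 for the non-jump classes and j for jumps,
j ∈ [0, 3), normalized within each ancestral state.  With two areas and a
two-area DEC ancestor this yields the familiar six equiprobable
daughter pairs at j = 0.

The likelihood is Felsenstein pruning over the state space with the
cladogenesis distribution applied at internal nodes and the root
likelihood taken as the mean of the root conditionals over non-null
states (a flat root prior; a size-weighted prior was considered and
rejected to keep the default assumption-minimal).  Branches crossing
stratum boundaries are split at the boundaries, with the stratum-specific
rate matrix in each segment; transition matrices come from an
eigendecomposition per stratum (validated against `expm` at construction,
with automatic fallback to scaling-and-squaring when the decomposition is
ill-conditioned), and partial likelihoods are rescaled per node.  On
3-tip/2-area instances the pruning log-likelihood matches exhaustive
enumeration over all internal states and cladogenetic outcomes to 1e−8
for all six models.

Fitting is bounded quasi-Newton (L-BFGS-B) over (log₁₀ d, log₁₀ e[, j])
with d, e ∈ [1e−12, 5] and j ∈ [0, 3), from a fixed moderate start plus
seeded random restarts (default 5).  AIC uses the free parameter count
(2 or 3); AICc uses n = number of terminal taxa.  Model comparison
reports ΔAIC, Akaike weights, AICc weights, and likelihood-ratio tests
for the nested (M, M+J) pairs with one degree of freedom; fits are
hash-checked to be on identical data.  Marginal ancestral ranges use the
standard two-pass (inside–outside) algorithm, reported at the instant
before cladogenesis, normalized with zero probability on the null range;
they match brute-force posteriors on small instances to 1e−8.

### Survival conditioning

The forward process can extirpate a lineage entirely (null range), but
observed trees contain only surviving, range-bearing tips.  Two
conditioning conventions are implemented and must be matched between
simulator and likelihood:

* none (default) — the standard unconditioned likelihood, as used on real
  data;
* branch — every branch transition matrix is row-normalized over non-null
  endpoints.  This is the exact likelihood of the simulator variant that
  redraws a branch until its endpoint is non-null (see below); with it,
  the likelihood summed over all tip configurations is 1 to machine
  precision.

Ignoring the mismatch is not benign: fitting the unconditioned likelihood
to survival-conditioned simulations biases ê towards zero strongly enough
to put it at the optimizer boundary.

## Synthetic data generator

The generator emulates a continental-scale fossil-vertebrate dataset and
defines the package's study conditions: trees of order 100–200 terminals
spanning ~200 Myr with both extant and extinct tips; a handful of
occurrences per taxon (1 + Poisson(2.5), matching ~3.5 occurrences per
species); von Mises–Fisher coordinate scatter (κ = 50, ≈ 8° angular
spread) around well-separated continental centroids; and known
(d, e, j).

* Trees: forward Gillespie birth–death (b = 0.1, d = 0.05 per lineage per
  Myr), conditioned on exactly `n_tips` extant lineages by stopping at a
  uniform point of the first holding interval at that count.  Fossil tips
  are sampled along extinct lineages at rate ψ (default 0.05/lineage/Myr)
  and unsampled extinct material is pruned, each sampled extinct lineage
  truncated at its youngest sample.  After pruning, depths are normalized
  so the surviving MRCA sits at `root_age`; branches shorter than 0.1 Myr
  are raised to 0.1 Myr, the standard minimum-branch-length convention
  for time-scaled fossil trees.  Serially sampled tips are not cosmetic:
  extirpation (e) is close to unidentifiable from extant-only tip ranges,
  because cladogenetic range subdivision mimics range loss.
* Range histories: exact Gillespie anagenesis along branches (stratified
  rates where multipliers are supplied) and cladogenetic daughter draws
  from the same normalized event table the likelihood uses.  Replicates
  in which any branch endpoint is the null range are, by default,
  rejected wholesale — exactly the stated forward model, and the variant
  used in forward-vs-likelihood consistency checks.  Because the expected
  number of null endpoints on a 200-tip, 200-Myr tree at e = 0.01 is ≈ 15
  (acceptance probability ≈ e^−15), study-scale simulation instead uses
  per-branch conditioning (`condition_branches=True`): each branch is
  redrawn until its endpoint is non-null, whose exact likelihood is the
  "branch" conditioning above.
* A designated saltwater-intolerant clade can have its non-land-connected
  gains and founder jumps multiplied by an `ocean_suppression` factor;
  event truth labels (terrestrial/transoceanic) are recorded at
  generation time, with indirect-land-route cases resolved by a fair coin
  — the truth for a crossing that could have gone either way.
* Occurrences: per tip, each point picks one of the tip's areas uniformly
  and draws a vMF deviate around that area's centroid; ages are uniform
  within the tip's stratum; palaeo- and modern coordinates coincide (no
  plate motion is modelled).

What the generator does not emulate: plate rotation (per-stratum
midpoints are inputs), spatially autocorrelated sampling failure,
taxonomic error, or diversity-dependent diversification.  Passing tests
therefore demonstrate internal statistical correctness of the estimators
under the stated model, not robustness to those real-data pathologies.

## Brownian-motion ancestral coordinates

Tip midpoints are mapped to unit 3-vectors and each Cartesian axis is
treated as a BM trait with one shared rate; estimates are renormalized to
the sphere.  Three dimensions avoid longitude-wrap bias and make
rotation equivariance exact.  The ML/GLS estimator is Gaussian message
passing on the tree (two passes, flat root prior) and agrees with a dense
GLS solve of the full BM covariance to 1e−8.  The Bayesian variant runs
MCMC over all internal node positions and the rate: node positions are
updated in two depth-parity blocks by sampling their exact Gaussian full
conditionals (the tree is bipartite, so a block is conditionally
independent; a full-conditional proposal is always accepted), and the
log-rate takes a Metropolis random walk under a Jeffreys prior.  Full-
conditional updates were adopted after random-walk proposals left deep
nodes several degrees from the exact posterior mean at desk-scale chain
lengths purely through slow mixing.  Chains (default 5) are concatenated
after burn-in; "confidence intervals" are 95% equal-tailed posterior
intervals per axis; convergence is flagged (not fatal) when split-chain
R̂ exceeds 1.1.  Desk defaults are 100 000 iterations with 15 000
burn-in; production-scale settings (5 × 10⁷-iteration chains) are
expressible through the same config.

One caveat governs interpretation: the posterior median vector of a node
whose location is genuinely diffuse can lie near the centre of the Earth,
where its angular position is ill-conditioned — a 0.02 perturbation of a
0.1-length vector moves it ~10°.  Agreement between MCMC medians and GLS
(< 2° on 10-tip data) therefore holds for clustered, study-like tip
coordinates; for near-uniformly scattered tips the angular summary itself
is unstable, which is also why a node estimate can fall "in open water":
the mean of a wide range is not a place the lineage need ever have
occupied.  `summarize_node_location` reports the nearest area midpoint in
the node's stratum and flags nodes farther than `water_threshold_km`
(default 2000 km) from any midpoint.

## Dispersal events and the skew test

For each branch, the cladogenetic outcome at the parent is resolved to
its most probable daughter pair given the parent's MAP range and the
branch processes towards both children's states; areas in the child
state absent from the inherited range become anagenetic gain events timed
at the branch midpoint (the stratum of an event is determined by that
time; the timing convention is explicit because strata change
connectivity), and a jump outcome contributes a founder event at the
node's age.  Events are classified against the stratum's land
connectivity: terrestrial (a direct link from any source area),
ambiguous (a land route only via intermediate areas — the long-way-around
case), or transoceanic (no land route).  The minimum scenario counts
ambiguous events as terrestrial, the maximum as transoceanic; on
synthetic truths the two scenarios bracket the true transoceanic count in
every replicate.

Event-level recovery has a model-dependent ceiling: under full-range
inheritance (BAYAREALIKE) with e = 0, every gain leaves an unambiguous
clade signature and MAP extraction recovers ≈ 90% of true (branch, area)
events, but under DEC only ≈ 72–76% are recoverable at any event density
tried, because cladogenetic subset inheritance can absorb a true
anagenetic gain into a higher-probability no-event explanation; a joint
(max-product) reconstruction does not beat the marginal-MAP extraction.
This is a limitation of event counting from point estimates generally,
not of the implementation.

The skew test compares observed transoceanic counts in a
saltwater-tolerant and an intolerant clade against expectations
apportioned by clade size: E_t = N_to·N_ct/N_T and E_i = N_to·N_ci/N_T,
where N_to is the total transoceanic count, N_ct and N_ci the internal
node counts of the two clades and N_T their sum ("nodes" = internal nodes
of each clade's subtree; the convention is configurable input, not
hard-coded, and clade definitions are supplied as tip sets).  The
statistic is Pearson's χ² = (O_t−E_t)²/E_t + (O_i−E_i)²/E_i with one
degree of freedom and no continuity correction — a convention validated
by reproducing all sixteen printed (χ², p) pairs of the reference
analysis at three decimals — with significance at p < 0.05 and an
explicit error (suggesting an exact test) when an expected count is zero.

## Study conditions used by the acceptance script

The parameter-recovery experiment fits DEC (matched "branch"
conditioning) on 20 replicates of ~200-terminal trees (150 extant tips
plus ψ = 0.05 fossil tips) spanning 200 Myr over six areas at
d = 0.02, e = 0.01; the model-preference experiment simulates the same
conditions at j = 1 and compares DEC against DEC+J by AIC.  Six areas
(rather than the ten of a full continental scheme) keeps a single
replicate's fit in seconds while preserving enough per-lineage loss
events for ê to be informative; with four areas ê's sampling scatter at
this data size straddles the factor-of-two band.  Forward/likelihood
consistency uses 100 000 exact-forward replicates on a fixed 3-tip tree;
cluster-count selection uses eight vMF blobs (κ = 300, 25 points each);
the skew-test pipeline uses 40-tip trees with a four-area chain
connectivity (A–B–C linked, D isolated) and ocean suppression 0.1 inside
the intolerant clade.  Problem sizes are the package's own desk-scale
choices and are recorded in the script output (`n` per quantity).

## Known limitations

* ML estimates of e sit on the boundary (ê → 0) for extant-only trees;
  this is a property of the DEC family, not an optimizer failure (the
  profile likelihood is maximized there).
* Event extraction from MAP states under-counts gains absorbed by
  cladogenetic subset inheritance (see above); stochastic mapping would
  be the remedy and is out of scope.
* The +J models inherit the known degeneracy in which j can absorb
  anagenetic dispersal signal; comparisons involving +J should lean on
  the likelihood-ratio test against the nested base model.
* No plate rotation: palaeocoordinates and per-stratum midpoints are
  caller-supplied inputs throughout.
* The Bayesian location model assumes a single isotropic BM rate; rate
  heterogeneity across lineages or axes is not modelled.
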