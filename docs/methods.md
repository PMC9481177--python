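# Methods

## Model and assumptions

The package analyses positive-valued network activity through the
cooperative Lotka-Volterra (LV) system

    u_i' = u_i (α_i − u_i + g Σ_{j≠i} γ_ij u_j),    i = 1..n,

with nonnegative interaction weights γ (zero diagonal) and a global
coupling g. Cooperativity plus the validated bound g·ρ(γ) < 1 (ρ the
spectral radius) guarantee that every principal submatrix of I − g·γ is a
nonsingular M-matrix with a nonnegative inverse. Consequences the code
relies on throughout:

* each candidate support S ⊆ {1..n} admits at most one nonnegative
  equilibrium, the solution of (I − g·γ)[S,S] u_S = α_S with zeros
  elsewhere, feasible iff all components of u_S are strictly positive;
* a unique globally asymptotically stable solution (GASS) exists and its
  support is the union of all feasible supports — asserted on every
  enumeration, together with linear stability of that point;
* equilibria are monotone in each α_i, so sensitivity analysis
  (criticality, below) is affine and exact.

The bound g·ρ(γ) < 1 is this package's sufficient condition for the
attractor theory to apply; the literature states existence/uniqueness
conditions in several forms, and this one was chosen because it is cheap to
verify and implies everything the algorithms need.

The Information Structure (IS) is the set of all feasible equilibria
ordered by support size into energy levels (origin at level 0, GASS on
top). Edges stored with an IS are the covering pairs of the
support-inclusion order; they serve visualisation and serialisation only.
Heteroclinic connections are **not** computed — no scalar measure depends
on edges.

## Measures

With P the set of feasible supports and G the GASS support:

* **NoEL** = |G| + 1.
* **Frondosity** = |P| / 2^(NoEL−1) ∈ (0, 1]; equals 1 iff every subset of
  G is feasible (checked as an invariant).
* **Cooperation.** L1 is the set of networks feasible alone ({k} ∈ P). A
  network k ∈ G \ L1 is *cooperative*; its cooperation nodes are the
  inclusion-minimal supports in P containing k (a network may have
  several). With ℓ_k the lowest level among k's cooperation nodes:
  highest cooperation level = max node level; value A = Σ over all
  (k, node) pairs of (level − 1); value B = Σ_k (ℓ_k − 1); value
  C = Σ_k 2^(ℓ_k − 1). The minimal-container reading and the exact A/B/C
  formulas are this package's formalisation of measures that are usually
  described only qualitatively; counting *all* containers instead of
  minimal ones would blow up combinatorially with landscape size and make
  the values dominated by frondosity rather than by genuine carrying
  relations.
* **Criticality** is the smallest |δ| such that perturbing a single α_i by
  δ changes the GASS support. Because u_S is affine in α, the only
  crossing events are (a) a GASS component reaching 0 (as α_i decreases;
  the sensitivity column is a nonnegative inverse column) and (b) an
  absent network's invasion rate α_k + g Σ_j γ_kj u*_j reaching 0 (as α_i
  increases). The implementation enumerates both candidate families over
  all i and both signs analytically; it was validated against an
  independent grid-scan + bisection oracle to 1e-8 on random systems, and
  that oracle is kept in the test suite. Absolute (not normalised)
  α-distance is used, and only bifurcations that change the GASS support
  count — reshapings of intermediate levels that leave the GASS intact do
  not. Joint perturbations of several α are out of scope.
* **Synchronicity** = fraction of timepoints whose NoEL is extreme (1 or
  n+1), i.e. all networks jointly present in or absent from the GASS.
* **Pairwise differentiation** = fraction of timepoints where exactly one
  of two chosen networks is in the GASS; defaults to DMN–Frontoparietal
  and DMN–DorsalAttention, configurable to any pair.

## The transform

The LVT inverts the explicit-Euler discretisation
u(t+1) = u(t) + h·u(t)·(α − u(t) + g·γu(t)) for α(t); forward simulation
uses the same scheme, so transform∘simulate is an exact round trip
(asserted to 1e-8 in tests; the one-step reconstruction contract to 1e-12
holds for arbitrary positive series by construction). The step is
h = 3.55e-4 at TR = 2000 ms, scaled proportionally for other repetition
times (4.26e-4 at 2400 ms); the coupling default is g = 0.27. Both are
exposed in `RunConfig`; fitting them is out of scope.

Raw (possibly zero-centred) series are made positive by a *single* affine
map per subject onto [0.05, 1], not per network: a per-network map would
erase the between-network amplitude relations that decide GASS membership.
The CLI applies this map only when a series is not already strictly
positive.

## Aggregation

Per-timepoint measures are aggregated per subject into 15 features: mean
and population standard deviation (divisor N) of NoEL, frondosity, highest
cooperation level and cooperation values A/B/C; median and standard
deviation of criticality (the median because a few far-from-bifurcation
timepoints skew the mean); and synchronicity. Timepoints with infinite
criticality (no finite bifurcation in any direction — possible only in
degenerate corners) are excluded from the criticality statistics and
counted; all valid timepoints enter every other statistic. All features
are order-free statistics of the timepoint sequence.

## Statistics and classification

Group contrasts use the two-sided Mann-Whitney rank-sum test (exact for
small tie-free samples, normal approximation with tie correction
otherwise). A paired Wilcoxon signed-rank variant is provided for designs
with a genuine pairing, but it is not the default because the cohort
groups are independent and of unequal size. The multiple-comparison
threshold is Bonferroni, α/m.

Classification is leave-one-out: one fold per subject, feature selection
(top-k by absolute point-biserial correlation; mutual-information ranking
as fallback; k = 5) on the training split only, and the held-out
prediction pooled across folds into a confusion matrix, per-class and
class-size-weighted metrics (TP/FP rate, precision, recall, F-measure,
MCC, ROC and PRC areas from pooled held-out scores), and per-feature
selection frequency (%f). Two interpretable learners are provided:

* a RIPPER-style rule inducer written in-package (no suitable library
  implementation exists in the dependency set): rules for the minority
  class are grown by FOIL information gain on two thirds of the training
  data, pruned on the held-out third by the (p − n)/(p + n) rule-value
  metric, induction stopping when a pruned rule is no better than chance;
  class scores are Laplace-corrected coverage frequencies;
* a reduced-error-pruning decision tree backed by scikit-learn: grown on
  two thirds, the cost-complexity pruning path evaluated on the remaining
  third, the smallest subtree with maximal held-out accuracy kept and
  refit on the full training split.

Both learners take an explicit seed for their internal grow/prune splits.
Zero-denominator metric cells are reported as 0 with a flag.

## Synthetic cohorts

The generator produces everything the pipeline consumes, with ground
truth. A cohort shares one connectivity matrix: symmetric, lognormal
weights (σ = 0.6) present with probability `density` (default 0.5),
modulated by per-network strength factors spread geometrically over
[0.35, 1.3] — structural connectomes are strongly heterogeneous, and that
heterogeneity is what lets single networks join or leave the attractor
independently rather than all at once. The matrix is rescaled so that
g·ρ(γ) = 0.6, comfortably inside the validity region.

Latent growth parameters follow a mean-reverting bounded random walk per
network (AR(1) with reversion rate 0.15, innovations scaled to a target
stationary spread, hard clipping). Three archetypes encode the regimes the
analysis is meant to distinguish, with parameters in
`src/lvscape/config/archetypes.yaml`:

* `near_bifurcation` (healthy-control-like): means in [−0.08, 0.25],
  spread 0.22 — parameters straddle the membership thresholds, networks
  join and leave the attractor, cooperation is frequent, criticality low;
* `intermediate` (MCS-like): means in [0.10, 0.40], spread 0.095 — the
  attractor is usually full but occasionally loses its most weakly coupled
  network;
* `saturated` (UWS-like): means in [0.65, 0.90], spread 0.05, clipped
  strictly positive — the attractor always contains every network, so
  frondosity and synchronicity are exactly 1 and cooperation 0.

These values were calibrated once with `scripts/calibrate_archetypes.py`
so that the qualitative group orderings (frondosity and synchronicity:
saturated > intermediate > near-bifurcation; cooperation means and spreads
reversed; median criticality lowest near bifurcation) hold across seeds at
cohort scale, then frozen.

Observed series are produced by the same explicit-Euler forward model the
LVT inverts (one step per TR), plus additive Gaussian observation noise and
clamping to a positive floor. Because the inverse transform divides
increments by h ≈ 3.55e-4, series-level noise is amplified by roughly 1/h
in the recovered parameters; the default noise (sd 1e-6) is therefore
chosen so the α-scale perturbation is ~10% of the archetype signal. The
noiseless case round-trips exactly, and recovery error scales linearly as
the noise shrinks (tested). What the generator deliberately does **not**
emulate: hemodynamics, realistic BOLD spectra and autocorrelation,
scanner/site effects, or subject-specific connectivity. Passing the
cohort-level tests therefore shows that the pipeline is correct and that
the measures separate the intended dynamical regimes — not that real
recordings of the corresponding patient groups will separate equally well.

## Numerical choices

* Feasibility threshold 1e-12 on equilibrium components; borderline
  supports count as infeasible (conservative at bifurcation boundaries).
* Stability tolerance 1e-9 on Jacobian eigenvalue real parts; eigenvalues
  inside the band trigger a marginality warning.
* Enumeration is exact over all 2^n supports (n = 7 → 128 linear solves
  per timepoint); no pruning, because frondosity and cooperation need the
  complete node set. Submatrix inverses depend only on (γ, g) and are
  cached once per connectivity, so a whole recording reuses one
  factorisation set.
* The integration oracle in the tests uses batched adaptive explicit Euler
  (step 0.05, stop when the step delta falls below 1e-12, cap 6e5 steps):
  near-marginal systems converge arbitrarily slowly, which bounds how
  tight that oracle can be made.
* Problem sizes in the test suite (100 random systems for the oracle
  suites; 15 subjects/group × 100 timepoints for the cohort property) are
  the package's chosen verification scale: large enough that the sampled
  properties are meaningful, small enough to run routinely.

## Known limitations

* Cooperation values A/B/C follow this package's explicit formalisation;
  other formalisations of the same qualitative idea would differ in scale
  (not in ordering behaviour across the archetypes).
* Criticality treats one α at a time; the distance to the nearest
  bifurcation under joint perturbations can be smaller.
* The rule inducer is deliberately modest (binary, axis-aligned
  thresholds, no rule optimisation passes); it is meant to be readable and
  seeded, not to match a mature rule-learning system feature-for-feature.
* Non-cooperative (competitive) systems, stochastic dynamics and
  continuation/bifurcation software are out of scope; `validate_system`
  rejects anything outside the supported class.
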