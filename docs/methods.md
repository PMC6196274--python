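# Methods

## The ternary logic model

Each cellular or molecular entity carries a balanced-ternary state: −1
(below typical healthy level), 0 (typical), +1 (above). The model is purely
qualitative — no kinetic parameters — and is determined by the signed,
directed interaction topology alone. Per entity the *image* (preferred next
value) is computed in three cases:

1. stimulators and inhibitors present: `pass(agg(activators), agg(inhibitors))`;
2. stimulators only: `agg(activators)`;
3. inhibitors only: `not(agg(inhibitors))`.

`agg` pools parallel inputs of one mode as the **sign of the arithmetic
sum** — a majority reading of "the target rises when stimulating signals
outnumber inhibiting ones". It is defined n-ary rather than as a fold of a
binary OR because majority aggregation is not associative. The empty pool
contributes a neutral 0, which makes the three cases special cases of one
formula, since every admissible `pass` table satisfies `pass(a, 0) = a`.

`pass` is injectable (`LogicTables`). Admissibility requires
`pass(a, 0) = a` (hence `pass(0,0) = 0`), monotone nondecreasing in the
stimulatory argument and nonincreasing in the inhibitory one. Exactly 25
3×3 tables satisfy these constraints; the default is `sign(a − i)`.
Entities with no inputs keep their current value (inertial; the shipped
network has none).

### Asynchronous dynamics

A transition moves exactly one entity one step toward its image (an entity
at −1 preferring +1 passes through 0). Among all entities whose image
differs from their value, the mover is drawn uniformly at random. States
with no movers are fixed points (steady states). Walks are capped at
10,000 steps; hitting the cap (a limit cycle or very long transient) is
recorded as non-convergence and counted as failure in treatment trials.
Per-trial random generators derive deterministically from
(base seed, batch, trial), so any single trajectory is replayable.

### The shipped network

Fifteen entities (5 cells, 10 molecules) and 50 signed edges, each carrying
a mechanism note that is also written into exported network files. Edge
highlights: the cytokine–microglia positive feedback (IL-1β/IL-6/TNF-α both
activate and are secreted by microglia and reactive astrocytes);
glucocorticoid priming of microglia and suppression of astrogliogenesis,
neurons and (via HPA feedback) cytokine-driven CORT release; BBB disruption
modeled as inhibitory endothelial→cytokine edges; T-cell Th1/Th2
polarization inhibited by cytokines, with Th2 output (IL-4) restraining
microglia and supporting astrocytic BDNF; IL-1-driven VEGF secretion as a
direct IL1b→VEGF edge alongside the astrocytic one.

Two homeostatic programs anchor the analysis: SS0 (all baseline) and the
neuroinflammatory signature SS1 (CORT, IL-1β, IL-6, TNF-α, VEGF, microglia
+1; ACh, neurons, endothelial, IL-4, T cells −1; astrocytes, BDNF, IGF-1,
CD200 unconstrained). Algebra, confirmed by enumeration: any admissible
pass table keeping SS1 fixed must have `pass(1,1) = 0` and
`pass(0,1) = −1`, and then forces the unique completion
{Astrocytes 0, IGF1 0, CD200 −1, BDNF −1}.

## Attractor enumeration and operator calibration

Enumeration scans all 3^N states in lexicographic order in vectorized
chunks (default 2^20 states per chunk; N = 15 ≈ 14.3 M states in ~15 s on
one core). Only point attractors are enumerated; cycles surface as
non-convergent walks in the dynamics module.

The default `sign(a − i)` table is an odd function, so together with the
odd sum-sign aggregation the whole image map is odd: fixed points come in
sign-mirrored pairs. Consequently the default network has **three** fixed
points — SS0, SS1, and SS1's global mirror (a biologically implausible
"anti-inflamed, hyper-healthy" profile).

`calibrate_pass_operator` searches all 25 admissible tables for a
fixed-point set matching required signatures at a required total count. An
exact prefilter (any fixed point matching a signature must be one of its
3^k completions) rejects 20 tables instantly; the five SS1-preserving
tables were each fully enumerated. Result: fixed-point counts 3–5, never
2 — every SS1-preserving table leaves at least one extra attractor (the
mirror, or an anti-inflamed variant). The package therefore keeps the
sign-difference default (it is among the minimal-count tables) and reports
the calibration finding instead of shipping a pseudo-calibrated table. The
corresponding acceptance-style test is deliberately left failing with the
enumerated extras in its message rather than weakened.

## Treatment simulation

Treatments shift chosen entities: delta mode (default) displaces by the
mode value with clipping at the ternary bounds; set mode pins the entity to
the mode value. The shift is applied once (instantaneous perturbation, no
clamping during evolution); the system then walks freely until an
attractor. Success means terminating exactly at SS0. Protocol: 1000 trials
per batch, 10 batches, reported as per-batch success fractions with mean
and standard deviation. Strategies: GRB {CORT −1}; IST {IL-1β, IL-6,
TNF-α −1}; BAA = IST ∪ {microglia −1}; IST+GRB = IST ∪ {CORT −1}.

### Why escape probabilities are near zero on this reconstruction

On the shipped 15-entity topology with sum-sign pooling, suppressing CORT
alone can *never* restore baseline, for a structural reason. While the
three cytokines sit at +1: T cells are pinned at Th1 (−1), hence IL-4 at
−1; neurons cannot exceed 0 (their inhibitor pool stays +1 and every
admissible SS1-preserving table has `pass(a, 1) ≤ 0`), hence ACh ≤ 0; so
microglia's inhibitor pool sign(IL4 + CD200 + ACh) never reaches +1 and
microglia stay active (`pass(1, i ≤ 0) = +1`). Astrocyte images are ≥ 0
throughout, so the cytokines' activator pool sign(MG + Ast) stays +1 while
their inhibitor pool sign(End) stays ≤ 0 — the cytokines are locked at +1
and the walk returns to SS1. The same lock re-ignites the cascade after
IST/BAA-style one-step shifts through the still-elevated CORT node, in
either application mode, for every admissible table (verified empirically
over all 25 tables × both modes). Escape rates on this reconstruction are
therefore ≈ 0–0.2%, far below rates reported for tighter published
circuits whose exact topology and operator tables are not fully specified;
the package reports its own computed rates and keeps the corresponding
comparison test failing by design. Delta mode is retained as the default
(the natural displacement reading); neither mode changes the structural
conclusion.

## Expression concordance statistics

Per marker gene, a two-sample pooled-variance Student t-test compares an
exposure group against control (Welch behind `equal_var=False`; the choice
matters little at n = 6). Direction follows the predicted ternary value:
right-tailed for +1, left-tailed for −1, and for predicted 0 the
complement 1 − p_two-tail (the probability of the predicted absence of
change). Degenerate inputs (both groups constant) resolve by comparing
means: equal → p_two-tail 1, else 0; one-sided 0/0.5/1 by direction.
P-values are clipped to [1e−15, 1 − 1e−15] so logs stay finite.

Brown's method pools the dependent per-gene p-values: T₀ = −2Σln pᵢ,
σ² = 4N + 2Σᵢ<ⱼ cov, cov = ρ(3.25 + 0.75ρ) for 0 ≤ ρ ≤ 1 and
ρ(3.27 + 0.71ρ) for −0.5 ≤ ρ < 0 (correlations below −0.5, common in
small-sample estimates, are clamped to −0.5 with a warning), c = σ²/4N,
and P is the upper tail of χ² with 2N/c degrees of freedom at T₀/c. With a
diagonal ρ this is exactly Fisher's method; with N = 1 it returns the
input p. ρ is estimated as the pairwise Pearson correlation over control
(saline) samples and reused for state-vs-state comparisons, where agreement
on a marker's owning entity contributes the conventional p = 0.05 and
disagreement p = 1.

Distance matrices mix three pair types: state–state and group–state as
above; group–group (needed to place multiple exposures on one map, but not
otherwise specified) uses per-gene two-tailed tests between the groups with
p = 1 − p_two-tail pooled by Brown — the natural extension of the
predicted-0 convention, so near-identical groups sit close. Aggregate P is
used raw as the distance (no log transform).

Sammon mapping minimizes E = (Σd)⁻¹ Σᵢ<ⱼ (dᵢⱼ − Dᵢⱼ)²/dᵢⱼ. Initialization
is classical metric scaling plus seeded jitter (10⁻⁴ of the mean
distance); iteration is Sammon's diagonal-Newton step scaled by a 0.3
factor with step halving so stress never increases; max 500 iterations,
stop when the stress improvement falls below 1e−9. Zero off-diagonal
distances (duplicate profiles) are jittered to 1e−6 with a warning. Three
mutually equidistant profiles embed as an equilateral triangle with stress
below 1e−6.

Signed fold change is mean(treated)/mean(control) reported as +r for
r ≥ 1 and −1/r otherwise, so |value| ≥ 1 and the sign encodes direction;
equal means sit on the positive side at +1.

## Synthetic expression generator

The generator emulates the data model the concordance statistics assume:
n = 6 samples per group (saline control plus CORT, DFP, CORT+DFP
exposures), log-normal marginals with fixed per-gene baseline means
(committed constants spanning ~40–5000 normalized counts) and a common
coefficient of variation of 0.25, and a Gaussian-copula dependence whose
log-scale correlation is pre-compensated for lognormal attenuation so the
count-scale Pearson correlation matches the target in expectation. The
default target is block-structured: 0.5 within the six pro-inflammatory
markers (IL1B, IL6, TNF, LIF, OSM, CCL2), 0.3 within the trophic block
(BDNF, IGF1, CD200, VEGFA, IL4), 0.3 between GFAP and the inflammatory
block; positive definite by construction.

Exposure effects are additive mean shifts of `effect_size × control SD ×
predicted sign` on the genes whose owning entity is nonzero in the target
state, with the concordance fraction κ choosing how many of those genes
shift (selection seeded); values clip at zero. The default design points
all exposures at the completed SS1 state: CORT alone weak and
half-concordant (0.5 SD, κ = 0.5 — perturbed but aligned with neither
program), DFP strong and fully concordant (2 SD, κ = 1), CORT+DFP slightly
stronger (2.5 SD). Group sizes and dispersions are declared assumptions of
a plausible rodent cortex RNAseq layout, not estimates of any particular
dataset.

Deliberately not emulated: count discreteness and mean–variance coupling of
sequencing data, batch effects, sex or covariate structure, gene-specific
dispersion. Passing recovery tests therefore demonstrates that the
statistical machinery detects the structure it assumes, not that real
tissue data will behave as cleanly.

Everything is deterministic given (design, seed): regenerating from a
fixture's `truth.json` reproduces the CSV byte for byte.

## Parameter-recovery behavior

Fully concordant fixtures (κ = 1, 2 SD, n = 6) yield alignment P < 0.05
against SS1 and P > 0.5 against SS0 in ≈100% of 200 seeds. Null fixtures
(no effect) show that joint pattern at roughly its chance rate (~3%), and
both alignment P values are approximately uniform — with all marker genes
truly at baseline the directional tests carry no signal in either
direction, so "alignment with the true state SS0" is *not* detectable by
this statistic; only departures from baseline are. This asymmetry is a
property of the statistic, not a bug: the predicted-0 convention
1 − p_two-tail is uniform under the null.

## Numerical and design choices, in brief

- Vectorized enumeration uses float32 matrix products for the input pools;
  exact for these small integer sums.
- Fixed points are reported in lexicographic order (−1 < 0 < +1, first
  entity most significant); enumeration is deterministic and
  chunk-size-invariant.
- Networks above 16 entities require an explicit `scan_budget` override
  (3^17 ≈ 129 M states), failing fast with a resource error instead.
- Treatment outcome standard deviation uses the sample (ddof = 1) estimator
  over batch fractions.
- The correlation estimator maps constant genes (zero variance) to zero
  correlation rather than NaN.
- Problem sizes in the test suite — 200-seed recovery loops, 1000 × 10
  Monte-Carlo protocols, full 3^15 scans — are the study-scale defaults;
  toy networks (N ≤ 4) are used wherever an independent brute-force oracle
  must be exhaustive.

## Known limitations

- The entity set is a 15-node reconstruction; published circuit diagrams
  at 13 components (with unspecified merging) and unpublished operator
  truth tables mean exact steady-state counts and treatment-escape rates
  are not directly comparable (see the calibration and treatment sections).
- Only point attractors are characterized; limit cycles are detected but
  not enumerated.
- The concordance statistics inherit the t-test's small-sample normality
  sensitivity; with n = 6 log-normal data the directional p-values are
  mildly miscalibrated in the tails.
- Aggregate-P distances are not metric (no triangle inequality); the
  Sammon map is a visualization aid, not an embedding with guarantees.
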