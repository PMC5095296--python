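# Methods

## Data model and preprocessing

Analyses operate on trial-averaged firing rates sampled every 10 ms
(`PopulationResponse`: neurons × conditions × time, with target-onset,
go-cue and movement-onset annotations).  Spike trains, when given, are
smoothed with a unit-area Gaussian kernel (s.d. 20 ms, default) and averaged
across trials; at the trial edges the kernel mass falling outside the window
is renormalized away rather than truncated, which prevents artificial rate
droop at the boundaries.

Preprocessing follows the standard population-dynamics recipe, in this
order:

1. **Soft normalization** — each neuron's trace is divided by its
   firing-rate range (max − min over all conditions and times) plus
   5 spikes/s.  Strong responders end near unity range; weak, noisy neurons
   are down-weighted rather than amplified.  Applying it twice raises, so a
   pipeline cannot silently double-normalize.  The offset is applied to the
   trial-averaged, smoothed traces.
2. **Mean centering** — at every timepoint, the mean across conditions is
   subtracted per neuron, leaving only cross-condition structure.

Two epochs anchor everything: *preparatory* = 300 ms starting 150 ms after
target onset; *movement* = 300 ms starting 50 ms before movement onset.
Epoch matrices unfold to neurons × (conditions·times), condition-major /
time-minor — fixed so PCA and correlation outputs are bit-reproducible.
Epoch covariances center rows over columns with divisor C·T − 1 (the
alignment index is a ratio, so the divisor cancels; it is fixed for
determinism).  Neurons with exactly zero rate in an epoch are flagged and
excluded from correlation analyses (correlation is undefined for them) but
retained for the epoch-preference index, where excluding them would bias the
result.

## Correlation structure and epoch preference

The pairwise correlation matrix of an epoch is the Pearson correlation
between neuron rows across the C·T epoch columns.  Similarity across epochs
is the squared Pearson correlation of the paired upper-triangle entries; its
confidence interval comes from a bootstrap that resamples *neurons* (not
pairs), respecting the dependence between pairs sharing a neuron
(1,000 resamples; pairs duplicated within a resample are dropped).  The
spread of the bootstrap distribution is reported both as s.d. and as a
2.5–97.5 percentile interval, and the full distribution is kept.

Tuning strength of neuron *i* in an epoch is the maximum over epoch
timepoints of the cross-condition rate range, divided by the neuron's
average cross-condition range over all recorded times.  ("Maximum range in
the epoch" is read as max-over-time of the per-time range, not the range of
the flattened epoch; the two are close, one is fixed for determinism.)
After normalizing each epoch's strengths by their mean across neurons
(movement activity is stronger on average; without this the index would be
offset for every neuron), the epoch-preference index is the bounded
contrast

    index_i = (Ŝ_prep,i − Ŝ_move,i) / (Ŝ_prep,i + Ŝ_move,i) ∈ [−1, 1],

zero for a neuron with the population-average ratio, ±1 for single-epoch
neurons.  This contrast form is adopted as the unique standard form
satisfying all stated properties of the index (zero at the average ratio,
correct signs, bounded); the underlying normalization admits no other
bounded symmetric contrast with those properties.

Bimodality of the index distribution is tested with Hartigan's dip
statistic, implemented here with the classical iterative convex-minorant /
concave-majorant algorithm (no suitable installed implementation exists).
The implementation was verified, case by case, against an exact oracle that
minimizes the sup-norm distance to a unimodal CDF by linear programming over
every mode placement (`tests/dip_lp_oracle.py`); frozen oracle values and a
live cross-check are in the test suite.  p-values are calibrated by
simulating uniform samples of the same size (the least-favourable unimodal
null), 10,000 bootstrap draws by default, seeded.

## Alignment index and its random-subspace null

With C_prep the preparatory-epoch covariance and D_move the top-d
movement-epoch PCs,

    A = trace(D_moveᵀ C_prep D_move) / Σ_{i≤d} σ_i(C_prep),

which is 0 when the tested span is orthogonal to the preparatory activity
and 1 when it coincides with the top-d prep-PCs.  d defaults to 10 for
data-scale analyses and to 2 for the 4-latent generator model (ten
dimensions would exhaust the model's rank and trivialize the index); d is
an explicit argument everywhere and echoed into outputs.

The null draws each surrogate basis as the QR-orthonormalization of
C_full^{1/2}·W (W standard normal), where C_full is the covariance of the
responses at *all* task times: draws concentrate on directions the
population actually visits, so the null reflects the data's dimensionality
rather than the ambient neuron count.  The observed index's percentile and
one-tailed p count null samples at or below it (misalignment direction).
The denominator is always the data quantity Σ top-d σ(C_prep), not
recomputed per draw — it is the quantity the ratio is defined against.
Tie counting uses a 1e-9 absolute tolerance: on rank-degenerate data (e.g.
the overlapping scenario, where observed and all null indices equal 1 to
machine precision) percentiles would otherwise be decided by floating-point
jitter.

## Joint subspace identification

The preparatory and movement subspaces are found simultaneously by
maximizing

    f(Q_p, Q_m) = ½ [ trace(Q_pᵀ C_prep Q_p) / Σ_{i≤d_p} σ_i(C_prep)
                    + trace(Q_mᵀ C_move Q_m) / Σ_{i≤d_m} σ_i(C_move) ]

over jointly orthonormal blocks.  The per-epoch normalization makes the
objective insensitive to the epochs' relative variance and dimensionality
(movement activity is stronger and higher-dimensional).  Defaults are
d_prep = 2, d_move = 4 for data-scale runs and 2/2 for the generator model.

**Optimizer.**  Alternating block eigen-updates: with one block fixed, the
other block's exact optimum is the span of the top eigenvectors of its
covariance compressed into the fixed block's orthogonal complement.  Each
half-step solves its subproblem exactly, so the objective is monotone
(asserted per iteration).  Convergence: relative change < 1e-10 or 500
iterations; 20 restarts by default (movement-PCs-first, preparatory-PCs-
first, then random jointly orthonormal frames), ties resolved to the highest
objective then the earliest restart.  When C_prep = C_move and
d_prep = d_move = d the optimum has the closed form
Σ_{i≤2d}σ_i / (2Σ_{i≤d}σ_i) (any split of the top-2d eigenspace attains
it), which the tests assert to 1e-8.  Axis indeterminacy within each block
is removed by rotating to the eigenbasis of QᵀCQ (descending) and making
each axis's largest-magnitude loading positive.  Any display-only rotation
of the movement plane (e.g. to exhibit rotational dynamics) leaves every
reported statistic unchanged — objective, captured variance and decoder R²
are all invariant to within-block rotations (asserted).

**Interaction with soft normalization.**  Per-neuron rescaling does not
preserve orthogonality between planted planes: two exactly orthogonal
readout planes end up a few degrees from orthogonal in analysis space.  The
jointly orthonormal optimum then provably splits the discrepancy between
the two blocks (second-order loss in each block beats a one-sided
projection), so recovered planes sit within a few degrees — not arbitrarily
close — of the planted ones after preprocessing.  Exact recovery (≪1°)
holds on raw centered readouts whose epochs each contain only their own
plane; both behaviors are asserted in the tests at their own tolerances.

## Preparatory→movement linkage

X_prep collects the preparatory-subspace state 450 ms after target onset
(one column per condition), X_move the movement-subspace state 100 ms after
movement onset.  The decoder X_move ≈ W·X_prep is fit by least squares with
no intercept — the states are cross-condition centered by preprocessing, so
the affine term is identically zero (checked at fit time in the pipeline).
R² is pooled over all matrix entries (one scalar per fit), generalization is
leave-one-condition-out (with C = 8 conditions and d_prep = 2 the fit has 8
observations per output dimension against 2 coefficients; feasibility is a
precondition), and significance comes from shuffling each preparatory
dimension's values independently across conditions and refitting
(1,000 shuffles; the tail count uses ≥, the conservative choice).

## The synthetic generator

The generator is a gated two-stage linear dynamical system:

    d/dt x_prep = J_prep x_prep + (1 − g_t) B u(c, t)
    d/dt x_move = g_t J_FF x_prep + J_move x_move

with d_prep = d_move = 2.  Inputs u*(c) are the 8 reach-target positions,
equally spaced on a 130 mm circle; u ramps from 0 to u*(c) via a Gaussian-
smoothed step (s.d. 20 ms) just after target onset.  The gate g_t is 0
before the go cue and rises as a 20 ms-s.d. smoothed step to ~1 just before
movement onset, simultaneously switching the input off and the feed-forward
transfer on, so the late preparatory state sets the amplitude and phase of
the movement oscillation.  Rates are r = L·x with L's entries i.i.d.
N(0, 50²), N = 127 neurons.  Radial targets sum to zero and the dynamics
are linear, so r is cross-condition zero-mean by construction; analyses run
on this raw linear readout (a baseline and rectification are applied only
when Poisson spike emission is requested, since mean-centering removes any
baseline anyway).

Parameter defaults, chosen once to honor the stated qualitative properties
(exact published values were not available):

| parameter | default | rationale |
|---|---|---|
| J_prep | −I₂/100 ms⁻¹ | leaky integrator, 100 ms time constant: prep state ~converged 450 ms after target onset |
| J_move | 2π·2.5 Hz rotation | pure oscillation, ~¾ cycle inside the 300 ms movement epoch |
| J_FF | I₂/50 ms⁻¹ | transfers the prep state within the ~100 ms gate window without dominating the oscillation |
| gate center / s.d. | 575 ms / 20 ms | 0 before the 500 ms go cue, >0.999 by 640 ms (movement onset 650 ms) |
| timeline | target 0, go 500, move 650, end 950 ms | fixed delay; epochs 150–450 and 600–900 ms |
| loading s.d. | 50 | stated readout scale |
| integration | forward Euler, dt = 1 ms, decimated to 10 ms | linear system, stable at default leaks; divergence guard at |x| > 1e9 |

Under these defaults the movement-epoch latent variance exceeds the
preparatory-epoch variance (×1.6), movement latents are exactly zero before
the go cue, and the post-go movement state is a fixed linear image of the
pre-go preparatory state across conditions — the three qualitative
signatures the model exists to produce.

**Scenarios.**  `orthogonal_linked` is the model itself (by default the
movement loading columns are projected off the preparatory plane so the
planted planes are exactly orthogonal; `orthogonalize=False` keeps the raw
Gaussian loading, as used for the reference alignment computation).
`overlapping` reads the movement latents out through the *same* neuron-space
plane as the preparatory latents, with the condition assignment cyclically
shifted — states change lawfully, the subspace does not.  `independent`
keeps orthogonal planes but randomly permutes the movement latents'
condition assignment, erasing the lawful linkage.  Ground-truth bases are
returned with every scenario.

**What the generator does not emulate.**  It is noiseless (no trial-to-trial
variability or sampling noise in the trial averages), has a fixed delay (no
variable-delay splicing), exactly low-dimensional latents, Gaussian i.i.d.
readout weights, and no single-neuron nonlinearities beyond optional
rectification.  Tests passing on it show the estimators are correct and
well-calibrated under the model's assumptions — orthogonality detected when
planted, linkage recovered when present, nulls not anti-conservative on
degenerate inputs — not that real recordings satisfy those assumptions.

## Pipeline and scenario classification

`run_pipeline` chains simulate → preprocess → correlate → align → identify
→ link from one config (every stochastic stage separately seeded; the
config is serialized verbatim into the report; written artifacts are
checksummed; reruns are bit-identical apart from runtimes).  The report's
scenario classification is a convenience of this software, not a scientific
claim: overlapping iff correlation-structure R² > 0.5; otherwise
orthogonal-but-linked iff the linkage beats its shuffle null at p < 0.01;
otherwise independent.  An alignment percentile < 0.05 is reported as an
additional signature flag.  The correlation split is checked first because
it is the most numerically robust discriminator on rank-degenerate
overlapping data, where the alignment percentile is a tie decided by the
1e-9 tolerance.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the generator at its study
scale (N = 127, C = 8) throughout; resampling sizes are the method defaults
(10,000-sample alignment null; 1,000-shuffle linkage null) except where a
check needs many replicates, where smaller nulls (200–500) are used per
replicate — e.g. scenario discrimination uses 100 replicates × 200-sample
nulls.  The reference alignment value for the generator model is an average
over 24 independent simulations.

## Known limitations

- The dip test's null is the uniform distribution, the standard
  least-favourable choice; heavy-tailed unimodal alternatives can inflate
  the dip slightly.
- The alternating optimizer is monotone but not globally convergent in
  theory; in practice the PCA-based restarts reach the closed-form optimum
  on every tested instance, and random restarts guard the rest.  Any
  optimizer reaching the same objective within 1e-6 is equivalent for all
  downstream quantities.
- With C = 8 conditions the linkage shuffle null has 8!² ≈ 1.6e9 nominal
  permutations but only 8! distinct per-row arrangements matter jointly;
  p-values below ~1e-3 should be read as "smaller than resolvable".
- `state_at` snaps off-grid readout times to the nearest 10 ms sample (with
  a warning) rather than interpolating.
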