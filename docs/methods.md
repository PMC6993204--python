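# Methods

This note documents the models, conventions and numerical choices
behind `needledrive`, in the package's own terms.

## Task and data model

A needle-driving trial is one throw of a curved suturing needle
through a planar soft-tissue phantom, recorded as synchronized time
series of tooltip position (m), orientation (unit quaternion,
scalar-first), gripper state, and tissue-interaction force (N) and
torque (N·m) measured by a 6-axis sensor under the tissue.  The tissue
frame is right-handed with `z` along the surface normal.  Open-
instrument trials are acquired at 120 Hz (magnetic tracking), teleoperated
trials at 500 Hz (robot side).  Tissue geometry — surface frame,
outline polygon, entrance point, desired and actual exit points — is an
input; in the original apparatus the actual exit point comes from
fixed cameras, which exist only in the teleoperation setup, so
exit-point error and total normalized force are defined there only and
are reported as explicit missing values elsewhere.

## Preprocessing

* Resampling to 100 Hz: shape-preserving piecewise-cubic (PCHIP)
  interpolation for position/force/torque; per-interval spherical
  linear interpolation for quaternions after enforcing sign continuity
  (dot(q_n, q_{n+1}) ≥ 0), which prevents spurious 2π-complement
  rotations from the double cover; zero-order hold (nearest-previous)
  for the categorical gripper channel.  The new grid spans only the
  original time support — no extrapolation.  Resampling at the same
  rate twice is idempotent.
* Filtering: 2nd-order Butterworth, 10 Hz design cutoff, applied
  forward and backward (zero phase).  The double pass squares the
  magnitude response, moving the empirical −3 dB point to 8 Hz (the
  analog prototype gives 10·(√2−1)^{1/4} ≈ 8.02 Hz; the discrete
  bilinear design at 100 Hz sampling lands at ≈ 8.1 Hz).  Edge transients are
  suppressed with reflective padding of 3× the filter order; series
  shorter than the pad are rejected.  Time-reversal symmetry holds
  once edge transients (~0.5 s) have decayed.
* Derivatives: central differences at 0.01 s steps, re-filtered with
  the same filter after every differentiation.  Interior samples are
  exact for low-order polynomials; the edges carry transient error,
  so assertions about derivatives are interior-only.

## Segmentation

Trial bounds are the first and last samples satisfying **both**
|f| > 0.06 N (the force sensor's noise threshold) and in-contour
projection of the tooltip — the conjunction rejects accidental
contacts with the fixture.  Driving samples require a closed gripper
(threshold 0.5 on the gripper channel; the hardware reports no
canonical value, so it is a config parameter) and supra-threshold
force.  Maximal driving runs are ordered in time: first run insertion,
last run extraction, intermediate runs correction iff the run-mean
tooltip position projected to the surface plane is nearer the entrance
than the exit (the run mean is our choice of statistic; a per-sample
rule would fragment runs).  A single continuous run is insertion —
insertion always exists, extraction may merge into it.  When an
intermediate run sits nearer the exit it is classed extraction-like,
but the *final* run always wins the extraction label ("last-run wins");
the precedence between recency and proximity is genuinely open and
this package fixes it this way.  Indices are 0-based with inclusive
bounds throughout.  Manually validated bounds can be supplied as an
override table keyed by trial id, mirroring a manual-validation pass
without a GUI.

## Metrics

All per-trial metrics are computed on the insertion subtask by default
(any segment is selectable); force metrics integrate over the whole
bounded trial.

* Time integrals (total normalized force, RMS jerk) are evaluated with
  trapezoidal quadrature of the sampled integrand — the discrete
  right-endpoint sums often written for these quantities differ by
  O(Δt) at the ends; the trapezoid is the standard consistent choice.
* Plane fit: ordinary regression of z on (x, y) is the field
  convention, but it is undefined when the movement plane is (near-)
  vertical — exactly the geometry of an ideal insertion arc, whose
  horizontal footprint is a line.  The default mode therefore falls
  back to the orthogonal (total-least-squares, SVD) plane on a
  degenerate horizontal footprint; the strict OLS mode raises.  The
  TLS plane is also the one under which plane/circle deviation are
  exactly invariant to rigid motions of the scene; the OLS plane is
  only approximately so, because vertical-distance regression is
  orientation dependent.  Reported point-to-plane distances are
  orthogonal in every mode.
* Circle fit: algebraic (Kåsa) least squares on the in-plane
  projection seeds a Levenberg–Marquardt refinement of center and
  radius on the radial residuals.  Arc angles are unwrapped; the
  total arc path Θ_arc = r·|Δθ_arc| uses the *fitted* radius by
  default (self-contained when the true needle radius is unknown) with
  an optional nominal needle radius.  Circle deviation sums s²·|Δθ|
  over samples and divides by Θ_arc; it scales linearly under spatial
  scaling, plane deviation quadratically, angular path inversely.
* Max torque about the tissue normal uses |τ_z|, making the metric
  sign-invariant: ideal needle driving is planar, so any rotation
  about the normal is equally wrong in either direction.
* Consistency: profiles (3-DOF force or position over the insertion
  subtask of 5 consecutive trials) are aligned by unconstrained DTW
  with squared-Euclidean local cost and symmetric steps; the medoid
  (minimum summed DTW cost) provides the common time base, each
  profile is warped onto it (samples matched to the same medoid index
  are averaged), and the score is (1/N_t)·ΣᵢΣₙ‖pᵢ(n) − mean(n)‖² —
  zero iff all profiles coincide after alignment.  The notation
  (|·|₂)² sometimes used for this quantity is read as a squared norm
  (sum of squared distances), not a 4th power.
* Curvature and torsion come from the filtered kinematic chain:
  κ = |v×a|/|v|³, τ = ((v×a)·j)/|v×a|².  Samples with |v| < 1e−4 m/s
  or |v×a| < 1e−12 are flagged invalid rather than raising; the power-
  law regression additionally drops |τ| < 1e−6 1/m, because log|τ| is
  unbounded near zero, and requires ≥ 10 valid samples.
* RMS jerk √((1/T)∫‖x⃛‖²dt) has units of jerk and is only weakly
  correlated with completion time; it spans orders of magnitude, so
  tables carry log₁₀ of it.  It scales as c⁻³ under time dilation.

## Statistics

Stage values are medians of 5-trial blocks (the metrics are mostly
non-normal): open1-late, tele-early, tele-late, open2-early.  The
three contrasts — learning (tele-late − tele-early), aftereffect
(open2-early − open1-late), final performance (tele-late −
open1-late) — are per-participant differences, tested per condition
with a two-sided Wilcoxon signed-rank (exact zeros dropped first, the
classic convention; exact null for small tie-free samples, tie-
corrected normal approximation otherwise), compared across the three
feedback conditions with a tie-corrected Kruskal–Wallis H against a
χ²(k−1) reference, and summarized with a percentile bootstrap CI of
the median difference.  The bootstrap resamples participants (the
exchangeable unit), B = 10000 by default, deterministic under seed.
Note the percentile bootstrap of a median under-covers at small n:
simulation at n = 10 gives ≈ 92% coverage for the nominal 95%
interval.  No multiple-testing correction is applied by default; a
Benjamini–Hochberg option exists.  Pairwise entries accompanying the
Kruskal–Wallis table are the difference of group medians with a
two-sided Mann–Whitney p — this package's own definition of the
pairwise comparison.

Quarantine: any trial failing preprocessing, segmentation or scoring
is logged and skipped; a stage left with fewer than 5 trials becomes
missing for that participant only.

## Synthetic data

The generator emulates what the analysis assumes, not tissue physics:

* Ideal insertions lie exactly on a circle of the needle's radius
  (default 12 mm — the arc radius of a large semicircular suturing
  needle; a config value, not a constant) swept with a minimum-jerk
  angular profile, orientation rotating with the arc tangent.
* Full trials follow a subtask schedule (default 0.5 s approach, 3 s
  insertion, 1 s repositioning, 1 s extraction, 0.5 s retreat) with
  the qualitative force phases of the task: correlated horizontal
  components along the entrance–exit chord and a vertical sign
  reversal halfway through insertion, transient sub-threshold forces
  while repositioning, vertical-dominant extraction.  Waveforms are
  smooth sinusoidal envelopes with a floor that keeps driving samples
  above the 0.06 N threshold; outside driving subtasks the force
  magnitude stays below it by construction.  Noise defaults (0.2 mm
  positional, 0.3 mm out-of-plane ripple, 0.5 mm radial wobble,
  5 mN force) are on the scale of the magnetic tracker and force
  sensor.  Exit points scatter around the desired exit with 2 mm
  in-plane sd (the exit-marker scale), clamped to the needle's reach.
* Power-law trajectories time-reparameterize an analytic elliptic
  helix with a small axial ripple (curvature and torsion closed-form,
  both bounded away from zero) so the sampled speed satisfies
  v = ακ^β|τ|^γ exactly; velocity, acceleration and jerk come from
  the chain rule, so a downstream fit recovers (α, β, γ) to machine
  precision.  The ripple amplitude is kept small (d = 1 mm, k = 2)
  because larger ripples drive the torsion through zero, where
  |τ|^γ is singular.
* Cohorts: 3 conditions × 10 participants × 120 trials (4 open + 6
  teleoperation + 2 open blocks of 10).  Learning effects are
  additive on the log scale for strictly positive metrics (keeping
  them positive) and accrue linearly over the teleoperation phase;
  defaults inject learning in completion time (0.45), total
  normalized force (0.35) and the two consistency metrics, with
  between-participant sd 0.25 and trial sd 0.35 — effect-to-noise
  ratios that make the learning contrast comfortably detectable at
  n = 10, as in the modeled study design.  Two tiers exist: the
  signal tier synthesizes full 6-DOF recordings (used end to end at
  small cohort sizes), and the metrics tier draws per-trial metric
  values directly from the same effect model for statistical
  calibration at scale (in this tier the consistency metrics are
  drawn per trial like any other metric).  Everything is
  bit-reproducible under a fixed seed.

What the generator does **not** emulate: tissue deformation mechanics
and force-deflection behavior, visual feedback, hand tremor spectra,
participant strategy changes, or any coupling between kinematic noise
and force.  Passing tests therefore validate the *pipeline* —
formulas, segmentation logic, statistical calibration — not claims
about real surgical recordings.

## Problem sizes

The test suite runs signal-level cohorts of 6 participants × 15
trials and statistical calibration on 100 metric-tier replicate
cohorts (30 × 120 each); the acceptance script uses 12 generated
trials for segmentation accuracy and 60 replicate cohorts per
calibration arm.  These sizes give stable estimates (binomial se of a
5% rate at 180 cells ≈ 1.6%) while keeping a full run in the minutes
range on one CPU.

## Known limitations

* The OLS plane fit reproduces the field convention but is not
  rotation-invariant for noisy paths; use TLS mode when invariance
  matters.
* DTW alignment to the medoid is one of several reasonable mean-
  profile constructions; scores are comparable within a convention,
  not across conventions.
* The signed-rank test's exact distribution is used only in the
  tie-free small-sample regime; heavily tied data fall back to the
  normal approximation.
* Percentile bootstrap CIs under-cover at n = 10 (see above).
* Synthetic force magnitudes are free parameters; only the phase
  structure is meaningful.
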