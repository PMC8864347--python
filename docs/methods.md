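# Methods

## The model

A recorded session is a list of tic onset times inside a fixed observation
window (nominally 300 s). The method scores the temporal *disorder* of that
list by turning it into a one-dimensional random walk and measuring the
walk's fractal dimension.

**Tic-modulated walk.** The walker starts at x = 0 with velocity +1
position unit per second and advances on a 0.1 s grid (N = 3000 steps for a
300 s session). At each step the velocity either persists or reverses. For
the tic-modulated walk the turn "probability" is the binary tic indicator:
the velocity reverses exactly in the bins that contain a tic, so the walk
is a deterministic function of the tic train. Two stochastic reference
walkers bracket the behaviour:

* **ballistic** (turn probability p = 0): a straight line; the zero-tic,
  maximally ordered limit;
* **Brownian** (p = 0.5): a fair coin every step; the maximally chaotic
  limit in which tic and no-tic are equally likely at every instant.

**Spectral density.** The trajectory is treated as the point set
{(t_j, x_j)} in the plane. Both axes are first normalized — t by the
session span, x by the walker's maximum absolute displacement — so that
rotations mix commensurate coordinates and the statistic is independent of
physical units. For frequency f and orientation θ,

    S(f, θ) = | (1/N) Σ_j exp( i f (cos θ · t̃_j + sin θ · x̃_j) ) |²,

and S_f is the average over n_θ = 180 orientations evenly spaced on
[0, 2π). S_f is 1 at f → 0, lies in [0, 1], and is invariant to translating
the trajectory and to rotating it by grid multiples. Because
S(f, θ+π) = S(f, θ), an even orientation grid is evaluated on half the
angles with an identical result.

**From slope to dimension.** On a log-spaced grid above the fundamental
f₀ = 2π/√2 of the normalized frame, log S_f falls linearly in log f over a
wide window, and the slope encodes the roughness of the walk. For the
self-affine graph of a constant-step walk with Hurst-type roughness
exponent H, the statistic decays as f^−(2−H): measured slopes are −1.00 for
the ballistic line (H = 1) and −1.50 for the Brownian ensemble (H = 1/2).
The reported dimension is an affine map of the slope, **anchored
empirically, never hard-coded**: the calibration requires the ballistic
walker to land at D_f = 2 and the Brownian ensemble mean at D_f = 1, both
within ±0.2. With the measured slopes this forces the coefficient-2 map
D_f = 2·slope + c (equivalently D_f = 2H), with the offset c fixed by the
anchors. Severe, chaotic tic timing therefore scores near 1; sparse,
ordered timing near 2.

## Calibration

`calibrate_convention` computes S_f for the ballistic walk and for a seeded
ensemble of M ≥ 100 Brownian walks, then

1. enumerates every contiguous window of ≥ 8 grid frequencies on which the
   ballistic curve is a clean power law (OLS r² ≥ 0.98), widest first;
2. for each window, fits both anchor slopes and searches the affine family
   D_f = a·slope + c, a ∈ {±1, ±2}, with c chosen to centre the two
   anchors; the first (widest) window whose best map puts both anchors
   within ±0.2 is accepted;
3. persists the window, the map, both slopes and both anchor dimensions as
   a JSON record.

The offset is the only free continuous parameter, so the calibration is a
genuine two-point check: it succeeds only if the ballistic and Brownian
slopes differ by ≈ 1/|a|. If no window and map satisfy both anchors the
calibration fails loudly with both slopes in the error. At the default
settings the accepted window is ≈ [f₀, 39 f₀] and the anchors land at
≈ 1.93 and ≈ 1.07.

Session estimates (`estimate_df`) always use a calibration record — the
same window and map for every session — so anchor calibration and cohort
scoring can never drift apart. The CLI enforces this by refusing to score
sessions without a record.

## Numerical choices and edge cases

* **Frequency grid**: 64 log-spaced frequencies over 2.5 decades above f₀.
  The grid is fixed by the normalized frame, not per trajectory, so one
  calibrated window applies to all sessions.
* **Orientation grid**: θ_k = 2πk/180 including 0. Doubling to 360 angles
  changes S_f by < 1% RMS wherever the grid resolves the angular structure
  — everywhere on the fit window for Brownian-like walks, and below
  ≈ 20 f₀ for the ballistic line. The ballistic line is the worst case: it
  carries a spike of angular width ~1/f at the orientation perpendicular
  to itself (where all points project together and S → 1), which no
  ~180-point grid resolves at the top of the frequency range; a 360-angle
  grid even samples that orientation exactly. All estimates therefore use
  one fixed n_θ, and the calibration belongs to that n_θ.
* **Fit**: unweighted OLS of log₁₀ S_f on log₁₀ f. Exact zeros of S_f are
  dropped with a warning; fewer than 8 usable frequencies is an error.
* **Discretization**: an event at time t activates bin ⌊t/dt⌋; the window
  is half-open [0, duration). Multiple tics in a bin collapse to one
  reversal, because the turn rule is binary.
* **Walk start**: the initial direction is +1; a tic in the very first bin
  coincides with the start, has no prior velocity to reverse, and is
  ignored.
* **Degenerate sessions**: a walker that never leaves one step's reach of
  the origin (e.g. a tic in every bin, oscillating in place) has no usable
  spatial structure. Its spectrum is still computed but the estimate
  carries a `degenerate` flag, and group statistics exclude and count such
  sessions.

## Synthetic data

No clinical recordings ship with the package, so the generator stands in
for them and defines the conditions under which the pipeline is tested.

* **Train cascade**: episode onsets are Poisson; each episode holds a
  geometric number of bouts (mean 1.5, exponential gaps of mean 8 s); each
  bout a geometric number of tics (mean 2.5, exponential gaps of mean
  0.7 s). Counts and gaps are chosen for closed-form expectations:
  E[count] = rate · duration · bouts · tics. Within a 300 s session the
  visible clustering is bout-scale; hour-scale episode grouping lies beyond
  one session, which is why the per-session cascade keeps episodes small
  and frequent rather than deep.
* **Severity**: a latent 0–50 score (a stand-in for a clinician-rated
  total tic score; no clinical meaning claimed). Clinical frequency
  scoring is banded roughly logarithmically in rate, so the score acts
  log-linearly on the episode rate: 0.0133·e^(0.06·s) episodes/s, i.e.
  ≈ 15 expected tics per session at severity 0 up to ≈ 300 at severity 50.
  This spans the dimension estimate's sensitive range and makes the mean
  D_f response approximately linear in severity (≈ 2.0 down to ≈ 1.55).
* **Cohort**: 78 subjects by default (the scale of the clinical screening
  cohort), screening severity ~ N(25, 9) clipped to [3, 48], 12-month
  change ~ N(−4, 9), two visits × four conditions. Suppression conditions
  scale the rate multiplicatively: verbal 0.6, DRO 0.4, NCR 0.85, baseline
  1.0.
* **Raters**: a second rater is emulated by independent misses (default
  probability 0.05 in the robustness experiments), Gaussian onset jitter
  (0.05 s) and optional Poisson false alarms. With all parameters zero the
  model is the identity.

What the generator does **not** emulate: premonitory-urge dynamics, reward
learning within a session, hour-to-month self-similarity, rater biases
that correlate with condition, or any true mapping between the latent
score and a clinical scale. Passing tests therefore show that the pipeline
recovers directions and orderings its own generator encodes — not that the
clinical effect sizes are reproduced.

## Group statistics

* **Change correlation**: per subject, baseline-condition D_f change
  between visits against severity change; Pearson r with the two-sided
  t-test on n−2 df. Zero-variance change scores are flagged, not computed.
* **Condition summary**: per-condition mean D_f with t-based 95% CIs;
  singleton cells flagged.
* **Repeated-measures ANOVA**: one-way within-subjects across conditions
  (per visit), F = MS_condition/MS_error on (k−1, (n−1)(k−1)) df;
  incomplete subjects dropped with a warning. The implementation is
  statsmodels' AnovaRM; the test suite cross-checks it against hand-coded
  sums of squares and a within-subject permutation null.
* **Inter-rater agreement**: Pearson r of D_f over sessions matched on
  (subject, visit, condition).

p-values are descriptive; no multiplicity correction is applied.

## Study sizes used by the test suite

Anchor checks run at the full settings (180 angles, 64 frequencies,
N = 3000; Brownian ensembles of 100). The severity-recovery experiment
uses 40 subjects; the suppression experiment 78 subjects at one visit; the
inter-rater experiment 100 sessions spanning the severity range and all
four conditions. The ANOVA type-I calibration (200 null cohorts of 6
subjects × 4 conditions) runs at reduced spectral settings (24 angles,
48 frequencies): under the null the estimate only needs to be exchangeable
across conditions, not accurate. The monotonicity-in-p sweep runs at full
settings because narrow reduced-settings fit windows probe only the
largest-scale part of the curve, where mean D_f is no longer monotone in
the turn probability.

## Known limitations

* D_f is genuinely sensitive to small timing perturbations: displacing one
  reversal offsets the whole remaining path, and a missed tic mirrors it.
  Under 0.05 s jitter alone the paired D_f difference between raters has
  sd ≈ 0.12; inter-rater correlation is high only because true
  between-session spread is larger.
* The slope→dimension convention is empirical by design. It holds at the
  calibrated settings; changing n_θ, the grid or the normalization
  requires recalibration (the CLI workflow enforces this).
* The generator's cascade covers second-to-minute clustering only; nothing
  here speaks to day- or month-scale self-similarity.
* With fewer than ~10 tics a session is nearly ballistic and D_f saturates
  near 2; with more than ~300 it approaches the Brownian floor. Outside
  that range the score discriminates poorly.
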