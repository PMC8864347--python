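# ticwalk

Fractal-dimension severity scoring of tic time series.

Tics — brief, purposeless movements or vocalizations in Tourette syndrome
and provisional tic disorder — arrive in bursts: bouts of several tics
within seconds, separated by longer quiet intervals, with similar grouping
at larger timescales. `ticwalk` quantifies how *disordered* a recorded
session's tic timing is with a single number, the fractal dimension
**D_f**, and provides the group statistics needed to relate it to severity,
suppression condition and rater.

## The method

1. **Velocity-reversal walk.** Tic onset times within a session (nominally
   300 s) are binned on a 0.1 s grid. A walker starts at x = 0 with
   velocity +1 unit/s and reverses velocity exactly in the bins that
   contain a tic — the walk is a deterministic transform of the tic train.
   Two reference walkers bracket it: *ballistic* (turn probability 0, the
   zero-tic limit) and *Brownian* (turn probability 0.5 each step, the
   maximally chaotic limit).
2. **Orientation-averaged spectral density.** The trajectory, as a point
   set in the normalized (t, x) plane, is rotated through 180 angles θ and

       S_f = ⟨ | (1/N) Σ_j exp(i f (cosθ·t̃_j + sinθ·x̃_j)) |² ⟩_θ

   is evaluated on a log-spaced frequency grid.
3. **Calibrated slope → D_f.** log S_f is linear in log f over a wide
   window; an affine map of the slope — anchored so that the ballistic
   walker scores D_f ≈ 2 and the Brownian ensemble mean D_f ≈ 1 — gives
   the session's dimension. More chaotic (more severe) tic timing scores
   closer to 1, sparser and more ordered timing closer to 2.

The anchoring is empirical and explicit: `calibrate_convention` selects the
fit window (the widest log-frequency interval on which the ballistic curve
is a clean power law) and the slope map from the two reference walkers, and
persists them as a JSON record that every session estimate then reuses.
See `docs/methods.md` for the model, the calibration procedure and the
generator that stands in for clinical recordings (which are not deposited).

## Worked example

```python
import numpy as np
from ticwalk import (SpectralSettings, calibrate_convention,
                     TicEventSeries, estimate_df)

settings = SpectralSettings()            # 0.1 s grid, 300 s, 180 angles
record = calibrate_convention(settings, seed=0)
print(f"anchors: ballistic {record.D_f_ballistic:.3f}, "
      f"Brownian {record.D_f_brownian:.3f}")

rng = np.random.default_rng(0)
session = TicEventSeries("child01", "screening", "baseline", "r1", 300.0,
                         np.sort(rng.uniform(0, 300, 40)))
est = estimate_df(session, settings, record)
print(f"D_f = {est.D_f:.3f} (fit r^2 = {est.fit_r2:.3f}, "
      f"{est.n_points} freqs)")
```

prints

```
anchors: ballistic 1.932, Brownian 1.068
D_f = 1.603 (fit r^2 = 0.992, 41 freqs)
```

The two anchors sit near 2 and 1 as required, and a session with 40
uniformly scattered tics lands in between — more chaotic than an ordered
train, far from the coin-flip limit. Lower D_f means more severe,
more Brownian-like tic timing.

The same pipeline from the shell:

```
ticwalk calibrate --out calib.json --seed 0
ticwalk simulate --out sessions.csv --severity-out severity.csv --seed 1
ticwalk df --sessions sessions.csv --calibration calib.json --out results.csv
ticwalk cohort --results results.csv --severity severity.csv
```

`simulate` generates a synthetic cohort (bursty tic trains driven by a
latent severity score, visits × suppression conditions), `df` scores every
session, and `cohort` reports the severity-change correlation, the
per-condition D_f summary, a repeated-measures ANOVA across suppression
conditions and, when two raters are present, their agreement.

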