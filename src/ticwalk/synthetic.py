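"""Synthetic tic trains, cohorts and rater noise.

Clinical tic recordings show bursty, multi-timescale clustering: several
tics a few tenths of a second to a couple of seconds apart form a *bout*,
bouts recur in grouped *episodes*, and episodes are separated by longer
tic-free intervals. Within a 300 s session two of those timescales are
observable, so trains are generated by a three-level renewal cascade:

* episode onsets follow a Poisson process (``episode_rate``);
* each episode contains a geometric number of bouts (mean
  ``mean_bouts_per_episode``) separated by exponential gaps (mean
  ``within_episode_gap_s``);
* each bout contains a geometric number of tics (mean
  ``mean_tics_per_bout``) separated by exponential gaps (mean
  ``within_bout_gap_s``).

Geometric counts and exponential gaps keep the expected event count in
closed form: rate * duration * bouts * tics, ignoring end-of-window
truncation.

Cohorts carry a latent per-subject severity score on a 0-50 scale (a
stand-in for a clinician-rated total tic score, with no claim of clinical
meaning); severity maps monotonically to the episode rate, and suppression
conditions scale the rate by factors <= 1. A simple observation model
(misses, uniform false alarms, Gaussian onset jitter) emulates a second,
independent rater.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .session_io import TicEventSeries, Visit, Condition

__all__ = [
    "TicTrainParams",
    "NormalSpec",
    "CohortSpec",
    "RaterModel",
    "severity_to_params",
    "generate_tic_train",
    "generate_cohort",
    "apply_rater",
]

# severity -> episode rate map: exponential, strictly increasing. Clinical
# frequency scoring is banded roughly logarithmically in tic rate, so the
# latent 0-50 score maps log-linearly onto episode rate: ~15 expected tics
# per 300 s baseline session at severity 0 up to ~300 at severity 50, which
# spans the dimension estimate's sensitive range (within a 300 s window the
# visible clustering is bout-scale; hour-scale episode grouping is beyond
# one session).
_RATE_AT_ZERO = 0.0133
_LOG_RATE_PER_POINT = 0.06

DEFAULT_CONDITION_EFFECTS = {
    Condition.BASELINE: 1.0,
    Condition.VERBAL: 0.6,
    Condition.DRO: 0.4,
    Condition.NCR: 0.85,
}


@dataclass
class TicTrainParams:
    """Parameters of the three-level bursty train generator."""

    episode_rate: float = 0.05
    mean_bouts_per_episode: float = 1.5
    mean_tics_per_bout: float = 2.5
    within_bout_gap_s: float = 0.7
    within_episode_gap_s: float = 8.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.episode_rate < 0:
            raise ValueError(f"episode_rate must be >= 0, got {self.episode_rate}")
        if self.mean_bouts_per_episode < 1 or self.mean_tics_per_bout < 1:
            raise ValueError("mean bout/tic counts must be >= 1")
        if self.within_bout_gap_s <= 0 or self.within_episode_gap_s <= 0:
            raise ValueError("gap means must be positive")
        if self.within_bout_gap_s >= self.within_episode_gap_s:
            raise ValueError(
                "within_bout_gap_s must be < within_episode_gap_s "
                "(timescale separation)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def expected_count(self) -> float:
        """Expected tics per session, ignoring end-of-window truncation."""
        return (self.episode_rate * self.duration_s *
                self.mean_bouts_per_episode * self.mean_tics_per_bout)


@dataclass
class NormalSpec:
    """A clipped normal distribution spec for latent cohort quantities."""

    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, size=n), self.lo, self.hi)


@dataclass
class CohortSpec:
    """A synthetic cohort: subjects with latent severity, visits x conditions.

    Severity is drawn per subject at screening, a 12-month change is added,
    and each (visit, condition) session's episode rate is the severity map
    times the condition's multiplicative factor (<= 1 for suppression).
    """

    # default cohort size mirrors the clinical screening cohort (78 children)
    n_subjects: int = 78
    severity_baseline: NormalSpec = field(
        default_factory=lambda: NormalSpec(25.0, 9.0, 3.0, 48.0))
    severity_change: NormalSpec = field(
        default_factory=lambda: NormalSpec(-4.0, 9.0))
    condition_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_EFFECTS))
    conditions: tuple = (Condition.BASELINE, Condition.VERBAL,
                         Condition.DRO, Condition.NCR)
    visits: tuple = (Visit.SCREENING, Visit.TWELVE_MONTH)
    duration_s: float = 300.0
    severity_floor: float = 2.0
    severity_ceiling: float = 50.0
    rater_id: str = "r1"
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError(
                f"n_subjects must be >= 2 for group statistics, "
                f"got {self.n_subjects}")
        self.conditions = tuple(Condition(c) for c in self.conditions)
        self.visits = tuple(Visit(v) for v in self.visits)
        self.condition_effects = {Condition(k): float(v)
                                  for k, v in self.condition_effects.items()}
        for cond in self.conditions:
            fac = self.condition_effects.get(cond)
            if fac is None:
                raise ValueError(f"no condition factor for {cond.value}")
            if cond is not Condition.BASELINE and fac > 1.0:
                raise ValueError(
                    f"suppression factor for {cond.value} must be <= 1, got {fac}")


@dataclass
class RaterModel:
    """Observation noise of one rater: misses, false alarms, onset jitter.

    With every parameter at zero the model is the identity.
    """

    miss_prob: float = 0.0
    false_alarm_rate: float = 0.0
    jitter_sd_s: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError(f"miss_prob must be in [0, 1], got {self.miss_prob}")
        if self.false_alarm_rate < 0 or self.jitter_sd_s < 0:
            raise ValueError("false_alarm_rate and jitter_sd_s must be >= 0")


def severity_to_params(severity: float, duration_s: float = 300.0,
                       seed: int = 0,
                       rate_factor: float = 1.0) -> TicTrainParams:
    """Map a latent severity score (0-50 scale) to train parameters.

    The episode rate increases exponentially with severity (the score acts
    log-linearly on rate, mirroring frequency-banded clinical scoring);
    bout/tic structure is held fixed so severity acts purely through how
    often tic episodes occur. ``rate_factor`` scales the rate
    multiplicatively (suppression conditions).
    """
    if severity < 0:
        raise ValueError(f"severity must be >= 0, got {severity}")
    rate = _RATE_AT_ZERO * np.exp(_LOG_RATE_PER_POINT * severity) * rate_factor
    return TicTrainParams(episode_rate=rate, mean_bouts_per_episode=1.5,
                          mean_tics_per_bout=2.5, within_bout_gap_s=0.7,
                          within_episode_gap_s=8.0, duration_s=duration_s,
                          seed=seed)


def generate_tic_train(params: TicTrainParams,
                       subject_id: str = "sim",
                       visit: Visit = Visit.SCREENING,
                       condition: Condition = Condition.BASELINE,
                       rater_id: str = "r1") -> TicEventSeries:
    """Draw one bursty tic train from the three-level cascade."""
    rng = np.random.default_rng(params.seed)
    events: list[float] = []
    if params.episode_rate > 0:
        t = rng.exponential(1.0 / params.episode_rate)
        while t < params.duration_s:
            bout_start = t
            n_bouts = rng.geometric(1.0 / params.mean_bouts_per_episode)
            for b in range(n_bouts):
                if b > 0:
                    bout_start += rng.exponential(params.within_episode_gap_s)
                tic_t = bout_start
                n_tics = rng.geometric(1.0 / params.mean_tics_per_bout)
                for k in range(n_tics):
                    if k > 0:
                        tic_t += rng.exponential(params.within_bout_gap_s)
                    if tic_t < params.duration_s:
                        events.append(tic_t)
            t += rng.exponential(1.0 / params.episode_rate)
    return TicEventSeries(subject_id=subject_id, visit=visit,
                          condition=condition, rater_id=rater_id,
                          duration_s=params.duration_s,
                          event_times_s=np.sort(np.asarray(events)))


def generate_cohort(spec: CohortSpec):
    """Generate a cohort of sessions plus the latent severity table.

    Returns ``(series_list, severity_table)`` where the table has one row per
    (subject, visit) with the latent severity in effect at that visit.
    Fully reproducible from ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    master = np.random.default_rng(root.spawn(1)[0])
    base = spec.severity_baseline.sample(master, spec.n_subjects)
    change = spec.severity_change.sample(master, spec.n_subjects)
    followup = np.clip(base + change, spec.severity_floor, spec.severity_ceiling)

    series_list: list[TicEventSeries] = []
    sev_rows = []
    subject_seeds = root.spawn(spec.n_subjects)
    for s in range(spec.n_subjects):
        sid = f"S{s:03d}"
        sev_by_visit = {Visit.SCREENING: float(base[s]),
                        Visit.TWELVE_MONTH: float(followup[s])}
        session_seeds = subject_seeds[s].spawn(len(spec.visits) * len(spec.conditions))
        k = 0
        for visit in spec.visits:
            sev = sev_by_visit[visit]
            sev_rows.append((sid, visit.value, sev))
            for cond in spec.conditions:
                seed = int(session_seeds[k].generate_state(1)[0] % 2 ** 31)
                k += 1
                params = severity_to_params(
                    sev, duration_s=spec.duration_s, seed=seed,
                    rate_factor=spec.condition_effects[cond])
                series_list.append(generate_tic_train(
                    params, subject_id=sid, visit=visit, condition=cond,
                    rater_id=spec.rater_id))
    severity_table = pd.DataFrame(sev_rows,
                                  columns=["subject_id", "visit", "severity"])
    return series_list, severity_table


def apply_rater(series: TicEventSeries, model: RaterModel,
                rater_id: Optional[str] = "r2") -> TicEventSeries:
    """Pass a ground-truth train through one rater's observation model.

    Each true event is kept with probability 1 - miss_prob and its onset
    jittered by centred Gaussian noise (clipped to the window); false alarms
    are added as a homogeneous Poisson process.
    """
    rng = np.random.default_rng(model.seed)
    t = series.event_times_s
    kept = t[rng.random(t.size) >= model.miss_prob]
    if model.jitter_sd_s > 0 and kept.size:
        kept = kept + rng.normal(0.0, model.jitter_sd_s, size=kept.size)
        kept = np.clip(kept, 0.0, np.nextafter(series.duration_s, 0.0))
    n_fa = rng.poisson(model.false_alarm_rate * series.duration_s)
    fa = rng.uniform(0.0, series.duration_s, size=n_fa)
    out = np.sort(np.concatenate([kept, fa]))
    return TicEventSeries(
        subject_id=series.subject_id, visit=series.visit,
        condition=series.condition,
        rater_id=series.rater_id if rater_id is None else rater_id,
        duration_s=series.duration_s, event_times_s=out)
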