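"""Synthetic visual-search cohort generator.

Emulates the museum-style experiment: six-face circular displays, 40%
no-target (all-neutral) displays, 60% with one angry or happy deviant at a
uniform position, a fixed per-participant emotional-intensity level
(difficulty 80/90/100), a run-until-20-correct stopping rule, and
re-presentation ("recycling") of errored displays at a random later point.

Each trial's (correctness, RT) pair is drawn from a drift-diffusion process
whose effective parameters depend on the display cell (difficulty x trial
type) and on the lag state: the distance d since the most recent error,
counted only through correct trials (a new error resets the count), with
configurable additive offsets on (a, v, T_er) for d = 1..5 and an extra
drift offset at d = 1 keyed by the emotion of the errored display.
Distances beyond 5 (or no prior error) use baseline parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .ddm import DDMParams, FirstPassageSampler
from .io import DIFFICULTIES, SCHEMA, TRIAL_TYPES

MAX_LAG = 5

__all__ = ["CohortConfig", "GenerativeParams", "default_generative_params",
           "simulate_cohort"]


@dataclass(frozen=True)
class CohortConfig:
    """Paradigm-level settings of the simulated experiment."""

    n_participants: int = 100
    difficulties: Tuple[int, ...] = DIFFICULTIES  # randomized per participant
    p_no_target: float = 0.40
    p_angry_within_target: float = 0.50
    stop_criterion: int = 20  # correct trials required to finish
    recycle_errors: bool = True
    rt_floor_ms: float = 50.0
    rt_ceiling_ms: float = 60_000.0

    def __post_init__(self):
        if not 0.0 <= self.p_no_target <= 1.0:
            raise ValueError("p_no_target must be in [0, 1]")
        if not 0.0 <= self.p_angry_within_target <= 1.0:
            raise ValueError("p_angry_within_target must be in [0, 1]")
        if self.stop_criterion < 1:
            raise ValueError("stop_criterion must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass(frozen=True)
class GenerativeParams:
    """State-dependent diffusion parameters of the generator.

    baseline maps (difficulty, trial_type) to the resting DDMParams;
    post_outcome_modulation maps distance-since-error d in 1..5 to additive
    offsets (da, dv, dt_er); emotion_modulation maps the errored display's
    deviant emotion to an extra drift offset applied at d = 1 only (errors
    on no-target displays carry no emotion offset).
    """

    baseline: Dict[Tuple[int, str], DDMParams]
    post_outcome_modulation: Dict[int, Tuple[float, float, float]] = field(
        default_factory=dict)
    emotion_modulation: Dict[str, float] = field(default_factory=dict)
    # between-participant lognormal SDs of multiplicative (a, v, t_er)
    # factors; a heterogeneous walk-in cohort is what keeps the pooled
    # +/-2 SD log-RT trim from selectively censoring slow conditions
    participant_sd: Tuple[float, float, float] = (0.10, 0.25, 0.25)

    def effective(self, difficulty: int, trial_type: str,
                  lag: Optional[int], anchor_emotion: Optional[str],
                  person: Tuple[float, float, float] = (1.0, 1.0, 1.0),
                  ) -> DDMParams:
        """Parameters for one trial given its cell, lag state, and the
        participant's multiplicative (a, v, t_er) factors.

        Raises ValueError (from DDMParams) if the combination leaves the
        parameter domain — checked for every reachable state up front by
        :func:`simulate_cohort`.
        """
        base = self.baseline[(difficulty, trial_type)]
        if lag is not None and 1 <= lag <= MAX_LAG:
            da, dv, dter = self.post_outcome_modulation.get(lag, (0.0, 0.0, 0.0))
            if lag == 1 and anchor_emotion is not None:
                dv += self.emotion_modulation.get(anchor_emotion, 0.0)
            base = base.shifted(da, dv, dter)
        fa, fv, ft = person
        if person != (1.0, 1.0, 1.0):
            base = DDMParams(a=base.a * fa, v=base.v * fv,
                             t_er=base.t_er * ft, z_rel=base.z_rel, s=base.s)
        return base

    def validate_reachable(self, config: CohortConfig) -> None:
        """Construct every reachable effective parameter set (raises early)."""
        anchors = [None, "neutral", "angry", "happy"]
        for (diff, tt) in self.baseline:
            for lag in [None] + list(range(1, MAX_LAG + 1)):
                for anc in anchors:
                    self.effective(diff, tt, lag, anc)


def default_generative_params() -> GenerativeParams:
    """Defaults emulating reference post-error dynamics at realistic magnitudes.

    Baselines use the post-correct group estimates (a = 2.874, T_er =
    0.795 s at distance 1) with drift rates chosen to reproduce the
    observed accuracy ordering neutral > happy > angry and the small
    easy-to-hard difficulty gradient.  Distance offsets follow the reference
    post-error minus post-correct differences: boundary elevated at all
    distances 1-5, drift dipping at distance 1 and rebounding above
    baseline afterwards, non-decision time slightly reduced throughout.
    Errors on angry displays depress the next trial's drift relative to
    errors on happy displays.
    """
    v_type = {"neutral": 1.06, "happy": 0.91, "angry": 0.55}
    v_diff = {80: -0.04, 90: 0.0, 100: +0.02}
    baseline = {
        (d, tt): DDMParams(a=2.874, v=v_type[tt] + v_diff[d], t_er=0.795)
        for d in DIFFICULTIES for tt in TRIAL_TYPES
    }
    post = {
        1: (+0.345, -0.125, -0.028),
        2: (+0.242, +0.053, -0.024),
        3: (+0.308, +0.124, -0.021),
        4: (+0.276, +0.107, -0.040),
        5: (+0.235, +0.082, -0.020),
    }
    emotion = {"angry": -0.05, "happy": +0.05}
    return GenerativeParams(baseline, post, emotion)


def _draw_display(rng, config):
    """(trial_type, target_position) of a fresh random display."""
    if rng.random() < config.p_no_target:
        return "neutral", None
    tt = "angry" if rng.random() < config.p_angry_within_target else "happy"
    return tt, int(rng.integers(1, 7))


def simulate_cohort(config: CohortConfig,
                    gen: GenerativeParams | None = None,
                    seed=None) -> pd.DataFrame:
    """Simulate a full cohort; returns a trial log in the canonical schema.

    Fully reproducible given ``seed`` (mandatory).  Each participant runs
    until ``stop_criterion`` correct responses; errored displays are
    re-inserted uniformly at random among the remaining planned displays
    when recycling is on, and fresh random displays are appended whenever
    the plan runs out before the criterion is met.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    gen = gen if gen is not None else default_generative_params()
    gen.validate_reachable(config)

    samplers: Dict[tuple, FirstPassageSampler] = {}

    def sampler_for(p: DDMParams) -> FirstPassageSampler:
        key = (round(p.a, 10), round(p.v, 10), round(p.t_er, 10))
        if key not in samplers:
            samplers[key] = FirstPassageSampler(p, n_grid=1536, tail=1e-8)
        return samplers[key]

    streams = np.random.SeedSequence(seed).spawn(config.n_participants)
    width = len(str(config.n_participants))
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"P{i + 1:0{width}d}"
        difficulty = int(rng.choice(config.difficulties))
        sa, sv, st = gen.participant_sd
        person = (float(np.exp(sa * rng.standard_normal())),
                  float(np.exp(sv * rng.standard_normal())),
                  float(np.exp(st * rng.standard_normal())))
        queue = [(_draw_display(rng, config) + (False,))
                 for _ in range(config.stop_criterion)]
        n_correct = 0
        ordinal = 0
        last_error_ord: Optional[int] = None
        anchor_emotion: Optional[str] = None
        while n_correct < config.stop_criterion:
            if not queue:
                queue.append(_draw_display(rng, config) + (False,))
            trial_type, position, recycled = queue.pop(0)
            ordinal += 1
            lag = None if last_error_ord is None else ordinal - last_error_ord
            params = gen.effective(difficulty, trial_type, lag,
                                   anchor_emotion, person)
            draw = sampler_for(params).sample(1, rng)
            correct = bool(draw.upper[0])
            rt_ms = float(np.clip(draw.rt[0] * 1000.0,
                                  config.rt_floor_ms, config.rt_ceiling_ms))
            truth_present = trial_type != "neutral"
            response = ("present" if truth_present == correct else "absent")
            rows.append((pid, ordinal, trial_type, difficulty,
                         position, response, correct, rt_ms, recycled))
            if correct:
                n_correct += 1
            else:
                last_error_ord = ordinal
                anchor_emotion = trial_type
                if config.recycle_errors:
                    pos = int(rng.integers(0, len(queue) + 1))
                    queue.insert(pos, (trial_type, position, True))
    df = pd.DataFrame(rows, columns=SCHEMA)
    df["target_position"] = df["target_position"].astype("Int64")
    return df
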