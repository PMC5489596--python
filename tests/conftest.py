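import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None,
                          max_examples=25)
settings.load_profile("suite")


def make_log(patterns, rng=None, difficulty=90):
    """Build a trial log from per-participant outcome patterns.

    ``patterns`` maps participant id to a string over {C, E} (correct /
    error) or to a list of (correct, trial_type, rt_ms) triples.  Types and
    RTs are filled deterministically unless a ``rng`` is given.
    """
    rows = []
    for pid, pat in patterns.items():
        if isinstance(pat, str):
            pat = [(ch == "C", "neutral", 1000.0 + 10 * k)
                   for k, ch in enumerate(pat)]
        for k, (correct, ttype, rt) in enumerate(pat, start=1):
            truth_present = ttype != "neutral"
            response = "present" if truth_present == correct else "absent"
            rows.append(dict(
                participant_id=pid, ordinal=k, trial_type=ttype,
                difficulty=difficulty,
                target_position=(1 if truth_present else None),
                response=response, correct=correct, rt_ms=float(rt),
                recycled=False))
    df = pd.DataFrame(rows)
    df["target_position"] = df["target_position"].astype("Int64")
    return df


def random_log(rng, n_participants=20, max_trials=60, p_error=0.15,
               with_gaps=True):
    """Randomized trial log (optionally with trimming-style ordinal gaps)."""
    patterns = {}
    for i in range(n_participants):
        n = int(rng.integers(8, max_trials + 1))
        trials = []
        for _ in range(n):
            ttype = rng.choice(["neutral", "angry", "happy"], p=[0.4, 0.3, 0.3])
            correct = bool(rng.random() > p_error)
            trials.append((correct, str(ttype), float(rng.uniform(500, 4000))))
        patterns[f"S{i:03d}"] = trials
    df = make_log(patterns, difficulty=int(rng.choice([80, 90, 100])))
    if with_gaps:
        keep = rng.random(len(df)) > 0.06
        df = df[keep].reset_index(drop=True)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20170629)
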