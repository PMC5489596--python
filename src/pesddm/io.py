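"""Trial-log CSV schema and round-trip I/O.

Schema (one row per behavioral trial):
``participant_id,ordinal,trial_type,difficulty,target_position,response,correct,rt_ms,recycled``
with trial_type in {neutral, angry, happy}, difficulty in {80, 90, 100},
target_position in {1..6, NA}, response in {present, absent},
correct/recycled in {0, 1}, ordinal 1-based within participant.
"""

from __future__ import annotations

import pandas as pd

SCHEMA = [
    "participant_id", "ordinal", "trial_type", "difficulty",
    "target_position", "response", "correct", "rt_ms", "recycled",
]

TRIAL_TYPES = ("neutral", "angry", "happy")
DIFFICULTIES = (80, 90, 100)
RESPONSES = ("present", "absent")


class LogFormatError(ValueError):
    """Malformed trial-log content; message names the offending row."""


def validate_log(df: pd.DataFrame, consecutive_ordinals: bool = False) -> None:
    """Raise LogFormatError on schema violations.

    ``consecutive_ordinals`` enforces ordinals 1..n per participant (true
    for raw logs; trimmed logs legitimately have gaps).
    """
    missing = [c for c in SCHEMA if c not in df.columns]
    if missing:
        raise LogFormatError(f"missing columns: {missing}")

    def bad_rows(mask, what):
        if mask.any():
            row = int(df.index[mask][0])
            raise LogFormatError(f"row {row}: {what}")

    bad_rows(~df["trial_type"].isin(TRIAL_TYPES), "invalid trial_type")
    bad_rows(~df["difficulty"].isin(DIFFICULTIES), "invalid difficulty")
    bad_rows(~df["response"].isin(RESPONSES), "invalid response")
    bad_rows(~(df["rt_ms"] > 0), "rt_ms must be > 0")
    bad_rows(df["ordinal"] < 1, "ordinal must be >= 1")
    has_target = df["trial_type"] != "neutral"
    bad_rows(has_target & ~df["target_position"].isin(range(1, 7)),
             "target trials need target_position in 1..6")
    bad_rows(~has_target & df["target_position"].notna(),
             "neutral trials must have target_position NA")
    # correctness must match the display's ground truth
    truth_present = has_target
    said_present = df["response"] == "present"
    bad_rows(df["correct"].astype(bool) != (truth_present == said_present),
             "correct flag inconsistent with trial_type/response")
    if consecutive_ordinals:
        for pid, grp in df.groupby("participant_id", sort=False):
            o = grp["ordinal"].to_numpy()
            if not (o[0] == 1 and (o[1:] - o[:-1] == 1).all()):
                raise LogFormatError(
                    f"participant {pid}: ordinals not consecutive from 1")


def write_log(df: pd.DataFrame, path) -> None:
    """Write a trial log in the canonical column order; NA positions as 'NA'."""
    out = df.copy()
    out["correct"] = out["correct"].astype(int)
    out["recycled"] = out["recycled"].astype(int)
    out["target_position"] = out["target_position"].astype("Int64")
    out.to_csv(path, index=False, columns=SCHEMA, na_rep="NA")


def read_log(path, validate: bool = True) -> pd.DataFrame:
    """Read a trial log written by :func:`write_log` (or hand-built)."""
    try:
        df = pd.read_csv(
            path,
            dtype={"participant_id": str, "trial_type": str, "response": str},
            na_values=["NA"], keep_default_na=False,
            float_precision="round_trip",
        )
        df["ordinal"] = df["ordinal"].astype(int)
        df["difficulty"] = df["difficulty"].astype(int)
        df["target_position"] = df["target_position"].astype("Int64")
        df["correct"] = df["correct"].astype(int).astype(bool)
        df["recycled"] = df["recycled"].astype(int).astype(bool)
        df["rt_ms"] = df["rt_ms"].astype(float)
    except (ValueError, TypeError, KeyError) as exc:
        raise LogFormatError(f"cannot parse trial log {path}: {exc}") from exc
    if validate:
        validate_log(df)
    return df
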