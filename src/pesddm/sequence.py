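"""Preprocessing and outcome-conditioned trial-sequence extraction.

Preprocessing follows the two-stage convention: first remove whole
participants (accuracy outliers and anyone with a single response above
10 s), then trim individual trials whose log RT falls outside mean +/- 2 SD
of the pooled log-RT distribution.  Both stages report the thresholds they
used and accept them back, so re-applying a stage with its recorded
thresholds is a no-op.

Sequence extraction is anchored on error (E) or correct (C) trials with a
required correct context: a valid error anchor is preceded by at least two
correct trials (pattern ``C C E x``), a valid correct anchor by two further
corrects (``C C C x``).  The analyzed target trial sits ``distance`` trials
after the anchor with all intervening trials correct; trials removed by
trimming break sequences; episodes never cross participants.  The target
trial's own correctness is unconstrained — it is the outcome under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

MAX_DISTANCE = 5

__all__ = [
    "ExclusionReport", "TrimReport", "EpisodeSet",
    "exclude_participants", "trim_rts", "participants_with_errors",
    "extract_post_outcome", "split_by_future_accuracy",
    "split_by_error_emotion", "pes_delta_rt", "summarize_behavior",
]


@dataclass
class ExclusionReport:
    n_participants_before: int
    n_participants_after: int
    accuracy_mean: float
    accuracy_sd: float
    accuracy_threshold: Optional[float]  # None when SD degenerate
    excluded: pd.DataFrame  # participant_id, reason, accuracy, max_rt_ms


@dataclass
class TrimReport:
    n_before: int
    n_removed: int
    log_rt_mean: float
    log_rt_sd: float
    lower_ms: float
    upper_ms: float

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_before if self.n_before else 0.0


def exclude_participants(log: pd.DataFrame,
                         report: ExclusionReport | None = None):
    """Remove whole participants by accuracy and slow-trial rules.

    Accuracy rule: overall accuracy at least 3 SD below the cohort mean
    (mean/SD taken over participants' accuracies).  Degenerate SD = 0 (or a
    single participant) excludes nobody by accuracy.  Slow-trial rule: any
    single response above 10,000 ms removes the participant entirely.
    Passing a previous ``report`` reuses its accuracy threshold.
    """
    if len(log) == 0:
        raise ValueError("empty trial log")
    stats = log.groupby("participant_id").agg(
        accuracy=("correct", "mean"), max_rt_ms=("rt_ms", "max"))
    if report is not None:
        mean, sd, thr = (report.accuracy_mean, report.accuracy_sd,
                         report.accuracy_threshold)
    else:
        mean = float(stats["accuracy"].mean())
        sd = float(stats["accuracy"].std(ddof=1)) if len(stats) > 1 else 0.0
        thr = mean - 3.0 * sd if sd > 0 else None
    low_acc = stats["accuracy"] <= thr if thr is not None else pd.Series(False, index=stats.index)
    slow = stats["max_rt_ms"] > 10_000.0
    reasons = []
    for pid in stats.index[low_acc | slow]:
        why = []
        if bool(low_acc.loc[pid]):
            why.append("low_accuracy")
        if bool(slow.loc[pid]):
            why.append("slow_trial")
        reasons.append((pid, "+".join(why), float(stats.loc[pid, "accuracy"]),
                        float(stats.loc[pid, "max_rt_ms"])))
    excluded = pd.DataFrame(reasons, columns=["participant_id", "reason",
                                              "accuracy", "max_rt_ms"])
    keep = ~log["participant_id"].isin(excluded["participant_id"])
    rep = ExclusionReport(len(stats), int(len(stats) - len(excluded)),
                          mean, sd, thr, excluded)
    return log[keep].copy(), rep


def trim_rts(log: pd.DataFrame, report: TrimReport | None = None):
    """Drop trials whose ln(rt_ms) lies outside mean +/- 2 SD (pooled).

    Bounds are computed over the whole post-exclusion dataset; pass a
    previous ``report`` to reuse its bounds (making trimming a no-op on its
    own output).  Zero log-RT variance trims nothing.
    """
    lr = np.log(log["rt_ms"].to_numpy(dtype=float))
    if report is not None:
        lo, hi = np.log(report.lower_ms), np.log(report.upper_ms)
        mean, sd = report.log_rt_mean, report.log_rt_sd
    else:
        mean = float(lr.mean())
        sd = float(lr.std(ddof=1)) if len(lr) > 1 else 0.0
        lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
    keep = (lr >= lo) & (lr <= hi)
    rep = TrimReport(len(log), int((~keep).sum()), mean, sd,
                     float(np.exp(lo)), float(np.exp(hi)))
    return log[keep].copy(), rep


def participants_with_errors(log: pd.DataFrame) -> pd.DataFrame:
    """Restrict to participants who committed at least one error (the
    inclusion rule applied before all diffusion-model fits)."""
    any_err = ~log.groupby("participant_id")["correct"].agg("all")
    keep = any_err[any_err].index
    return log[log["participant_id"].isin(keep)].copy()


@dataclass
class EpisodeSet:
    """Outcome-conditioned trial references.

    ``frame`` has one row per episode: participant_id, anchor_ordinal,
    target_ordinal, anchor_type (trial_type of the anchoring trial).
    """

    label: str
    anchor: str  # 'error' | 'correct'
    distance: int
    frame: pd.DataFrame = field(repr=False)

    def __len__(self):
        return len(self.frame)

    def target_trials(self, log: pd.DataFrame) -> pd.DataFrame:
        """Target-trial rows of ``log`` for every episode, in episode order."""
        key = log.set_index(["participant_id", "ordinal"])
        idx = pd.MultiIndex.from_frame(
            self.frame[["participant_id", "target_ordinal"]])
        out = key.loc[idx].reset_index()
        return out.rename(columns={"ordinal": "target_ordinal"})

    def to_csv(self, path) -> None:
        self.frame.assign(label=self.label, anchor=self.anchor,
                          distance=self.distance).to_csv(path, index=False)


def _participant_arrays(grp: pd.DataFrame):
    """Dense ordinal-indexed presence/correct/type/rt arrays (1-based)."""
    o = grp["ordinal"].to_numpy()
    n = int(o.max())
    present = np.zeros(n + 1, dtype=bool)
    corr = np.zeros(n + 1, dtype=bool)
    ttype = np.empty(n + 1, dtype=object)
    rt = np.full(n + 1, np.nan)
    present[o] = True
    corr[o] = grp["correct"].to_numpy(dtype=bool)
    ttype[o] = grp["trial_type"].to_numpy()
    rt[o] = grp["rt_ms"].to_numpy(dtype=float)
    return present, corr, ttype, rt


def _context_ok(present, corr, anchor_ord, anchor_is_error):
    """CC context before the anchor (and the anchor itself correct for CCC)."""
    if anchor_ord - 2 < 1:
        return False
    if not (present[anchor_ord - 1] and corr[anchor_ord - 1]
            and present[anchor_ord - 2] and corr[anchor_ord - 2]):
        return False
    if anchor_is_error:
        return present[anchor_ord] and not corr[anchor_ord]
    return present[anchor_ord] and corr[anchor_ord]


def extract_post_outcome(log: pd.DataFrame, anchor: str,
                         distance: int) -> EpisodeSet:
    """Episodes at ``distance`` trials after an error/correct anchor.

    Error anchor: pattern ``C C E`` (the error preceded by two corrects).
    Correct anchor: pattern ``C C C`` (matched control).  The target is the
    distance-th trial after the anchor; for distance >= 2 all intervening
    trials must be present and correct.  Targets must be present (not
    trimmed); their correctness is unconstrained.
    """
    if anchor not in ("error", "correct"):
        raise ValueError(f"anchor must be 'error' or 'correct', got {anchor!r}")
    if not 1 <= distance <= MAX_DISTANCE:
        raise ValueError(f"distance must be in 1..{MAX_DISTANCE}, got {distance}")
    rows = []
    is_err = anchor == "error"
    for pid, grp in log.groupby("participant_id", sort=False):
        present, corr, ttype, _ = _participant_arrays(grp)
        n = len(present) - 1
        for a in range(3, n - distance + 1):
            if not _context_ok(present, corr, a, is_err):
                continue
            tgt = a + distance
            if not present[tgt]:
                continue
            if distance > 1 and not all(
                    present[j] and corr[j] for j in range(a + 1, tgt)):
                continue
            rows.append((pid, a, tgt, ttype[a]))
    frame = pd.DataFrame(rows, columns=["participant_id", "anchor_ordinal",
                                        "target_ordinal", "anchor_type"])
    return EpisodeSet(f"post-{anchor} d{distance}", anchor, distance, frame)


def split_by_future_accuracy(log: pd.DataFrame):
    """Partition distance-1 post-error trials by the next five outcomes.

    A post-error trial goes to the first set when the five trials following
    it are all present and correct, to the second when at least one of them
    is an error; trials without five following trials (participant ends, or
    the lookahead window broken by trimming) join neither set.
    """
    base = extract_post_outcome(log, "error", 1)
    ok_rows, bad_rows = [], []
    arrays = {pid: _participant_arrays(grp)
              for pid, grp in log.groupby("participant_id", sort=False)}
    for row in base.frame.itertuples(index=False):
        present, corr, _, _ = arrays[row.participant_id]
        n = len(present) - 1
        t = row.target_ordinal
        if t + 5 > n or not present[t + 1:t + 6].all():
            continue
        (ok_rows if corr[t + 1:t + 6].all() else bad_rows).append(tuple(row))
    cols = list(base.frame.columns)
    return (
        EpisodeSet("post-error d1, next-5-correct", "error", 1,
                   pd.DataFrame(ok_rows, columns=cols)),
        EpisodeSet("post-error d1, next-5-with-error", "error", 1,
                   pd.DataFrame(bad_rows, columns=cols)),
    )


def split_by_error_emotion(log: pd.DataFrame):
    """Partition distance-1 post-error trials by the error trial's deviant
    emotion (angry vs happy); errors on no-target displays join neither."""
    base = extract_post_outcome(log, "error", 1)
    angry = base.frame[base.frame["anchor_type"] == "angry"].reset_index(drop=True)
    happy = base.frame[base.frame["anchor_type"] == "happy"].reset_index(drop=True)
    return (EpisodeSet("post-error d1, after-angry-error", "error", 1, angry),
            EpisodeSet("post-error d1, after-happy-error", "error", 1, happy))


@dataclass
class PESResult:
    """Robust post-error slowing: per-episode RT(E+1) - RT(E-1) in ms."""

    deltas: pd.DataFrame  # participant_id, anchor_ordinal, delta_rt_ms
    n_skipped: int  # episodes whose E-1/E+1 trial types did not match

    @property
    def mean_ms(self) -> float:
        return float(self.deltas["delta_rt_ms"].mean()) if len(self.deltas) else float("nan")


def pes_delta_rt(log: pd.DataFrame) -> PESResult:
    """Trial-type-matched ΔRT over all valid C C E x episodes.

    ΔRT = rt(E+1) - rt(E-1), computed only when the post-error trial and the
    pre-error trial share a trial type (so type-specific RT differences do
    not masquerade as slowing); mismatching episodes are skipped and counted.
    """
    base = extract_post_outcome(log, "error", 1)
    arrays = {pid: _participant_arrays(grp)
              for pid, grp in log.groupby("participant_id", sort=False)}
    rows, skipped = [], 0
    for row in base.frame.itertuples(index=False):
        _, _, ttype, rt = arrays[row.participant_id]
        pre, post = row.anchor_ordinal - 1, row.target_ordinal
        if ttype[pre] != ttype[post]:
            skipped += 1
            continue
        rows.append((row.participant_id, row.anchor_ordinal,
                     float(rt[post] - rt[pre])))
    return PESResult(pd.DataFrame(
        rows, columns=["participant_id", "anchor_ordinal", "delta_rt_ms"]),
        skipped)


def summarize_behavior(log: pd.DataFrame,
                       episodes: Iterable[EpisodeSet]) -> pd.DataFrame:
    """Descriptive table per episode set: mean RT, SEM, accuracy, ΔRT.

    One row per (label, difficulty, trial_type) cell plus an '(all)' roll-up
    row per set; empty cells are simply absent (never reported as zero).
    ΔRT is the trial-type-matched target-minus-pre-anchor difference and is
    filled only for error-anchored sets.
    """
    out = []
    for ep in episodes:
        if len(ep) == 0:
            continue
        tgt = ep.target_trials(log)
        arrays = {pid: _participant_arrays(grp)
                  for pid, grp in log.groupby("participant_id", sort=False)}
        deltas = []
        for row in ep.frame.itertuples(index=False):
            _, _, ttype, rt = arrays[row.participant_id]
            pre = row.anchor_ordinal - 1
            if ep.anchor == "error" and ttype[pre] == ttype[row.target_ordinal]:
                deltas.append(float(rt[row.target_ordinal] - rt[pre]))
            else:
                deltas.append(np.nan)
        tgt = tgt.assign(delta_rt_ms=deltas)

        def cell(sub, difficulty, trial_type):
            rt = sub["rt_ms"]
            return dict(
                label=ep.label, anchor=ep.anchor, distance=ep.distance,
                difficulty=difficulty, trial_type=trial_type, n=len(sub),
                mean_rt_ms=float(rt.mean()),
                sem_rt_ms=float(rt.std(ddof=1) / np.sqrt(len(sub))) if len(sub) > 1 else np.nan,
                accuracy=float(sub["correct"].mean()),
                mean_delta_rt_ms=float(sub["delta_rt_ms"].mean())
                if sub["delta_rt_ms"].notna().any() else np.nan,
            )

        out.append(cell(tgt, "(all)", "(all)"))
        for (diff, tt), sub in tgt.groupby(["difficulty", "trial_type"]):
            out.append(cell(sub, diff, tt))
    return pd.DataFrame(out)
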