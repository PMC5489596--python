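"""Brute-force window-scan oracles for sequence extraction.

Deliberately plain and quadratic: every candidate anchor/target window is
re-checked from scratch against the raw predicates, independently of the
package's vectorised implementation.
"""


def _records(log_df):
    out = {}
    for row in log_df.itertuples():
        out.setdefault(row.participant_id, {})[row.ordinal] = row
    return out


def _anchor_ok(recs, o, want_error):
    for k in (1, 2):
        if (o - k) not in recs or not recs[o - k].correct:
            return False
    if o not in recs:
        return False
    return (not recs[o].correct) if want_error else recs[o].correct


def oracle_post_outcome(log_df, anchor, distance):
    """Sorted (participant, anchor_ordinal, target_ordinal) triples."""
    eps = []
    for pid, recs in _records(log_df).items():
        for o in list(recs):
            if not _anchor_ok(recs, o, anchor == "error"):
                continue
            tgt = o + distance
            if tgt not in recs:
                continue
            if any((o + j) not in recs or not recs[o + j].correct
                   for j in range(1, distance)):
                continue
            eps.append((pid, o, tgt))
    return sorted(eps)


def oracle_future_accuracy(log_df):
    """(all-correct-next-5, has-error-next-5) target triples."""
    good, bad = [], []
    by_pid = _records(log_df)
    for pid, o, tgt in oracle_post_outcome(log_df, "error", 1):
        recs = by_pid[pid]
        window = [recs.get(tgt + j) for j in range(1, 6)]
        if any(w is None for w in window):
            continue
        (good if all(w.correct for w in window) else bad).append((pid, o, tgt))
    return sorted(good), sorted(bad)


def oracle_error_emotion(log_df):
    """(after-angry, after-happy) target triples; neutral anchors dropped."""
    angry, happy = [], []
    by_pid = _records(log_df)
    for pid, o, tgt in oracle_post_outcome(log_df, "error", 1):
        ttype = by_pid[pid][o].trial_type
        if ttype == "angry":
            angry.append((pid, o, tgt))
        elif ttype == "happy":
            happy.append((pid, o, tgt))
    return sorted(angry), sorted(happy)


def oracle_pes(log_df):
    """Sorted (participant, anchor, delta_rt_ms) for type-matched episodes,
    plus the count of type-mismatched (skipped) episodes."""
    vals, skipped = [], 0
    by_pid = _records(log_df)
    for pid, o, tgt in oracle_post_outcome(log_df, "error", 1):
        recs = by_pid[pid]
        if recs[o - 1].trial_type != recs[tgt].trial_type:
            skipped += 1
            continue
        vals.append((pid, o, recs[tgt].rt_ms - recs[o - 1].rt_ms))
    return sorted(vals), skipped
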