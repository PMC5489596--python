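"""Glue between preprocessing, episode extraction and the model fits.

The four analyses cover the standard post-error questions:

* model1 — first trial after an error (CCEx) vs after a correct run (CCCx),
  optionally split by difficulty;
* model2 — trials at distances 2..5 after the error/correct anchor with all
  intervening trials correct;
* model3 — first post-error trials split by whether the next five trials
  were all correct;
* model4 — first post-error trials split by the errored display's deviant
  emotion (angry vs happy).

Every analysis produces condition-labelled ChoiceData (RT in seconds,
upper boundary = correct) ready for :func:`pesddm.inference.fit_pooled`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import sequence
from .ddm import ChoiceData
from .inference import (FitResult, compare_models, fit_pooled,
                        posterior_prob_greater, seven_model_set)

ANALYSES = ("model1", "model2", "model3", "model4")

__all__ = ["ANALYSES", "MCMCSettings", "preprocess", "episode_choice_data",
           "analysis_data", "run_analysis", "AnalysisResult"]


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    draws: int = 5000
    burn_in: int = 1000
    seed: int = 0


def preprocess(log: pd.DataFrame):
    """Participant exclusion followed by pooled log-RT trimming."""
    kept, excl = sequence.exclude_participants(log)
    trimmed, trim = sequence.trim_rts(kept)
    return trimmed, excl, trim


def episode_choice_data(log: pd.DataFrame,
                        episodes: sequence.EpisodeSet) -> ChoiceData:
    """Target trials of an episode set as fit-ready choice/RT data."""
    tgt = episodes.target_trials(log)
    return ChoiceData(tgt["rt_ms"].to_numpy(dtype=float) / 1000.0,
                      tgt["correct"].to_numpy(dtype=bool))


def analysis_data(log: pd.DataFrame, analysis: str,
                  distance: int = 1, by_difficulty: bool = False,
                  ) -> Dict[str, ChoiceData]:
    """Condition-labelled data for one of the four analyses.

    The diffusion-model inclusion rule (participants with at least one
    error) is applied here, before extraction.
    """
    log = sequence.participants_with_errors(log)
    if analysis == "model1" or analysis == "model2":
        d = distance if analysis == "model2" else 1
        pe = sequence.extract_post_outcome(log, "error", d)
        pc = sequence.extract_post_outcome(log, "correct", d)
        if by_difficulty:
            out = {}
            for label, ep in (("PE", pe), ("PC", pc)):
                tgt = ep.target_trials(log)
                for diff, sub in tgt.groupby("difficulty"):
                    out[f"{label}-I{diff}"] = ChoiceData(
                        sub["rt_ms"].to_numpy(float) / 1000.0,
                        sub["correct"].to_numpy(bool))
            return out
        return {"PE": episode_choice_data(log, pe),
                "PC": episode_choice_data(log, pc)}
    if analysis == "model3":
        good, bad = sequence.split_by_future_accuracy(log)
        return {"future-correct": episode_choice_data(log, good),
                "future-error": episode_choice_data(log, bad)}
    if analysis == "model4":
        angry, happy = sequence.split_by_error_emotion(log)
        return {"after-angry": episode_choice_data(log, angry),
                "after-happy": episode_choice_data(log, happy)}
    raise ValueError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")


@dataclass
class AnalysisResult:
    analysis: str
    distance: int
    data_sizes: Dict[str, int]
    comparison: pd.DataFrame  # seven-model DIC table
    best_fit: FitResult
    full_fit: FitResult  # the all-varying fit used for contrasts
    contrasts: pd.DataFrame


def _contrast_table(fit: FitResult) -> pd.DataFrame:
    """All pairwise P(param(label_i) > param(label_j)) for varying params."""
    rows = []
    for p in fit.spec.varying:
        labs = fit.spec.labels
        for i in range(len(labs)):
            for j in range(len(labs)):
                if i == j:
                    continue
                rows.append(dict(
                    parameter=p, greater=labs[i], lesser=labs[j],
                    prob=posterior_prob_greater(
                        fit, f"{p}({labs[i]})", f"{p}({labs[j]})")))
    return pd.DataFrame(rows)


def run_analysis(log: pd.DataFrame, analysis: str, mcmc: MCMCSettings,
                 distance: int = 1, compare: bool = True,
                 by_difficulty: bool = False) -> AnalysisResult:
    """Extract, fit the seven-model set (or just the full model), and
    report posterior contrasts from the all-varying fit."""
    data = analysis_data(log, analysis, distance=distance,
                         by_difficulty=by_difficulty)
    labels = tuple(sorted(data))
    if compare:
        table, fits = compare_models(
            data, seven_model_set(labels), chains=mcmc.chains,
            draws=mcmc.draws, burn_in=mcmc.burn_in, seed=mcmc.seed)
        best = fits[int(table["dic"].idxmin())]
        full = fits[-1]  # [a,v,t_er] is last in the canonical ordering
    else:
        full = fit_pooled(data, seven_model_set(labels)[-1],
                          chains=mcmc.chains, draws=mcmc.draws,
                          burn_in=mcmc.burn_in, seed=mcmc.seed)
        best = full
        table = pd.DataFrame([dict(model=full.spec.name, dic=full.dic,
                                   mean_deviance=full.mean_deviance,
                                   p_d=full.p_d,
                                   max_rhat=max(full.rhat.values()),
                                   converged=full.converged,
                                   seed=mcmc.seed, delta_dic=0.0,
                                   winner=True)])
    return AnalysisResult(analysis, distance,
                          {lab: len(d) for lab, d in data.items()},
                          table, best, full, _contrast_table(full))
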