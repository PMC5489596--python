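"""Posterior predictive checks via quantile-probability summaries.

For each condition the observed choice probability and the mean RTs at the
10/30/50/70/90% quantiles are compared against replicate datasets simulated
from posterior draws: every selected draw generates a synthetic dataset of
the observed size, the same summaries are computed per replicate, and their
mean and SD across replicates form the predictive band (the "ellipse
height" of a quantile-probability plot).  Quantiles use linear
interpolation of order statistics (numpy's default, the type-7 convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm import ChoiceData, DDMParams, FirstPassageSampler
from .inference import FitResult

DEFAULT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)

__all__ = ["QuantileSummary", "posterior_predictive"]


@dataclass
class QuantileSummary:
    """Observed vs predicted quantile-probability summary.

    ``quantiles``: rows (condition, boundary, quantile) with observed RT,
    predictive mean and predictive SD.  ``choice``: per condition the
    observed upper-boundary probability with its predictive mean/SD.
    Error-boundary quantiles appear only for conditions with at least
    ``min_error_trials`` observed errors (stability guard).
    """

    quantiles: pd.DataFrame
    choice: pd.DataFrame
    n_draws: int

    def coverage(self, n_sd: float = 2.0) -> float:
        """Fraction of quantile cells with |observed - predicted mean|
        within ``n_sd`` predictive SDs."""
        q = self.quantiles.dropna(subset=["predicted_sd"])
        ok = (q["observed"] - q["predicted_mean"]).abs() <= n_sd * q["predicted_sd"]
        return float(ok.mean())


def _summaries(cd: ChoiceData, qs, min_n):
    """(p_upper, upper-RT quantiles, lower-RT quantiles or None)."""
    p_up = float(np.mean(cd.upper))
    up = cd.rt[cd.upper]
    lo = cd.rt[~cd.upper]
    q_up = np.quantile(up, qs) if up.size >= 2 else np.full(len(qs), np.nan)
    q_lo = np.quantile(lo, qs) if lo.size >= min_n else None
    return p_up, q_up, q_lo


def posterior_predictive(fit: FitResult, data, n_draws: int = 200,
                         seed: int = 0, quantiles=DEFAULT_QUANTILES,
                         min_error_trials: int = 50) -> QuantileSummary:
    """Quantile-probability PPC of a pooled fit against its data.

    ``data`` maps condition labels to ChoiceData (the observed trials the
    fit used).  ``n_draws`` posterior draws are taken evenly across the
    pooled trace; each simulates a replicate of the observed size.
    """
    rng = np.random.default_rng(seed)
    idx_map = fit.spec.index_map()
    names = fit.trace.param_names
    nc, nd, _ = fit.trace.draws.shape
    flat = fit.trace.draws.reshape(nc * nd, -1)
    sel = np.linspace(0, nc * nd - 1, num=min(n_draws, nc * nd)).astype(int)

    qrows, crows = [], []
    for lab in fit.spec.labels:
        cd = data[lab]
        obs_p, obs_qu, obs_ql = _summaries(cd, quantiles, min_error_trials)
        rep_p = np.empty(len(sel))
        rep_qu = np.empty((len(sel), len(quantiles)))
        rep_ql = np.full((len(sel), len(quantiles)), np.nan)
        for r, k in enumerate(sel):
            th = flat[k]
            p = DDMParams(a=th[idx_map["a"][lab]], v=th[idx_map["v"][lab]],
                          t_er=th[idx_map["t_er"][lab]])
            rep = FirstPassageSampler(p).sample(len(cd), rng)
            rep_p[r], rep_qu[r], ql = _summaries(rep, quantiles, 2)
            if ql is not None:
                rep_ql[r] = ql
        def sd(x):
            x = np.asarray(x)[~np.isnan(np.asarray(x))]
            return float(x.std(ddof=1)) if x.size > 1 else float("nan")

        crows.append(dict(condition=lab, observed=obs_p,
                          predicted_mean=float(rep_p.mean()),
                          predicted_sd=sd(rep_p)))
        for qi, q in enumerate(quantiles):
            qrows.append(dict(condition=lab, boundary="upper", quantile=q,
                              observed=float(obs_qu[qi]),
                              predicted_mean=float(np.nanmean(rep_qu[:, qi])),
                              predicted_sd=sd(rep_qu[:, qi])))
            if obs_ql is not None:
                col = rep_ql[:, qi]
                pm = (float(np.mean(col[~np.isnan(col)]))
                      if (~np.isnan(col)).any() else float("nan"))
                psd = sd(col)
                qrows.append(dict(condition=lab, boundary="lower", quantile=q,
                                  observed=float(obs_ql[qi]),
                                  predicted_mean=pm, predicted_sd=psd))
    return QuantileSummary(pd.DataFrame(qrows), pd.DataFrame(crows), len(sel))
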