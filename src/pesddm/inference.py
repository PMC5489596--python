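"""Pooled Bayesian estimation of condition-wise diffusion parameters.

All trials of a condition are pooled across participants ("group level")
and the three central parameters (boundary separation a, drift rate v,
non-decision time T_er) are estimated under a sharing structure given by a
:class:`ModelSpec`: each parameter either varies freely across condition
labels or is shared.  The seven-model set enumerates every non-empty subset
of {a, v, t_er} as the varying parameters.

Sampling is adaptive Metropolis-within-Gibbs over the scalar parameters
with weakly-informative truncated-normal priors.  Proposal scales adapt
during burn-in only (targeting ~30% acceptance) and are frozen afterwards
so the retained chain is Markov.  Model comparison uses the Deviance
Information Criterion DIC = D-bar + pD with pD = D-bar - D(theta-bar);
convergence is monitored with the Gelman-Rubin potential scale reduction
factor computed from between- and within-chain variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .ddm import ChoiceData, DDMParams, _as_choice_data
from ._wfpt import EPS_SERIES, loglik_sum

PARAMS = ("a", "v", "t_er")

__all__ = [
    "ModelSpec", "PriorSpec", "TruncNormal", "Trace", "FitResult",
    "seven_model_set", "fit_pooled", "dic", "gelman_rubin",
    "posterior_prob_greater", "compare_models", "default_priors",
]


@dataclass(frozen=True)
class ModelSpec:
    """Which of (a, v, t_er) vary across the condition labels."""

    varying: Tuple[str, ...]
    labels: Tuple[str, ...]

    def __post_init__(self):
        if not set(self.varying) <= set(PARAMS):
            raise ValueError(f"varying must be a subset of {PARAMS}")
        if len(self.labels) == 0:
            raise ValueError("at least one condition label required")

    @property
    def shared(self) -> Tuple[str, ...]:
        return tuple(p for p in PARAMS if p not in self.varying)

    @property
    def name(self) -> str:
        return "[" + ",".join(p for p in PARAMS if p in self.varying) + "]"

    def param_names(self) -> List[str]:
        names = []
        for p in PARAMS:
            if p in self.varying:
                names.extend(f"{p}({lab})" for lab in self.labels)
            else:
                names.append(p)
        return names

    def index_map(self) -> Dict[str, Dict[str, int]]:
        """Per base parameter: condition label -> flat parameter index."""
        names = self.param_names()
        out: Dict[str, Dict[str, int]] = {}
        for p in PARAMS:
            if p in self.varying:
                out[p] = {lab: names.index(f"{p}({lab})") for lab in self.labels}
            else:
                out[p] = {lab: names.index(p) for lab in self.labels}
        return out


def seven_model_set(labels: Sequence[str]) -> List[ModelSpec]:
    """The canonical seven specs: every non-empty subset of {a, v, t_er}."""
    subsets = [("a",), ("v",), ("t_er",), ("a", "v"), ("a", "t_er"),
               ("v", "t_er"), ("a", "v", "t_er")]
    return [ModelSpec(s, tuple(labels)) for s in subsets]


@dataclass(frozen=True)
class TruncNormal:
    """Normal(mu, sd) truncated to (lo, hi); proper by construction."""

    mu: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if not (self.sd > 0 and self.lo < self.hi):
            raise ValueError("need sd > 0 and lo < hi")

    def in_support(self, x: float) -> bool:
        return self.lo < x < self.hi

    def logpdf_unnorm(self, x: float) -> float:
        # the truncation constant cancels in Metropolis ratios
        z = (x - self.mu) / self.sd
        return -0.5 * z * z


@dataclass(frozen=True)
class PriorSpec:
    a: TruncNormal
    v: TruncNormal
    t_er: TruncNormal

    def for_param(self, base: str) -> TruncNormal:
        return getattr(self, base)


def default_priors() -> PriorSpec:
    """Weakly-informative priors centered on literature-typical values
    (configurable; supports respect the parameter domain)."""
    return PriorSpec(
        a=TruncNormal(2.0, 1.0, 0.3, 6.0),
        v=TruncNormal(0.7, 2.0, -8.0, 8.0),
        t_er=TruncNormal(0.4, 0.35, 0.05, 2.0),
    )


@dataclass
class Trace:
    """Post-burn-in MCMC draws: (chains, draws, params) plus bookkeeping."""

    param_names: List[str]
    draws: np.ndarray  # (n_chains, n_draws, n_params)
    loglik: np.ndarray  # (n_chains, n_draws) total data log-likelihood
    burn_in: int
    seed: int
    acceptance: np.ndarray  # (n_chains, n_params)
    proposal_scales: np.ndarray  # frozen post-adaptation scales

    def pooled(self, name: str) -> np.ndarray:
        j = self.param_names.index(name)
        return self.draws[:, :, j].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        nc, nd, np_ = self.draws.shape
        rec = []
        for c in range(nc):
            for j, name in enumerate(self.param_names):
                rec.append(pd.DataFrame({
                    "chain": c, "draw": np.arange(nd), "parameter": name,
                    "value": self.draws[c, :, j]}))
        return pd.concat(rec, ignore_index=True)


@dataclass
class FitResult:
    spec: ModelSpec
    trace: Trace
    posterior_mean: Dict[str, float]
    posterior_sd: Dict[str, float]
    rhat: Dict[str, float]
    mean_deviance: float
    p_d: float
    dic: float
    converged: bool
    rhat_threshold: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.posterior_mean,
            "sd": self.posterior_sd,
            "rhat": self.rhat,
        })


def _initial_values(data: Dict[str, ChoiceData], spec: ModelSpec,
                    prior: PriorSpec, rng) -> np.ndarray:
    """Moment-based start: t_er below the fastest response, a near the
    prior center, v from the accuracy logit; jittered per chain."""
    names = spec.param_names()
    idx = spec.index_map()
    theta = np.empty(len(names))
    min_rt = {lab: float(np.min(d.rt)) for lab, d in data.items()}
    acc = {lab: float(np.clip(np.mean(d.upper), 0.05, 0.95))
           for lab, d in data.items()}
    for p in PARAMS:
        pr = prior.for_param(p)
        for lab in spec.labels:
            j = idx[p][lab]
            if p == "a":
                val = 2.0
            elif p == "t_er":
                lo = min(min_rt[la] for la, jj in idx["t_er"].items() if jj == j)
                val = 0.7 * lo
            else:
                a0 = 2.0
                val = math.log(acc[lab] / (1 - acc[lab])) / a0
            val *= 1.0 + 0.05 * rng.standard_normal()
            theta[j] = float(np.clip(val, pr.lo + 1e-6, pr.hi - 1e-6))
    return theta


def _cond_loglik(d: ChoiceData, a, v, t_er) -> float:
    return loglik_sum(d.rt, d.upper, a, v, t_er, 0.5, 1.0, EPS_SERIES)


def fit_pooled(data: Dict[str, ChoiceData], spec: ModelSpec,
               prior: PriorSpec | None = None, *,
               chains: int = 4, draws: int = 5000, burn_in: int = 1000,
               seed: int = 0, rhat_threshold: float = 1.1,
               adapt_interval: int = 50, target_accept: float = 0.3) -> FitResult:
    """Pooled MCMC fit of ``spec`` to condition-labelled choice/RT data.

    ``data`` maps each condition label of the spec to its trials; every
    condition must be non-empty.  Returns the post-burn-in trace together
    with posterior summaries, Gelman-Rubin diagnostics and DIC components.
    Non-convergence (max R-hat above ``rhat_threshold``) is flagged on the
    result, never silently ignored.
    """
    prior = prior if prior is not None else default_priors()
    if set(data) != set(spec.labels):
        raise ValueError(f"data labels {sorted(data)} do not match spec labels "
                         f"{sorted(spec.labels)}")
    data = {lab: _as_choice_data(d) for lab, d in data.items()}
    for lab, d in data.items():
        if len(d) == 0:
            raise ValueError(f"condition {lab!r} has no trials")

    names = spec.param_names()
    idx = spec.index_map()
    n_par = len(names)
    # which conditions each flat parameter touches
    touches: List[List[str]] = [[] for _ in range(n_par)]
    for p in PARAMS:
        for lab, j in idx[p].items():
            touches[j].append(lab)
    base_of = [next(p for p in PARAMS if n == p or n.startswith(p + "("))
               for n in names]

    ss = np.random.SeedSequence(seed).spawn(chains)
    total = burn_in + draws
    all_draws = np.empty((chains, draws, n_par))
    all_ll = np.empty((chains, draws))
    all_acc = np.empty((chains, n_par))
    all_scales = np.empty((chains, n_par))

    for c in range(chains):
        rng = np.random.default_rng(ss[c])
        theta = _initial_values(data, spec, prior, rng)

        def cond_ll_all(th):
            return {lab: _cond_loglik(data[lab],
                                      th[idx["a"][lab]], th[idx["v"][lab]],
                                      th[idx["t_er"][lab]])
                    for lab in spec.labels}

        ll = cond_ll_all(theta)
        # walk t_er down until the start is inside the likelihood support
        guard = 0
        while not all(math.isfinite(x) for x in ll.values()) and guard < 200:
            for j, b in enumerate(base_of):
                if b == "t_er":
                    theta[j] = max(prior.t_er.lo + 1e-6, theta[j] * 0.8)
            ll = cond_ll_all(theta)
            guard += 1
        if not all(math.isfinite(x) for x in ll.values()):
            raise RuntimeError("could not find a finite-likelihood start")

        scales = np.full(n_par, 0.1)
        acc_n = np.zeros(n_par)
        win_acc = np.zeros(n_par)
        win_n = np.zeros(n_par)
        for it in range(total):
            for j in range(n_par):
                pr = prior.for_param(base_of[j])
                prop = theta[j] + scales[j] * rng.standard_normal()
                win_n[j] += 1
                if not pr.in_support(prop):
                    continue
                delta = pr.logpdf_unnorm(prop) - pr.logpdf_unnorm(theta[j])
                new_ll = {}
                for lab in touches[j]:
                    th_a = prop if idx["a"][lab] == j else theta[idx["a"][lab]]
                    th_v = prop if idx["v"][lab] == j else theta[idx["v"][lab]]
                    th_t = prop if idx["t_er"][lab] == j else theta[idx["t_er"][lab]]
                    new_ll[lab] = _cond_loglik(data[lab], th_a, th_v, th_t)
                    delta += new_ll[lab] - ll[lab]
                if delta >= 0 or rng.random() < math.exp(max(delta, -700)):
                    theta[j] = prop
                    ll.update(new_ll)
                    win_acc[j] += 1
                    if it >= burn_in:
                        acc_n[j] += 1
            if it < burn_in and (it + 1) % adapt_interval == 0:
                rate = win_acc / np.maximum(win_n, 1)
                scales *= np.exp(0.8 * (rate - target_accept))
                scales = np.clip(scales, 1e-4, 5.0)
                win_acc[:] = 0
                win_n[:] = 0
            if it >= burn_in:
                k = it - burn_in
                all_draws[c, k] = theta
                all_ll[c, k] = sum(ll.values())
        all_acc[c] = acc_n / draws
        all_scales[c] = scales

    trace = Trace(names, all_draws, all_ll, burn_in, seed, all_acc, all_scales)
    rhat = gelman_rubin(trace)
    mean = {n: float(all_draws[:, :, j].mean()) for j, n in enumerate(names)}
    sd = {n: float(all_draws[:, :, j].std(ddof=1)) for j, n in enumerate(names)}

    fit = FitResult(spec, trace, mean, sd, rhat,
                    math.nan, math.nan, math.nan,
                    converged=bool(max(rhat.values()) < rhat_threshold),
                    rhat_threshold=rhat_threshold)
    d_bar, p_d, dic_val = dic(fit, data)
    fit.mean_deviance, fit.p_d, fit.dic = d_bar, p_d, dic_val
    return fit


def dic(fit: FitResult, data: Dict[str, ChoiceData]):
    """Deviance Information Criterion of a fit.

    D(theta) = -2 log L; returns (D-bar, pD, DIC) with D-bar the posterior
    mean deviance, pD = D-bar - D(theta-bar) the effective number of
    parameters at the posterior mean theta-bar, DIC = D-bar + pD.
    """
    data = {lab: _as_choice_data(d) for lab, d in data.items()}
    d_bar = float(np.mean(-2.0 * fit.trace.loglik))
    idx = fit.spec.index_map()
    theta_bar = {n: fit.posterior_mean[n] for n in fit.trace.param_names}
    ll_hat = 0.0
    for lab in fit.spec.labels:
        names = fit.trace.param_names
        a = theta_bar[names[idx["a"][lab]]]
        v = theta_bar[names[idx["v"][lab]]]
        t = theta_bar[names[idx["t_er"][lab]]]
        ll_hat += _cond_loglik(data[lab], a, v, t)
    d_hat = -2.0 * ll_hat
    p_d = d_bar - d_hat
    return d_bar, p_d, d_bar + p_d


def gelman_rubin(trace: Trace) -> Dict[str, float]:
    """Potential scale reduction factor per parameter (classic PSRF).

    R-hat = sqrt(V-hat / W) with W the mean within-chain variance and
    V-hat = (n-1)/n W + B/n the pooled posterior variance estimate.
    Requires at least two chains.
    """
    nc, nd, _ = trace.draws.shape
    if nc < 2:
        raise ValueError("Gelman-Rubin diagnostic requires >= 2 chains")
    out = {}
    for j, name in enumerate(trace.param_names):
        x = trace.draws[:, :, j]
        w = float(np.mean(np.var(x, axis=1, ddof=1)))
        b_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
        if w <= 0:
            out[name] = 1.0
            continue
        v_hat = (nd - 1) / nd * w + b_over_n
        out[name] = float(np.sqrt(v_hat / w))
    return out


def posterior_prob_greater(trace: Trace | FitResult, param_x: str,
                           param_y: str) -> float:
    """Posterior probability P(x > y): fraction of pooled draws with x > y."""
    tr = trace.trace if isinstance(trace, FitResult) else trace
    return float(np.mean(tr.pooled(param_x) > tr.pooled(param_y)))


def compare_models(data: Dict[str, ChoiceData],
                   specs: Sequence[ModelSpec] | None = None,
                   prior: PriorSpec | None = None, *,
                   chains: int = 4, draws: int = 5000, burn_in: int = 1000,
                   seed: int = 0, rhat_threshold: float = 1.1):
    """Fit every spec to the same data and rank by DIC.

    Returns (table, fits): the table has one
    row per model, its DIC, and the DIC difference to the best-fitting
    model (0 marks the winner); per-fit seeds are recorded.  Any
    non-converged member is flagged in the table.
    """
    labels = tuple(sorted(data))
    if specs is None:
        specs = seven_model_set(labels)
    fits = []
    rows = []
    for k, spec in enumerate(specs):
        fit_seed = (seed * 1009 + k * 9973) % (2 ** 31 - 1)
        fit = fit_pooled(data, spec, prior, chains=chains, draws=draws,
                         burn_in=burn_in, seed=fit_seed,
                         rhat_threshold=rhat_threshold)
        fits.append(fit)
        rows.append(dict(model=spec.name, dic=fit.dic,
                         mean_deviance=fit.mean_deviance, p_d=fit.p_d,
                         max_rhat=max(fit.rhat.values()),
                         converged=fit.converged, seed=fit_seed))
    table = pd.DataFrame(rows)
    table["delta_dic"] = table["dic"] - table["dic"].min()
    table["winner"] = table["delta_dic"] == 0.0
    return table, fits
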