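"""Two-boundary drift-diffusion (Wiener) decision model.

Evidence accumulates at drift rate ``v`` with within-trial noise ``s``
between absorbing boundaries separated by ``a``; absorption at the upper
boundary is a correct response (accuracy coding), at the lower an error.
Observed response time is the first-passage time plus a non-decision
offset ``t_er``.  This module provides the defective first-passage
densities, choice probabilities, closed-form moments for the symmetric
start, quasi-exact sampling by inverse transform of the numerically
integrated CDF, and the dataset log-likelihood used by the Bayesian fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._wfpt import EPS_SERIES, loglik_sum, pdf_array

__all__ = [
    "DDMParams",
    "ChoiceRT",
    "ChoiceData",
    "wfpt_density",
    "prob_upper",
    "mean_decision_time",
    "sample_trials",
    "log_likelihood",
    "FirstPassageSampler",
]


@dataclass(frozen=True)
class DDMParams:
    """Parameters of one diffusion process.

    a : boundary separation (evidence units, > 0)
    v : drift rate (evidence units / s, signed; positive toward correct)
    t_er : non-decision time (s, >= 0)
    z_rel : relative starting point in (0, 1); 0.5 = unbiased
    s : within-trial diffusion coefficient (evidence units / sqrt(s)),
        a fixed scaling convention, never fitted
    """

    a: float
    v: float
    t_er: float = 0.0
    z_rel: float = 0.5
    s: float = 1.0

    def __post_init__(self):
        vals = (self.a, self.v, self.t_er, self.z_rel, self.s)
        if not all(math.isfinite(x) for x in vals):
            raise ValueError(f"non-finite diffusion parameter in {vals}")
        if self.a <= 0:
            raise ValueError(f"boundary separation must be > 0, got {self.a}")
        if not 0 < self.z_rel < 1:
            raise ValueError(f"z_rel must lie in (0, 1), got {self.z_rel}")
        if self.t_er < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.t_er}")
        if self.s <= 0:
            raise ValueError(f"diffusion coefficient must be > 0, got {self.s}")

    def shifted(self, da=0.0, dv=0.0, dt_er=0.0) -> "DDMParams":
        """Return a copy with additive offsets applied (validated)."""
        return replace(self, a=self.a + da, v=self.v + dv, t_er=self.t_er + dt_er)


class ChoiceRT(NamedTuple):
    """One observed decision: boundary hit (True = upper/correct) and RT in s."""

    upper: bool
    rt: float


class ChoiceData:
    """Column store of decisions: rt (s, ndarray) and upper (bool ndarray)."""

    def __init__(self, rt: np.ndarray, upper: np.ndarray):
        rt = np.asarray(rt, dtype=float)
        upper = np.asarray(upper, dtype=bool)
        if rt.shape != upper.shape or rt.ndim != 1:
            raise ValueError("rt and upper must be 1-d arrays of equal length")
        self.rt = rt
        self.upper = upper

    def __len__(self):
        return self.rt.shape[0]

    def __iter__(self):
        for u, t in zip(self.upper, self.rt):
            yield ChoiceRT(bool(u), float(t))

    @classmethod
    def from_records(cls, records: Iterable[ChoiceRT]) -> "ChoiceData":
        recs = list(records)
        return cls(np.array([r.rt for r in recs], dtype=float),
                   np.array([r.upper for r in recs], dtype=bool))

    def concat(self, other: "ChoiceData") -> "ChoiceData":
        return ChoiceData(np.concatenate([self.rt, other.rt]),
                          np.concatenate([self.upper, other.upper]))


def _as_choice_data(data) -> ChoiceData:
    if isinstance(data, ChoiceData):
        return data
    return ChoiceData.from_records(data)


def wfpt_density(t, params: DDMParams, boundary: str = "upper") -> np.ndarray | float:
    """Defective first-passage density over decision time ``t`` (per second).

    ``t`` is the decision time, i.e. the response time minus ``t_er``.
    Integrating over t in (0, inf) yields the probability of absorbing at
    ``boundary`` ('upper' or 'lower').
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = pdf_array(t_arr, params.a, params.v, 0.0, params.z_rel, params.s,
                    boundary == "upper", EPS_SERIES)
    return out if np.ndim(t) else float(out[0])


def prob_upper(params: DDMParams) -> float:
    """Probability of absorbing at the upper (correct) boundary.

    Classical two-boundary absorption probability for drifted Brownian
    motion; continuous limit z_rel at v = 0.
    """
    q = 2.0 * params.v / (params.s * params.s)
    qa = q * params.a
    if abs(qa) < 1e-10:
        return params.z_rel
    z = params.z_rel * params.a
    return math.expm1(-q * z) / math.expm1(-qa)


def mean_decision_time(params: DDMParams) -> float:
    """Mean first-passage time for the symmetric start z_rel = 0.5.

    (a / 2v) * tanh(a v / 2 s^2); limit a^2 / 4 s^2 as v -> 0.  The general
    asymmetric-start expression is not needed anywhere in this package.
    """
    if params.z_rel != 0.5:
        raise NotImplementedError("mean_decision_time requires z_rel = 0.5")
    x = params.a * params.v / (2.0 * params.s * params.s)
    if abs(x) < 1e-9:
        return params.a * params.a / (4.0 * params.s * params.s)
    return params.a / (2.0 * params.v) * math.tanh(x)


class FirstPassageSampler:
    """Quasi-exact trial sampler via inverse transform of the FPT CDF.

    The defective CDFs of both boundaries are integrated on a sqrt-spaced
    time grid (dense near zero, where the density peaks sharply); draws
    invert the conditional CDF by linear interpolation.  Grid resolution is
    chosen so the interpolation error is far below Monte-Carlo noise at the
    sample sizes used here.
    """

    def __init__(self, params: DDMParams, n_grid: int = 4096, tail: float = 1e-9):
        self.params = params
        self.p_upper = prob_upper(params)
        t_max = max(6.0 * (params.a / params.s) ** 2, 1.0)
        for _ in range(60):
            t = (np.linspace(0.0, math.sqrt(t_max), n_grid)) ** 2
            pdf_u = pdf_array(t, params.a, params.v, 0.0, params.z_rel,
                              params.s, True, EPS_SERIES)
            pdf_l = pdf_array(t, params.a, params.v, 0.0, params.z_rel,
                              params.s, False, EPS_SERIES)
            cdf_u = _cumtrapz(pdf_u, t)
            cdf_l = _cumtrapz(pdf_l, t)
            if cdf_u[-1] + cdf_l[-1] >= 1.0 - tail:
                break
            t_max *= 1.7
        self.t_grid = t
        self.cdf_upper = np.minimum(cdf_u / max(cdf_u[-1], 1e-300), 1.0)
        self.cdf_lower = np.minimum(cdf_l / max(cdf_l[-1], 1e-300), 1.0)
        self.mass = cdf_u[-1] + cdf_l[-1]

    def sample(self, n: int, rng: np.random.Generator) -> ChoiceData:
        upper = rng.random(n) < self.p_upper
        u = rng.random(n)
        dt = np.empty(n)
        if upper.any():
            dt[upper] = np.interp(u[upper], self.cdf_upper, self.t_grid)
        if (~upper).any():
            dt[~upper] = np.interp(u[~upper], self.cdf_lower, self.t_grid)
        return ChoiceData(dt + self.params.t_er, upper)

    def numeric_cdf(self, boundary: str = "upper"):
        """(t_grid, conditional CDF) for the named boundary, for diagnostics."""
        cdf = self.cdf_upper if boundary == "upper" else self.cdf_lower
        return self.t_grid + self.params.t_er, cdf


def _cumtrapz(y, x):
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


def sample_trials(params: DDMParams, n: int, seed) -> ChoiceData:
    """Draw ``n`` i.i.d. (boundary, rt) pairs from the diffusion process.

    ``seed`` is mandatory (int or numpy Generator); identical seeds give
    identical output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return FirstPassageSampler(params).sample(n, rng)


def log_likelihood(data, params: DDMParams) -> float:
    """Summed log wfpt density of the dataset at ``params``.

    Any trial with rt <= t_er lies outside the model's support and makes the
    whole sum -inf (a legal return meaning zero likelihood).
    """
    cd = _as_choice_data(data)
    if len(cd) == 0:
        raise ValueError("log_likelihood requires non-empty data")
    return float(loglik_sum(cd.rt, cd.upper, params.a, params.v, params.t_er,
                            params.z_rel, params.s, EPS_SERIES))
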