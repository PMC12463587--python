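"""Parametric survival distributions, MLE fitting, and AIC/BIC model selection.

Five families are supported, all parameterized on a months time scale with
the conventions standard in survival-extrapolation practice:

========== ===================== =========================================
family     parameters            survival function S(t)
========== ===================== =========================================
exponential rate > 0             exp(-rate * t)
weibull     shape, scale > 0     exp(-(t/scale)^shape)
gompertz    shape in R, rate > 0 exp(-(rate/shape) * (exp(shape*t) - 1))
loglogistic shape, scale > 0     1 / (1 + (t/scale)^shape)
lognormal   meanlog in R,        1 - Phi((ln t - meanlog)/sdlog)
            sdlog > 0
========== ===================== =========================================

A Gompertz with negative shape has a defective survival function that
plateaus at exp(rate/shape); the other four families are proper.

Fitting maximizes the right-censored log-likelihood
``sum_events ln f(t_i) + sum_censored ln S(t_i)`` by quasi-Newton search on
log-transformed positive parameters, with multiple starts to guard against
local optima.  The exponential MLE is available in closed form
(rate = events / total follow-up) and is used directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

log = logging.getLogger(__name__)

FAMILIES = ("exponential", "weibull", "gompertz", "loglogistic", "lognormal")

#: parameter names, in canonical order, per family
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
}

#: which parameters must be strictly positive (the rest are unrestricted)
_POSITIVE: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gompertz": ("rate",),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("sdlog",),
}

_EXP_CLIP = 700.0  # exp() overflow guard


@dataclass(frozen=True)
class ParametricSurvival:
    """A named parametric survival model, time unit = months."""

    family: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family: {self.family!r}")
        names = PARAM_NAMES[self.family]
        missing = set(names) - set(self.params)
        if missing:
            raise ValueError(f"{self.family}: missing parameters {sorted(missing)}")
        for name in _POSITIVE[self.family]:
            if not self.params[name] > 0:
                raise ValueError(
                    f"{self.family}: parameter {name}={self.params[name]} must be > 0"
                )
        for name, value in self.params.items():
            if not math.isfinite(value):
                raise ValueError(f"{self.family}: parameter {name} is not finite")

    @property
    def n_params(self) -> int:
        return len(PARAM_NAMES[self.family])

    def survival(self, t):
        """S(t) for scalar or array ``t >= 0``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("t must be finite and >= 0")
        out = np.exp(self.log_survival(t))
        return out if out.ndim else float(out)

    def log_survival(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.family == "exponential":
            return -p["rate"] * t
        if self.family == "weibull":
            with np.errstate(divide="ignore"):
                return -np.power(t / p["scale"], p["shape"])
        if self.family == "gompertz":
            g, r = p["shape"], p["rate"]
            if abs(g) < 1e-12:
                return -r * t
            return -(r / g) * np.expm1(np.clip(g * t, -_EXP_CLIP, _EXP_CLIP))
        if self.family == "loglogistic":
            a, b = p["shape"], p["scale"]
            with np.errstate(divide="ignore"):
                z = a * (np.log(t) - np.log(b))
            # -log(1 + e^z), stable for large |z|
            return -np.logaddexp(0.0, z)
        # lognormal
        mu, sigma = p["meanlog"], p["sdlog"]
        with np.errstate(divide="ignore"):
            z = (np.log(t) - mu) / sigma
        return special.log_ndtr(-z)

    def log_density(self, t):
        """ln f(t); requires t > 0 (except exponential/gompertz, t >= 0)."""
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.family == "exponential":
            return math.log(p["rate"]) - p["rate"] * t
        if self.family == "weibull":
            a, b = p["shape"], p["scale"]
            lt = np.log(t / b)
            return math.log(a / b) + (a - 1.0) * lt - np.exp(a * lt)
        if self.family == "gompertz":
            g, r = p["shape"], p["rate"]
            gt = np.clip(g * t, -_EXP_CLIP, _EXP_CLIP)
            if abs(g) < 1e-12:
                return math.log(r) - r * t
            return math.log(r) + gt - (r / g) * np.expm1(gt)
        if self.family == "loglogistic":
            a, b = p["shape"], p["scale"]
            z = a * (np.log(t) - np.log(b))
            return math.log(a) - np.log(t) + z - 2.0 * np.logaddexp(0.0, z)
        mu, sigma = p["meanlog"], p["sdlog"]
        z = (np.log(t) - mu) / sigma
        return -np.log(t) - math.log(sigma) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` event times by inverse-CDF sampling.

        A defective Gompertz (negative shape) returns ``inf`` for the
        never-event fraction.
        """
        u = rng.uniform(size=n)  # u plays the role of S(t)
        p = self.params
        if self.family == "exponential":
            return -np.log(u) / p["rate"]
        if self.family == "weibull":
            return p["scale"] * np.power(-np.log(u), 1.0 / p["shape"])
        if self.family == "loglogistic":
            return p["scale"] * np.power((1.0 - u) / u, 1.0 / p["shape"])
        if self.family == "lognormal":
            return np.exp(p["meanlog"] + p["sdlog"] * stats.norm.ppf(1.0 - u))
        g, r = p["shape"], p["rate"]
        if abs(g) < 1e-12:
            return -np.log(u) / r
        arg = 1.0 - (g / r) * np.log(u)
        out = np.full(n, np.inf)
        ok = arg > 0
        out[ok] = np.log(arg[ok]) / g
        return out


@dataclass
class FitResult:
    """MLE fit of one family to one IPD set."""

    model: ParametricSurvival
    loglik: float
    aic: float
    bic: float
    n: int
    converged: bool = True

    @classmethod
    def from_loglik(cls, model, loglik, n, converged=True) -> "FitResult":
        k = model.n_params
        return cls(
            model=model,
            loglik=loglik,
            aic=2.0 * k - 2.0 * loglik,
            bic=k * math.log(n) - 2.0 * loglik,
            n=n,
            converged=converged,
        )


def _check_ipd(times: np.ndarray, events: np.ndarray, family: str) -> None:
    if len(times) == 0:
        raise ValueError("empty IPD")
    if events.sum() < 2:
        raise ValueError("need at least 2 events to fit a survival model")
    if np.any(times < 0):
        raise ValueError("negative times in IPD")
    if family in ("loglogistic", "lognormal", "weibull") and np.any(times[events == 1] <= 0):
        raise ValueError(f"{family} requires strictly positive event times")


def loglik(model: ParametricSurvival, times, events) -> float:
    """Right-censored log-likelihood of ``model`` on (times, events)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ll = 0.0
    ev = events == 1
    if ev.any():
        ll += float(np.sum(model.log_density(times[ev])))
    if (~ev).any():
        ll += float(np.sum(model.log_survival(times[~ev])))
    return ll


def _starts(family: str, times: np.ndarray, events: np.ndarray) -> list[np.ndarray]:
    """Three moment-guided starting points on the unconstrained scale."""
    ev_t = times[events == 1]
    ev_t = ev_t[ev_t > 0] if len(ev_t[ev_t > 0]) else np.maximum(ev_t, 1e-6)
    m, med = float(np.mean(ev_t)), float(np.median(ev_t))
    rate0 = events.sum() / max(times.sum(), 1e-12)
    if family == "weibull":
        base = [math.log(1.2), math.log(m)]
    elif family == "gompertz":
        base = [0.01, math.log(max(rate0, 1e-8))]
    elif family == "loglogistic":
        base = [math.log(1.5), math.log(max(med, 1e-6))]
    else:  # lognormal
        lt = np.log(ev_t)
        base = [float(np.mean(lt)), math.log(max(float(np.std(lt)), 1e-3))]
    base = np.asarray(base, dtype=float)
    shifts = [np.zeros(2), np.array([0.7, 0.3]), np.array([-0.7, -0.3])]
    return [base + s for s in shifts]


def _to_params(family: str, x: np.ndarray) -> dict[str, float]:
    names = PARAM_NAMES[family]
    pos = _POSITIVE[family]
    vals = {}
    for name, xi in zip(names, x):
        vals[name] = math.exp(min(xi, _EXP_CLIP)) if name in pos else float(xi)
    return vals


def fit_mle(ipd, family: str) -> FitResult:
    """Fit one parametric family to right-censored IPD by maximum likelihood.

    ``ipd`` is anything with ``time`` and ``event`` columns/fields (an
    ``IPDSet``, a DataFrame, or a dict of arrays).  Raises on fewer than 2
    events; a non-converged optimum is returned with ``converged=False``.
    """
    times, events = _ipd_arrays(ipd)
    _check_ipd(times, events, family)
    n = len(times)

    if family == "exponential":
        # closed-form MLE: rate = d / total follow-up
        d, total = int(events.sum()), float(times.sum())
        rate = d / total
        model = ParametricSurvival("exponential", {"rate": rate})
        return FitResult.from_loglik(model, d * math.log(rate) - rate * total, n)

    def nll(x: np.ndarray) -> float:
        try:
            model = ParametricSurvival(family, _to_params(family, x))
        except ValueError:
            return 1e12
        val = -loglik(model, times, events)
        return val if math.isfinite(val) else 1e12

    best = None
    for x0 in _starts(family, times, events):
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        res = optimize.minimize(nll, res.x, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.fun < 1e11)
    if not converged:
        log.warning("fit_mle(%s): optimizer failed to find a finite optimum", family)
    model = ParametricSurvival(family, _to_params(family, best.x))
    return FitResult.from_loglik(model, -float(best.fun), n, converged=converged)


def select_model(fits: list[FitResult]) -> FitResult:
    """Pick the fit with minimal AIC; ties broken by BIC, then fewer params."""
    if not fits:
        raise ValueError("select_model: empty candidate list")
    return min(fits, key=lambda f: (f.aic, f.bic, f.model.n_params))


def fit_all(ipd, families=FAMILIES) -> list[FitResult]:
    """Fit every family in ``families``, skipping non-convergent ones with a warning."""
    out = []
    for fam in families:
        try:
            out.append(fit_mle(ipd, fam))
        except ValueError as exc:
            log.warning("skipping %s: %s", fam, exc)
    return out


def fit_report(fits: list[FitResult]) -> pd.DataFrame:
    """AIC/BIC selection table, one row per candidate family."""
    rows = []
    for f in fits:
        row = {"family": f.model.family}
        row.update(f.model.params)
        row.update(loglik=f.loglik, aic=f.aic, bic=f.bic, n=f.n, converged=f.converged)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)


def _ipd_arrays(ipd) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(ipd, "times") and hasattr(ipd, "events"):
        return np.asarray(ipd.times, float), np.asarray(ipd.events, int)
    if isinstance(ipd, pd.DataFrame):
        return ipd["time"].to_numpy(float), ipd["event"].to_numpy(int)
    return np.asarray(ipd["time"], float), np.asarray(ipd["event"], int)
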