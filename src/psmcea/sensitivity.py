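"""Deterministic and probabilistic sensitivity analyses, scenarios, pricing.

* ``one_way`` — tornado analysis: each uncertain parameter is set to its low
  and high bound (Table-1 printed ranges; +/-20% where the range is symmetric)
  with everything else at base, and the ICER spread is ranked.
* ``sample_psa`` — Monte-Carlo PSA: every non-fixed parameter is drawn from a
  gamma (costs, weight, BSA) or beta (utilities, probabilities) distribution
  moment-matched to its base value and range, treating the printed range as a
  95% interval (sd = (high - low)/3.92).
* ``ceac`` — cost-effectiveness acceptability: the probability, at each WTP,
  that the incremental net monetary benefit lambda*dE - dC is positive.
* ``scenario_price`` — deterministic re-evaluation with the ramucirumab unit
  price scaled by a multiplier (1.0 / 0.75 / 0.5 / 0.25).
* ``threshold_price`` — bisection on the price multiplier, re-running the PSA
  with common random numbers at each step, for the price at which the
  acceptance probability at the WTP reaches a target (e.g. 50%).

Survival-model parameters carry no ranges and are held fixed throughout
(a known limitation of the source parameter table).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (TABLE1, ModelConfig, evaluate, get_path, perturbed,
                     set_path)
from .costing import ConfigurationError
from .engine import CEComparison

log = logging.getLogger(__name__)

RAMUCIRUMAB_PATH = "prices.ramucirumab"


@dataclass
class ParamSpec:
    """One uncertain parameter: base value, range, sampling distribution."""

    name: str
    path: str
    base: float
    low: float
    high: float
    distribution: str  # gamma | beta | fixed

    def __post_init__(self):
        if self.distribution not in ("gamma", "beta", "fixed"):
            raise ConfigurationError(f"{self.name}: bad distribution")
        if self.low > self.high:
            raise ConfigurationError(f"{self.name}: low > high")
        if not self.low <= self.base <= self.high:
            # tolerated: one printed range in the source table excludes its base
            log.warning("%s: base %.4g outside range [%.4g, %.4g]",
                        self.name, self.base, self.low, self.high)
        if self.distribution == "beta" and not (0 <= self.low and self.high <= 1):
            raise ConfigurationError(f"{self.name}: beta requires values in [0,1]")

    @property
    def sd(self) -> float:
        """Moment-matched sd, treating [low, high] as a 95% interval."""
        return (self.high - self.low) / (2.0 * 1.96)

    def sampler(self):
        """Vectorized sampler ``f(rng, n) -> ndarray`` for this parameter."""
        if self.distribution == "fixed" or self.sd == 0:
            return lambda rng, n: np.full(n, self.base)
        m, s = self.base, self.sd
        if self.distribution == "gamma":
            shape = m * m / (s * s)
            scale = s * s / m
            return lambda rng, n: rng.gamma(shape, scale, size=n)
        # beta, matching mean and sd
        nu = m * (1.0 - m) / (s * s) - 1.0
        if nu <= 0:
            raise ConfigurationError(
                f"{self.name}: sd {s:.4g} too large for a beta with mean {m:.4g}")
        a, b = m * nu, (1.0 - m) * nu
        return lambda rng, n: rng.beta(a, b, size=n)


def default_param_specs(config: ModelConfig) -> list[ParamSpec]:
    """Uncertain-parameter list for one configuration (Table-1 ranges)."""
    side = TABLE1[config.perspective]
    specs: list[ParamSpec] = []

    def add(table: dict, prefix: str, label: str) -> None:
        for key, (base, low, high, dist) in table.items():
            specs.append(ParamSpec(f"{label}: {key}", f"{prefix}.{key}",
                                   base, low, high, dist))

    add(side["prices"], "prices", "price")
    add(side["care"], "care", "care cost")
    add(side["ae_costs"], "ae_costs", "AE cost")
    add(TABLE1["utilities"], "utilities", "utility")
    add(TABLE1["ae_disutility"], "ae_disutility", "disutility")
    add(TABLE1["ae_incidence_switch"], "ae_incidence_switch", "AE incidence (switch)")
    add(TABLE1["ae_incidence_control"], "ae_incidence_control", "AE incidence (control)")
    w, b = side["weight"], side["bsa"]
    specs.append(ParamSpec("patient weight", "patient.weight", w[0], w[1], w[2], w[3]))
    specs.append(ParamSpec("patient BSA", "patient.bsa", b[0], b[1], b[2], b[3]))
    d = side["discount"]
    specs.append(ParamSpec("discount rate", "discount_rate", d[0], d[1], d[2], d[3]))
    return specs


# ---------------------------------------------------------------------------
# One-way (tornado)
# ---------------------------------------------------------------------------

@dataclass
class TornadoEntry:
    name: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def one_way(config: ModelConfig, specs: list[ParamSpec] | None = None
            ) -> list[TornadoEntry]:
    """Tornado analysis: two full evaluations per parameter, sorted by spread."""
    if specs is None:
        specs = default_param_specs(config)
    entries = []
    for spec in specs:
        get_path(config, spec.path)  # raises early on an unresolvable path
        icers = []
        for value in (spec.low, spec.high):
            res = evaluate(perturbed(config, spec.path, value))
            icers.append(res.comparison.icer)
        entries.append(TornadoEntry(spec.name, icers[0], icers[1]))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{"parameter": e.name, "icer_at_low": e.icer_at_low,
                          "icer_at_high": e.icer_at_high, "spread": e.spread}
                         for e in entries])


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """(dC, dE) Monte-Carlo draws plus the CEAC evaluated on a WTP grid."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    wtp: float
    samples: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.delta_cost)

    def acceptance_probability(self, wtp: float | None = None) -> float:
        """Fraction of draws with positive incremental net monetary benefit."""
        lam = self.wtp if wtp is None else wtp
        return float(np.mean(lam * self.delta_qaly - self.delta_cost > 0))

    def ceac(self, wtp_grid) -> pd.DataFrame:
        return ceac(self, wtp_grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delta_cost": self.delta_cost,
                             "delta_qaly": self.delta_qaly,
                             "seed": self.seed})


def draw_parameters(specs: list[ParamSpec], n: int, seed: int) -> pd.DataFrame:
    """Sample all non-fixed parameters; one column per spec path.

    Each parameter consumes its own child generator of a ``SeedSequence``
    spawned from ``seed``, so the draws for one parameter do not depend on
    which other parameters are in the list (common-random-number friendly).
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(specs))
    cols = {}
    for spec, ss in zip(specs, children):
        rng = np.random.Generator(np.random.PCG64(ss))
        cols[spec.path] = spec.sampler()(rng, n)
    return pd.DataFrame(cols)


def sample_psa(config: ModelConfig, specs: list[ParamSpec] | None = None,
               n: int = 5000, seed: int = 2025,
               samples: pd.DataFrame | None = None) -> PSAResult:
    """Monte-Carlo PSA: evaluate the model once per parameter draw.

    Pass ``samples`` (from :func:`draw_parameters`) to reuse a draw table
    across configurations — the common-random-numbers device used by the
    threshold-price search.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if specs is None:
        specs = default_param_specs(config)
    if samples is None:
        samples = draw_parameters(specs, n, seed)
    dc = np.empty(len(samples))
    de = np.empty(len(samples))
    cfg = copy.deepcopy(config)
    for i, row in enumerate(samples.itertuples(index=False)):
        for path, value in zip(samples.columns, row):
            set_path(cfg, path, float(value))
        res = evaluate(cfg)
        dc[i] = res.comparison.delta_cost
        de[i] = res.comparison.delta_qaly
    return PSAResult(dc, de, seed, config.wtp, samples)


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Acceptability curve: P(lambda*dE - dC > 0) over a WTP grid."""
    if psa.n == 0:
        raise ValueError("no PSA draws")
    rows = [{"wtp": float(lam),
             "probability": psa.acceptance_probability(float(lam))}
            for lam in np.asarray(wtp_grid, dtype=float)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenarios and threshold pricing
# ---------------------------------------------------------------------------

def scenario_price(config: ModelConfig, multiplier: float) -> CEComparison:
    """Deterministic base case with the ramucirumab price scaled."""
    if multiplier <= 0:
        raise ValueError("price multiplier must be > 0")
    base = get_path(config, RAMUCIRUMAB_PATH)
    res = evaluate(perturbed(config, RAMUCIRUMAB_PATH, base * multiplier))
    return res.comparison


def scenario_table(config: ModelConfig, multipliers=(1.0, 0.75, 0.5, 0.25),
                   psa_n: int = 0, seed: int = 2025) -> pd.DataFrame:
    """Price-scenario table: price/mg, totals, ICER, acceptance probability."""
    base_price = get_path(config, RAMUCIRUMAB_PATH)
    # the price under study is set by the scenario, not resampled in the PSA
    specs = [s for s in default_param_specs(config)
             if s.path != RAMUCIRUMAB_PATH]
    samples = draw_parameters(specs, psa_n, seed) if psa_n else None
    rows = []
    for m in multipliers:
        cfg = perturbed(config, RAMUCIRUMAB_PATH, base_price * m)
        res = evaluate(cfg)
        row = {
            "price_multiplier": m,
            "ramucirumab_price_per_mg": base_price * m,
            "total_cost_switch": res.switch.total_cost,
            "total_cost_control": res.control.total_cost,
            "qaly_switch": res.switch.total_qaly,
            "qaly_control": res.control.total_qaly,
            "icer": res.comparison.icer,
        }
        if psa_n:
            psa = sample_psa(cfg, specs, psa_n, seed, samples=samples)
            row["acceptance_probability"] = psa.acceptance_probability()
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ThresholdPriceResult:
    price_per_mg: float | None
    multiplier: float | None
    acceptance_probability: float | None
    converged: bool
    message: str = ""


def threshold_price(config: ModelConfig, target_probability: float = 0.5,
                    wtp: float | None = None, seed: int = 2025,
                    n: int = 5000, tol: float = 0.01,
                    max_iter: int = 40) -> ThresholdPriceResult:
    """Ramucirumab price at which P(cost-effective at ``wtp``) hits the target.

    Bisects the price multiplier on (0, 1], re-running the PSA at every
    candidate with common random numbers (one frozen draw table), which makes
    the acceptance probability a non-increasing step function of price.
    Stops when the probability is within ``tol`` of the target or the bracket
    is exhausted.
    """
    wtp = config.wtp if wtp is None else wtp
    base_price = get_path(config, RAMUCIRUMAB_PATH)
    # hold the bisected price fixed per candidate; sample everything else
    specs = [s for s in default_param_specs(config)
             if s.path != RAMUCIRUMAB_PATH]
    samples = draw_parameters(specs, n, seed)

    def prob_at(multiplier: float) -> float:
        cfg = perturbed(config, RAMUCIRUMAB_PATH, base_price * multiplier)
        psa = sample_psa(cfg, specs, n, seed, samples=samples)
        return psa.acceptance_probability(wtp)

    p_zero = prob_at(1e-9)
    if p_zero < target_probability:
        return ThresholdPriceResult(
            None, None, p_zero, False,
            f"acceptance probability at zero price is {p_zero:.3f} < target")
    p_full = prob_at(1.0)
    if p_full >= target_probability:
        return ThresholdPriceResult(base_price, 1.0, p_full, True,
                                    "already acceptable at full price")
    lo, hi = 1e-9, 1.0  # prob(lo) >= target > prob(hi)
    mid, p_mid = lo, p_zero
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p_mid = prob_at(mid)
        if abs(p_mid - target_probability) <= tol:
            break
        if p_mid >= target_probability:
            lo = mid
        else:
            hi = mid
    return ThresholdPriceResult(base_price * mid, mid, p_mid,
                                abs(p_mid - target_probability) <= tol + 0.05,
                                "bisection on price multiplier")
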