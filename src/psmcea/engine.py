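"""Three-state partitioned-survival cohort model and incremental results.

State occupancy is read directly off the survival curves: at any time t the
progression-free fraction is S_PFS(t), the dead fraction 1 - S_OS(t), and
the progressed-disease fraction S_OS(t) - S_PFS(t) (clamped at 0 should the
fitted curves cross, with the clamps counted).  Occupancy within a cycle is
the average of the two boundary values (half-cycle correction) and all
accruals are discounted at the cycle midpoint with the annual formula
(1 + r)^(-t_years).

The default horizon is 10 years in 28-day cycles (130 cycles); terminal-care
cost attaches to the cycle of death via the new-deaths column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costing import DAYS_PER_MONTH, DAYS_PER_YEAR, ArmCosting, ConfigurationError
from .survival import ParametricSurvival

log = logging.getLogger(__name__)

PFS_GT_OS_TOL = 1e-9
COST_COMPONENTS = ("drug", "administration", "tests", "ae", "subsequent",
                   "bsc", "terminal")


@dataclass
class CohortTrace:
    """Per-cycle state membership of the cohort (half-cycle-corrected)."""

    t_start: np.ndarray      # months
    t_end: np.ndarray        # months
    pfs: np.ndarray          # mean PFS-state fraction over the cycle
    pd_frac: np.ndarray      # mean PD-state fraction
    dead: np.ndarray         # mean dead fraction
    new_deaths: np.ndarray   # fraction dying during the cycle
    clamp_events: int = 0

    @property
    def n_cycles(self) -> int:
        return len(self.t_start)

    @property
    def cycle_days(self) -> float:
        return float((self.t_end[0] - self.t_start[0]) * DAYS_PER_MONTH)

    def validate(self) -> None:
        total = self.pfs + self.pd_frac + self.dead
        if np.max(np.abs(total - 1.0)) > 1e-12:
            raise AssertionError("state fractions do not sum to 1")
        for arr in (self.pfs, self.pd_frac, self.dead):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise AssertionError("state fraction outside [0, 1]")
        if np.any(np.diff(self.dead) < -1e-12):
            raise AssertionError("dead fraction decreased")
        if np.any(np.diff(self.pfs) > 1e-12):
            raise AssertionError("PFS fraction increased")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_start_months": self.t_start, "t_end_months": self.t_end,
            "pfs": self.pfs, "pd": self.pd_frac, "dead": self.dead,
            "new_deaths": self.new_deaths,
        })


@dataclass
class StrategyOutcome:
    """Discounted totals for one strategy, with a per-component cost breakdown."""

    name: str
    total_cost: float
    total_qaly: float
    life_years: float
    cost_breakdown: dict[str, float]

    def __post_init__(self):
        if abs(self.total_cost - sum(self.cost_breakdown.values())) > 1e-6 * max(
                1.0, abs(self.total_cost)):
            raise AssertionError("cost breakdown does not sum to total")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"component": k, "cost": v} for k, v in self.cost_breakdown.items()]
        rows.append({"component": "total", "cost": self.total_cost})
        return pd.DataFrame(rows)


@dataclass
class CEComparison:
    """Incremental result of strategy a vs strategy b at a WTP threshold."""

    delta_cost: float
    delta_qaly: float
    icer: float | None          # None when dominance makes it undefined
    dominance: str              # "" | "a_dominant" | "b_dominant"
    wtp: float
    cost_effective: bool


def build_trace(os_model: ParametricSurvival, pfs_model: ParametricSurvival,
                horizon_years: float = 10.0, cycle_days: float = 28.0) -> CohortTrace:
    """Cohort trace from OS and PFS curves over the model horizon.

    One row per cycle; state fractions are boundary averages; PD is clamped
    at 0 wherever S_PFS exceeds S_OS (counted in ``clamp_events``).
    """
    if horizon_years <= 0 or cycle_days <= 0:
        raise ValueError("horizon and cycle length must be > 0")
    cycle_months = cycle_days / DAYS_PER_MONTH
    n_cycles = int(math.floor(horizon_years * 12.0 / cycle_months))
    bounds = np.arange(n_cycles + 1) * cycle_months
    s_os = np.asarray(os_model.survival(bounds))
    s_pfs = np.asarray(pfs_model.survival(bounds))
    excess = s_pfs - s_os
    clamp = int(np.sum(excess > PFS_GT_OS_TOL))
    if clamp:
        log.warning("PFS exceeds OS at %d cycle boundaries (max excess %.3g); "
                    "PD clamped to 0 there", clamp, float(excess.max()))
    s_pfs = np.minimum(s_pfs, s_os)
    pd_b = s_os - s_pfs

    pfs_c = 0.5 * (s_pfs[:-1] + s_pfs[1:])
    pd_c = 0.5 * (pd_b[:-1] + pd_b[1:])
    dead_c = 1.0 - pfs_c - pd_c
    trace = CohortTrace(
        t_start=bounds[:-1], t_end=bounds[1:],
        pfs=pfs_c, pd_frac=pd_c, dead=dead_c,
        new_deaths=s_os[:-1] - s_os[1:], clamp_events=clamp,
    )
    trace.validate()
    return trace


def accumulate(trace: CohortTrace, costing: ArmCosting | None,
               utilities: dict[str, float], discount_rate: float,
               name: str = "") -> StrategyOutcome:
    """Discounted cost, QALY and life-year totals for one strategy.

    Per cycle: QALY += (pfs*u_pfs + pd*u_pd) * cycle_years * d(t);
    cost += (on-treatment cost * pfs + PD cost * pd + terminal * new deaths)
    * d(t); AE cost/disutility land in the first cycle only.  d(t) is
    (1+r)^(-t) at the cycle midpoint.  Life-years are undiscounted.
    """
    u_pfs, u_pd = utilities["pfs"], utilities["pd"]
    if u_pfs < 0 or u_pd < 0:
        raise ConfigurationError("utilities must be >= 0")
    if not 0.0 <= discount_rate <= 0.08:
        raise ConfigurationError("annual discount rate must lie in [0, 0.08]")

    cycle_years = (trace.t_end - trace.t_start) / 12.0
    t_mid_years = 0.5 * (trace.t_start + trace.t_end) / 12.0
    disc = (1.0 + discount_rate) ** (-t_mid_years)

    qaly = float(np.sum((trace.pfs * u_pfs + trace.pd_frac * u_pd) * cycle_years * disc))
    life_years = float(np.sum((trace.pfs + trace.pd_frac) * cycle_years))

    breakdown = dict.fromkeys(COST_COMPONENTS, 0.0)
    if costing is not None:
        cycle_days = trace.cycle_days
        model_days = trace.t_start * DAYS_PER_MONTH
        pfs_disc = trace.pfs * disc
        pd_disc = trace.pd_frac * disc
        for comp, vals in costing.pfs_cost_arrays(model_days, cycle_days).items():
            breakdown[comp] += float(np.dot(np.asarray(vals), pfs_disc))
        for comp, val in costing.pd_cycle_cost(cycle_days).items():
            breakdown[comp] += val * float(pd_disc.sum())
        breakdown["terminal"] += costing.terminal_cost * float(
            np.dot(trace.new_deaths, disc))
        ae_cost, ae_dq = costing.ae_cost_and_disutility()
        breakdown["ae"] += ae_cost * disc[0]
        qaly -= ae_dq * disc[0]

    return StrategyOutcome(
        name=name or (costing.name if costing is not None else ""),
        total_cost=float(sum(breakdown.values())),
        total_qaly=qaly,
        life_years=life_years,
        cost_breakdown=breakdown,
    )


def compare(a: StrategyOutcome, b: StrategyOutcome, wtp: float) -> CEComparison:
    """Incremental cost-effectiveness of strategy ``a`` against ``b``."""
    dc = a.total_cost - b.total_cost
    de = a.total_qaly - b.total_qaly
    dominance = ""
    icer = None
    if de == 0.0:
        dominance = "a_dominant" if dc < 0 else ("b_dominant" if dc > 0 else "")
    elif dc <= 0 and de > 0:
        dominance = "a_dominant"
        icer = dc / de
    elif dc >= 0 and de < 0:
        dominance = "b_dominant"
        icer = dc / de
    else:
        icer = dc / de
    cost_effective = dominance == "a_dominant" or (
        icer is not None and de > 0 and icer <= wtp)
    return CEComparison(delta_cost=dc, delta_qaly=de, icer=icer,
                        dominance=dominance, wtp=wtp,
                        cost_effective=cost_effective)
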