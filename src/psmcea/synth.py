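"""Synthetic two-arm trial data with known ground truth.

Stands in for the unpublished patient-level data behind the survival curves:
generates per-patient OS/PFS times from specified parametric models with
administrative and random (exponential dropout) censoring, and emulates the
"digitized KM curve + numbers-at-risk table" representation that the
reconstruction stage consumes — so every pipeline stage can be validated
round-trip against a known generating truth.

Progression-free survival is coupled to overall survival by drawing a
progression time independently and taking PFS = min(progression, OS), which
guarantees PFS <= OS for every record.  Arm sizes default to the 144/142
randomization of the emulated trial; default curve parameters are the
shipped base-case survival models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import TABLE1
from .reconstruct import DigitizedCurve, IPDSet, RiskTable, km_estimate
from .survival import ParametricSurvival


def _default_models() -> dict[str, ParametricSurvival]:
    return {k: ParametricSurvival(fam, dict(p))
            for k, (fam, p) in TABLE1["survival"]["overall"].items()}


@dataclass
class TrialSpec:
    """Generating truth for one synthetic two-arm trial."""

    models: dict[str, ParametricSurvival] = field(default_factory=_default_models)
    #: keys os_switch, os_control, pfs_switch, pfs_control
    n_switch: int = 144
    n_control: int = 142
    cutoff_months: float = 36.0        # administrative censoring time
    dropout_rate: float = 0.01         # exponential dropout hazard, per month
    seed: int = 0

    def __post_init__(self):
        if self.n_switch < 2 or self.n_control < 2:
            raise ValueError("need at least 2 patients per arm")
        if self.cutoff_months <= 0:
            raise ValueError("administrative cutoff must be > 0")
        if self.dropout_rate < 0:
            raise ValueError("dropout rate must be >= 0")


def gen_ipd(spec: TrialSpec) -> dict[str, IPDSet]:
    """Per-endpoint, per-arm IPD sets: keys like ``os_switch``, ``pfs_control``.

    Per patient, OS is drawn from the arm's OS model and a progression time
    from its PFS model; PFS = min(progression, OS).  Observation stops at
    min(administrative cutoff, exponential dropout); the event flag records
    whether the endpoint preceded censoring.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, IPDSet] = {}
    for arm, n in (("switch", spec.n_switch), ("control", spec.n_control)):
        t_os = spec.models[f"os_{arm}"].rvs(n, rng)
        t_prog = spec.models[f"pfs_{arm}"].rvs(n, rng)
        t_pfs = np.minimum(t_prog, t_os)
        if spec.dropout_rate > 0:
            dropout = rng.exponential(1.0 / spec.dropout_rate, size=n)
        else:
            dropout = np.full(n, np.inf)
        cens = np.minimum(dropout, spec.cutoff_months)
        for endpoint, t_true in (("os", t_os), ("pfs", t_pfs)):
            observed = np.minimum(t_true, cens)
            event = (t_true <= cens).astype(int)
            out[f"{endpoint}_{arm}"] = IPDSet(observed, event, arm=arm)
    return out


def emulate_digitization(ipd: IPDSet, n_points: int = 100,
                         risk_times=None, jitter: float = 0.0,
                         seed: int = 0) -> tuple[DigitizedCurve, RiskTable]:
    """Digitized-curve + risk-table representation of an IPD set.

    The KM estimate is read off at ``n_points`` times spread over the follow-
    up (optionally perturbed by uniform jitter on the survival axis, clipped
    back to monotonicity, to mimic pixel-extraction error); at-risk counts at
    ``risk_times`` are exact.
    """
    if n_points < 5:
        raise ValueError("need at least 5 digitized points")
    km = km_estimate(ipd)
    t_max = float(ipd.times.max())
    times = np.linspace(0.0, t_max, n_points)
    surv = km.at(times).astype(float)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        surv = surv + rng.uniform(-jitter, jitter, size=n_points)
        surv[0] = 1.0
        surv = np.minimum.accumulate(np.clip(surv, 0.0, 1.0))
    curve = DigitizedCurve(times, surv)
    if risk_times is None:
        risk_times = np.linspace(0.0, t_max, 7)[:-1]
    risk_times = np.asarray(risk_times, dtype=float)
    n_risk = np.array([(ipd.times >= t).sum() for t in risk_times], dtype=int)
    return curve, RiskTable(risk_times, n_risk, total_events=ipd.n_events)
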