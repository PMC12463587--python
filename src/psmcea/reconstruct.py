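"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published KM figures carry more information than the medians quoted in text:
together with the numbers-at-risk row they almost fully determine the event
and censoring pattern.  The iterative algorithm of Guyot et al. (the standard
tool for this job) is implemented here: within each at-risk interval it
solves for event and censoring counts consistent with the digitized survival
drops and the next published at-risk count, assuming censoring is spread
uniformly within the interval.  The product-limit estimator computed from
the reconstructed records then reproduces the digitized curve.

Inputs and outputs travel as plain CSV: digitized points (time, surv),
risk table (time, n_risk), IPD (time, event).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

log = logging.getLogger(__name__)


@dataclass
class DigitizedCurve:
    """Ordered (time, survival) coordinates read off a published KM plot."""

    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.times.shape != self.surv.shape or self.times.ndim != 1:
            raise ValueError("times and surv must be equal-length 1-d arrays")
        if len(self.times) < 2:
            raise ValueError("need at least two digitized points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("digitized times must be strictly increasing")
        if np.any(self.surv > 1 + 1e-9) or np.any(self.surv < -1e-9):
            raise ValueError("survival probabilities must lie in [0, 1]")
        self.surv = np.clip(self.surv, 0.0, 1.0)
        rises = np.diff(self.surv) > 0
        if rises.any():
            # tiny digitization jitter is repaired; real rises are rejected
            if np.max(np.diff(self.surv)[rises]) > 0.02:
                k = int(np.argmax(np.diff(self.surv)))
                raise ValueError(
                    f"survival rises by more than digitization jitter between "
                    f"t={self.times[k]} and t={self.times[k + 1]}"
                )
            log.warning("digitized survival not monotone; snapping %d point(s)",
                        int(rises.sum()))
            self.surv = np.minimum.accumulate(self.surv)

    @classmethod
    def read_csv(cls, path) -> "DigitizedCurve":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["surv"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "surv": self.surv}).to_csv(path, index=False)

    def at(self, t) -> np.ndarray:
        """Step-function value at times ``t`` (right-continuous)."""
        idx = np.searchsorted(self.times, np.asarray(t, float), side="right") - 1
        return self.surv[np.clip(idx, 0, len(self.surv) - 1)]


@dataclass
class RiskTable:
    """Numbers at risk at published times; first entry must be at time 0."""

    times: np.ndarray
    n_risk: np.ndarray
    total_events: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=int)
        if self.times[0] != 0:
            raise ValueError("risk table must start at time 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(self.n_risk < 0) or np.any(np.diff(self.n_risk) > 0):
            raise ValueError("numbers at risk must be non-negative and non-increasing")

    @classmethod
    def read_csv(cls, path) -> "RiskTable":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["n_risk"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.times, "n_risk": self.n_risk}).to_csv(path, index=False)


@dataclass
class IPDSet:
    """Per-patient (time, event) records for one endpoint of one arm."""

    times: np.ndarray
    events: np.ndarray
    arm: str = ""
    population: str = "overall"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if np.any(self.times < 0):
            raise ValueError("times must be >= 0")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "event": self.events, "arm": self.arm})

    @classmethod
    def read_csv(cls, path, arm: str = "", population: str = "overall") -> "IPDSet":
        df = pd.read_csv(path)
        if "arm" in df.columns and not arm:
            arms = df["arm"].unique()
            if len(arms) == 1:
                arm = str(arms[0])
        return cls(df["time"].to_numpy(), df["event"].to_numpy(), arm, population)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def km_estimate(ipd: IPDSet) -> DigitizedCurve:
    """Product-limit (Kaplan-Meier) estimate of an IPD set, as a step curve."""
    if len(ipd) == 0:
        raise ValueError("empty IPD")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, ipd.events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    if t[0] != 0:
        t = np.insert(t, 0, 0.0)
        s = np.insert(s, 0, 1.0)
    return DigitizedCurve(t, s)


def reconstruct_ipd(curve: DigitizedCurve, risk: RiskTable,
                    arm: str = "", population: str = "overall") -> IPDSet:
    """Guyot reconstruction of pseudo-IPD from a digitized curve + risk table.

    Iterates, per at-risk interval, on the number censored until the implied
    at-risk count at the start of the next interval matches the published
    one; censoring times are spread uniformly within the interval.  If the
    risk table carries ``total_events``, censoring in the final interval is
    additionally adjusted so the total event count matches.
    """
    t_s = curve.times.copy()
    s = curve.surv.copy()
    if t_s[0] != 0 or s[0] != 1.0:
        t_s = np.insert(t_s, 0, 0.0)
        s = np.insert(s, 0, 1.0)
    t_risk = risk.times
    n_risk = risk.n_risk.astype(float).copy()
    if t_risk[-1] > t_s[-1]:
        raise ValueError("risk table extends beyond the digitized curve")
    n_int = len(t_risk)
    n_k = len(t_s)

    # lower[i]: first digitized index at/after risk time i; last interval runs to the end
    lower = np.searchsorted(t_s, t_risk, side="left")
    if lower[0] != 0:
        raise ValueError("digitized curve must start at the first risk-table time (0)")
    upper = np.append(lower[1:] - 1, n_k - 1)

    d = np.zeros(n_k, dtype=int)         # events at click k
    cen_k = np.zeros(n_k, dtype=int)     # censorings in (t_k, t_{k+1})
    n_hat = np.zeros(n_k + 1)
    n_hat[0] = n_risk[0]
    km_hat = np.ones(n_k)
    last_i = 0                           # index of last click with an event

    def run_interval(i: int, n_cen: int, last: int) -> int:
        """Distribute ``n_cen`` censorings over interval i and recompute clicks.

        Returns the index of the last event click.  Updates d, cen_k, n_hat,
        km_hat in place over clicks lower[i]..upper[i].
        """
        lo, up = lower[i], upper[i]
        t_end = t_risk[i + 1] if i + 1 < n_int else t_s[-1]
        # uniform censor times over the interval
        if n_cen > 0:
            cen_t = t_s[lo] + (np.arange(1, n_cen + 1)) * (t_end - t_s[lo]) / (n_cen + 1)
        else:
            cen_t = np.empty(0)
        # bucket them by click: censorings in (t_k, t_{k+1})
        edges = np.append(t_s[lo:up + 1], t_end)
        counts, _ = np.histogram(cen_t, bins=np.append(edges[:-1], np.inf))
        n_hat[lo] = n_risk[i]
        for j, k in enumerate(range(lo, up + 1)):
            if k == 0:
                d[k] = 0
                km_hat[k] = 1.0
            else:
                if n_hat[k] > 0:
                    d[k] = int(round(n_hat[k] * (1.0 - s[k] / km_hat[last])))
                    d[k] = max(0, min(d[k], int(n_hat[k])))
                    km_hat[k] = km_hat[last] * (1.0 - d[k] / n_hat[k])
                else:
                    d[k] = 0
                    km_hat[k] = km_hat[last]
            cen_k[k] = counts[j]
            n_hat[k + 1] = n_hat[k] - d[k] - cen_k[k]
            if d[k] != 0:
                last = k
        return last

    for i in range(n_int - 1):
        lo, up = lower[i], upper[i]
        # first guess for number censored in interval i
        denom = s[lo] if s[lo] > 0 else 1.0
        n_cen = int(round(n_hat[lo] * s[lower[i + 1]] / denom)) - int(n_risk[i + 1])
        guard = 0
        while True:
            n_cen = max(0, min(n_cen, int(n_hat[lo])))
            last = run_interval(i, n_cen, last_i)
            gap = n_hat[lower[i + 1]] - n_risk[i + 1]
            if gap == 0 or (gap < 0 and n_cen == 0) or guard > 2 * int(n_risk[0]) + 10:
                break
            n_cen += int(gap)
            guard += 1
        if n_hat[lower[i + 1]] < n_risk[i + 1]:
            n_risk[i + 1] = n_hat[lower[i + 1]]
        last_i = last

    # last interval: censoring from the average prior censoring rate (Guyot),
    # or solved against the reported total event count when available
    i = n_int - 1
    lo = lower[i]
    t_end = t_s[-1]
    if n_int > 1 and t_risk[-1] > 0:
        cen_rate = cen_k[:lo].sum() / t_risk[-1]
    else:
        cen_rate = 0.0
    n_cen = min(int(round(cen_rate * (t_end - t_s[lo]))), int(n_hat[lo]))
    last_before = last_i  # last event click prior to the final interval
    last_i = run_interval(i, n_cen, last_before)
    if risk.total_events is not None:
        # monotone search: more censoring -> fewer events
        guard = 0
        while d.sum() != risk.total_events and guard <= int(n_risk[0]):
            step = int(d.sum() - risk.total_events)
            new_cen = max(0, min(n_cen + step, int(n_hat[lo])))
            if new_cen == n_cen:
                break  # bracket exhausted; leave the closest attainable count
            n_cen = new_cen
            last_i = run_interval(i, n_cen, last_before)
            guard += 1

    # assemble records: events at clicks, censorings inside intervals,
    # survivors administratively censored at the last digitized time
    times, events = [], []
    for k in range(n_k):
        times.extend([t_s[k]] * d[k])
        events.extend([1] * d[k])
    for i in range(n_int):
        lo, up = lower[i], upper[i]
        t_end = t_risk[i + 1] if i + 1 < n_int else t_s[-1]
        n_cen_i = int(cen_k[lo:up + 1].sum())
        if n_cen_i > 0:
            cen_t = t_s[lo] + np.arange(1, n_cen_i + 1) * (t_end - t_s[lo]) / (n_cen_i + 1)
            times.extend(cen_t.tolist())
            events.extend([0] * n_cen_i)
    n_left = int(round(n_hat[n_k]))
    if n_left > 0:
        times.extend([t_s[-1]] * n_left)
        events.extend([0] * n_left)
    order = np.argsort(times, kind="stable")
    ipd = IPDSet(np.asarray(times)[order], np.asarray(events)[order], arm, population)
    if len(ipd) != int(risk.n_risk[0]):
        log.warning("reconstructed cohort size %d != initial at-risk %d",
                    len(ipd), int(risk.n_risk[0]))
    return ipd
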