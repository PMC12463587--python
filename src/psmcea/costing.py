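"""Per-cycle cost and disutility quantities for each strategy, arm, country.

Turns dosing regimens (mg/kg, mg/m², flat), unit drug prices (USD/mg),
patient anthropometrics, adverse-event profiles, and care costs into the
per-model-cycle quantities the partitioned-survival engine accrues:

* on-treatment cost per cycle of PFS occupancy (drugs, administration fees,
  monitoring tests), respecting treatment-duration windows;
* progressed-disease cost per cycle of PD occupancy (subsequent active
  therapy for a fraction of patients, best supportive care for the rest);
* one-off adverse-event cost and QALY decrement (first model cycle);
* terminal-care cost per death.

Regimens on 21- or 14-day cycles are aligned onto the 28-day model cycle by
scaling the per-regimen-cycle cost by ``model_cycle_days/regimen_cycle_days``.
Fractional milligrams are priced exactly (no vial rounding / wastage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0  # one global month-length constant


class ConfigurationError(ValueError):
    """A cost input is missing or out of range."""


@dataclass
class Patient:
    weight: float  # kg
    bsa: float     # m^2

    def __post_init__(self):
        if self.weight <= 0 or self.bsa <= 0:
            raise ConfigurationError("patient weight and BSA must be > 0")


@dataclass
class RegimenComponent:
    """One drug within a regimen, with its dosing rule and schedule."""

    drug: str
    dose_basis: str          # per_kg | per_m2 | flat
    dose_value: float        # mg per basis unit, per administration day
    administration_days: tuple[int, ...]
    regimen_cycle_days: int
    admin_cost_class: str = "intravenous"   # intravenous | injection | oral
    active_window_days: tuple[float, float] | None = None
    #: model-time window [start, stop) in days during which the component is
    #: given; None = whole horizon (e.g. "until progression")
    weight: float = 1.0
    #: fraction of the cohort receiving this component (regimen-mix weight)

    def __post_init__(self):
        if self.dose_basis not in ("per_kg", "per_m2", "flat"):
            raise ConfigurationError(f"{self.drug}: bad dose_basis {self.dose_basis!r}")
        if self.dose_value <= 0:
            raise ConfigurationError(f"{self.drug}: dose_value must be > 0")
        if self.admin_cost_class not in ("intravenous", "injection", "oral"):
            raise ConfigurationError(f"{self.drug}: bad admin class")
        if any(d < 1 or d > self.regimen_cycle_days for d in self.administration_days):
            raise ConfigurationError(f"{self.drug}: administration day outside cycle")

    def active_at(self, model_day: float) -> bool:
        if self.active_window_days is None:
            return True
        lo, hi = self.active_window_days
        return lo <= model_day < hi


@dataclass
class AEItem:
    """A grade >=3 adverse event with incidence, cost and utility decrement."""

    name: str
    incidence: float
    management_cost: float
    disutility: float

    def __post_init__(self):
        if not 0.0 <= self.incidence <= 1.0:
            raise ConfigurationError(f"{self.name}: incidence must be in [0,1]")
        if self.management_cost < 0 or not 0.0 <= self.disutility <= 1.0:
            raise ConfigurationError(f"{self.name}: bad cost/disutility")


@dataclass
class CareCosts:
    """Unit test/administration/care costs and the monitoring schedule."""

    enhanced_ct: float
    blood_biochemistry: float
    blood_routine: float
    urine_routine: float
    injection_administration: float
    intravenous_injection: float
    bsc_per_cycle: float
    terminal_care: float
    # monitoring: units of each test per model cycle while on treatment
    ct_per_cycle: float = 0.5
    biochemistry_per_cycle: float = 1.0
    blood_routine_per_cycle: float = 1.0
    urine_routine_per_cycle: float = 1.0

    def __post_init__(self):
        for name in ("enhanced_ct", "blood_biochemistry", "blood_routine",
                     "urine_routine", "injection_administration",
                     "intravenous_injection", "bsc_per_cycle", "terminal_care"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"care cost {name} must be >= 0")

    def monitoring_cost_per_cycle(self) -> float:
        return (self.ct_per_cycle * self.enhanced_ct
                + self.biochemistry_per_cycle * self.blood_biochemistry
                + self.blood_routine_per_cycle * self.blood_routine
                + self.urine_routine_per_cycle * self.urine_routine)

    def admin_fee(self, admin_class: str) -> float:
        if admin_class == "intravenous":
            return self.intravenous_injection
        if admin_class == "injection":
            return self.injection_administration
        return 0.0


@dataclass
class SubsequentTherapy:
    """Post-progression management: active regimen for a fraction, BSC for the rest."""

    fraction_active: float
    active_regimen: tuple[RegimenComponent, ...]

    def __post_init__(self):
        if not 0.0 <= self.fraction_active <= 1.0:
            raise ConfigurationError("fraction_active must be in [0,1]")


def dose_mg(component: RegimenComponent, patient: Patient) -> float:
    """Milligrams per administration day for one patient."""
    if component.dose_basis == "per_kg":
        return component.dose_value * patient.weight
    if component.dose_basis == "per_m2":
        return component.dose_value * patient.bsa
    return component.dose_value


def model_cycle_drug_cost(components, prices: dict[str, float], patient: Patient,
                          care: CareCosts, model_cycle_days: float = 28.0,
                          model_day: float = 0.0,
                          include_admin: bool = True) -> tuple[float, float]:
    """(drug cost, administration-fee cost) accrued in one model cycle.

    Components whose active window excludes ``model_day`` (the cycle start in
    model time) contribute nothing; regimen cycles shorter than the model
    cycle are scaled up by ``model_cycle_days / regimen_cycle_days``.
    """
    drug = admin = 0.0
    for comp in components:
        if not comp.active_at(model_day):
            continue
        if comp.drug not in prices:
            raise ConfigurationError(f"no unit price configured for drug {comp.drug!r}")
        scale = comp.weight * model_cycle_days / comp.regimen_cycle_days
        n_admin = len(comp.administration_days)
        drug += dose_mg(comp, patient) * n_admin * prices[comp.drug] * scale
        if include_admin:
            admin += n_admin * care.admin_fee(comp.admin_cost_class) * scale
    return drug, admin


def ae_burden(profile, duration_years: float = 28.0 / DAYS_PER_YEAR
              ) -> tuple[float, float]:
    """Expected one-off AE management cost and QALY decrement.

    QALY decrement = sum incidence * disutility * duration; the default
    duration is one 28-day model cycle.
    """
    cost = sum(a.incidence * a.management_cost for a in profile)
    qaly = sum(a.incidence * a.disutility * duration_years for a in profile)
    return cost, qaly


@dataclass
class ArmCosting:
    """Everything the engine needs to cost one strategy arm."""

    name: str
    regimen: tuple[RegimenComponent, ...]
    prices: dict[str, float]
    patient: Patient
    care: CareCosts
    subsequent: SubsequentTherapy
    ae_profile: tuple[AEItem, ...]
    ae_duration_years: float = 28.0 / DAYS_PER_YEAR
    monitor_in_pd: bool = False

    def pfs_cycle_cost(self, model_day: float,
                       model_cycle_days: float = 28.0) -> dict[str, float]:
        """Cost per cycle of PFS occupancy, by component, at a cycle start."""
        drug, admin = model_cycle_drug_cost(
            self.regimen, self.prices, self.patient, self.care,
            model_cycle_days, model_day)
        tests = self.care.monitoring_cost_per_cycle()
        return {"drug": drug, "administration": admin, "tests": tests}

    def pfs_cost_arrays(self, model_days, model_cycle_days: float = 28.0
                        ) -> dict[str, list]:
        """Per-cycle on-treatment costs for a whole vector of cycle starts.

        Memoized on the active-component signature, so regimens that only
        change at a treatment-cap boundary cost two evaluations, not one per
        cycle.
        """
        cache: dict[tuple, dict[str, float]] = {}
        out = {"drug": [], "administration": [], "tests": []}
        for day in model_days:
            key = tuple(c.active_at(day) for c in self.regimen)
            if key not in cache:
                cache[key] = self.pfs_cycle_cost(day, model_cycle_days)
            for comp, val in cache[key].items():
                out[comp].append(val)
        return out

    def pd_cycle_cost(self, model_cycle_days: float = 28.0) -> dict[str, float]:
        """Cost per cycle of PD occupancy, by component."""
        f = self.subsequent.fraction_active
        drug, admin = model_cycle_drug_cost(
            self.subsequent.active_regimen, self.prices, self.patient,
            self.care, model_cycle_days, 0.0)
        tests = self.care.monitoring_cost_per_cycle() if self.monitor_in_pd else 0.0
        return {"subsequent": f * (drug + admin) + tests,
                "bsc": (1.0 - f) * self.care.bsc_per_cycle}

    def ae_cost_and_disutility(self) -> tuple[float, float]:
        return ae_burden(self.ae_profile, self.ae_duration_years)

    @property
    def terminal_cost(self) -> float:
        return self.care.terminal_care
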