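"""Analysis configuration: base-case parameter set, schema, and evaluation.

One ``ModelConfig`` holds every input of one perspective x population cell:
fitted survival models, unit drug prices (USD/mg), dosing regimens, care and
adverse-event costs, utilities, discount rate and WTP threshold.  Shipped
defaults come from ``TABLE1``, a machine-readable copy of the base-case
parameter table (2023 USD; Chinese prices from the Shanghai Sunshine
procurement network, US prices from the Red Book / Medicare fee schedules;
survival parameters fitted to the ARMANI trial curves).

``evaluate(config)`` runs both strategies through the partitioned-survival
engine and returns the incremental comparison; it is the single entry point
the base case, tornado, PSA and scenario analyses all share.  Uncertain
parameters are addressed by dotted paths into the config (e.g.
``prices.ramucirumab``, ``utilities.pfs``, ``patient.weight``), which is how
the sensitivity module perturbs them.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from .costing import (AEItem, ArmCosting, CareCosts, ConfigurationError,
                      Patient, RegimenComponent, SubsequentTherapy,
                      DAYS_PER_YEAR)
from .engine import CEComparison, StrategyOutcome, accumulate, build_trace, compare
from .survival import ParametricSurvival

log = logging.getLogger(__name__)

PERSPECTIVES = ("china", "us")
POPULATIONS = ("overall", "cps_ge5")

# ---------------------------------------------------------------------------
# Machine-readable base-case parameter table.
# Scalars are (base, low, high, distribution); distribution "fixed" means the
# parameter is not sampled in PSA (its range is still used one-way).
# ---------------------------------------------------------------------------
TABLE1: dict = {
    "survival": {
        "overall": {
            "os_switch": ("loglogistic", {"shape": 2.309, "scale": 13.051}),
            "os_control": ("loglogistic", {"shape": 1.891, "scale": 9.593}),
            "pfs_switch": ("loglogistic", {"shape": 2.061, "scale": 6.767}),
            "pfs_control": ("loglogistic", {"shape": 1.697, "scale": 3.579}),
        },
        "cps_ge5": {
            "os_switch": ("loglogistic", {"shape": 2.386, "scale": 15.518}),
            "os_control": ("lognormal", {"meanlog": 2.376, "sdlog": 0.805}),
            "pfs_switch": ("lognormal", {"meanlog": 2.0989, "sdlog": 0.7146}),
            "pfs_control": ("lognormal", {"meanlog": 1.802, "sdlog": 0.856}),
        },
    },
    "china": {
        "prices": {  # USD per mg
            "ramucirumab": (5.2322, 4.186, 6.279, "gamma"),
            "paclitaxel": (0.280, 0.224, 0.335, "gamma"),
            "ondansetron": (0.360, 0.288, 0.433, "gamma"),
            "dexamethasone": (0.018, 0.0148, 0.0221, "gamma"),
            "diphenhydramine": (0.103, 0.0823, 0.123, "gamma"),
            "capecitabine": (0.000653, 0.000522, 0.000783, "gamma"),
            "calcium_folinate": (0.0355, 0.0284, 0.0426, "gamma"),
            "oxaliplatin": (0.881, 0.705, 1.058, "gamma"),
            "fluorouracil": (0.0183, 0.0146, 0.0220, "gamma"),
            "irinotecan": (0.0955, 0.0764, 0.115, "gamma"),
        },
        "care": {
            "enhanced_ct": (23.693, 10.659, 106.647, "gamma"),
            "blood_biochemistry": (63.814, 33.253, 93.564, "gamma"),
            "blood_routine": (1.930, 1.425, 3.622, "gamma"),
            "urine_routine": (0.594, 0.287, 2.553, "gamma"),
            "injection_administration": (0.802, 0.158, 0.643, "gamma"),
            "intravenous_injection": (0.713, 0.356, 1.564, "gamma"),
            "terminal_care": (1506.51, 1205.21, 1807.81, "gamma"),
            "bsc_per_cycle": (267.78, 214.22, 321.34, "gamma"),
        },
        "ae_costs": {
            "neutropenia": (136.792, 109.418, 164.147, "gamma"),
            "peripheral_neuropathy": (1097.008, 877.607, 1316.410, "gamma"),
            "hypertension": (17.824, 14.261, 21.387, "gamma"),
        },
        "weight": (69.0, 55.2, 82.88, "gamma"),
        "bsa": (1.74, 1.392, 2.088, "gamma"),
        "discount": (0.05, 0.0, 0.08, "fixed"),
        "wtp": 38042.49,
    },
    "us": {
        "prices": {
            "ramucirumab": (15.0, 12.0, 18.0, "gamma"),
            "paclitaxel": (0.2882, 0.23056, 0.34584, "gamma"),
            "ondansetron": (0.1056, 0.08448, 0.12672, "gamma"),
            "dexamethasone": (0.02255, 0.01804, 0.02706, "gamma"),
            "diphenhydramine": (0.0602, 0.04816, 0.07224, "gamma"),
            "capecitabine": (0.002, 0.0016, 0.0024, "gamma"),
            "calcium_folinate": (0.07026, 0.056208, 0.084312, "gamma"),
            "oxaliplatin": (0.6, 0.48, 0.72, "gamma"),
            "fluorouracil": (0.01027, 0.008216, 0.012324, "gamma"),
            "irinotecan": (0.3, 0.24, 0.36, "gamma"),
        },
        "care": {
            "enhanced_ct": (530.79, 424.63, 636.95, "gamma"),
            "blood_biochemistry": (10.56, 8.45, 12.67, "gamma"),
            "blood_routine": (7.77, 6.22, 9.32, "gamma"),
            "urine_routine": (3.17, 2.54, 3.80, "gamma"),
            "injection_administration": (13.91, 11.13, 16.69, "gamma"),
            "intravenous_injection": (223.30, 178.64, 267.96, "gamma"),
            "terminal_care": (19247.03, 15397.62, 23096.44, "gamma"),
            "bsc_per_cycle": (2262.59, 1810.07, 2715.11, "gamma"),
        },
        "ae_costs": {
            "neutropenia": (18360.82, 14688.66, 22032.98, "gamma"),
            "peripheral_neuropathy": (14184.2, 11347.36, 17021.04, "gamma"),
            "hypertension": (19272.01, 15417.61, 23126.41, "gamma"),
        },
        "weight": (75.0, 60.0, 90.0, "gamma"),
        "bsa": (1.8, 1.44, 2.16, "gamma"),
        "discount": (0.03, 0.0, 0.08, "fixed"),
        "wtp": 150000.0,
    },
    "utilities": {
        "pfs": (0.797, 0.64, 0.96, "beta"),
        "pd": (0.577, 0.46, 0.69, "beta"),
    },
    "ae_disutility": {
        "neutropenia": (0.2, 0.16, 0.24, "beta"),
        "peripheral_neuropathy": (0.16, 0.128, 0.192, "beta"),
        "hypertension": (0.04, 0.032, 0.048, "beta"),
    },
    "ae_incidence_switch": {
        "neutropenia": (0.2624, 0.2099, 0.3149, "beta"),
        "peripheral_neuropathy": (0.06, 0.048, 0.072, "beta"),
        "hypertension": (0.06, 0.048, 0.072, "beta"),
    },
    "ae_incidence_control": {
        "neutropenia": (0.0963, 0.0770, 0.1156, "beta"),
        "peripheral_neuropathy": (0.07, 0.056, 0.084, "beta"),
    },
    "subsequent_fraction": {"switch": 0.58, "control": 0.56},
}


@dataclass
class ModelConfig:
    """All inputs for one perspective x population base case."""

    perspective: str
    population: str
    patient: Patient
    prices: dict[str, float]
    care: CareCosts
    utilities: dict[str, float]
    ae_costs: dict[str, float]
    ae_disutility: dict[str, float]
    ae_incidence_switch: dict[str, float]
    ae_incidence_control: dict[str, float]
    survival: dict[str, ParametricSurvival]
    discount_rate: float
    wtp: float
    horizon_years: float = 10.0
    cycle_days: float = 28.0
    subsequent_fraction_switch: float = 0.58
    subsequent_fraction_control: float = 0.56
    capox_fraction: float = 0.5          # CAPOX vs FOLFOX mix in the control arm
    oxaliplatin_cap_days: float = 168.0  # 24 weeks of oxaliplatin-based therapy
    premed_doses: dict[str, float] = field(default_factory=lambda: {
        "ondansetron": 8.0, "dexamethasone": 10.0, "diphenhydramine": 25.0})
    ae_duration_years: float = 28.0 / DAYS_PER_YEAR

    def __post_init__(self):
        if self.perspective not in PERSPECTIVES:
            raise ConfigurationError(f"perspective must be one of {PERSPECTIVES}")
        if self.population not in POPULATIONS:
            raise ConfigurationError(f"population must be one of {POPULATIONS}")

    # -- regimen construction ------------------------------------------------

    def switch_regimen(self) -> tuple[RegimenComponent, ...]:
        """Ramucirumab 8 mg/kg d1,8 + paclitaxel 80 mg/m2 d1,8,15 q28d,
        with antiemetic/antihistamine premedication at each paclitaxel dose,
        continued until progression."""
        pac_days = (1, 8, 15)
        comps = [
            RegimenComponent("ramucirumab", "per_kg", 8.0, (1, 8), 28, "intravenous"),
            RegimenComponent("paclitaxel", "per_m2", 80.0, pac_days, 28, "intravenous"),
        ]
        for drug, dose in self.premed_doses.items():
            comps.append(RegimenComponent(drug, "flat", dose, pac_days, 28, "injection"))
        return tuple(comps)

    def control_regimen(self) -> tuple[RegimenComponent, ...]:
        """CAPOX/FOLFOX mix for 24 weeks, then fluoropyrimidine alone.

        CAPOX: oxaliplatin 130 mg/m2 d1 + capecitabine 1000 mg/m2 b.i.d.
        d1-14, q21d.  FOLFOX: oxaliplatin 85 mg/m2 + calcium folinate
        400 mg/m2 + 5-FU 400 mg/m2 bolus and 2400 mg/m2 infusion, q14d.
        After the cap the fluoropyrimidine continues at the same dose.
        """
        w_cap = self.capox_fraction
        w_fol = 1.0 - w_cap
        combo = (0.0, self.oxaliplatin_cap_days)
        mono = (self.oxaliplatin_cap_days, float("inf"))
        cape_days = tuple(range(1, 15))
        comps = []
        if w_cap > 0:
            comps += [
                RegimenComponent("oxaliplatin", "per_m2", 130.0, (1,), 21,
                                 "intravenous", combo, w_cap),
                RegimenComponent("capecitabine", "per_m2", 2000.0, cape_days, 21,
                                 "oral", combo, w_cap),
                RegimenComponent("capecitabine", "per_m2", 2000.0, cape_days, 21,
                                 "oral", mono, w_cap),
            ]
        if w_fol > 0:
            comps += [
                RegimenComponent("oxaliplatin", "per_m2", 85.0, (1,), 14,
                                 "intravenous", combo, w_fol),
                RegimenComponent("calcium_folinate", "per_m2", 400.0, (1,), 14,
                                 "intravenous", combo, w_fol),
                RegimenComponent("fluorouracil", "per_m2", 2800.0, (1,), 14,
                                 "intravenous", combo, w_fol),
                RegimenComponent("fluorouracil", "per_m2", 2800.0, (1,), 14,
                                 "intravenous", mono, w_fol),
            ]
        return tuple(comps)

    def subsequent_therapy(self, arm: str) -> SubsequentTherapy:
        """Irinotecan 150 mg/m2 d1 q21d for the active-therapy fraction."""
        frac = (self.subsequent_fraction_switch if arm == "switch"
                else self.subsequent_fraction_control)
        iri = RegimenComponent("irinotecan", "per_m2", 150.0, (1,), 21, "intravenous")
        return SubsequentTherapy(frac, (iri,))

    def ae_profile(self, arm: str) -> tuple[AEItem, ...]:
        inc = (self.ae_incidence_switch if arm == "switch"
               else self.ae_incidence_control)
        return tuple(
            AEItem(name, p, self.ae_costs[name], self.ae_disutility[name])
            for name, p in inc.items())

    def arm_costing(self, arm: str) -> ArmCosting:
        regimen = self.switch_regimen() if arm == "switch" else self.control_regimen()
        return ArmCosting(
            name=arm, regimen=regimen, prices=self.prices, patient=self.patient,
            care=self.care, subsequent=self.subsequent_therapy(arm),
            ae_profile=self.ae_profile(arm),
            ae_duration_years=self.ae_duration_years)


@dataclass
class BaseCaseResult:
    switch: StrategyOutcome
    control: StrategyOutcome
    comparison: CEComparison
    clamp_events: int = 0


def evaluate(config: ModelConfig) -> BaseCaseResult:
    """Run both strategies through the partitioned-survival model."""
    clamp = 0
    outcomes = {}
    for arm in ("switch", "control"):
        trace = build_trace(config.survival[f"os_{arm}"],
                            config.survival[f"pfs_{arm}"],
                            config.horizon_years, config.cycle_days)
        clamp += trace.clamp_events
        outcomes[arm] = accumulate(trace, config.arm_costing(arm),
                                   config.utilities, config.discount_rate, arm)
    comparison = compare(outcomes["switch"], outcomes["control"], config.wtp)
    return BaseCaseResult(outcomes["switch"], outcomes["control"], comparison, clamp)


def default_config(perspective: str = "china", population: str = "overall",
                   **overrides) -> ModelConfig:
    """Shipped base-case configuration for one perspective x population."""
    if perspective not in PERSPECTIVES:
        raise ConfigurationError(f"perspective must be one of {PERSPECTIVES}")
    side = TABLE1[perspective]
    base = lambda table: {k: v[0] for k, v in table.items()}
    cfg = ModelConfig(
        perspective=perspective,
        population=population,
        patient=Patient(weight=side["weight"][0], bsa=side["bsa"][0]),
        prices=base(side["prices"]),
        care=CareCosts(**base(side["care"])),
        utilities=base(TABLE1["utilities"]),
        ae_costs=base(side["ae_costs"]),
        ae_disutility=base(TABLE1["ae_disutility"]),
        ae_incidence_switch=base(TABLE1["ae_incidence_switch"]),
        ae_incidence_control=base(TABLE1["ae_incidence_control"]),
        survival={k: ParametricSurvival(fam, dict(params))
                  for k, (fam, params) in TABLE1["survival"][population].items()},
        discount_rate=side["discount"][0],
        wtp=side["wtp"],
        subsequent_fraction_switch=TABLE1["subsequent_fraction"]["switch"],
        subsequent_fraction_control=TABLE1["subsequent_fraction"]["control"],
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown configuration field {key!r}")
        setattr(cfg, key, value)
    return cfg


# ---------------------------------------------------------------------------
# Dotted-path access (used by tornado / PSA to perturb single parameters)
# ---------------------------------------------------------------------------

def get_path(config, path: str):
    obj = config
    for part in path.split("."):
        if isinstance(obj, dict):
            if part not in obj:
                raise ConfigurationError(f"path {path!r}: no key {part!r}")
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise ConfigurationError(f"path {path!r}: no attribute {part!r}")
            obj = getattr(obj, part)
    return obj


def set_path(config, path: str, value) -> None:
    parts = path.split(".")
    obj = get_path(config, ".".join(parts[:-1])) if len(parts) > 1 else config
    last = parts[-1]
    if isinstance(obj, dict):
        if last not in obj:
            raise ConfigurationError(f"path {path!r}: no key {last!r}")
        obj[last] = value
    else:
        if not hasattr(obj, last):
            raise ConfigurationError(f"path {path!r}: no attribute {last!r}")
        setattr(obj, last, value)


def perturbed(config: ModelConfig, path: str, value) -> ModelConfig:
    """Deep copy of ``config`` with one dotted-path parameter replaced."""
    cfg = copy.deepcopy(config)
    set_path(cfg, path, value)
    return cfg


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------

def to_dict(config: ModelConfig) -> dict:
    d = dataclasses.asdict(config)
    d["patient"] = {"weight": config.patient.weight, "bsa": config.patient.bsa}
    d["care"] = dataclasses.asdict(config.care)
    d["survival"] = {k: {"family": m.family, "params": dict(m.params)}
                     for k, m in config.survival.items()}
    return d


def from_dict(d: dict) -> ModelConfig:
    d = copy.deepcopy(d)
    d["patient"] = Patient(**d["patient"])
    d["care"] = CareCosts(**d["care"])
    d["survival"] = {k: ParametricSurvival(v["family"], v["params"])
                     for k, v in d["survival"].items()}
    if "oxaliplatin_cap_days" in d and d["oxaliplatin_cap_days"] is None:
        d["oxaliplatin_cap_days"] = float("inf")
    return ModelConfig(**d)


def save_yaml(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=False)


def load_yaml(path) -> ModelConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))
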