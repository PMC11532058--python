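"""Synthetic ICD cohort with covariates, event processes and endpoints.

Covariates are drawn from documented marginals chosen to resemble a
contemporary single-center ICD registry (mostly male, mean age ~63 years,
severely reduced ejection fraction, two-thirds ischemic etiology); age,
LVEF and creatinine share a small Gaussian copula, everything else is
independent.  Death and appropriate-therapy times follow Weibull
proportional-hazards models whose log-hazard coefficients are scenario
configuration; the fragmentation effect defaults to 0, i.e. the null
association scenario.  Transplant and administrative censoring are
independent.

Endpoints derived per patient: overall / 1-year / 3-year mortality and
appropriate therapy, first appropriate shock, ever inappropriate shock,
and ICD-resistant mortality (ICD-RM): death within the first year after
implantation, or within 30 days of the first appropriate shock, or death
without any documented appropriate ICD intervention during follow-up.
Transplantation ends follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classifier import REFERENCE_CUTOFF
from .errors import ConfigError, InconsistentCalendarError

DAYS_PER_YEAR = 365.0
ICD_RM_SHOCK_WINDOW_DAYS = 30.0
LANDMARK_HORIZONS = (365.0, 1095.0)

#: continuous covariate marginals: name -> (mean, sd, lower, upper)
CONTINUOUS_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "age": (62.6, 11.5, 18.0, 95.0),
    "bmi": (26.4, 4.4, 14.0, 50.0),
    "lvef": (31.0, 12.0, 5.0, 70.0),
    "creatinine": (1.26, 0.48, 0.3, 6.0),
    "qtc": (443.0, 51.0, 300.0, 650.0),
}

#: binary covariate prevalences
BINARY_PREVALENCES: dict[str, float] = {
    "female": 0.183,
    "ihd": 0.643,
    "secondary_prevention": 0.362,
    "crtd": 0.296,
    "stroke": 0.108,
    "dm": 0.210,
    "af": 0.286,
    "aht": 0.535,
    "bb": 0.853,
    "acei_arb": 0.879,
    "loop": 0.488,
    "aldactone": 0.550,
    "antiaggregant": 0.603,
    "anticoagulation": 0.338,
    "amiodarone": 0.356,
    "sotalol": 0.009,
    "digitalis": 0.085,
    "statin": 0.612,
    "lbbb": 0.362,
}

NYHA_PROBS = (0.260, 0.444, 0.289, 0.007)

#: Gaussian-copula correlations among (age, lvef, creatinine)
COPULA_CORR = np.array(
    [
        [1.00, -0.15, 0.30],
        [-0.15, 1.00, -0.15],
        [0.30, -0.15, 1.00],
    ]
)

CONTINUOUS_NAMES = tuple(CONTINUOUS_MARGINALS)
COVARIATE_NAMES = CONTINUOUS_NAMES + tuple(BINARY_PREVALENCES) + ("nyha",)

ENDPOINT_NAMES = (
    "mortality_overall",
    "mortality_1y",
    "mortality_3y",
    "app_therapy_overall",
    "app_therapy_1y",
    "app_therapy_3y",
    "app_shock",
    "inapp_shock",
    "icd_rm",
)


@dataclass(frozen=True)
class HazardModel:
    """Weibull proportional-hazards event process.

    Survival is ``exp(-(t / scale)^shape * exp(lp))`` where the linear
    predictor applies ``coefficients`` (log hazard ratios) to standardised
    continuous covariates (z-scores of the stated marginals) and raw 0/1
    binaries; ``nyha`` enters per class above I.
    """

    shape: float
    scale_days: float
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale_days <= 0:
            raise ConfigError("Weibull shape and scale must be positive")
        for name, c in self.coefficients.items():
            if not np.isfinite(c):
                raise ConfigError(f"non-finite log-hazard coefficient for {name}")


@dataclass(frozen=True)
class CohortScenario:
    """Full generative configuration of the simulated registry."""

    fqrs_prevalence: float = 0.433
    cutoff: float = REFERENCE_CUTOFF
    death: HazardModel = HazardModel(
        shape=1.1,
        scale_days=4600.0,
        coefficients={
            "age": 0.35, "lvef": -0.25, "creatinine": 0.20,
            "nyha": 0.30, "dm": 0.30, "af": 0.25, "ihd": 0.20,
            "crtd": -0.20, "fqrs": 0.0,
        },
    )
    app_therapy: HazardModel = HazardModel(
        shape=0.9,
        scale_days=4200.0,
        coefficients={
            "secondary_prevention": 0.30, "digitalis": 0.20,
            "statin": -0.15, "fqrs": 0.0,
        },
    )
    inapp_shock: HazardModel = HazardModel(
        shape=1.0, scale_days=15000.0, coefficients={"af": 0.50, "age": -0.20}
    )
    transplant_scale_days: float = 40000.0
    first_therapy_shock_prob: float = 0.5
    atp_to_shock_mean_days: float = 700.0
    followup_range_days: tuple[float, float] = (365.0, 3650.0)
    region_positive_probs: tuple[float, float, float] = (0.45, 0.35, 0.60)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fqrs_prevalence <= 1.0):
            raise ConfigError("fqrs_prevalence must be a probability")
        if not (0.0 < self.cutoff < 1.0):
            raise ConfigError("cutoff must be in (0, 1)")
        if not (0.0 <= self.first_therapy_shock_prob <= 1.0):
            raise ConfigError("first_therapy_shock_prob must be a probability")
        if self.followup_range_days[0] > self.followup_range_days[1]:
            raise ConfigError("follow-up range reversed")

    def with_fqrs_log_hr(
        self, death: float = 0.0, therapy: float = 0.0
    ) -> "CohortScenario":
        """Scenario copy with non-null fragmentation effects."""
        d = replace(self.death, coefficients={**self.death.coefficients,
                                              "fqrs": death})
        t = replace(self.app_therapy,
                    coefficients={**self.app_therapy.coefficients,
                                  "fqrs": therapy})
        return replace(self, death=d, app_therapy=t)


@dataclass
class CohortPatient:
    """Covariates, fragmentation scores and the event calendar (days from
    implantation; ``None`` = the event never happened)."""

    patient_id: int
    covariates: dict[str, float]
    fqrs_positive: bool
    regional_probs: dict[str, float]
    death_day: float | None
    atp_day: float | None            # first appropriate ATP-only therapy
    app_shock_day: float | None      # first appropriate shock
    inapp_shock_day: float | None
    htx_day: float | None            # transplant = end of follow-up
    fu_end_day: float                # last day of follow-up

    def __post_init__(self) -> None:
        for name in ("death_day", "atp_day", "app_shock_day",
                     "inapp_shock_day", "htx_day"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InconsistentCalendarError(f"{name} is negative")
            if v is not None and v > self.fu_end_day + 1e-9:
                raise InconsistentCalendarError(
                    f"{name} = {v} exceeds follow-up end {self.fu_end_day}"
                )
        a, s = self.atp_day, self.app_shock_day
        if a is not None and s is not None and s < a:
            # a shock is itself an appropriate therapy; first therapy <= first shock
            raise InconsistentCalendarError("first shock precedes first therapy")

    @property
    def first_app_therapy_day(self) -> float | None:
        days = [d for d in (self.atp_day, self.app_shock_day) if d is not None]
        return min(days) if days else None


def _weibull_time(rng: np.random.Generator, model: HazardModel, lp: float) -> float:
    u = rng.uniform()
    return model.scale_days * (-np.log(u) / np.exp(lp)) ** (1.0 / model.shape)


def _linear_predictor(model: HazardModel, cov: dict[str, float],
                      fqrs: bool) -> float:
    lp = 0.0
    for name, c in model.coefficients.items():
        if c == 0.0:
            continue
        if name == "fqrs":
            lp += c * float(fqrs)
        elif name == "nyha":
            lp += c * (cov["nyha"] - 1.0)
        elif name in CONTINUOUS_MARGINALS:
            mean, sd, _, _ = CONTINUOUS_MARGINALS[name]
            lp += c * (cov[name] - mean) / sd
        else:
            lp += c * cov[name]
    return lp


def _draw_regional_probs(
    rng: np.random.Generator, positive: bool, scenario: CohortScenario
) -> dict[str, float]:
    cut = scenario.cutoff
    if not positive:
        vals = rng.uniform(0.02, max(cut - 0.05, 0.05), size=3)
        return dict(zip(("anterior", "lateral", "inferior"), vals))
    probs = np.asarray(scenario.region_positive_probs)
    while True:
        hot = rng.uniform(size=3) < probs
        if hot.any():
            break
    vals = np.where(
        hot,
        rng.uniform(cut + 1e-6, 1.0, size=3),
        rng.uniform(0.02, max(cut - 0.05, 0.05), size=3),
    )
    return dict(zip(("anterior", "lateral", "inferior"), vals))


def simulate_cohort(
    n: int, scenario: CohortScenario | None = None, seed: int = 0
) -> list[CohortPatient]:
    """Draw ``n`` independent patients under the scenario (default: the
    null-fragmentation-effect registry look-alike)."""
    if n < 50:
        raise ConfigError("cohort size must be at least 50")
    scenario = scenario or CohortScenario()
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(COPULA_CORR)

    patients: list[CohortPatient] = []
    for pid in range(n):
        cov: dict[str, float] = {}
        z3 = chol @ rng.standard_normal(3)
        for name, zval in zip(("age", "lvef", "creatinine"), z3):
            mean, sd, lo, hi = CONTINUOUS_MARGINALS[name]
            cov[name] = float(np.clip(mean + sd * zval, lo, hi))
        for name in ("bmi", "qtc"):
            mean, sd, lo, hi = CONTINUOUS_MARGINALS[name]
            cov[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
        for name, prev in BINARY_PREVALENCES.items():
            cov[name] = float(rng.uniform() < prev)
        nyha_p = np.asarray(NYHA_PROBS) / np.sum(NYHA_PROBS)
        cov["nyha"] = float(rng.choice([1, 2, 3, 4], p=nyha_p))

        fqrs = bool(rng.uniform() < scenario.fqrs_prevalence)
        regional = _draw_regional_probs(rng, fqrs, scenario)

        death_t = _weibull_time(
            rng, scenario.death, _linear_predictor(scenario.death, cov, fqrs)
        )
        therapy_t = _weibull_time(
            rng, scenario.app_therapy,
            _linear_predictor(scenario.app_therapy, cov, fqrs),
        )
        inapp_t = _weibull_time(
            rng, scenario.inapp_shock,
            _linear_predictor(scenario.inapp_shock, cov, fqrs),
        )
        htx_t = rng.exponential(scenario.transplant_scale_days)
        admin_t = rng.uniform(*scenario.followup_range_days)

        if rng.uniform() < scenario.first_therapy_shock_prob:
            atp_t, shock_t = None, therapy_t
        else:
            atp_t = therapy_t
            shock_t = therapy_t + rng.exponential(scenario.atp_to_shock_mean_days)

        censor = min(htx_t, admin_t)
        death_day = death_t if death_t <= censor else None
        fu_end = death_day if death_day is not None else censor
        keep = lambda t: t if (t is not None and t <= fu_end) else None  # noqa: E731

        patients.append(
            CohortPatient(
                patient_id=pid,
                covariates=cov,
                fqrs_positive=fqrs,
                regional_probs=regional,
                death_day=death_day,
                atp_day=keep(atp_t),
                app_shock_day=keep(shock_t),
                inapp_shock_day=keep(inapp_t),
                htx_day=htx_t if htx_t <= fu_end else None,
                fu_end_day=float(fu_end),
            )
        )
    return patients


def label_icd_rm(patient: CohortPatient) -> int:
    """ICD-resistant mortality indicator.

    1 iff the patient died and (death within 365 days of implantation, or
    within 30 days of the first appropriate shock, or without any
    appropriate ICD intervention during follow-up).  Survivors and
    transplant-censored patients score 0.
    """
    d = patient.death_day
    if d is None:
        return 0
    if d > patient.fu_end_day + 1e-9:
        raise InconsistentCalendarError("death after end of follow-up")
    if d <= DAYS_PER_YEAR:
        return 1
    if (
        patient.app_shock_day is not None
        and d <= patient.app_shock_day + ICD_RM_SHOCK_WINDOW_DAYS
    ):
        return 1
    if patient.first_app_therapy_day is None:
        return 1
    return 0


def _landmark(ind: int, t: float, horizon: float) -> tuple[int, float]:
    return (0, horizon) if t > horizon else (ind, t)


def derive_endpoints(
    patient: CohortPatient,
    horizons: tuple[float, float] = LANDMARK_HORIZONS,
) -> dict[str, tuple[int, float]]:
    """(event indicator, time-to-event-or-censoring in days) per endpoint."""
    h1, h3 = horizons
    died = int(patient.death_day is not None)
    t_death = patient.death_day if died else patient.fu_end_day
    out: dict[str, tuple[int, float]] = {
        "mortality_overall": (died, float(t_death)),
        "mortality_1y": _landmark(died, t_death, h1),
        "mortality_3y": _landmark(died, t_death, h3),
    }
    ther = patient.first_app_therapy_day
    got = int(ther is not None)
    t_ther = ther if got else patient.fu_end_day
    out["app_therapy_overall"] = (got, float(t_ther))
    out["app_therapy_1y"] = _landmark(got, t_ther, h1)
    out["app_therapy_3y"] = _landmark(got, t_ther, h3)

    shock = patient.app_shock_day
    out["app_shock"] = (
        int(shock is not None),
        float(shock if shock is not None else patient.fu_end_day),
    )
    inapp = patient.inapp_shock_day
    out["inapp_shock"] = (
        int(inapp is not None),
        float(inapp if inapp is not None else patient.fu_end_day),
    )
    out["icd_rm"] = (label_icd_rm(patient), float(t_death))
    return out


def endpoint_frame(
    patients: list[CohortPatient],
    horizons: tuple[float, float] = LANDMARK_HORIZONS,
) -> pd.DataFrame:
    """One row per patient: covariates, fragmentation status, endpoint
    indicator/time pairs -- the analysis table of the outcome stage."""
    rows = []
    for p in patients:
        row: dict[str, float] = {"patient_id": p.patient_id, **p.covariates}
        row["fqrs"] = float(p.fqrs_positive)
        for region, v in p.regional_probs.items():
            row[f"prob_{region}"] = v
        for name, (ind, t) in derive_endpoints(p, horizons).items():
            row[f"{name}_event"] = ind
            row[f"{name}_time"] = t
        rows.append(row)
    return pd.DataFrame(rows)


_EVENT_COLS = ("death_day", "atp_day", "app_shock_day", "inapp_shock_day",
               "htx_day", "fu_end_day")


def cohort_to_csv(patients: list[CohortPatient], path) -> None:
    """One row per patient; absent events are empty cells."""
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id, **p.covariates,
               "fqrs": int(p.fqrs_positive)}
        for region, v in p.regional_probs.items():
            row[f"prob_{region}"] = v
        for col in _EVENT_COLS:
            v = getattr(p, col)
            row[col] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def cohort_from_csv(path) -> list[CohortPatient]:
    df = pd.read_csv(path)
    patients = []
    for _, r in df.iterrows():
        cov = {name: float(r[name]) for name in COVARIATE_NAMES}
        get = lambda c: None if pd.isna(r[c]) else float(r[c])  # noqa: E731
        patients.append(
            CohortPatient(
                patient_id=int(r["patient_id"]),
                covariates=cov,
                fqrs_positive=bool(r["fqrs"]),
                regional_probs={
                    reg: float(r[f"prob_{reg}"])
                    for reg in ("anterior", "lateral", "inferior")
                },
                death_day=get("death_day"),
                atp_day=get("atp_day"),
                app_shock_day=get("app_shock_day"),
                inapp_shock_day=get("inapp_shock_day"),
                htx_day=get("htx_day"),
                fu_end_day=float(r["fu_end_day"]),
            )
        )
    return patients
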