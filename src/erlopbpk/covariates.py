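"""Co-variate scenario engine: paired simulations against the standard patient.

Each scenario modifies exactly one clinically interpretable factor of the
standard fasted 60 kg / 60 y patient on 100 mg oral erlotinib:

* ``fed``        -- fed-state GI physiology and raised liver blood flow
* ``weight_45`` / ``weight_85`` -- body size (clearance held fixed)
* ``ara``        -- acid-reducing co-medication (stomach pH 1.3 -> 5.0,
                    gastric emptying 0.25 -> 0.5 h)
* ``clh_10`` / ``clh_2`` -- hepatic clearance
* ``fu_10``      -- plasma fraction unbound raised to 10%, with all tissue
                    partition coefficients recomputed

and reports C_max, AUC(0-24), V_d and Cl_tot with percent changes versus
the standard run, from single-administration profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .physchem import DrugParams
from .gi_absorption import Physiology, build_physiology
from .pbpk_body import Subject, build_subject, scale_subject
from .engine import Regimen, ConcTimeProfile, simulate_single
from .nca import NCAResult, compute_nca

SCENARIO_IDS = ("standard", "fed", "weight_45", "weight_85", "ara",
                "clh_10", "clh_2", "fu_10")

#: Simulated span of the single-administration comparison, h. Long enough
#: for a reliable terminal slope at the lowest clearance considered.
SCENARIO_DURATION_H = 96.0


@dataclass(frozen=True)
class Scenario:
    id: str
    prandial_state: str = "fasted"
    ara: bool = False
    body_weight: Optional[float] = None
    hepatic_clearance: Optional[float] = None
    fu: Optional[float] = None

    def __post_init__(self):
        if self.id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario id {self.id!r}")


SCENARIOS = {
    "standard": Scenario("standard"),
    "fed": Scenario("fed", prandial_state="fed"),
    "weight_45": Scenario("weight_45", body_weight=45.0),
    "weight_85": Scenario("weight_85", body_weight=85.0),
    "ara": Scenario("ara", ara=True),
    "clh_10": Scenario("clh_10", hepatic_clearance=10.0),
    "clh_2": Scenario("clh_2", hepatic_clearance=2.0),
    "fu_10": Scenario("fu_10", fu=0.10),
}


@dataclass
class CovariateReport:
    scenario: str
    C_max: float
    AUC_0_24: float
    V_d: Optional[float]
    Cl_tot: Optional[float]
    pct_C_max: float
    pct_AUC_0_24: float
    pct_V_d: Optional[float]
    pct_Cl_tot: Optional[float]
    profile: ConcTimeProfile
    nca: NCAResult


def scenario_inputs(scenario: Scenario, drug: DrugParams
                    ) -> tuple[Subject, Physiology]:
    """Subject and physiology realizing one scenario's overrides."""
    subject = build_subject(drug, hepatic_clearance=scenario.hepatic_clearance,
                            fu=scenario.fu)
    if scenario.body_weight is not None:
        subject = scale_subject(subject, scenario.body_weight)
    physiology = build_physiology(scenario.prandial_state, scenario.ara)
    return subject, physiology


def run_scenario(scenario: Scenario | str, drug: DrugParams,
                 regimen: Optional[Regimen] = None,
                 baseline: Optional[CovariateReport] = None,
                 duration: float = SCENARIO_DURATION_H) -> CovariateReport:
    """Simulate one scenario and report changes versus the standard patient.

    The baseline (standard scenario) is computed with identical solver
    settings when not supplied. Percent changes are
    100 * (scenario - standard) / standard on day-1 single-dose NCA.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    regimen = regimen or Regimen(dose=100.0, n_doses=1)
    if baseline is None and scenario.id != "standard":
        baseline = run_scenario("standard", drug, regimen, duration=duration)
    subject, physiology = scenario_inputs(scenario, drug)
    profile = simulate_single(drug, subject, physiology, regimen, duration)
    nca = compute_nca(profile, dose=regimen.dose,
                      F=drug.oral_bioavailability_F)

    def pct(new, ref):
        if new is None or ref in (None, 0):
            return None
        return 100.0 * (new - ref) / ref

    if scenario.id == "standard":
        ref = nca
    else:
        ref = baseline.nca
    return CovariateReport(
        scenario=scenario.id,
        C_max=nca.C_peak, AUC_0_24=nca.AUC_0_24,
        V_d=nca.V_d, Cl_tot=nca.Cl_tot,
        pct_C_max=pct(nca.C_peak, ref.C_peak),
        pct_AUC_0_24=pct(nca.AUC_0_24, ref.AUC_0_24),
        pct_V_d=pct(nca.V_d, ref.V_d),
        pct_Cl_tot=pct(nca.Cl_tot, ref.Cl_tot),
        profile=profile, nca=nca)


def run_all(drug: DrugParams, regimen: Optional[Regimen] = None,
            duration: float = SCENARIO_DURATION_H
            ) -> dict[str, CovariateReport]:
    """Run the full scenario panel sharing one standard baseline."""
    regimen = regimen or Regimen(dose=100.0, n_doses=1)
    reports = {"standard": run_scenario("standard", drug, regimen,
                                        duration=duration)}
    for sid in SCENARIO_IDS:
        if sid != "standard":
            reports[sid] = run_scenario(sid, drug, regimen,
                                        baseline=reports["standard"],
                                        duration=duration)
    return reports
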