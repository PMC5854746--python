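"""Solubility, dissolution and precipitation sub-models for a weak-base BCS class II drug.

Erlotinib is a monoprotic weak base (pKa 5.4): it dissolves readily in gastric
acid but its aqueous solubility collapses above its pKa, which makes oral
absorption dissolution- and precipitation-limited and sensitive to gastric pH.
This module holds the drug parameter set and the three luminal rate laws used
by the gastrointestinal transit model:

* Henderson-Hasselbalch pH-dependent solubility with a solubility-factor cap,
* bile-salt solubilization anchored on the measured FeSSIF solubility,
* Johnson (shrinking-sphere, diffusion-layer) dissolution and first-order
  precipitation of supersaturated drug.

Units: masses mg, luminal concentrations mg/ml, particle radii um, time s
inside this module (the simulation engine converts to hours).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

from pydantic import BaseModel, ConfigDict, model_validator

# Reference bile-salt concentrations of the biorelevant media (mM).
FASTED_BILE_MM = 3.0
FED_BILE_MM = 15.0

#: True density of the solid drug, mg/cm^3.
PARTICLE_DENSITY_MG_CM3 = 1200.0

#: Diffusion-layer thickness cap, um (Johnson-model convention h = min(r, 30)).
DIFFUSION_LAYER_CAP_UM = 30.0


class DrugParams(BaseModel):
    """Physicochemical and ADME constants of the compound.

    Defaults (via :func:`load_drug`) are the optimized erlotinib parameter
    set; a predicted (purely in-silico) set ships alongside it.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str = "erlotinib"
    molecular_weight: float  # g/mol
    logP: float
    pKa_base: float
    intrinsic_solubility: float  # mg/ml, unionized species
    solubility_factor: float  # cap on ionized/unionized solubility ratio
    reference_solubility_pH2: float  # mg/ml, as printed (informational)
    fassif_solubility: float  # mg/ml
    fessif_solubility: float  # mg/ml
    solubilization_ratio: float  # dimensionless bile-salt gain
    effective_permeability: float  # cm/s
    fraction_unbound: float  # (0, 1]
    blood_plasma_ratio: float
    hepatic_clearance: float  # l/h, plasma-referenced
    particle_radius: float  # um
    mean_precipitation_time: float  # s
    oral_bioavailability_F: float = 0.60  # used only for NCA scaling

    @model_validator(mode="after")
    def _check(self) -> "DrugParams":
        positive = (
            "molecular_weight", "pKa_base", "intrinsic_solubility",
            "solubility_factor", "fassif_solubility", "fessif_solubility",
            "solubilization_ratio", "effective_permeability",
            "fraction_unbound", "blood_plasma_ratio", "hepatic_clearance",
            "particle_radius", "mean_precipitation_time",
            "oral_bioavailability_F",
        )
        for key in positive:
            if not getattr(self, key) > 0:
                raise ValueError(f"{key} must be strictly positive")
        if self.fraction_unbound > 1:
            raise ValueError("fraction_unbound must be <= 1")
        if self.solubility_factor < 1:
            raise ValueError("solubility_factor must be >= 1")
        if self.fassif_solubility > self.fessif_solubility:
            raise ValueError("fassif_solubility must be <= fessif_solubility")
        return self

    @property
    def diffusion_coefficient(self) -> float:
        """Aqueous diffusion coefficient, cm^2/s, from molecular weight.

        Stokes-Einstein-style size scaling D ~ MW^(-1/3); the prefactor is a
        dissolution-modeling default whose absolute value is absorbed into
        the absorption-scale calibration.
        """
        return 9.9e-6 * self.molecular_weight ** (-1.0 / 3.0)


def load_drug(which: str = "optimized") -> DrugParams:
    """Load a packaged erlotinib parameter set ("optimized" or "predicted")."""
    fname = {
        "optimized": "drug_erlotinib.json",
        "predicted": "drug_erlotinib_predicted.json",
    }[which]
    text = resources.files("erlopbpk.data").joinpath(fname).read_text()
    return DrugParams(**json.loads(text))


@dataclass
class ParticleState:
    """Dissolution state of one GI compartment (carrier for the rate laws)."""

    undissolved_mass: float  # mg
    current_radius: float  # um
    dissolved_concentration: float  # mg/ml
    precipitated_mass: float  # mg
    lumen_volume: float  # ml

    def __post_init__(self) -> None:
        for key in ("undissolved_mass", "current_radius",
                    "dissolved_concentration", "precipitated_mass",
                    "lumen_volume"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be non-negative")


def solubility_at_ph(drug: DrugParams, pH: float) -> float:
    """Aqueous solubility (mg/ml) of the weak base at a given pH.

    Henderson-Hasselbalch: S(pH) = S0 * (1 + 10^(pKa - pH)), capped at
    S0 * SF where SF limits the ionized/unionized solubility ratio (the
    salt's common-ion ceiling). Monotonically non-increasing in pH, bounded
    by [S0, S0*SF].
    """
    if not math.isfinite(pH):
        raise ValueError("pH must be finite")
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    ratio = 1.0 + 10.0 ** (drug.pKa_base - pH)
    return drug.intrinsic_solubility * min(ratio, drug.solubility_factor)


def bile_enhancement(drug: DrugParams, bile_conc: float) -> float:
    """Multiplicative solubility gain from bile-salt micelles.

    Exponential in bile concentration, anchored so that the fed reference
    state (15 mM) reproduces the measured FeSSIF solubility at its reference
    pH 5.0: E(b) = E15^(b/15) with E15 = FeSSIF / S_aq(5.0), clamped at >= 1.
    The measured FaSSIF value cannot serve as a second anchor because it lies
    below the aqueous solubility at its own pH, which no additive
    solubilization model can reproduce.
    """
    if bile_conc < 0:
        raise ValueError("bile_conc must be non-negative")
    e15 = drug.fessif_solubility / solubility_at_ph(drug, 5.0)
    if e15 <= 1.0:
        return 1.0
    return max(1.0, e15 ** (bile_conc / FED_BILE_MM))


def solubility_with_bile(drug: DrugParams, pH: float, bile_conc: float) -> float:
    """Effective luminal solubility (mg/ml) at a given pH and bile level.

    Equals the aqueous solubility at zero bile, increases strictly with bile
    concentration, and reproduces the FeSSIF measurement at the fed reference
    state (15 mM, pH 5.0).
    """
    return solubility_at_ph(drug, pH) * bile_enhancement(drug, bile_conc)


def dissolution_rate(state: ParticleState, drug: DrugParams,
                     solubility_eff: float) -> float:
    """Johnson shrinking-sphere dissolution rate, mg/s (>= 0).

    Rate = 3 D M (Cs - C) / (rho r h) for a monodisperse population of
    spherical particles of radius r, with diffusion-layer thickness
    h = min(r, 30 um). A zero or negative driving force clamps to zero
    (supersaturation is handled by :func:`precipitation_rate`).
    """
    if solubility_eff < 0:
        raise ValueError("solubility_eff must be non-negative")
    if state.undissolved_mass <= 0.0:
        return 0.0
    if state.lumen_volume <= 0.0:
        raise ValueError("zero lumen volume with undissolved mass present")
    driving = solubility_eff - state.dissolved_concentration
    if driving <= 0.0 or state.current_radius <= 0.0:
        return 0.0
    r_cm = state.current_radius * 1e-4
    h_cm = min(state.current_radius, DIFFUSION_LAYER_CAP_UM) * 1e-4
    return (3.0 * drug.diffusion_coefficient * state.undissolved_mass
            * driving / (PARTICLE_DENSITY_MG_CM3 * r_cm * h_cm))


def precipitation_rate(state: ParticleState, drug: DrugParams,
                       solubility_eff: float) -> float:
    """First-order precipitation of supersaturated dissolved drug, mg/s.

    Active only above the effective solubility; the excess decays with
    e-folding time tau_p (mean precipitation time).
    """
    excess = state.dissolved_concentration - solubility_eff
    if excess <= 0.0:
        return 0.0
    return excess * state.lumen_volume / drug.mean_precipitation_time
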