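"""Whole-body perfusion-limited distribution with hepatic elimination.

Fourteen perfusion-limited tissue compartments plus arterial and venous
blood, closed through the lung. Tissue:plasma partition coefficients (Kp)
are computed mechanistically from tissue composition with the
Rodgers-Rowland-family equation for a weak base with pKa < 7 (the
"Lukacova" variant: neutral-lipid and neutral-phospholipid partitioning,
Henderson-Hasselbalch ionization at plasma pH 7.4 / intracellular pH 7.0,
and an extracellular albumin-binding ratio tied to the plasma fraction
unbound). Because fu enters the Kp equation, overriding fu re-computes
every Kp — which is what couples protein binding to both distribution and
clearance in covariate scenarios.

Hepatic elimination is well-stirred: the intrinsic unbound clearance is
back-calculated from the drug's plasma-referenced hepatic clearance at the
reference liver blood flow, and the liver ODE clears drug from its outflow
concentration. Renal elimination is zero (erlotinib is cleared by hepatic
CYPs).

Units: amounts mg, volumes l, flows l/h, time h, concentrations mg/l
(= ug/ml).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .physchem import DrugParams

PLASMA_PH = 7.4
INTRACELLULAR_PH = 7.0

# plasma neutral lipid / neutral phospholipid fractions
PLASMA_F_NL = 0.0023
PLASMA_F_NP = 0.0013

# blood volumes of the 70 kg reference subject, l
REF_WEIGHT_KG = 70.0
REF_ARTERIAL_L = 1.7
REF_VENOUS_L = 3.5

#: Fraction of a body-weight difference carried by adipose tissue.
#: Excess (or deficit) weight relative to the reference build is mostly fat.
ADIPOSE_WEIGHT_SHARE = 0.75

TISSUE_ORDER = (
    "lung", "adipose", "bone", "brain", "gut", "heart", "kidney", "liver",
    "muscle", "skin", "spleen", "reproductive", "rest",
)


@dataclass(frozen=True)
class Tissue:
    """One perfusion-limited tissue with its composition and computed Kp."""

    name: str
    volume: float  # l
    blood_flow: float  # l/h
    f_ew: float
    f_iw: float
    f_nl: float
    f_np: float
    ra_albumin: float
    Kp: float = float("nan")

    def __post_init__(self):
        if self.volume <= 0 or self.blood_flow <= 0:
            raise ValueError("tissue volume and blood flow must be positive")
        comp = self.f_ew + self.f_iw + self.f_nl + self.f_np
        if not 0.0 < comp <= 1.0:
            raise ValueError(
                f"{self.name}: composition fractions must sum into (0, 1]")


@dataclass(frozen=True)
class Subject:
    """A virtual subject: scaled tissue set plus clearance and binding."""

    age: float
    sex: str
    body_weight: float  # kg
    tissues: tuple[Tissue, ...]
    arterial_volume: float  # l
    venous_volume: float  # l
    hepatic_clearance: float  # l/h, plasma-referenced
    fraction_unbound: float

    def __post_init__(self):
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")

    def tissue(self, name: str) -> Tissue:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def cardiac_output(self) -> float:
        return sum(t.blood_flow for t in self.tissues if t.name != "lung")

    @property
    def liver_blood_flow(self) -> float:
        """Total liver inflow: hepatic artery + portal (gut + spleen)."""
        return (self.tissue("liver").blood_flow
                + self.tissue("gut").blood_flow
                + self.tissue("spleen").blood_flow)

    @property
    def vss(self) -> float:
        """Steady-state distribution volume referenced to plasma, l."""
        v = sum(t.Kp * t.volume for t in self.tissues)
        return v + self.arterial_volume + self.venous_volume


def load_tissue_table() -> pd.DataFrame:
    text = resources.files("erlopbpk.data").joinpath(
        "tissue_composition.csv").read_text()
    return pd.read_csv(io.StringIO(text), comment="#")


def kp_lukacova(drug: DrugParams, tissue: Tissue, fu: float) -> float:
    """Tissue:plasma partition coefficient for a weak base with pKa < 7.

    Kp = fu * [ f_EW + (1+X)/(1+Y) f_IW + (P f_NL + (0.3 P + 0.7) f_NP)/(1+Y)
                + RA (1/fu - 1 - (P f_NLp + (0.3 P + 0.7) f_NPp)/(1+Y)) ]

    with X, Y the base ionization ratios at intracellular and plasma pH.
    Adipose uses the vegetable-oil:water partition coefficient
    (log Dvo:w = 1.115 logP - 1.35) in place of the octanol P.
    """
    if not 0.0 < fu <= 1.0:
        raise ValueError("fu must lie in (0, 1]")
    X = 10.0 ** (drug.pKa_base - INTRACELLULAR_PH)
    Y = 10.0 ** (drug.pKa_base - PLASMA_PH)
    if tissue.name == "adipose":
        P = 10.0 ** (1.115 * drug.logP - 1.35)
    else:
        P = 10.0 ** drug.logP
    lipid = (P * tissue.f_nl + (0.3 * P + 0.7) * tissue.f_np) / (1.0 + Y)
    plasma_lipid = (P * PLASMA_F_NL + (0.3 * P + 0.7) * PLASMA_F_NP) / (1.0 + Y)
    protein = tissue.ra_albumin * max(1.0 / fu - 1.0 - plasma_lipid, 0.0)
    kpu = (tissue.f_ew + (1.0 + X) / (1.0 + Y) * tissue.f_iw + lipid + protein)
    kp = fu * kpu
    if not kp > 0:
        raise ValueError("computed Kp must be positive")
    return kp


def build_subject(drug: DrugParams, body_weight: float = 60.0,
                  age: float = 60.0, sex: str = "male",
                  hepatic_clearance: float | None = None,
                  fu: float | None = None) -> Subject:
    """Build a subject by rescaling the reference tissue table.

    Volumes scale linearly with weight, blood flows allometrically
    (exponent 0.75); Kp values are computed from composition via
    :func:`kp_lukacova`. The study default is a 60-year-old man of 60 kg.
    """
    if not 30.0 <= body_weight <= 200.0:
        raise ValueError("body_weight must lie in [30, 200] kg")
    fu = drug.fraction_unbound if fu is None else fu
    clh = drug.hepatic_clearance if hepatic_clearance is None else hepatic_clearance
    table = load_tissue_table()
    vol_scale = body_weight / REF_WEIGHT_KG
    flow_scale = (body_weight / REF_WEIGHT_KG) ** 0.75
    tissues = []
    for row in table.itertuples(index=False):
        t = Tissue(name=row.tissue, volume=row.volume_l * vol_scale,
                   blood_flow=row.flow_l_h * flow_scale,
                   f_ew=row.f_ew, f_iw=row.f_iw, f_nl=row.f_nl,
                   f_np=row.f_np, ra_albumin=row.ra_albumin)
        tissues.append(replace(t, Kp=kp_lukacova(drug, t, fu)))
    order = {n: i for i, n in enumerate(TISSUE_ORDER)}
    tissues.sort(key=lambda t: order[t.name])
    return Subject(age=age, sex=sex, body_weight=body_weight,
                   tissues=tuple(tissues),
                   arterial_volume=REF_ARTERIAL_L * vol_scale,
                   venous_volume=REF_VENOUS_L * vol_scale,
                   hepatic_clearance=clh, fraction_unbound=fu)


def scale_subject(base: Subject, body_weight: float) -> Subject:
    """Re-scale a subject to a new body weight, clearance unchanged.

    Adipose tissue absorbs ADIPOSE_WEIGHT_SHARE of the weight difference
    (excess weight is predominantly fat); the remaining tissues and blood
    volumes scale with the residual lean-mass change. Blood flows scale
    allometrically with total weight. Hepatic clearance and fu are NOT
    scaled (body weight does not change erlotinib clearance).
    """
    if not 30.0 <= body_weight <= 200.0:
        raise ValueError("body_weight must lie in [30, 200] kg")
    dw = body_weight - base.body_weight
    adipose = base.tissue("adipose")
    adipose_gain = ADIPOSE_WEIGHT_SHARE * dw  # kg ~ l (density ~1)
    new_adipose_vol = adipose.volume + adipose_gain
    if new_adipose_vol <= 0:
        raise ValueError("weight change would eliminate adipose tissue")
    lean_base = (base.body_weight - adipose.volume
                 - base.arterial_volume - base.venous_volume)
    lean_factor = (lean_base + (1.0 - ADIPOSE_WEIGHT_SHARE) * dw) / lean_base
    flow_factor = (body_weight / base.body_weight) ** 0.75
    tissues = []
    for t in base.tissues:
        vol = new_adipose_vol if t.name == "adipose" else t.volume * lean_factor
        tissues.append(replace(t, volume=vol,
                               blood_flow=t.blood_flow * flow_factor))
    return replace(base, body_weight=body_weight, tissues=tuple(tissues),
                   arterial_volume=base.arterial_volume * lean_factor,
                   venous_volume=base.venous_volume * lean_factor)


@dataclass
class BodyModel:
    """Vectorized RHS of the systemic distribution/elimination ODEs.

    State (length 16): amounts (mg) in the 13 tissues of TISSUE_ORDER,
    arterial blood, venous blood, plus cumulative eliminated mass.
    Blood-pool concentrations are blood-referenced; tissue outflow blood
    concentration is C_t * Rbp / Kp_t. Plasma concentration = C_blood / Rbp.
    """

    subject: Subject
    drug: DrugParams
    liver_flow_factor: float = 1.0

    def __post_init__(self):
        s, d = self.subject, self.drug
        self.n_state = len(TISSUE_ORDER) + 3
        self.volumes = np.array([s.tissue(n).volume for n in TISSUE_ORDER])
        self.flows = np.array([s.tissue(n).blood_flow for n in TISSUE_ORDER])
        self.kps = np.array([s.tissue(n).Kp for n in TISSUE_ORDER])
        self.rbp = d.blood_plasma_ratio
        self.i = {n: k for k, n in enumerate(TISSUE_ORDER)}
        splanchnic = (self.i["gut"], self.i["spleen"])
        self.i_gut, self.i_spleen = splanchnic
        self.i_liver, self.i_lung = self.i["liver"], self.i["lung"]
        self.i_art, self.i_ven, self.i_elim = 13, 14, 15
        self.v_art, self.v_ven = s.arterial_volume, s.venous_volume
        # hepatic artery + portal flows, optionally raised (fed state);
        # cardiac output rises by the same increment so the loop stays
        # flow-balanced at every node
        self.q_ha = s.tissue("liver").blood_flow * self.liver_flow_factor
        self.q_gut = s.tissue("gut").blood_flow * self.liver_flow_factor
        self.q_spleen = s.tissue("spleen").blood_flow * self.liver_flow_factor
        self.q_liver = self.q_ha + self.q_gut + self.q_spleen
        self.co = (s.cardiac_output
                   + (self.liver_flow_factor - 1.0) * s.liver_blood_flow)
        # Well-stirred back-calculation of the unbound intrinsic clearance:
        # the drug's plasma-referenced hepatic clearance is interpreted at
        # the subject's own (unfactored) liver flow and the drug's reference
        # fu. CLint_u is the invariant; overriding the subject's fu or
        # raising liver flow (fed state) then moves the realized clearance.
        q_ref = s.liver_blood_flow
        clb = s.hepatic_clearance / self.rbp
        if clb >= q_ref:
            raise ValueError(
                "hepatic blood clearance must be below liver blood flow")
        fub_clint_ref = q_ref * clb / (q_ref - clb)
        self.fub_clint = fub_clint_ref * (s.fraction_unbound
                                          / d.fraction_unbound)
        # systemic (non-lung, non-splanchnic-adjusted) flow bookkeeping
        self.mask_to_venous = np.ones(13, dtype=bool)
        for k in (self.i_lung, self.i_gut, self.i_spleen, self.i_liver):
            self.mask_to_venous[k] = False

    @property
    def hepatic_extraction(self) -> float:
        return self.fub_clint / (self.q_liver + self.fub_clint)

    @property
    def fh(self) -> float:
        """Hepatic availability of orally absorbed drug."""
        return 1.0 - self.hepatic_extraction

    def rhs(self, t: float, y: np.ndarray,
            absorption_flux: float = 0.0) -> np.ndarray:
        A = y[:13]
        c_art = y[self.i_art] / self.v_art
        c_ven = y[self.i_ven] / self.v_ven
        c_out = A / self.volumes * self.rbp / self.kps  # venous-side blood conc
        dA = self.flows * (c_art - c_out)
        # splanchnic loop: gut and spleen drain into the liver, not venous
        dA[self.i_gut] = self.q_gut * (c_art - c_out[self.i_gut])
        dA[self.i_spleen] = self.q_spleen * (c_art - c_out[self.i_spleen])
        liver_in = (self.q_ha * c_art
                    + self.q_gut * c_out[self.i_gut]
                    + self.q_spleen * c_out[self.i_spleen]
                    + absorption_flux)
        # elimination = CLint_u * C_unbound,out = (fu_b * CLint_u) * C_blood,out
        elim = self.fub_clint * c_out[self.i_liver]
        dA[self.i_liver] = liver_in - self.q_liver * c_out[self.i_liver] - elim
        # lung takes the whole cardiac output from the venous pool
        dA[self.i_lung] = self.co * (c_ven - c_out[self.i_lung])
        d_art = self.co * (c_out[self.i_lung] - c_art)
        d_ven = (np.sum(self.flows[self.mask_to_venous]
                        * c_out[self.mask_to_venous])
                 + self.q_liver * c_out[self.i_liver]
                 - self.co * c_ven)
        dy = np.empty(self.n_state)
        dy[:13] = dA
        dy[self.i_art] = d_art
        dy[self.i_ven] = d_ven
        dy[self.i_elim] = elim
        return dy

    def plasma_concentration(self, y: np.ndarray) -> float:
        """Venous plasma concentration, ug/ml."""
        return y[self.i_ven] / self.v_ven / self.rbp

    def total_amount(self, y: np.ndarray) -> float:
        return float(np.sum(y[:15]))


def assemble_body_odes(subject: Subject, drug: DrugParams,
                       absorption_flux=None, liver_flow_factor: float = 1.0):
    """Return ``(rhs, model)`` for the systemic ODEs.

    ``absorption_flux`` may be None (no input), a scalar (constant mg/h into
    the portal inlet) or a callable of time.
    """
    model = BodyModel(subject, drug, liver_flow_factor)

    if absorption_flux is None:
        flux = lambda t: 0.0
    elif callable(absorption_flux):
        flux = absorption_flux
    else:
        flux = lambda t, _v=float(absorption_flux): _v

    def rhs(t, y):
        return model.rhs(t, y, flux(t))

    return rhs, model
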