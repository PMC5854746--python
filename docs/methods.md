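# Methods

`erlopbpk` is a mechanistic simulator of oral erlotinib pharmacokinetics
(100 mg once daily, the regimen used in advanced pancreatic cancer) plus the
analytics of long-term therapeutic drug monitoring (TDM). This note records
the model, its assumptions, the numerical choices, and what the synthetic
data can and cannot demonstrate.

## Physicochemistry of the absorption problem

Erlotinib free base (MW 393.45 g/mol, logP 2.7) is a monoprotic weak base
with pKa 5.4 and an intrinsic aqueous solubility of 0.0089 mg/ml — a BCS
class II compound. Ionization follows Henderson–Hasselbalch,

    S(pH) = S0 · min(1 + 10^(pKa − pH), SF),

where the solubility factor SF = 50 caps the ionized:unionized ratio (the
common-ion ceiling of the hydrochloride salt). At gastric pH 1.3 the cap is
active (S = 0.445 mg/ml); at duodenal pH ~6 solubility collapses to
~0.011 mg/ml. Absorption is therefore driven by rapid gastric dissolution
followed by intestinal supersaturation, precipitation and redissolution —
which is exactly why raising gastric pH (acid-reducing agents, ARAs)
suppresses exposure.

Bile-salt solubilization is a single-anchor exponential enhancement,
`S_eff(pH, b) = S(pH) · E15^(b/15 mM)` with `E15 = FeSSIF / S(pH 5.0)`, so
the measured fed-state biorelevant solubility (FeSSIF, 0.7 mg/ml at pH 5.0,
15 mM bile) is reproduced exactly and the enhancement vanishes at zero bile.
The measured FaSSIF value (0.003 mg/ml) lies *below* the aqueous solubility
at its own pH 6.5 and therefore cannot be an anchor of any additive
solubilization model; we keep the physical invariant (bile never reduces
solubility) and accept that the fasted biorelevant point is not reproduced.
Micelle-bound drug does not permeate: the absorptive flux acts on the free
aqueous fraction `C_free = C · S_aq/S_eff` (linear partitioning into
micelles). This is the standard mechanism by which bile helps dissolution
yet tempers the permeation gain.

Dissolution follows the Johnson shrinking-sphere law for a monodisperse
particle population (radius 15 µm),

    dM/dt = 3 D M (Cs − C) / (ρ r h),   h = min(r, 30 µm),

with true density ρ = 1.2 g/cm³ and diffusion coefficient
D = 9.9×10⁻⁶·MW^(−1/3) cm²/s (a Stokes–Einstein-style size scaling whose
absolute value is absorbed by the absorption-scale calibration).
Supersaturated drug precipitates first-order with mean precipitation time
τ = 100 s. Precipitate is modeled as a fine population of fixed 2 µm radius
that redissolves by the same law; without redissolution the drug lost to
precipitation in the upper intestine could never support the known ~60%
oral bioavailability. The shrinking-sphere endpoint (rate ∝ M^⅓, non-
Lipschitz at M → 0) is regularized by flooring the radius at 2 µm, which
holds ≤ 0.24% of an original particle's mass.

## Gastrointestinal transit and absorption

Nine serial compartments (stomach, duodenum, jejunum ×2, ileum ×3, caecum,
ascending colon) with first-order transit; literature-standard fasted
volumes, radii and pH (duodenum 6.0 rising to distal ileum 7.4), gastric
emptying 0.25 h and total small-intestinal transit ≈ 3.3 h. Bile tapers
from the fasted duodenal reference 3 mM to zero in the colon. Absorptive
flux per compartment is

    J_i = Peff · ASF_i · (2/R_i) · V_i · C_free,i ,

cylindrical surface-to-volume scaling times an absorption scale factor.
One global ASF coefficient (8.0 for the small intestine, ×0.15 in
caecum/colon, 0 in stomach) is the model's single calibrated constant,
chosen once so the standard fasted run meets Fa·Fh ≈ 0.60, the literature
oral bioavailability; it ships as a package default and is not revisited
per scenario. The stomach does not absorb; gut-wall metabolism is zero.

Scenario presets change only what they claim to change:

* ARA: stomach pH 1.3 → 5.0 and gastric emptying 0.25 → 0.5 h; nothing else.
* Fed: stomach pH 4.9, emptying 1.0 h; postprandial bile spike declining
  down the small intestine (15/10/6/4/3/2 mM); chyme-acidified upper
  intestinal pH (duodenum and jejunum‑1 5.4, jejunum‑2 6.0); liver blood
  flow +35% (cardiac output raised by the same increment so every
  circulatory node stays flow-balanced).

## Whole-body distribution and elimination

Fourteen perfusion-limited tissues plus arterial/venous blood closed
through the lung. Tissue volumes, flows and fractional compositions come
from published reference-adult tables, rescaled to the 60 kg / 60 y study
subject (volumes linearly, flows allometrically with exponent 0.75).
Partition coefficients use the Rodgers–Rowland-family equation for a weak
base with pKa < 7: neutral-lipid/phospholipid partitioning, ionization at
plasma pH 7.4 and intracellular pH 7.0, and an extracellular
albumin-binding term tied to 1/fu; adipose uses the vegetable-oil:water
partition coefficient (log Dvow = 1.115·logP − 1.35). With the optimized
parameters this yields Vss ≈ 76 l at 60 kg, consistent with the reported
simulated distribution volume (67.8 l) within the concordance achievable
without the proprietary physiology tables.

Hepatic elimination is well-stirred. The drug's plasma-referenced hepatic
clearance (4.0 l/h) is back-calculated at reference liver flow and fu into
an unbound intrinsic clearance, which is then the invariant: overriding fu
rescales fu·CLint (and every Kp), so raising the unbound fraction raises
extraction and tissue distribution and *lowers* plasma exposure — the
protein-binding paradox the co-variate panel reproduces. Renal elimination
is zero. Body-weight scaling sends 75% of a weight change to adipose
(excess weight is predominantly fat) and the rest to lean tissues;
clearance is never weight-scaled.

## Engine, populations, NCA

The luminal (38 states) and systemic (16 states) ODEs integrate as one
coupled system (LSODA, rtol 1e−8 / atol 1e−10 by default — mass-balance
assertions hold to ≤ 1e−6 relative). Each daily dose re-initializes the
gastric solid while the body state persists. Virtual populations draw
log-normal, mean-preserving factors per subject — CV 30% on hepatic
clearance, 20% on weight truncated to the observed 44–97 kg, 30% on
gastric emptying, age uniform 50–70 y (the study population's variability
is not printed; these are typical oral-PK inter-individual CVs, recorded
here for audit) — using one seed with per-subject substreams, so results
are bit-reproducible regardless of evaluation order.

NCA: C_peak/T_max by direct maximum; linear trapezoid AUC; λz by best
adjusted-R² log-linear fit over the last 3–6 points after T_max;
AUC(0–∞) = AUC(0–last) + C_last/λz; Cl_tot = F·dose/AUC(0–∞) and
V_d = Cl_tot/λz with F = 0.60. V_d is thus the terminal (λz-based) volume,
the only reading consistent with the Cl/λz arithmetic.

## Synthetic TDM cohorts

The generator reproduces the monitoring design: 26 patients sampled densely
on day 1 (pre-dose, 1, 2, 3, 4, 5, 6, 8, 24 h), trough + 4 h on days 2–8,
and a 10-patient subset followed with weekly troughs to 50 weeks. ARA
prevalence defaults to 5/26 (the study's identified ARA users); ARA
patients are simulated with the ARA gastric physiology rather than a
post-hoc exposure scaling, so the group contrast is mechanistic. Residual
(intra-patient/assay) noise is multiplicative log-normal with CV 25%,
chosen to reproduce the scale of the printed per-patient SDs. Cohort
simulations default to rtol 1e−6; monitoring analytics do not need
mass-balance-grade tolerances. The analytics use Student's pooled
unpaired t-test by default: on the printed per-patient means the pooled
test gives p ≈ 0.0016 (matching the reported p < 0.002) whereas Welch's
variant gives p ≈ 0.0073, so the pooled form is evidently what the original
analysis used; Welch remains available by flag.

What the synthetic cohorts do **not** emulate: toxicity-driven treatment
interruptions, capecitabine/bevacizumab co-medication kinetics, assay
limits of quantification, and — importantly — the absolute trough level of
the real cohort. The model's steady-state troughs (~0.45–0.5 µg/ml for the
standard subject) sit at the activity threshold itself, below the observed
mean day-6 trough (0.72 µg/ml). Binary threshold statistics (e.g. "what
fraction of patients never reach 0.5 µg/ml in week 1") are therefore
knife-edge functions of this calibration and of the unprinted variability:
the generator reproduces the qualitative pattern (ARA patients' troughs
stochastically below non-ARA, roughly half of long-term patients below
threshold) but not the study's 2/26 week-1 rate, and the tests assert the
directional property only.

## Design choices on genuinely open points

* **Fed-state magnitude.** The a priori fed physiology above yields a fed
  AUC(0–24) gain of ≈ +44% (the fed state removes the fasted precipitation
  loss). The study's simulation reports +12%; clinical label data put the
  erlotinib food effect at +33…100%. We keep the mechanistic prediction
  rather than contriving a fed-state loss mechanism to match the smaller
  printed number; every other co-variate contrast reproduces the reported
  value within ±10 percentage points.
* **V_d reading** (terminal vs steady-state): terminal, see above.
* **t-test variant**: Student's pooled, see above.
* **Particle population**: monodisperse at the reported radius; no size
  distribution is reported to justify more structure.
* **Weekly trough timing**: week w sampled at t = 168·w h, i.e. 24 h after
  the previous evening's dose, matching "once a week before ingestion".

## Problem sizes used by the shipped checks

Single-administration co-variate comparisons run 96 h at 0.05 h output
resolution; the virtual population uses 25 subjects over 24 h; the
multi-dose steady-state check uses 8 daily doses; synthetic-cohort tests
use 3–6 patients over 1–3 weeks; t-test calibration uses ≥ 1200
distribution-level null cohorts. These sizes reproduce the paper-scale
quantities while keeping the default test run fast.
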