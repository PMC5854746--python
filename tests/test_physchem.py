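"""Solubility, dissolution and precipitation rate laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from erlopbpk.physchem import (
    DrugParams, ParticleState, solubility_at_ph, solubility_with_bile,
    dissolution_rate, precipitation_rate, FASTED_BILE_MM, FED_BILE_MM,
)


class TestSolubilityAtPh:
    def test_half_ionized_at_pka(self, drug):
        # at pH = pKa half the drug is ionized: S = 2 * S0
        assert solubility_at_ph(drug, drug.pKa_base) == pytest.approx(
            2 * drug.intrinsic_solubility)
        assert solubility_at_ph(drug, drug.pKa_base) == pytest.approx(0.0178)

    def test_predicted_parameters_reproduce_measured_ph2_value(
            self, predicted_drug):
        # uncapped Henderson-Hasselbalch with the in-silico parameter set
        s = solubility_at_ph(predicted_drug, 2.0)
        assert s == pytest.approx(22.44, rel=0.01)

    def test_optimized_ph2_solubility_capped_by_sf(self, drug):
        s = solubility_at_ph(drug, 2.0)
        assert s == pytest.approx(drug.intrinsic_solubility
                                  * drug.solubility_factor)
        assert s == pytest.approx(0.40, rel=0.15)

    def test_high_ph_limit_is_intrinsic_solubility(self, drug):
        assert solubility_at_ph(drug, 12.0) == pytest.approx(
            drug.intrinsic_solubility, rel=1e-4)

    def test_rejects_invalid_ph(self, drug):
        for bad in (float("nan"), float("inf"), -1.0, 15.0):
            with pytest.raises(ValueError):
                solubility_at_ph(drug, bad)

    @settings(max_examples=200, deadline=None)
    @given(ph_lo=st.floats(0, 14), ph_hi=st.floats(0, 14),
           logs0=st.floats(-4, 0), pka=st.floats(2, 9),
           sf=st.floats(1, 1e4))
    def test_non_increasing_in_ph(self, drug, ph_lo, ph_hi, logs0, pka, sf):
        d = drug.model_copy(update={
            "intrinsic_solubility": 10.0 ** logs0, "pKa_base": pka,
            "solubility_factor": sf,
            "fassif_solubility": 1e-3, "fessif_solubility": 1e-3})
        lo, hi = sorted((ph_lo, ph_hi))
        assert solubility_at_ph(d, lo) >= solubility_at_ph(d, hi)
        for ph in (lo, hi):
            s = solubility_at_ph(d, ph)
            s0 = d.intrinsic_solubility
            assert s0 * (1 - 1e-12) <= s <= s0 * sf * (1 + 1e-12)


class TestSolubilityWithBile:
    def test_zero_bile_equals_aqueous(self, drug):
        for ph in (1.3, 5.0, 6.5, 7.4):
            assert solubility_with_bile(drug, ph, 0.0) == pytest.approx(
                solubility_at_ph(drug, ph))

    def test_fed_reference_reproduces_fessif(self, drug):
        assert solubility_with_bile(drug, 5.0, FED_BILE_MM) == pytest.approx(
            drug.fessif_solubility, rel=1e-9)

    def test_strictly_increasing_in_bile(self, drug):
        grid = [solubility_with_bile(drug, 6.5, b)
                for b in (1.0, FASTED_BILE_MM, 8.0, FED_BILE_MM)]
        assert all(a < b for a, b in zip(grid, grid[1:]))

    def test_never_below_aqueous_solubility(self, drug):
        # bile micelles add solubility; they cannot remove it
        for ph in (2.0, 5.0, 6.5, 7.4):
            for b in (0.0, 1.0, 3.0, 15.0, 30.0):
                assert (solubility_with_bile(drug, ph, b)
                        >= solubility_at_ph(drug, ph) * (1 - 1e-12))

    def test_negative_bile_rejected(self, drug):
        with pytest.raises(ValueError):
            solubility_with_bile(drug, 6.5, -1.0)


def _state(mass=50.0, radius=15.0, conc=0.0, precip=0.0, volume=100.0):
    return ParticleState(undissolved_mass=mass, current_radius=radius,
                         dissolved_concentration=conc, precipitated_mass=precip,
                         lumen_volume=volume)


class TestDissolutionRate:
    def test_saturated_lumen_gives_zero(self, drug):
        assert dissolution_rate(_state(conc=0.01), drug, 0.01) == 0.0

    def test_no_solid_gives_zero(self, drug):
        assert dissolution_rate(_state(mass=0.0), drug, 1.0) == 0.0

    def test_supersaturated_clamps_to_zero(self, drug):
        assert dissolution_rate(_state(conc=0.5), drug, 0.01) == 0.0

    def test_zero_volume_with_mass_is_degenerate(self, drug):
        with pytest.raises(ValueError):
            dissolution_rate(_state(volume=0.0), drug, 1.0)

    def test_initial_rate_scales_with_inverse_radius_squared(self, drug):
        # sink conditions, h = r: rate ratio (25/15)^2 for equal mass
        r25 = dissolution_rate(_state(radius=25.0), drug, 0.4)
        r15 = dissolution_rate(_state(radius=15.0), drug, 0.4)
        assert r15 / r25 == pytest.approx((25.0 / 15.0) ** 2, rel=1e-9)
        # cross-check against numerically integrated initial slopes
        ratio = _initial_slope(drug, 25.0) / _initial_slope(drug, 15.0)
        assert ratio == pytest.approx((15.0 / 25.0) ** 2, rel=2e-3)

    def test_diffusion_layer_capped_above_30um(self, drug):
        # for r > 30 um the layer thickness saturates: rate ~ 1/r not 1/r^2
        r60 = dissolution_rate(_state(radius=60.0), drug, 0.4)
        r30 = dissolution_rate(_state(radius=30.0), drug, 0.4)
        assert r30 / r60 == pytest.approx(2.0, rel=1e-9)


def _initial_slope(drug, radius_um, mass=10.0, volume=1000.0):
    """Dissolved mass slope at t -> 0 from an integrated shrinking sphere."""
    def rhs(t, y):
        m = max(y[0], 0.0)
        r = radius_um * (m / mass) ** (1 / 3) if m > 0 else 0.0
        st = ParticleState(undissolved_mass=m, current_radius=r,
                           dissolved_concentration=y[1] / volume,
                           precipitated_mass=0.0, lumen_volume=volume)
        rate = dissolution_rate(st, drug, 0.4)
        return [-rate, rate]
    sol = solve_ivp(rhs, (0.0, 0.05), [mass, 0.0], rtol=1e-10, atol=1e-12)
    return sol.y[1, -1] / sol.t[-1]


class TestPrecipitationRate:
    def test_subsaturated_gives_zero(self, drug):
        assert precipitation_rate(_state(conc=0.005), drug, 0.01) == 0.0

    def test_supersaturation_decays_with_tau(self, drug):
        # isolated compartment: dC/dt = -(C - Cs)/tau, closed form
        # C(t) = Cs + (C0 - Cs) exp(-t/tau)
        cs, c0, vol = 0.01, 0.02, 100.0
        tau = drug.mean_precipitation_time

        def rhs(t, y):
            st = _state(mass=0.0, conc=y[0] / vol)
            return [-precipitation_rate(st, drug, cs)]

        t_end = 250.0  # s
        sol = solve_ivp(rhs, (0, t_end), [c0 * vol], rtol=1e-10, atol=1e-14)
        expected = cs + (c0 - cs) * math.exp(-t_end / tau)
        assert sol.y[0, -1] / vol == pytest.approx(expected, rel=1e-6)

    def test_infinite_tau_disables_precipitation(self, drug):
        slow = drug.model_copy(update={"mean_precipitation_time": 1e12})
        assert precipitation_rate(_state(conc=1.0), slow, 0.01) == pytest.approx(0.0, abs=1e-9)


def test_closed_compartment_conserves_mass(drug):
    """Dissolution + precipitation in a sealed compartment conserve drug."""
    cs, vol, m0 = 0.01, 50.0, 5.0

    def rhs(t, y):
        m, a, p = y  # solid, dissolved amount, precipitated
        r = 15.0 * max(m / m0, 0.0) ** (1 / 3)
        st = ParticleState(undissolved_mass=max(m, 0.0), current_radius=r,
                           dissolved_concentration=a / vol,
                           precipitated_mass=p, lumen_volume=vol)
        dis = dissolution_rate(st, drug, cs) if m > 1e-9 else 0.0
        pre = precipitation_rate(st, drug, cs)
        return [-dis, dis - pre, pre]

    sol = solve_ivp(rhs, (0, 3600.0), [m0, 0.8 * vol * 0.04, 0.0],
                    rtol=1e-9, atol=1e-12)
    total0 = m0 + 0.8 * vol * 0.04
    totals = sol.y.sum(axis=0)
    assert np.max(np.abs(totals - total0) / total0) < 1e-6


@pytest.mark.parametrize("override", [
    {"fraction_unbound": 1.5},
    {"solubility_factor": 0.5},
    {"fassif_solubility": 1.0, "fessif_solubility": 0.5},
    {"intrinsic_solubility": -1.0},
])
def test_drug_params_invariants_enforced(drug, override):
    with pytest.raises(ValueError):
        DrugParams(**{**drug.model_dump(), **override})
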