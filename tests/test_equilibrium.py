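"""Binding degree, mass-action solvers vs bisection oracles, thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ligbind.equilibrium import (
    SITE_I,
    SITE_II,
    BindingSystem,
    DialysisMeasurement,
    ThermoParams,
    binding_degree,
    binding_degree_summary,
    deltaG_from_kd,
    kd_from_deltaG,
    predicted_bound_fraction,
    solve_competitive_two_site,
    solve_free_ligand_1to1,
)
from ligbind.errors import InvalidInputError


# --- independent oracles ------------------------------------------------------

def bisect_free_ligand(P_t, L_t, Kd, tol=1e-13):
    """Bisection on the 1:1 mass balance, independent of the quadratic."""
    def residual(L_f):
        return L_f + P_t * L_f / (Kd + L_f) - L_t
    lo, hi = 0.0, L_t
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * max(L_t, 1.0):
            break
    return 0.5 * (lo + hi)


def nested_bisect_two_site(P, L_t, Q_t, kd_sites, kq, probe_site, iters=200):
    """Brute-force nested bisection for the competitive two-site system."""
    def q_free(L_f):
        if Q_t == 0:
            return 0.0
        def qres(Q_f):
            occ = (Q_f / kq) / (1 + L_f / kd_sites[probe_site] + Q_f / kq)
            return Q_f + P * occ - Q_t
        lo, hi = 0.0, Q_t
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if qres(mid) > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    def lres(L_f):
        Q_f = q_free(L_f)
        total = L_f
        for s, kd in kd_sites.items():
            comp = Q_f / kq if s == probe_site and Q_t > 0 else 0.0
            total += P * (L_f / kd) / (1 + L_f / kd + comp)
        return total - L_t

    lo, hi = 0.0, L_t
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if lres(mid) > 0:
            hi = mid
        else:
            lo = mid
    L_f = 0.5 * (lo + hi)
    return L_f, q_free(L_f)


# --- binding degree -----------------------------------------------------------

class TestBindingDegree:
    @pytest.mark.parametrize("d_t,d_f,expected", [
        (100.0, 20.0, 80.0),
        (100.0, 0.0, 100.0),   # fully bound
        (100.0, 100.0, 0.0),   # no binding
    ])
    def test_worked_examples(self, d_t, d_f, expected):
        assert binding_degree(DialysisMeasurement(d_t, d_f)) == pytest.approx(expected)

    @given(
        d_t=st.floats(1e-6, 1e6),
        frac=st.floats(0.0, 1.0),
        scale=st.floats(1e-6, 1e6),
    )
    def test_scale_invariance(self, d_t, frac, scale):
        base = binding_degree(DialysisMeasurement(d_t, frac * d_t))
        scaled = binding_degree(DialysisMeasurement(scale * d_t, scale * frac * d_t))
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_free_exceeding_total_is_an_error(self):
        with pytest.raises(InvalidInputError):
            DialysisMeasurement(D_t=10.0, D_f=10.5)

    def test_summary_by_method(self):
        ms = [DialysisMeasurement(100, 20, "ED"), DialysisMeasurement(100, 22, "ED"),
              DialysisMeasurement(100, 19, "UF")]
        s = binding_degree_summary(ms)
        assert s["ED"]["mean_percent"] == pytest.approx(79.0)
        assert s["ED"]["n"] == 2 and s["UF"]["n"] == 1


# --- 1:1 solver ---------------------------------------------------------------

class TestFreeLigand1to1:
    def test_no_protein(self):
        assert solve_free_ligand_1to1(0.0, 5.0, 1.0) == pytest.approx(5.0)

    def test_weak_binding_limit(self):
        L_t = 800.0
        assert solve_free_ligand_1to1(20.0, L_t, 1e9 * L_t) == pytest.approx(
            L_t, rel=1e-6)

    def test_worked_conditions_vs_bisection(self):
        ours = solve_free_ligand_1to1(20.0, 800.0, 13.0)
        assert ours == pytest.approx(bisect_free_ligand(20.0, 800.0, 13.0), rel=1e-9)

    def test_mass_conservation_random(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            P = rng.uniform(0, 1000)
            L = rng.uniform(1e-3, 1000)
            Kd = 10 ** rng.uniform(-3, 4)
            L_f = solve_free_ligand_1to1(P, L, Kd)
            bound = P * L_f / (Kd + L_f)
            assert abs(L_f + bound - L) <= 1e-9 * max(L, 1.0)
            assert L_f == pytest.approx(bisect_free_ligand(P, L, Kd),
                                        rel=1e-8, abs=1e-10)


# --- competitive two-site solver ----------------------------------------------

class TestCompetitiveTwoSite:
    def test_single_site_no_probe_reduces_to_quadratic(self):
        sys1 = BindingSystem(P_t=20.0, L_t=800.0, Kd_site={SITE_II: 13.0})
        state = solve_competitive_two_site(sys1)
        assert state.L_free == pytest.approx(
            solve_free_ligand_1to1(20.0, 800.0, 13.0), rel=1e-12)

    def test_blocking_limit(self):
        # Saturating, quasi-irreversible probe empties its site of ligand.
        sys = BindingSystem(P_t=20.0, L_t=800.0,
                            Kd_site={SITE_I: 100.0, SITE_II: 13.0},
                            Q_t=1e6, Kd_probe=1e-6, probe_site=SITE_II)
        state = solve_competitive_two_site(sys)
        no_probe = BindingSystem(P_t=20.0, L_t=800.0,
                                 Kd_site={SITE_I: 100.0, SITE_II: 13.0})
        ref = solve_competitive_two_site(no_probe)
        assert state.L_bound_per_site[SITE_II] < 1e-6 * ref.L_bound_per_site[SITE_II]

    def test_agrees_with_nested_bisection_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            P = rng.uniform(1, 100)
            L_t = rng.uniform(10, 2000)
            Q_t = rng.uniform(0, 2000)
            kds = {SITE_I: 10 ** rng.uniform(-1, 3), SITE_II: 10 ** rng.uniform(-1, 3)}
            kq = 10 ** rng.uniform(-1, 2)
            probe_site = SITE_I if rng.random() < 0.5 else SITE_II
            sys = BindingSystem(P_t=P, L_t=L_t, Kd_site=kds, Q_t=Q_t,
                                Kd_probe=kq, probe_site=probe_site)
            state = solve_competitive_two_site(sys)
            L_f, Q_f = nested_bisect_two_site(P, L_t, Q_t, kds, kq, probe_site)
            assert state.L_free == pytest.approx(L_f, rel=1e-8, abs=1e-10)
            if Q_t > 0:
                assert state.Q_free == pytest.approx(Q_f, rel=1e-8, abs=1e-10)
            assert abs(state.L_free + state.L_bound - L_t) <= 1e-9 * max(L_t, 1.0)

    def test_nonnegative_concentrations(self):
        sys = BindingSystem(P_t=50.0, L_t=5.0, Kd_site={SITE_I: 0.1, SITE_II: 0.1},
                            Q_t=100.0, Kd_probe=0.05, probe_site=SITE_I)
        state = solve_competitive_two_site(sys)
        assert state.L_free >= 0 and state.Q_free >= 0
        assert all(v >= 0 for v in state.L_bound_per_site.values())


# --- bound fraction -----------------------------------------------------------

class TestPredictedBoundFraction:
    def test_tight_binding_limit(self):
        sys = BindingSystem(P_t=100.0, L_t=10.0, Kd_site={SITE_II: 1e-9})
        assert predicted_bound_fraction(sys) == pytest.approx(100.0, abs=1e-3)

    def test_no_protein(self):
        sys = BindingSystem(P_t=0.0, L_t=10.0, Kd_site={SITE_II: 1.0})
        assert predicted_bound_fraction(sys) == pytest.approx(0.0, abs=1e-9)

    def test_zero_ligand_rejected(self):
        sys = BindingSystem(P_t=10.0, L_t=0.0, Kd_site={SITE_II: 1.0})
        with pytest.raises(InvalidInputError):
            predicted_bound_fraction(sys)

    def test_monotone_in_kd_and_protein(self):
        kds = [0.1, 1.0, 10.0, 100.0, 1000.0]
        fracs = [predicted_bound_fraction(
            BindingSystem(P_t=50.0, L_t=10.0, Kd_site={SITE_II: kd})) for kd in kds]
        assert all(a > b for a, b in zip(fracs, fracs[1:]))
        pts = [0.0, 5.0, 20.0, 100.0, 500.0]
        fracs = [predicted_bound_fraction(
            BindingSystem(P_t=p, L_t=10.0, Kd_site={SITE_II: 20.0})) for p in pts]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))


# --- thermodynamics -----------------------------------------------------------

class TestThermo:
    def test_zero_energy_gives_molar_kd(self):
        assert kd_from_deltaG(0.0, 298.0) == pytest.approx(1.0)

    def test_micromolar_worked_example(self):
        # exp(-6.67 / (1.9872e-3 * 298)) = 1.2835e-5 M
        kd = kd_from_deltaG(-6.67, 298.0)
        assert kd == pytest.approx(1.2835e-5, rel=1e-4)
        assert 1e-6 < kd < 1e-3  # micromolar regime

    @given(dg=st.floats(-20.0, 5.0), temp=st.floats(200.0, 400.0))
    def test_round_trip_exact(self, dg, temp):
        assert deltaG_from_kd(kd_from_deltaG(dg, temp), temp) == pytest.approx(
            dg, rel=1e-12, abs=1e-12)

    def test_thermo_params_consistency_enforced(self):
        ThermoParams(deltaG=-6.0, Kd=kd_from_deltaG(-6.0))
        with pytest.raises(InvalidInputError):
            ThermoParams(deltaG=-6.0, Kd=1e-3)

    def test_invalid_temperature(self):
        with pytest.raises(InvalidInputError):
            kd_from_deltaG(-5.0, 0.0)


def test_system_validation():
    with pytest.raises(InvalidInputError):
        BindingSystem(P_t=-1.0, L_t=10.0, Kd_site={SITE_I: 1.0})
    with pytest.raises(InvalidInputError):
        BindingSystem(P_t=1.0, L_t=10.0, Kd_site={SITE_I: -2.0})
    with pytest.raises(InvalidInputError):
        BindingSystem(P_t=1.0, L_t=10.0, Kd_site={SITE_I: 1.0},
                      Q_t=5.0)  # probe present but no site/Kd
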