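"""Unit and property tests for the conformational-selection linkage model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from coopkin import (
    CannotSaturateError,
    ConfigurationError,
    ConformationalEnsemble,
    DoubleDrugScheme,
    InfeasibleCooperativityError,
    LigandProfile,
    UndefinedAffinityError,
    apparent_kd,
    cooperativity_factor,
    max_cooperativity_ceiling,
    shifted_ensemble,
    solve_free_concentrations,
    solve_selectivity,
    species_fractions,
)

from conftest import random_scheme

KEQ = 0.67


def two_state(keq=KEQ):
    return ConformationalEnsemble.two_state(keq)


def ligand(site, kd_active, kd_inactive, name="L"):
    return LigandProfile(
        name=name, site=site,
        kd_per_state={"active": kd_active, "inactive": kd_inactive},
    )


def scheme(keq, kdo_a, kdo_i, kda_a, kda_i, coupling=None):
    return DoubleDrugScheme(
        ensemble=two_state(keq),
        ortho=ligand("orthosteric", kdo_a, kdo_i, "O"),
        allo=ligand("allosteric", kda_a, kda_i, "A"),
        catalytic_weight_per_state={"active": 1.0},
        coupling_per_state=coupling or {},
    )


# ---------------------------------------------------------------------------
# oracle: half-occupancy titration on the full species lattice
# ---------------------------------------------------------------------------

def halfway_titration_kd(ensemble, lig, background=None):
    """Free concentration at which the ligand occupies half the enzyme,
    computed by numerically titrating the explicit Boltzmann lattice."""
    w = np.asarray(ensemble.weights)
    kd = np.array([lig.kd_per_state[s] for s in ensemble.states])
    if background is not None:
        bg, free_bg = background
        kd_bg = np.array([bg.kd_per_state[s] for s in ensemble.states])
        fac = np.where(np.isfinite(kd_bg), 1.0 + free_bg / kd_bg, 1.0)
        w = w * fac

    def occupancy(free):
        x = np.where(np.isfinite(kd), free / kd, 0.0)
        return float(np.sum(w * x) / np.sum(w * (1.0 + x)))

    lo, hi = 1e-18, 1.0
    return brentq(lambda f: occupancy(f) - 0.5, lo, hi, rtol=1e-14)


class TestSpeciesFractions:
    def test_symmetric_apo(self):
        s = scheme(1.0, 10e-9, 10e-9, 10e-9, 10e-9)
        pop = species_fractions(s, 0.0, 0.0)
        assert pop.fraction("active", "apo") == pytest.approx(0.5)
        assert pop.fraction("inactive", "apo") == pytest.approx(0.5)
        assert pop.fractions[:, 1:].sum() == 0.0

    def test_apo_populations_at_measured_keq(self):
        s = scheme(KEQ, 10e-9, 10e-9, 10e-9, 10e-9)
        pop = species_fractions(s, 0.0, 0.0)
        assert pop.fraction("inactive", "apo") == pytest.approx(0.67 / 1.67, abs=5e-4)

    def test_three_equal_boltzmann_terms(self):
        # active-exclusive orthosteric ligand at free = Kd splits the lattice
        # into three equally weighted species
        s = scheme(1.0, 10e-9, math.inf, math.inf, 10e-9)
        pop = species_fractions(s, 10e-9, 0.0)
        assert pop.fraction("active", "apo") == pytest.approx(1 / 3)
        assert pop.fraction("active", "ortho") == pytest.approx(1 / 3)
        assert pop.fraction("inactive", "apo") == pytest.approx(1 / 3)

    def test_fractions_are_probability_vector(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            s = random_scheme(rng, n_states=int(rng.integers(2, 4)))
            pop = species_fractions(s, 10 ** rng.uniform(-10, -5),
                                    10 ** rng.uniform(-10, -5))
            assert np.all(pop.fractions >= 0)
            assert pop.fractions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_mismatched_states_raise(self):
        bad = LigandProfile(name="B", site="allosteric",
                            kd_per_state={"open": 1e-9, "closed": 1e-9})
        with pytest.raises(ConfigurationError):
            DoubleDrugScheme(
                ensemble=two_state(),
                ortho=ligand("orthosteric", 1e-9, 1e-9),
                allo=bad,
            )


class TestApparentKd:
    def test_nonselective_ligand_is_ensemble_independent(self):
        for keq in (0.1, 0.67, 1.0, 10.0):
            lig = ligand("allosteric", 10e-9, 10e-9)
            assert apparent_kd(two_state(keq), lig) == pytest.approx(10e-9)

    def test_harmonic_mean_formula(self):
        lig = ligand("allosteric", 10e-9, 100e-9)
        expected = 1.0 / (0.5 / 10e-9 + 0.5 / 100e-9)  # 18.18 nM
        assert apparent_kd(two_state(1.0), lig) == pytest.approx(expected)
        assert expected == pytest.approx(18.18e-9, rel=1e-3)

    def test_inactive_exclusive_limit(self):
        k = 50e-9
        lig = ligand("allosteric", math.inf, k)
        assert apparent_kd(two_state(KEQ), lig) == pytest.approx(
            k * (1 + KEQ) / KEQ
        )

    def test_binds_no_state_raises(self):
        with pytest.raises(UndefinedAffinityError):
            LigandProfile(name="x", site="allosteric",
                          kd_per_state={"active": math.inf, "inactive": math.inf})

    @pytest.mark.parametrize("n_states", [2, 3])
    def test_matches_halfway_titration_oracle(self, n_states):
        """K_app equals the brute-force half-occupancy concentration."""
        rng = np.random.default_rng(42 + n_states)
        for _ in range(40):
            s = random_scheme(rng, n_states=n_states)
            bg_free = 10 ** rng.uniform(-9, -5)
            for lig, bg in [
                (s.allo, None),
                (s.ortho, None),
                (s.allo, (s.ortho, bg_free)),
            ]:
                ka = apparent_kd(s.ensemble, lig, background=bg)
                oracle = halfway_titration_kd(s.ensemble, lig, background=bg)
                assert ka == pytest.approx(oracle, rel=1e-6)
                # K_app is bracketed by the per-state Kds (inf allowed)
                kds = list(lig.kd_per_state.values())
                if bg is None:
                    assert min(kds) * (1 - 1e-12) <= ka <= max(kds)


class TestShiftedEnsemble:
    def test_zero_free_is_identity(self):
        ens = two_state(KEQ)
        lig = ligand("orthosteric", 10e-9, 1e-9)
        assert shifted_ensemble(ens, lig, 0.0).weights == ens.weights

    def test_saturation_multiplies_keq_by_selectivity(self):
        s = solve_selectivity(16.0, KEQ, "active-exclusive")
        lig = ligand("orthosteric", s * 1e-9, 1e-9)
        shifted = shifted_ensemble(two_state(KEQ), lig, math.inf)
        assert shifted.keq == pytest.approx(KEQ * s, rel=1e-12)
        # 0.67 * (16*1.67 - 1)/0.67 = 25.72 (25.73 if s is first rounded to 38.4)
        assert shifted.keq == pytest.approx(25.72, abs=0.01)

    def test_nonselective_ligand_leaves_keq(self):
        lig = ligand("orthosteric", 5e-9, 5e-9)
        for free in (1e-9, 1e-6, 1e-3):
            assert shifted_ensemble(two_state(KEQ), lig, free).keq == pytest.approx(KEQ)


class TestCooperativity:
    def test_nonselective_partner_gives_alpha_one(self, null_preset):
        assert cooperativity_factor(null_preset.scheme, "allo") == pytest.approx(1.0)
        assert cooperativity_factor(null_preset.scheme, "ortho") == pytest.approx(1.0)

    def test_mb1_like_sixteen_fold_weakening(self, mb1):
        alpha = cooperativity_factor(mb1.scheme, "allo")
        assert 1.0 / alpha == pytest.approx(16.0, rel=1e-9)

    def test_mb2_like_tightening(self, mb2):
        # same danusertib selectivity predicts 2.40-fold for an
        # inactive-exclusive binder
        assert cooperativity_factor(mb2.scheme, "allo") == pytest.approx(2.40, abs=0.005)

    def test_cycle_closure_hypothesis_seeded(self):
        @settings(max_examples=200, deadline=None, derandomize=True)
        @given(st.integers(min_value=0, max_value=10**6),
               st.integers(min_value=2, max_value=3))
        def inner(seed, n_states):
            s = random_scheme(np.random.default_rng(seed), n_states=n_states)
            try:
                a1 = cooperativity_factor(s, "ortho")
                a2 = cooperativity_factor(s, "allo")
            except CannotSaturateError:
                return
            assert a1 == pytest.approx(a2, rel=1e-9)

        inner()

    def test_partner_binds_nothing_cannot_saturate(self):
        ens = ConformationalEnsemble(("active", "inactive"), (1.0, 0.0))
        s = DoubleDrugScheme(
            ensemble=ens,
            ortho=ligand("orthosteric", math.inf, 1e-9),  # binds only inactive
            allo=ligand("allosteric", 1e-9, 1e-9),
        )
        with pytest.raises(CannotSaturateError):
            cooperativity_factor(s, "allo")


class TestCeilingAndInversion:
    def test_ceiling_values(self):
        assert max_cooperativity_ceiling(1.0) == pytest.approx(2.0)
        assert max_cooperativity_ceiling(KEQ) == pytest.approx(2.4925, abs=5e-4)
        assert max_cooperativity_ceiling(1e9) == pytest.approx(1.0, abs=1e-8)

    def test_ceiling_strictly_decreasing(self):
        keqs = np.geomspace(1e-3, 1e3, 50)
        vals = [max_cooperativity_ceiling(k) for k in keqs]
        assert np.all(np.diff(vals) < 0)

    def test_ceiling_domain_error(self):
        with pytest.raises(ValueError):
            max_cooperativity_ceiling(0.0)

    def test_selectivity_identity(self):
        assert solve_selectivity(1.0, KEQ, "active-exclusive") == pytest.approx(1.0)
        assert solve_selectivity(1.0, KEQ, "inactive-exclusive") == pytest.approx(1.0)

    def test_sixteen_fold_gives_printed_selectivity(self):
        s = solve_selectivity(16.0, KEQ, "active-exclusive")
        assert s == pytest.approx((16 * 1.67 - 1) / 0.67, rel=1e-12)
        assert s == pytest.approx(38.4, abs=0.05)

    def test_three_fold_tightening_is_infeasible(self):
        with pytest.raises(InfeasibleCooperativityError):
            solve_selectivity(3.0, KEQ, "inactive-exclusive")

    @pytest.mark.parametrize("probe", ["active-exclusive", "inactive-exclusive"])
    def test_round_trip_through_cooperativity_factor(self, probe):
        rng = np.random.default_rng(3)
        ceiling = max_cooperativity_ceiling(KEQ)
        for _ in range(25):
            if probe == "active-exclusive":
                fold = 10 ** rng.uniform(0.01, 2)  # weakening folds
                kd = {"active": 1e-9, "inactive": math.inf}
            else:
                fold = rng.uniform(1.01, ceiling * 0.99)
                kd = {"active": math.inf, "inactive": 1e-9}
            s = solve_selectivity(fold, KEQ, probe)
            sch = scheme(KEQ, s * 1e-9, 1e-9, kd["active"], kd["inactive"])
            alpha = cooperativity_factor(sch, "allo")
            observed = 1.0 / alpha if probe == "active-exclusive" else alpha
            assert observed == pytest.approx(fold, rel=1e-9)


class TestMassBalance:
    def test_zero_totals(self, mb1):
        pop = solve_free_concentrations(mb1.scheme, 1e-6, 0.0, 0.0)
        assert pop.free_ortho == 0.0 and pop.free_allo == 0.0
        assert pop.fractions[:, 0].sum() == pytest.approx(1.0)

    def test_single_ligand_quadratic(self):
        # degenerate two-state ensemble with identical states behaves as one
        # site: Et = Lt = 2 uM, Kd = 1 uM -> bound = free = 1 uM
        s = scheme(1.0, 1e-6, 1e-6, 1e3, 1e3)
        pop = solve_free_concentrations(s, 2e-6, 2e-6, 0.0)
        assert pop.free_ortho == pytest.approx(1e-6, rel=1e-8)
        assert 2e-6 * pop.bound_fraction("orthosteric") == pytest.approx(1e-6, rel=1e-8)

    def test_excess_ligand_limit(self, mb1):
        pop = solve_free_concentrations(mb1.scheme, 1e-9, 1e-4, 1e-4)
        assert pop.free_ortho == pytest.approx(1e-4, rel=0.01)
        assert pop.free_allo == pytest.approx(1e-4, rel=0.01)

    def test_mass_balance_residuals_random(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            s = random_scheme(rng, n_states=int(rng.integers(2, 4)))
            et, ot, at = 10 ** rng.uniform(-7, -4, 3)
            pop = solve_free_concentrations(s, et, ot, at)
            bound_o = et * pop.bound_fraction("orthosteric")
            bound_a = et * pop.bound_fraction("allosteric")
            assert pop.free_ortho + bound_o == pytest.approx(ot, rel=1e-8)
            assert pop.free_allo + bound_a == pytest.approx(at, rel=1e-8)


class TestNestedThreeState:
    def test_reduces_to_two_state_when_third_weight_zero(self):
        states = ("open", "closing-competent", "closed")
        ens3 = ConformationalEnsemble(states, (1.0, 0.3, 0.0))
        ens2 = ConformationalEnsemble(states[:2], (1.0, 0.3))

        def prof(site, kds, sts):
            return LigandProfile(name=site[0], site=site,
                                 kd_per_state=dict(zip(sts, kds)))

        o3 = prof("orthosteric", (15e-9, 400e-9, 400e-9), states)
        a3 = prof("allosteric", (5e-9, 0.5e-9, 0.5e-9), states)
        o2 = prof("orthosteric", (15e-9, 400e-9), states[:2])
        a2 = prof("allosteric", (5e-9, 0.5e-9), states[:2])
        s3 = DoubleDrugScheme(ensemble=ens3, ortho=o3, allo=a3)
        s2 = DoubleDrugScheme(ensemble=ens2, ortho=o2, allo=a2)
        assert apparent_kd(ens3, o3) == pytest.approx(apparent_kd(ens2, o2), rel=1e-12)
        assert cooperativity_factor(s3, "allo") == pytest.approx(
            cooperativity_factor(s2, "allo"), rel=1e-12
        )
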