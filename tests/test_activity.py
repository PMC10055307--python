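"""Activity readouts, 4PL fitting, residual-dose inversion, synergy grids."""

import math

import numpy as np
import pytest

from coopkin import (
    DoseResponseRecord,
    UnreachableInhibitionError,
    dose_for_residual_activity,
    fit_4pl,
    jackknife_se,
    kobs_from_absorbance,
    predicted_activity,
    synergy_grid,
)
from coopkin.activity import four_pl


def record_from_4pl(top=0.5, bottom=0.0, ic50=100e-9, hill=1.0,
                    concs=None, noise=0.0, seed=0):
    if concs is None:
        concs = np.concatenate([[0.0], np.geomspace(1e-9, 1e-4, 11)])
    y = four_pl(concs, top, bottom, ic50, hill)
    if noise:
        y = y * (1 + np.random.default_rng(seed).normal(0, noise, y.shape))
    return DoseResponseRecord(concs, np.maximum(y, 0.0))


class TestKobs:
    def test_zero_slope(self):
        t = np.linspace(0, 100, 20)
        kobs, r2 = kobs_from_absorbance(t, np.ones_like(t), enzyme_total=20e-9)
        assert kobs == 0.0

    def test_printed_arithmetic(self):
        # slope -6.22e-5 AU/s with eps = 6220 /M/cm, 1 cm, 20 nM enzyme
        t = np.linspace(0, 60, 30)
        a = 1.0 - 6.22e-5 * t
        kobs, r2 = kobs_from_absorbance(t, a, enzyme_total=20e-9)
        assert kobs == pytest.approx(0.5, rel=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_enzyme_proportionality(self):
        t = np.linspace(0, 60, 30)
        a = 1.0 - 6.22e-5 * t
        k1, _ = kobs_from_absorbance(t, a, enzyme_total=20e-9)
        k2, _ = kobs_from_absorbance(t, a, enzyme_total=40e-9)
        assert k2 == pytest.approx(k1 / 2)

    def test_nonlinearity_warning(self):
        t = np.linspace(0, 60, 30)
        a = np.exp(-0.1 * t)
        with pytest.warns(UserWarning, match="nonlinear"):
            kobs_from_absorbance(t, a, enzyme_total=20e-9)


class TestPredictedActivity:
    def test_uninhibited_is_unity(self, mb1, ablkd):
        for truth in (mb1, ablkd):
            assert predicted_activity(truth.scheme, 0.0, 0.0) == pytest.approx(1.0)

    def test_ablkd_thirty_percent_floor(self, ablkd):
        # saturating allosteric drug leaves ~70% residual activity
        act = predicted_activity(ablkd.scheme, 0.0, 1e-3)
        assert act == pytest.approx(0.70, abs=0.005)

    def test_ablfl_ninety_three_percent_inhibition(self, ablfl):
        act = predicted_activity(ablfl.scheme, 0.0, 1e-3)
        assert act == pytest.approx(0.07, abs=0.005)

    def test_monotone_decreasing_in_each_inhibitor(self, mb2):
        concs = np.geomspace(1e-10, 1e-5, 25)
        along_ortho = [predicted_activity(mb2.scheme, c, 1e-7) for c in concs]
        along_allo = [predicted_activity(mb2.scheme, 1e-8, c) for c in concs]
        assert np.all(np.diff(along_ortho) <= 1e-12)
        assert np.all(np.diff(along_allo) <= 1e-12)
        assert all(0 <= a <= 1 + 1e-12 for a in along_ortho + along_allo)

    def test_atp_competition_raises_apparent_ic50(self, ablfl):
        """A state-selective but catalytically productive ATP pool competes
        the orthosteric drug out of the active site."""
        from coopkin import LigandProfile

        atp = LigandProfile(
            name="AMPPCP", site="orthosteric",
            kd_per_state={s: 200e-6 for s in ablfl.scheme.ensemble.states},
        )
        no_atp = predicted_activity(ablfl.scheme, 1e-7, 0.0)
        with_atp = predicted_activity(ablfl.scheme, 1e-7, 0.0, atp=(atp, 1e-3))
        assert with_atp > no_atp


class TestFourPL:
    def test_midpoint_definition(self):
        assert four_pl(np.array([100e-9]), 1.0, 0.2, 100e-9, 1.3)[0] == (
            pytest.approx(0.6)
        )

    def test_noiseless_round_trip(self):
        fit = fit_4pl(record_from_4pl(top=0.5, bottom=0.15, ic50=230e-9, hill=1.4))
        assert fit.top == pytest.approx(0.5, rel=1e-6)
        assert fit.bottom == pytest.approx(0.15, rel=1e-6)
        assert fit.ic50 == pytest.approx(230e-9, rel=1e-6)
        assert fit.hill == pytest.approx(1.4, rel=1e-6)

    def test_partial_inhibition_floor_recovered(self):
        # a 30%-of-top floor yields 70% maximal inhibition of the signal
        fit = fit_4pl(record_from_4pl(top=1.0, bottom=0.3))
        assert 1 - fit.bottom / fit.top == pytest.approx(0.7, rel=1e-6)

    def test_recovery_under_multiplicative_noise(self):
        kds = [
            fit_4pl(record_from_4pl(ic50=100e-9, noise=0.02, seed=s)).ic50
            for s in range(60)
        ]
        assert np.median(kds) == pytest.approx(100e-9, rel=0.10)


class TestResidualDose:
    def test_closed_form_nine_ic50(self):
        fit = fit_4pl(record_from_4pl(top=1.0, bottom=0.0, ic50=50e-9, hill=1.0))
        assert dose_for_residual_activity(fit, 0.10) == pytest.approx(
            9 * 50e-9, rel=1e-6
        )

    def test_half_residual_is_ic50(self):
        fit = fit_4pl(record_from_4pl(top=1.0, bottom=0.0, ic50=50e-9))
        assert dose_for_residual_activity(fit, 0.5) == pytest.approx(50e-9, rel=1e-6)

    def test_floor_above_residual_unreachable(self, ablkd):
        # asciminib alone cannot push AblKD below its 70% floor
        apo = predicted_activity(ablkd.scheme, 0.0, 0.0)
        with pytest.raises(UnreachableInhibitionError):
            dose_for_residual_activity(
                lambda d: predicted_activity(ablkd.scheme, 0.0, d) / apo, 0.10
            )

    def test_mechanistic_matches_4pl_inversion(self, mb2):
        """The empirical 4PL approximates the mechanistic dose within 2%."""
        concs = np.concatenate([[0.0], np.geomspace(1e-10, 3e-5, 14)])
        act = np.array([predicted_activity(mb2.scheme, c, 0.0) for c in concs])
        fit = fit_4pl(DoseResponseRecord(concs, 0.5 * act))
        d_4pl = dose_for_residual_activity(fit, 0.10)
        d_mech = dose_for_residual_activity(
            lambda d: predicted_activity(mb2.scheme, d, 0.0), 0.10
        )
        assert d_4pl == pytest.approx(d_mech, rel=0.02)


class TestJackknife:
    def test_mean_matches_closed_form(self):
        data = [1.0, 2.0, 3.0]
        # jackknife of the mean equals s/sqrt(n) = 0.5774 for {1,2,3}
        se = jackknife_se([1.0, 2.0, 3.0, 4.0], np.mean)
        s = np.std([1, 2, 3, 4], ddof=1)
        assert se == pytest.approx(s / 2.0, rel=1e-12)
        del data

    def test_noiseless_ic50_jackknife_is_zero(self):
        rec = record_from_4pl(ic50=100e-9)
        pts = list(zip(rec.inhibitor_conc, rec.k_obs))

        def stat(sub):
            c, k = map(np.array, zip(*sub))
            return fit_4pl(DoseResponseRecord(c, k)).ic50

        assert jackknife_se(pts, stat) < 1e-6 * 100e-9

    def test_perturbed_point_gives_positive_se(self):
        data = [1.0] * 8 + [2.0]
        assert jackknife_se(data, np.mean) > 0


class TestSynergyGrid:
    ORTHO = np.concatenate([[0.0], np.geomspace(1e-9, 3e-5, 8)])
    ALLO = np.concatenate([[0.0], np.geomspace(3e-8, 3e-6, 4)])

    def test_positive_cooperativity_monotone_dose_reduction(self, mb2, mb3):
        for truth in (mb2, mb3):
            grid = synergy_grid(truth.scheme, self.ORTHO, self.ALLO)
            d = grid.dose_10pct
            assert not np.any(np.isnan(d))
            assert np.all(np.diff(d) < 0)  # strictly decreasing with co-drug
            assert np.all(grid.fold_reduction[1:] > 1)

    def test_negative_cooperativity_weaker_dose_reduction(self, mb1, mb2):
        g_neg = synergy_grid(mb1.scheme, self.ORTHO, self.ALLO)
        g_pos = synergy_grid(mb2.scheme, self.ORTHO, self.ALLO)
        assert np.all(g_neg.fold_reduction[1:] < g_pos.fold_reduction[1:])

    def test_zero_allo_row_is_single_drug_curve(self, mb2):
        grid = synergy_grid(mb2.scheme, self.ORTHO, self.ALLO)
        single = [predicted_activity(mb2.scheme, c, 0.0) for c in self.ORTHO]
        assert grid.activity[0] == pytest.approx(single, rel=1e-12)

    def test_data_grid_interpolation_close_to_model(self, mb2):
        ortho = np.concatenate([[0.0], np.geomspace(1e-10, 3e-5, 24)])
        act = np.array(
            [[predicted_activity(mb2.scheme, o, a) for o in ortho]
             for a in self.ALLO]
        )
        grid = synergy_grid(0.5 * act, ortho, self.ALLO)
        model_grid = synergy_grid(mb2.scheme, ortho, self.ALLO)
        assert grid.dose_10pct == pytest.approx(model_grid.dose_10pct, rel=0.10)

    def test_aura_ordering_mb3_below_mb2_below_apo(self, mb2, mb3):
        """Less orthosteric drug is needed for 10% residual activity with the
        stronger positive-cooperativity partner saturating."""
        allo_sat = 1e-5
        d_apo = dose_for_residual_activity(
            lambda d: predicted_activity(mb2.scheme, d, 0.0), 0.10
        )

        def dose_with(truth):
            apo = predicted_activity(truth.scheme, 0.0, allo_sat)
            return dose_for_residual_activity(
                lambda d: predicted_activity(truth.scheme, d, allo_sat) / apo, 0.10
            )

        d_mb2, d_mb3 = dose_with(mb2), dose_with(mb3)
        assert d_mb3 < d_mb2 < d_apo
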