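"""Hill fitting, coupling detection and the two-step operational procedure."""

import numpy as np
import pytest

from opbias.functional import (
    fit_hill,
    fit_operational,
    fit_operational_panel,
    fit_system_emax,
    flat_test,
)
from opbias.models import HillFit, hill_response, hill_to_operational
from opbias.simulate import (
    FunctionalTruth,
    SimulationConfig,
    simulate_functional,
)


class TestFitHill:
    def test_noise_free_exact_recovery(self, make_series):
        x = np.logspace(-9.5, -5.5, 9)
        y = hill_response(x, 6.99, 18.0, 1.0)
        fit = fit_hill(make_series(x, np.tile(y[:, None], (1, 3))))
        assert fit.pEC50 == pytest.approx(6.99, abs=1e-6)
        assert fit.EmaxPrime == pytest.approx(18.0, abs=1e-5)
        assert fit.nH == pytest.approx(1.0, abs=1e-6)

    def test_flat_input_flags_no_response(self, make_series):
        x = np.logspace(-9, -5, 9)
        fit = fit_hill(make_series(x, np.ones((9, 3))))
        assert fit.no_response and fit.EmaxPrime == 1.0

    def test_grid_oracle_agreement(self, config, make_series):
        """Fitted optimum matches a brute-force parameter grid."""
        truth = FunctionalTruth(system_Emax=30.7, tau=1.41, pKA=6.6)
        series, _ = simulate_functional(config, "carbachol", truth)
        x, y = series.pooled()
        fit = fit_hill(series)
        pec_grid = np.arange(fit.pEC50 - 0.5, fit.pEC50 + 0.5, 0.01)
        top_grid = np.arange(max(1.0, fit.EmaxPrime - 4), fit.EmaxPrime + 4,
                             0.04)
        nh_grid = np.arange(0.5, 2.0, 0.01)
        best = (np.inf, None, None, None)
        ec50 = 10.0 ** (-pec_grid)[:, None, None]
        top = top_grid[None, :, None]
        xx = x[None, None, :]
        for nh in nh_grid:  # chunk over nh to bound memory
            pred = 1.0 + (top - 1.0) * xx**nh / (ec50**nh + xx**nh)
            sse = np.sum((pred - y[None, None, :]) ** 2, axis=-1)
            i, j = np.unravel_index(np.argmin(sse), sse.shape)
            if sse[i, j] < best[0]:
                best = (float(sse[i, j]), pec_grid[i], top_grid[j], nh)
        sse_star, pec_star, top_star, nh_star = best
        assert fit.pEC50 == pytest.approx(pec_star, abs=0.02)
        assert fit.EmaxPrime == pytest.approx(top_star, abs=0.08)
        assert fit.nH == pytest.approx(nh_star, abs=0.03)
        from opbias.models import hill_response as hr
        fit_sse = float(np.sum((hr(x, fit.pEC50, fit.EmaxPrime, fit.nH)
                                - y) ** 2))
        assert fit_sse <= sse_star + 1e-12


class TestFlatTest:
    def test_overwhelming_signal(self, make_series):
        x = np.logspace(-9.5, -5.5, 9)
        y = hill_response(x, 6.99, 18.0, 1.0)
        v = flat_test(make_series(x, np.tile(y[:, None], (1, 3))))
        assert v.coupled and v.p_value < 1e-10

    def test_flat_noisy_camp_is_no_coupling(self, make_series):
        rng = np.random.default_rng(7)
        x = np.logspace(-9, -5, 9)
        y = 1.0 + 0.03 * rng.standard_normal((9, 3))
        assert flat_test(make_series(x, y)).verdict == "no coupling"

    def test_detects_modest_signal(self):
        """A twofold-over-basal plateau is detected under the default design."""
        # tau chosen so the re-based plateau is exactly 2 fold over basal
        cfg = SimulationConfig(rng_seed=11)
        series, _ = simulate_functional(
            cfg, "weak", FunctionalTruth(system_Emax=30.7, tau=1.0 / 28.7,
                                         pKA=7.0))
        assert flat_test(series).coupled


class TestSystemEmax:
    def _panel(self, cfg, truths):
        out = []
        for lig, (tau, pka) in truths.items():
            for e in range(3):
                s, _ = simulate_functional(
                    cfg, lig, FunctionalTruth(30.7, tau, pka), experiment=e)
                out.append(s)
        return out

    def test_refuses_single_ligand(self, config):
        panel = self._panel(config, {"carbachol": (1.41, 6.6)})
        with pytest.raises(ValueError, match="ridge|>= 2"):
            fit_system_emax(panel)

    def test_refuses_equi_efficacious_standards(self, config):
        panel = self._panel(config, {"a": (1.0, 6.5), "b": (1.0, 7.5)})
        with pytest.raises(ValueError, match="not identifiable"):
            fit_system_emax(panel)

    def test_profile_ridge_is_flat_for_unit_slope_curves(self, config):
        panel = self._panel(config, {"carbachol": (1.41, 6.6),
                                     "oxotremorine": (2.799, 7.64),
                                     "pilocarpine": (0.946, 6.39)})
        fit = fit_system_emax(panel)
        assert fit.ridge_flat
        # beyond the knee the profile is flat to numerical precision
        flat_part = fit.profile_sse[fit.profile_emax >= fit.system_Emax]
        assert (flat_part.max() - flat_part.min()) < 1e-6 * flat_part.min()

    def test_full_agonist_pins_ceiling_to_plateau(self, config):
        panel = []
        for lig, (tau, pka) in {"carbachol": (1.41, 6.6),
                                "super": (1e6, 8.0)}.items():
            s, _ = simulate_functional(config, lig,
                                       FunctionalTruth(30.7, tau, pka))
            panel.append(s)
        fit = fit_system_emax(panel)
        assert fit.system_Emax == pytest.approx(30.7, rel=0.10)


class TestFitOperational:
    def test_noise_free_exact_recovery(self, noisefree_config):
        truth = FunctionalTruth(system_Emax=30.7, tau=2.8, pKA=7.64)
        series, _ = simulate_functional(noisefree_config, "oxo", truth)
        fit = fit_operational(series, 30.7)
        assert fit.tau == pytest.approx(2.8, abs=1e-6)
        assert fit.pKA == pytest.approx(7.64, abs=1e-6)

    def test_flat_series_reported_as_tau_zero(self, config):
        series, _ = simulate_functional(config, "JR6",
                                        FunctionalTruth(responds=False))
        fit = fit_operational(series, 30.7)
        assert fit.tau == 0.0 and fit.pKA is None

    def test_two_step_equals_closed_form_on_noise_free_data(self,
                                                            noisefree_config):
        truth = FunctionalTruth(system_Emax=30.7, tau=1.41, pKA=6.6)
        series, _ = simulate_functional(noisefree_config, "cbc", truth)
        hill = fit_hill(series)
        closed = hill_to_operational(
            HillFit(pEC50=hill.pEC50, EmaxPrime=hill.EmaxPrime, nH=1.0), 30.7)
        fitted = fit_operational(series, 30.7)
        assert fitted.tau == pytest.approx(closed.tau, abs=1e-6)
        assert fitted.pKA == pytest.approx(closed.pKA, abs=1e-6)

    def test_tau_invariant_to_joint_concentration_rescale(self, make_series,
                                                          noisefree_config):
        truth = FunctionalTruth(system_Emax=30.7, tau=1.41, pKA=6.6)
        series, _ = simulate_functional(noisefree_config, "cbc", truth)
        shifted = make_series(series.concentrations * 100.0, series.responses)
        a = fit_operational(series, 30.7)
        b = fit_operational(shifted, 30.7)
        assert b.tau == pytest.approx(a.tau, rel=1e-6)
        assert b.pKA == pytest.approx(a.pKA - 2.0, abs=1e-6)

    def test_tau_monotonically_raises_apparent_max_and_potency(self,
                                                               make_series):
        from opbias.models import operational_response

        x = np.logspace(-10, -4, 12)
        tops, pecs = [], []
        for tau in (0.5, 1.0, 2.0, 4.0):
            y = operational_response(x, 30.7, tau, 7.0)
            fit = fit_hill(make_series(x, np.tile(y[:, None], (1, 2))))
            tops.append(fit.EmaxPrime)
            pecs.append(fit.pEC50)
        assert np.all(np.diff(tops) > 0) and np.all(np.diff(pecs) > 0)

    def test_panel_summary_across_experiments(self, config):
        truth = FunctionalTruth(system_Emax=30.7, tau=2.8, pKA=7.64)
        series = [simulate_functional(config, "oxo", truth, experiment=e)[0]
                  for e in range(3)]
        out = fit_operational_panel(series, 30.7)
        assert out["n_experiments"] == 3
        assert out["tau_mean"] == pytest.approx(2.8, rel=0.25)
        assert out["tau_sd"] > 0
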