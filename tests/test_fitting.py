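"""Kd fitting, replicate aggregation, and selectivity reporting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpbind import (
    AnisotropyModel,
    CompetitiveBindingFP,
    EquilibriumSystem,
    PlateDesign,
    ValidationError,
    aggregate_replicates,
    export_fitted_curve,
    fit_competitive,
    fit_direct,
    fold_selectivity,
    simulate_competition_plate,
    simulate_direct_titration,
)
from fpbind.fitting import DirectBindingFP

DIRECT_DESIGN = dict(top_concentration=10e-6, dilution_factor=2.0,
                     n_concentrations=14, n_experiments=1, n_replicates=1)


def _direct_curve(noise_sd=0.0, seed=0, kd=50e-9, probe=20e-9):
    design = PlateDesign(noise_sd=noise_sd, seed=seed, **DIRECT_DESIGN)
    return simulate_direct_titration(design, kd, probe)


def _competitive_curve(true_kd, noise_sd=0.0, seed=0, n_experiments=3,
                       n_replicates=3, **system_kwargs):
    constants = dict(protein_total=100e-9, probe_total=20e-9, probe_kd=50e-9)
    constants.update(system_kwargs)
    design = PlateDesign(noise_sd=noise_sd, seed=seed,
                         n_experiments=n_experiments, n_replicates=n_replicates)
    system = EquilibriumSystem(inhibitor_kd=true_kd, **constants)
    return simulate_competition_plate(design, system), constants


class TestDirectFit:
    def test_noiseless_recovery(self):
        result = fit_direct(_direct_curve())
        assert result.probe_kd == pytest.approx(50e-9, rel=1e-3)
        assert result.r_free == pytest.approx(0.05, abs=1e-4)
        assert result.r_bound == pytest.approx(0.25, abs=1e-4)
        assert result.converged and result.valid and not result.plateau_warning

    def test_noisy_recovery_is_unbiased(self):
        # 100 seeded repeats at instrument-level noise: the log-scale bias
        # of the recovered Kd* stays within 0.05 decades.
        errors = []
        for seed in range(100):
            result = fit_direct(_direct_curve(noise_sd=0.002, seed=seed))
            errors.append(math.log10(result.probe_kd / 50e-9))
        assert abs(np.median(errors)) <= 0.05

    def test_inverted_plateaus_flagged(self):
        curve = _direct_curve()
        flipped = curve.data.copy()
        flipped["anisotropy"] = 0.30 - flipped["anisotropy"]
        curve.data = flipped
        est = DirectBindingFP(probe_total=20e-9).fit(
            flipped["concentration_M"].to_numpy(), flipped["anisotropy"].to_numpy()
        )
        assert not est.valid_

    def test_no_upper_plateau_warns(self):
        # Top protein far below Kd*: the curve never bends over.
        design = PlateDesign(top_concentration=1e-9, dilution_factor=2.0,
                             n_concentrations=8, n_experiments=1, n_replicates=1,
                             noise_sd=0.0, seed=0)
        curve = simulate_direct_titration(design, 1e-6, 20e-9)
        result = fit_direct(curve)
        assert result.plateau_warning

    def test_mode_mismatch_rejected(self):
        curve, _ = _competitive_curve(1e-6)
        with pytest.raises(ValidationError):
            fit_direct(curve)


class TestCompetitiveFit:
    def test_noiseless_recovery_at_low_nanomolar(self):
        # Ground truth at the potency scale of the best inhibitors (5.7 nM).
        curve, constants = _competitive_curve(5.7e-9, n_experiments=1)
        result = fit_competitive(curve, probe_kd=constants["probe_kd"])
        assert result.kd_mean == pytest.approx(5.7e-9, rel=5e-3)

    def test_inhibitor_matching_probe_affinity(self):
        curve, constants = _competitive_curve(50e-9, n_experiments=1)
        result = fit_competitive(curve, probe_kd=constants["probe_kd"])
        assert result.kd_mean == pytest.approx(50e-9, rel=5e-3)

    def test_noisy_replicate_structure_recovers_truth(self):
        true_kd = 0.0097e-6
        curve, constants = _competitive_curve(true_kd, noise_sd=0.002, seed=1)
        result = fit_competitive(curve, probe_kd=constants["probe_kd"])
        assert result.kd_mean == pytest.approx(true_kd, rel=0.25)
        assert result.sd_defined and result.kd_sd > 0
        assert len(result.kd_per_experiment) == 3

    def test_single_experiment_has_undefined_sd(self):
        curve, constants = _competitive_curve(1e-6, n_experiments=1)
        result = fit_competitive(curve, probe_kd=constants["probe_kd"])
        assert not result.sd_defined
        assert math.isnan(result.kd_sd)

    def test_weak_binder_flagged(self):
        # Kd four decades above the top concentration: <20% displacement.
        curve, constants = _competitive_curve(1e-2, noise_sd=0.002, seed=3)
        result = fit_competitive(curve, probe_kd=constants["probe_kd"])
        assert result.weak_binder

    def test_multistart_winner_has_lowest_rss(self):
        curve, constants = _competitive_curve(1e-7, noise_sd=0.002, seed=5,
                                              n_experiments=1)
        est = CompetitiveBindingFP(**constants)
        sub = curve.data
        est.fit(sub["concentration_M"].to_numpy(), sub["anisotropy"].to_numpy())
        assert est.rss_ == pytest.approx(2.0 * min(est.multistart_costs_), rel=1e-9)

    def test_recovery_sweep_is_accurate_and_unbiased(self):
        # 200 seeded curves spanning 1 nM - 100 uM true Kd at noise 0.002:
        # median relative error <= 15%, median signed log-error within 0.05.
        rng = np.random.default_rng(42)
        rel_errors, log_errors = [], []
        for i in range(200):
            true_kd = 10.0 ** rng.uniform(-9, -4)
            curve, constants = _competitive_curve(
                true_kd, noise_sd=0.002, seed=1000 + i, n_experiments=1)
            result = fit_competitive(curve, probe_kd=constants["probe_kd"])
            rel_errors.append(abs(result.kd_mean - true_kd) / true_kd)
            log_errors.append(math.log10(result.kd_mean / true_kd))
        assert np.median(rel_errors) <= 0.15
        assert abs(np.median(log_errors)) <= 0.05

    def test_missing_conditions_rejected(self):
        curve, _ = _competitive_curve(1e-6, n_experiments=1)
        curve.protein_total = None
        with pytest.raises(ValidationError):
            fit_competitive(curve, probe_kd=50e-9)


class TestAggregateReplicates:
    def test_identical_replicates(self):
        mean, sd = aggregate_replicates([41e-6, 41e-6, 41e-6])
        assert mean == pytest.approx(41e-6)
        assert sd == pytest.approx(0.0, abs=1e-20)

    def test_hand_computed_pair(self):
        mean, sd = aggregate_replicates([2.0, 4.0])
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(math.sqrt(2.0))

    def test_single_value_sd_undefined(self):
        mean, sd = aggregate_replicates([5e-9])
        assert mean == pytest.approx(5e-9)
        assert math.isnan(sd)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            aggregate_replicates([])
        with pytest.raises(ValidationError):
            aggregate_replicates([1e-9, -1e-9])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-9, 1e-3), min_size=2, max_size=8),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, kds, rand):
        mean_a, sd_a = aggregate_replicates(kds)
        shuffled = list(kds)
        rand.shuffle(shuffled)
        mean_b, sd_b = aggregate_replicates(shuffled)
        assert mean_a == pytest.approx(mean_b, rel=1e-12)
        assert sd_a == pytest.approx(sd_b, rel=1e-9, abs=1e-18)


class TestFoldSelectivity:
    def test_reported_ratios(self):
        # Best-in-series inhibitor: 2.2 uM vs 5.7 nM -> ~390-fold.
        assert fold_selectivity(2.2e-6, 0.0057e-6, sig_figs=2) == pytest.approx(390)
        # Early hit: 860 uM vs 41 uM -> ~21-fold, at least 20.
        ratio = fold_selectivity(860e-6, 41e-6)
        assert ratio >= 20
        assert fold_selectivity(860e-6, 41e-6, sig_figs=2) == pytest.approx(21)

    def test_identity_for_equal_affinities(self):
        assert fold_selectivity(3.3e-6, 3.3e-6) == pytest.approx(1.0)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            fold_selectivity(0.0, 1e-6)
        with pytest.raises(ValidationError):
            fold_selectivity(1e-6, 1e-6, sig_figs=0)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(a=st.floats(1e-9, 1e-3), b=st.floats(1e-9, 1e-3))
    def test_reciprocal_product_is_unity(self, a, b):
        assert fold_selectivity(a, b) * fold_selectivity(b, a) == pytest.approx(1.0, rel=1e-12)


class TestExportFittedCurve:
    def test_monotone_over_transition(self):
        curve, constants = _competitive_curve(1e-7, n_experiments=1)
        result = fit_competitive(curve, probe_kd=constants["probe_kd"])
        grid = np.geomspace(1e-9, 1e-4, 50)
        table = export_fitted_curve(result, grid)
        anis = table["anisotropy"].to_numpy()
        assert np.all(np.diff(anis) <= 1e-12)  # displacement lowers anisotropy

    def test_plateau_regions_flat(self):
        result = fit_direct(_direct_curve())
        low = export_fitted_curve(result, [1e-12, 2e-12, 4e-12])["anisotropy"]
        assert np.allclose(low, result.r_free, atol=1e-4)
        high = export_fitted_curve(result, [1e-2, 2e-2])["anisotropy"]
        assert np.allclose(high, result.r_bound, atol=1e-4)

    def test_roundtrip_refit_recovers_parameters(self):
        curve, constants = _competitive_curve(2e-7, n_experiments=1)
        result = fit_competitive(curve, probe_kd=constants["probe_kd"])
        grid = np.geomspace(1e-10, 1e-3, 80)
        table = export_fitted_curve(result, grid)
        est = CompetitiveBindingFP(**constants)
        est.fit(table["concentration_M"].to_numpy(), table["anisotropy"].to_numpy())
        assert est.kd_ == pytest.approx(result.kd_mean, rel=1e-6)

    def test_unconverged_fit_rejected(self):
        curve, constants = _competitive_curve(1e-7, n_experiments=1)
        result = fit_competitive(curve, probe_kd=constants["probe_kd"])
        result.experiments[0].converged = False
        from fpbind import ConvergenceError
        with pytest.raises(ConvergenceError):
            export_fitted_curve(result, [1e-8, 1e-7])
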