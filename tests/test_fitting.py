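"""Likelihood, noise profiling, Latin-hypercube starts and model fitting."""

import math

import numpy as np
import pytest

from grnsets.fitting import (
    PENALTY,
    Bounds,
    FitOptions,
    FittingError,
    fit_family,
    fit_model,
    free_parameters,
    lhs_starts,
    negative_log_likelihood,
    params_from_theta,
    profile_sigma,
)
from grnsets.synth import DESIGN_TIMES, NoiseSpec, generate_dataset
from grnsets.terms import named_models, reduce_for_knockout, build_family


def reference_nll(x, y, sigma):
    """Independent direct evaluation of the likelihood formula (plain loops)."""
    n = len(x)
    total = n * math.log(sigma)
    for xi in x:
        total += math.log(xi)
    for xi, yi in zip(x, y):
        total += 0.5 / sigma**2 * ((yi - xi) / xi) ** 2
    return total


class TestNegativeLogLikelihood:
    def test_zero_residuals_leave_only_log_terms(self):
        x = np.array([0.5, 1.5, 2.0])
        assert negative_log_likelihood(x, x, 1.0) == pytest.approx(np.sum(np.log(x)))

    def test_hand_computed_single_observation(self):
        # n=1, y=2, x=1, sigma=1: 0 + 0 + 0.5 * 1^2
        assert negative_log_likelihood([1.0], [2.0], 1.0) == pytest.approx(0.5)

    def test_matches_independent_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(1, 30)
            x = rng.uniform(0.05, 5.0, n)
            y = x * (1 + 0.3 * rng.standard_normal(n))
            sigma = rng.uniform(0.01, 2.0)
            assert negative_log_likelihood(x, y, sigma) == pytest.approx(
                reference_nll(x, y, sigma), abs=1e-12, rel=1e-12
            )

    def test_nonpositive_prediction_is_penalised(self):
        assert negative_log_likelihood([1.0, 0.0], [1.0, 1.0], 0.5) == PENALTY
        assert negative_log_likelihood([1.0, -2.0], [1.0, 1.0], 0.5) == PENALTY


class TestProfileSigma:
    def test_closed_form(self):
        x = np.array([1.0, 1.0])
        y = np.array([1.1, 0.9])  # relative residuals (0.1, -0.1)
        assert profile_sigma(x, y) == pytest.approx(0.1)

    def test_degenerate_residuals_hit_floor(self):
        x = np.array([1.0, 2.0])
        assert profile_sigma(x, x) == pytest.approx(1e-6)

    def test_profile_beats_any_grid_sigma(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(2, 40)
            x = rng.uniform(0.05, 5.0, n)
            y = x * (1 + 0.4 * rng.standard_normal(n))
            best = negative_log_likelihood(x, y, profile_sigma(x, y))
            for sigma in np.logspace(-6, 2, 200):
                assert best <= negative_log_likelihood(x, y, sigma) + 1e-9


class TestLhsStarts:
    def test_log_midpoint_maps_to_unity(self):
        # the centre of the unscaled log-range (unit value 0.5) is 10^0 = 1
        starts = lhs_starts(1, ["unscaled"], Bounds(), seed=0, scramble=False)
        assert starts[0, 0] == pytest.approx(1.0)
        scaled = lhs_starts(1, ["scaled"], Bounds(), seed=0, scramble=False)
        assert scaled[0, 0] == pytest.approx(1.0)

    def test_stratification_one_sample_per_half(self):
        starts = lhs_starts(2, ["unscaled", "scaled"], Bounds(), seed=3)
        for j, (lo, hi) in enumerate([(1e-4, 1e4), (1e-8, 1e8)]):
            logs = np.log10(starts[:, j])
            mid = (np.log10(lo) + np.log10(hi)) / 2
            assert (logs < mid).sum() == 1 and (logs >= mid).sum() == 1

    def test_samples_strictly_inside_optimizer_bounds(self):
        bounds = Bounds()
        starts = lhs_starts(64, ["unscaled"] * 3 + ["scaled"] * 2, bounds, seed=5)
        assert np.all(starts[:, :3] > bounds.unscaled_lower)
        assert np.all(starts[:, :3] < bounds.unscaled_upper)
        assert np.all(starts[:, 3:] > bounds.scaled_lower)
        assert np.all(starts[:, 3:] < bounds.scaled_upper)

    def test_reproducible_by_seed(self):
        a = lhs_starts(8, ["unscaled"] * 4, Bounds(), seed=11)
        b = lhs_starts(8, ["unscaled"] * 4, Bounds(), seed=11)
        assert np.array_equal(a, b)


class TestFreeParameters:
    def test_nhr40_initial_condition_free_only_when_n_is_used(self):
        models = named_models()
        with_n = dict(free_parameters(models["model_11574"]))
        assert "p0_N" in with_n and with_n["p0_N"] == "scaled"
        without_n = dict(free_parameters(models["distant_minimal"]))  # no N anywhere
        assert "p0_N" not in without_n
        with_n_ko = dict(free_parameters(models["distant_rich"]))  # N regulates sult-1
        assert "p0_N" in with_n_ko

    def test_half_max_constants_follow_term_structure(self):
        names = [n for n, _ in free_parameters(named_models()["model_11574"])]
        # eud-1 pair uses K_1 and K_4; nhr-40 single K_2; sult-1 squared K_3
        assert {"K_1", "K_4", "K_2", "K_3"} <= set(names)
        assert "K_5" not in names and "K_6" not in names

    def test_preset_protein_ics_are_fixed(self):
        model = named_models()["model_11574"]
        theta = {name: 1.0 for name, _ in free_parameters(model)}
        params = params_from_theta(model, theta, preset_protein_ic=1e-3)
        assert params.p0["E"] == 1e-3 and params.p0["S"] == 1e-3
        assert params.p0["N"] == 1.0  # free because N regulates eud-1 and nhr-40


@pytest.fixture(scope="module")
def sparse_dataset(true_params):
    truth = named_models()["model_11574"]
    return generate_dataset(
        truth, true_params, np.asarray(DESIGN_TIMES), 4, NoiseSpec(cv=0.2, seed=42)
    )


FAST = FitOptions(race_budget=150, polish_top=2)


@pytest.fixture(scope="module")
def truth_fit(sparse_dataset):
    # every start optimised to convergence: capped screens can misrank the
    # deep basins of well-specified structures on this landscape
    truth = named_models()["model_11574"]
    return fit_model(
        truth, sparse_dataset, n_starts=30, seed=7,
        options=FitOptions(rtol=1e-5, atol=1e-8, mxstep=1500),
    )


class TestFitModel:
    def test_fit_beats_or_matches_truth_nll(self, truth_fit, sparse_dataset, true_params):
        """The optimised nll must not be (much) worse than the generating parameters'."""
        from grnsets.dynamics import compile_model, simulate_mrna
        from grnsets.fitting import _prepare_observations

        truth = named_models()["model_11574"]
        assert not truth_fit.failed
        _, utimes, gi, ti, y = _prepare_observations(truth, sparse_dataset)
        x = simulate_mrna(compile_model(truth, true_params), utimes)[gi, ti]
        truth_nll = negative_log_likelihood(x, y, profile_sigma(x, y))
        assert truth_fit.nll <= truth_nll + 10.0

    def test_monotone_under_nested_start_subsets(self, truth_fit):
        best_all = truth_fit.start_nlls.min()
        best_subset = truth_fit.start_nlls[:10].min()
        assert best_all <= best_subset
        assert truth_fit.nll == pytest.approx(best_all)

    def test_degenerate_structure_with_no_regulated_production_still_fits(
        self, true_params, design_times
    ):
        truth = named_models()["distant_minimal"]
        ko = reduce_for_knockout(truth, "sult-1")  # nhr-40 term collapses to None
        assert ko.terms["nhr-40"] is None
        dataset = generate_dataset(ko, _ko_params(true_params, ko), design_times, 2,
                                   NoiseSpec(cv=0.1, seed=2))
        result = fit_model(ko, dataset, n_starts=6, seed=3, options=FAST)
        assert not result.failed
        assert np.isfinite(result.nll)

    def test_predictions_align_with_dataset_rows(self, truth_fit, sparse_dataset):
        assert len(truth_fit.predictions) == sparse_dataset.n
        assert (truth_fit.predictions["prediction"] > 0).all()

    def test_all_starts_failing_flags_the_fit(self, sparse_dataset):
        """Penalised evaluations never win: if every start fails, the result
        is flagged failed with the penalty value, not reported as a fit."""
        truth = named_models()["model_11574"]
        # a 1-step integration cap makes every trajectory evaluation fail
        broken = FitOptions(mxstep=1, maxfun=30)
        result = fit_model(truth, sparse_dataset, n_starts=3, seed=0, options=broken)
        assert result.failed
        assert result.nll == PENALTY
        assert result.n_failed_starts == 3
        assert result.params is None

    def test_mismatched_dataset_rejected(self, sparse_dataset):
        ko_model = reduce_for_knockout(named_models()["model_11574"], "eud-1")
        trimmed = sparse_dataset.table[sparse_dataset.table["gene"] != "nhr-40"]
        from grnsets.synth import ExpressionDataset

        with pytest.raises(FittingError):
            fit_model(ko_model, ExpressionDataset("x", trimmed), n_starts=2, seed=0)


def _ko_params(params, model):
    import dataclasses

    return dataclasses.replace(
        params,
        alpha={g: params.alpha[g] for g in model.genes},
        k_tx={g: params.k_tx[g] for g in model.genes},
        m0={g: params.m0[g] for g in model.genes},
        p0={p: params.p0[p] for p in model.proteins},
    )


class TestFitFamily:
    def test_subset_sorted_and_deterministic(self, true_params, design_times):
        family = build_family(("N", "S"), ("nhr-40", "sult-1"))
        truth_wt = named_models()["model_11574"]
        ko = reduce_for_knockout(truth_wt, "eud-1")
        dataset = generate_dataset(ko, _ko_params(true_params, ko), design_times, 2,
                                   NoiseSpec(cv=0.2, seed=6))
        opts = FitOptions(race_budget=60, polish_top=1)
        table = fit_family(family, dataset, n_starts=3, seed=5, options=opts,
                           model_indices=[0, 7, 20, 77, 143])
        assert len(table) == 5
        assert (np.diff(table["nll"]) >= 0).all()
        again = fit_family(family, dataset, n_starts=3, seed=5, options=opts,
                           model_indices=[0, 7, 20, 77, 143])
        assert np.array_equal(table["nll"].to_numpy(), again["nll"].to_numpy())

    def test_checkpointing_resumes(self, true_params, design_times, tmp_path):
        family = build_family(("N", "S"), ("nhr-40", "sult-1"))
        ko = reduce_for_knockout(named_models()["model_11574"], "eud-1")
        dataset = generate_dataset(ko, _ko_params(true_params, ko), design_times, 2,
                                   NoiseSpec(cv=0.2, seed=6))
        opts = FitOptions(race_budget=60, polish_top=1)
        first = fit_family(family, dataset, n_starts=2, seed=5, options=opts,
                           model_indices=[1, 2], checkpoint_dir=tmp_path)
        assert (tmp_path / "model_1.json").exists()
        resumed = fit_family(family, dataset, n_starts=2, seed=5, options=opts,
                             model_indices=[1, 2, 3], checkpoint_dir=tmp_path)
        assert len(resumed) == 3
        merged = resumed[resumed["model_index"].isin([1, 2])].sort_values("model_index")
        original = first.sort_values("model_index")
        assert np.array_equal(merged["nll"].to_numpy(), original["nll"].to_numpy())
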