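"""Synthetic-cohort generator: schedule, priors, noise, phenotype linkage."""

import dataclasses

import numpy as np
import pytest

from weanling import (
    CohortConfig,
    PerturbedParams,
    build_schedule,
    generate_cohort,
    perturbed_weight,
    sample_animal_params,
    simulate_faecal_scores,
    simulate_haemogram,
    simulate_trajectory,
)

from conftest import REFERENCE_PARAMS


class TestSchedule:
    def test_twice_weekly_then_weekly(self):
        grid = build_schedule(CohortConfig(n_animals=1))
        assert list(grid.times[:7]) == [0, 3, 7, 10, 14, 17, 21]
        # weekly cadence after 50 d of age
        assert list(np.diff(grid.times[6:])) == [7] * (len(grid.times) - 7)

    def test_bounds_for_default_ages(self):
        grid = build_schedule(CohortConfig(n_animals=1))
        assert grid.times[0] == 0
        assert grid.times[-1] <= 72  # age cap 100 minus weaning age 28
        assert np.all(np.diff(grid.times) > 0)

    def test_about_thirteen_points_in_horizon(self):
        grid = build_schedule(CohortConfig(n_animals=1))
        in_horizon = (grid.times > 0) & (grid.times <= 75)
        assert 12 <= in_horizon.sum() <= 14


class TestParamSampling:
    def test_reproducible_streams(self):
        cfg = CohortConfig(n_animals=1, seed=3)
        a = [sample_animal_params(cfg, np.random.default_rng(9)) for _ in range(3)]
        b = [sample_animal_params(cfg, np.random.default_rng(9)) for _ in range(3)]
        assert a == b

    def test_ts_distribution_centres_on_nine_days(self):
        cfg = CohortConfig(n_animals=1)
        rng = np.random.default_rng(0)
        ts = np.array([sample_animal_params(cfg, rng).ts for _ in range(10_000)])
        se = ts.std(ddof=1) / np.sqrt(ts.size)
        assert abs(ts.mean() - 9.0) <= 2 * se + 0.1  # slight truncation shift
        assert ts.min() > 2.0 and ts.max() < 30.0

    def test_zero_perturbation_point_mass(self):
        cfg = CohortConfig(n_animals=1, c_zero_fraction=1.0)
        rng = np.random.default_rng(1)
        assert all(sample_animal_params(cfg, rng).C == 0.0 for _ in range(20))

    def test_draws_respect_invariants(self):
        cfg = CohortConfig(n_animals=1)
        rng = np.random.default_rng(5)
        for _ in range(200):
            p = sample_animal_params(cfg, rng)  # constructor validates
            assert 0 <= p.C <= cfg.c_max


class TestTrajectorySimulation:
    def test_zero_noise_is_exact(self, schedule):
        traj = simulate_trajectory(REFERENCE_PARAMS, schedule, 0.0,
                                   np.random.default_rng(0))
        np.testing.assert_array_equal(
            traj.weights, perturbed_weight(REFERENCE_PARAMS, schedule.times)
        )

    def test_day_one_weight_loss_for_strong_perturbation(self, schedule):
        # C = 0.08 > mu0 = 0.05: the truth curve drops on day 1
        w = perturbed_weight(REFERENCE_PARAMS, np.array([0.0, 1.0]))
        assert w[1] < w[0]

    def test_multiplicative_noise_keeps_weights_positive(self, schedule):
        rng = np.random.default_rng(8)
        traj = simulate_trajectory(REFERENCE_PARAMS, schedule, 0.5, rng)
        assert np.all(traj.weights > 0)

    def test_noise_scale_matches_cv(self, schedule):
        rng = np.random.default_rng(12)
        ratios = []
        truth = perturbed_weight(REFERENCE_PARAMS, schedule.times)
        for _ in range(400):
            traj = simulate_trajectory(REFERENCE_PARAMS, schedule, 0.015, rng)
            ratios.append(traj.weights / truth)
        cv = np.std(np.log(ratios))
        assert cv == pytest.approx(0.015, rel=0.1)


class TestFaecalSimulation:
    def test_panel_days(self):
        cfg = CohortConfig(n_animals=1)
        fs = simulate_faecal_scores(REFERENCE_PARAMS, cfg,
                                    np.random.default_rng(0))
        assert list(fs.days) == [0, 2, 6, 8, 12, 15, 20, 27, 34]

    def test_null_linkage_uncorrelated(self):
        cfg = CohortConfig(n_animals=1, faecal_slope_c=0.0,
                           faecal_recovery_decay=0.0)
        rng = np.random.default_rng(3)
        cs, sums = [], []
        for _ in range(400):
            p = sample_animal_params(cfg, rng)
            fs = simulate_faecal_scores(p, cfg, rng)
            cs.append(p.C)
            sums.append(np.mean(fs.scores == 2))
        r = np.corrcoef(cs, sums)[0, 1]
        assert abs(r) < 0.15

    def test_default_linkage_positive(self):
        cfg = CohortConfig(n_animals=1)
        rng = np.random.default_rng(4)
        cs, sums = [], []
        for _ in range(400):
            p = sample_animal_params(cfg, rng)
            fs = simulate_faecal_scores(p, cfg, rng)
            cs.append(p.C)
            sums.append(np.mean(fs.scores == 2))
        assert np.corrcoef(cs, sums)[0, 1] > 0.3


class TestHaemogramSimulation:
    def test_reproducible(self):
        cfg = CohortConfig(n_animals=1)
        h1 = simulate_haemogram(REFERENCE_PARAMS, cfg,
                                np.random.default_rng(6), 28)
        h2 = simulate_haemogram(REFERENCE_PARAMS, cfg,
                                np.random.default_rng(6), 28)
        assert h1 == h2

    def test_zero_loadings_independent(self):
        cfg = CohortConfig(n_animals=1, linkage={})
        rng = np.random.default_rng(7)
        cs, hcts = [], []
        for _ in range(400):
            p = sample_animal_params(cfg, rng)
            cs.append(p.C)
            hcts.append(simulate_haemogram(p, cfg, rng, 28)["Hct"])
        assert abs(np.corrcoef(cs, hcts)[0, 1]) < 0.15

    def test_hct_falls_with_perturbation_depth(self):
        cfg = CohortConfig(n_animals=1)
        rng = np.random.default_rng(8)
        cs, hcts = [], []
        for _ in range(400):
            p = sample_animal_params(cfg, rng)
            cs.append(p.C)
            hcts.append(simulate_haemogram(p, cfg, rng, 28)["Hct"])
        assert np.corrcoef(cs, hcts)[0, 1] < -0.1

    def test_derived_ratio_present(self):
        cfg = CohortConfig(n_animals=1)
        h = simulate_haemogram(REFERENCE_PARAMS, cfg,
                               np.random.default_rng(9), 34)
        assert h["N_Lym"] == pytest.approx(h["N"] / h["Lym"])


class TestCohort:
    def test_default_size_mirrors_study(self):
        assert CohortConfig().n_animals == 325

    def test_truth_joins_trajectories(self):
        cohort = generate_cohort(CohortConfig(n_animals=12, seed=2))
        ids = {a.animal_id for a in cohort.animals}
        assert set(cohort.truth.animal_id) == ids
        assert len(ids) == 12

    def test_byte_identical_outputs_for_fixed_seed(self, tmp_path):
        cfg = CohortConfig(n_animals=8, seed=5)
        p1 = generate_cohort(cfg).write_csvs(tmp_path / "a")
        p2 = generate_cohort(cfg).write_csvs(tmp_path / "b")
        for name in p1:
            assert open(p1[name], "rb").read() == open(p2[name], "rb").read()

    def test_noiseless_first_weighing_equals_w0(self):
        cohort = generate_cohort(CohortConfig(n_animals=5, seed=1,
                                              noise_cv=0.0))
        for a in cohort.animals:
            assert a.trajectory.weights[0] == pytest.approx(a.true_params.W0)
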