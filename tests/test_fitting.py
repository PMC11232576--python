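"""Weighted robust fitting, bootstrap CIs, and protein pooling."""

import numpy as np
import pytest

from silkdyn.fitting import (FittingError, Observation, bootstrap_ci,
                             compute_ria, evaluate_objective, fit_bounded,
                             fit_joint, pool_protein, robust_two_step_fit,
                             tukey_outliers, weighted_objective)
from silkdyn.models import Trajectory, integrate
from silkdyn.synthetic import ARCHETYPES, SyntheticDesign, generate_protein

from .conftest import make_observation
from .oracles import grid_search_single

TIMES = np.array([0, 3, 6, 9, 12, 15, 18, 21, 24, 27, 30, 33, 36.2])


class TestComputeRia:
    @pytest.mark.parametrize("i0,i6,n,expected", [
        (100.0, 0.0, 1, 0.0),
        (100.0, 100.0, 2, 0.25),
        (300.0, 100.0, 2, 0.125),
    ])
    def test_values(self, i0, i6, n, expected):
        assert compute_ria(i0, i6, n) == pytest.approx(expected, abs=1e-12)

    def test_zero_total_signal_is_missing_not_zero(self):
        assert np.isnan(compute_ria(0.0, 0.0, 1))
        arr = compute_ria(np.array([0.0, 100.0]), np.array([0.0, 100.0]), 1)
        assert np.isnan(arr[0]) and arr[1] == 0.5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_ria(100.0, 10.0, 0)
        with pytest.raises(ValueError):
            compute_ria(-1.0, 10.0, 1)


class TestWeightedObjective:
    def test_perfect_fit_is_zero(self, protocol, clean_single_obs):
        obs = clean_single_obs
        traj = integrate("single", [0.01, 0.15], protocol, obs.times,
                         method="expm")
        # the observation was built as curve + shift, zeroed at t=0
        val = weighted_objective(
            Trajectory(obs.times, traj.g,
                       np.where(obs.times == 0, 0.0, traj.r_plasma)),
            obs, shift=0.002)
        assert val == pytest.approx(0.0, abs=1e-18)

    def test_two_point_toy_value(self):
        # weights {1, 3} after normalization mean=1 -> I0 {0.5, 1.5} scaled
        obs = Observation("P", "LK", "F1", 2, "plasma", 1,
                          times=np.array([3.0, 6.0]),
                          i0=np.array([1.0, 3.0]) / 2.0,
                          i6=np.zeros(2))
        # craft model values so residuals are 0.01 and -0.02 with shift 0
        model = Trajectory(obs.times, np.zeros(2), np.array([0.01, -0.02]))
        w = obs.i0 / np.mean(obs.i0)      # {0.5, 1.5}
        expected = 0.5 * 1e-4 + 1.5 * 4e-4
        assert weighted_objective(model, obs, 0.0) == pytest.approx(expected)

    def test_uniform_weights_reduce_to_plain_sse(self):
        obs = Observation("P", "LK", "F1", 2, "plasma", 1,
                          times=np.array([3.0, 6.0, 9.0]),
                          i0=np.full(3, 7.0), i6=np.zeros(3))
        model = Trajectory(obs.times, np.zeros(3),
                           np.array([0.01, 0.02, -0.01]))
        assert weighted_objective(model, obs, 0.0) == pytest.approx(
            0.01 ** 2 + 0.02 ** 2 + 0.01 ** 2)

    def test_all_missing_raises(self):
        obs = Observation("P", "LK", "F1", 2, "plasma", 1,
                          times=np.array([3.0]), i0=np.array([0.0]),
                          i6=np.array([0.0]))
        model = Trajectory(obs.times, np.zeros(1), np.zeros(1))
        with pytest.raises(FittingError):
            weighted_objective(model, obs, 0.0)


class TestFitBounded:
    def test_noiseless_recovery(self, protocol, obs_times):
        truth = (0.01, 0.15, 0.002)
        obs = make_observation(truth[:2], protocol, obs_times,
                               shift=truth[2], zero_at_t0=False)
        fit = fit_bounded("single", [obs], protocol=protocol)
        assert fit.params["a"] == pytest.approx(truth[0], rel=1e-4)
        assert fit.params["b"] == pytest.approx(truth[1], rel=1e-4)
        assert fit.shifts["plasma"] == pytest.approx(truth[2], rel=1e-4)

    def test_zero_ria_drives_a_to_lower_bound(self, protocol, obs_times):
        obs = Observation("P", "LVK", "F1", 2, "plasma", 1, obs_times,
                          i0=np.full(13, 1e5), i6=np.zeros(13))
        fit = fit_bounded("single", [obs], protocol=protocol)
        assert fit.params["a"] == 0.0

    def test_objective_beats_grid_search_oracle(self, protocol, obs_times):
        rng = np.random.default_rng(11)
        obs = make_observation((0.012, 0.2), protocol, obs_times,
                               shift=0.003, noise_sd=0.002, rng=rng)
        fit = fit_bounded("single", [obs], protocol=protocol)
        best_sse, best_params = grid_search_single(
            obs, protocol, a_grid=np.linspace(0.001, 0.05, 50),
            b_grid=np.linspace(0.01, 1.0, 50),
            s_grid=np.linspace(-0.01, 0.01, 50))
        assert fit.weighted_sse <= best_sse + 1e-12

    def test_too_few_points_raises(self, protocol):
        obs = Observation("P", "LVK", "F1", 2, "plasma", 1,
                          times=np.array([0.0, 3.0, 6.0]),
                          i0=np.full(3, 1e5), i6=np.full(3, 100.0))
        with pytest.raises(FittingError):
            fit_bounded("single", [obs], protocol=protocol)

    def test_doubling_i0_leaves_argmin_unchanged(self, protocol, obs_times):
        rng = np.random.default_rng(5)
        i0 = rng.lognormal(np.log(1e5), 1.0, 13)
        obs1 = make_observation((0.01, 0.2), protocol, obs_times, i0=i0,
                                noise_sd=0.002, rng=np.random.default_rng(2))
        obs2 = make_observation((0.01, 0.2), protocol, obs_times, i0=2 * i0,
                                noise_sd=0.002, rng=np.random.default_rng(2))
        f1 = fit_bounded("single", [obs1], protocol=protocol)
        f2 = fit_bounded("single", [obs2], protocol=protocol)
        assert f1.params["a"] == pytest.approx(f2.params["a"], rel=1e-6)
        assert f1.params["b"] == pytest.approx(f2.params["b"], rel=1e-6)

    def test_deterministic(self, protocol, obs_times):
        obs = make_observation((0.01, 0.2), protocol, obs_times,
                               noise_sd=0.003, rng=np.random.default_rng(3))
        f1 = fit_bounded("single", [obs], protocol=protocol)
        f2 = fit_bounded("single", [obs], protocol=protocol)
        assert f1.params == f2.params and f1.weighted_sse == f2.weighted_sse


class TestRobustTwoStep:
    def test_clean_data_only_t0_flagged(self, protocol, clean_single_obs):
        fit = robust_two_step_fit("single", [clean_single_obs],
                                  protocol=protocol)
        flags = fit.outlier_flags[clean_single_obs.key]
        assert flags[0]                     # t = 0 always an outlier
        assert not flags[1:].any()

    def test_half_range_rule_flags_planted_outlier(self, protocol, obs_times):
        obs = make_observation((0.01, 0.15), protocol, obs_times, shift=0.0)
        # push one mid-curve point far outside half the curve range
        ria_spike = 0.2
        obs.i6[6] = ria_spike * obs.i0[6] / (1 - ria_spike)
        fit = robust_two_step_fit("single", [obs], protocol=protocol)
        assert fit.outlier_flags[obs.key][6]

    def test_step2_sse_not_worse_on_retained_points(self, protocol,
                                                    obs_times):
        rng = np.random.default_rng(8)
        obs = make_observation((0.012, 0.2), protocol, obs_times,
                               noise_sd=0.004, rng=rng)
        step1 = fit_bounded("single", [obs], protocol=protocol)
        fit = robust_two_step_fit("single", [obs], protocol=protocol)
        flags = fit.outlier_flags
        sse1 = evaluate_objective("single", step1, [obs], protocol=protocol,
                                  exclude=flags)
        assert fit.weighted_sse <= sse1 + 1e-12

    def test_all_points_flagged_raises(self, protocol):
        # a curve that fits nothing: single point repeated at t=0 only
        times = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
        obs = Observation("P", "LVK", "F1", 2, "plasma", 1, times,
                          i0=np.full(5, 1e5), i6=np.full(5, 1e4))
        with pytest.raises(FittingError):
            robust_two_step_fit("single", [obs], protocol=protocol,
                                min_points=5)


class TestBootstrap:
    def test_reproducible_and_degenerate_width(self, protocol, obs_times):
        obs = make_observation((0.01, 0.15), protocol, obs_times, shift=0.002)
        fit = robust_two_step_fit("single", [obs], protocol=protocol)
        b1 = bootstrap_ci("single", [obs], n_boot=50, seed=4, fit=fit,
                          protocol=protocol)
        lo, hi = b1.ci95["a"]
        assert hi - lo <= 1e-3              # zero-noise resampling
        fit2 = robust_two_step_fit("single", [obs], protocol=protocol)
        b2 = bootstrap_ci("single", [obs], n_boot=50, seed=4, fit=fit2,
                          protocol=protocol)
        assert b1.ci95 == b2.ci95

    def test_single_replicate_collapses_interval(self, protocol, obs_times):
        obs = make_observation((0.01, 0.15), protocol, obs_times,
                               noise_sd=0.002, rng=np.random.default_rng(6))
        fit = robust_two_step_fit("single", [obs], protocol=protocol)
        b = bootstrap_ci("single", [obs], n_boot=1, seed=0, fit=fit,
                         protocol=protocol)
        for lo, hi in b.ci95.values():
            assert lo == pytest.approx(hi)

    def test_coverage_on_simulated_replicates(self, protocol, obs_times):
        """~95% of replicates should cover the true clearance rate."""
        truth = (0.012, 0.2, 0.002)
        hits = 0
        n_rep = 120
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            obs = make_observation(truth[:2], protocol, obs_times,
                                   shift=truth[2], noise_sd=0.0015, rng=rng)
            try:
                fit = robust_two_step_fit("single", [obs], protocol=protocol)
                fit = bootstrap_ci("single", [obs], n_boot=300,
                                   seed=rep, fit=fit, protocol=protocol)
            except FittingError:
                continue
            lo, hi = fit.ci95["b"]
            if lo <= truth[1] <= hi:
                hits += 1
        coverage = hits / n_rep
        assert 0.88 <= coverage <= 0.99


class TestPooling:
    def test_tukey_rule(self):
        flags = tukey_outliers([0.10, 0.11, 0.12, 0.50])
        assert flags.tolist() == [False, False, False, True]

    def test_single_observation_is_identity(self, protocol, obs_times):
        obs = make_observation((0.01, 0.15), protocol, obs_times, shift=0.002)
        pooled = pool_protein([obs], n_boot=0, protocol=protocol)
        assert len(pooled.observations) == 1
        assert pooled.dropped == []

    def test_shared_peptides_dropped(self, protocol, obs_times):
        o1 = make_observation((0.01, 0.15), protocol, obs_times)
        o2 = make_observation((0.01, 0.15), protocol, obs_times,
                              peptide="SHRDLK", fraction="F2")
        o2.shared = True
        pooled = pool_protein([o1, o2], n_boot=0, protocol=protocol)
        assert [k for k, r in pooled.dropped] == [o2.key]
        assert len(pooled.observations) == 1

    def test_discordant_clearance_discarded(self, protocol, obs_times):
        obs = [make_observation((0.01, b), protocol, obs_times,
                                peptide=f"PEPL{i}K", fraction=f"F{i}")
               for i, b in enumerate([0.10, 0.11, 0.12])]
        obs.append(make_observation((0.01, 1.5), protocol, obs_times,
                                    peptide="PEPL9K", fraction="F9"))
        pooled = pool_protein(obs, n_boot=0, protocol=protocol)
        reasons = {k: r for k, r in pooled.dropped}
        assert reasons.get(obs[-1].key) == "clearance_outlier"
        assert len(pooled.observations) == 3

    def test_alignment_removes_constant_offset(self, protocol, obs_times):
        base = make_observation((0.01, 0.15), protocol, obs_times,
                                i0=np.full(13, 2e5))
        shifted = make_observation((0.01, 0.15), protocol, obs_times,
                                   shift=0.01, peptide="OFFLSK",
                                   fraction="F2")
        pooled = pool_protein([base, shifted], n_boot=0, protocol=protocol)
        a, b = pooled.observations
        ref = a if np.nanmedian(a.i6) >= np.nanmedian(b.i6) else b
        other = b if ref is a else a
        assert np.nanmax(np.abs(ref.ria - other.ria)) <= 1e-9

    def test_empty_input_raises(self):
        with pytest.raises(FittingError):
            pool_protein([])


class TestJointFit:
    def test_noiseless_joint_recovery_stays_on_truth(self, protocol,
                                                     obs_times,
                                                     simplified_spec):
        rates = ARCHETYPES["faster_csf"]
        design = SyntheticDesign(outlier_rate=0.0, missing_rate=0.0,
                                 noise_precision={"plasma": 1e12,
                                                  "csf": 1e12},
                                 shifts={"plasma": 0.0, "csf": 0.0},
                                 obs_shift_sd=0.0)
        obs, _ = generate_protein(rates, design, seed=1)
        fit = fit_joint("three_bc_simplified", obs, protocol=protocol)
        # the sloppy directions are not identifiable, but the fit must
        # reproduce the curves: near-zero objective on noiseless data
        assert fit.weighted_sse < 1e-6
        assert fit.params["syn_plasma"] == pytest.approx(
            rates["syn_plasma"], rel=0.35)

    def test_requires_both_fluids(self, protocol, obs_times):
        obs = make_observation((0.01, 0.15), protocol, obs_times)
        with pytest.raises(FittingError):
            fit_joint("three_bc_simplified", [obs], protocol=protocol)
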