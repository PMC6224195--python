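"""Selection-model mechanics: frequency prediction, logit fits, CIs."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compfit import (
    AlleleTrajectory,
    FitConfig,
    UnfittableTrajectoryError,
    fit_relative_fitness,
    logit,
    predict_frequency,
    selection_coefficient,
)


def brute_force_frequency(p0, w, t):
    """Independent oracle: iterate the per-generation recurrence."""
    p = p0
    for _ in range(t):
        p = p * w / (p * w + (1 - p))
    return p


class TestPredictFrequency:
    @pytest.mark.parametrize("p0,w,t,expected", [
        (0.5, 1.0, 10, 0.5),            # neutral allele stays put
        (0.0, 1.3, 5, 0.0),             # absorbing boundary
        (1.0, 0.7, 5, 1.0),             # absorbing boundary
        (0.5, 1.3, 1, 1.3 / 2.3),       # single generation, direct ratio
        (0.5, 1.3, 7, 0.8625401532240169),  # frozen from the recurrence oracle
    ])
    def test_matches_closed_form(self, p0, w, t, expected):
        assert predict_frequency(p0, w, t) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p0,w,t", [
        (0.3, 1.25, 5), (0.9, 0.8, 12), (0.01, 2.0, 9),
    ])
    def test_agrees_with_recurrence_oracle(self, p0, w, t):
        assert predict_frequency(p0, w, t) == pytest.approx(
            brute_force_frequency(p0, w, t), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            predict_frequency(0.5, 0.0, 1)
        with pytest.raises(ValueError):
            predict_frequency(0.5, -1.3, 1)
        with pytest.raises(ValueError):
            predict_frequency(1.2, 1.3, 1)
        with pytest.raises(ValueError):
            predict_frequency(0.5, 1.3, -1)

    @settings(deadline=None, derandomize=True)
    @given(p0=st.floats(0.01, 0.99), w=st.floats(0.2, 5.0),
           t1=st.integers(0, 20), t2=st.integers(0, 20))
    def test_composition_semigroup(self, p0, w, t1, t2):
        """Running t1 then t2 generations equals running t1+t2 at once."""
        step = predict_frequency(predict_frequency(p0, w, t1), w, t2)
        direct = predict_frequency(p0, w, t1 + t2)
        assert step == pytest.approx(direct, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(p0=st.floats(0.05, 0.95), w=st.floats(1.01, 3.0),
           t=st.integers(1, 15))
    def test_monotone_in_t_under_positive_selection(self, p0, w, t):
        assert predict_frequency(p0, w, t) > predict_frequency(p0, w, t - 1)
        # deleterious mirror via 1/w
        assert predict_frequency(p0, 1 / w, t) < predict_frequency(p0, 1 / w, t - 1)


class TestLogit:
    @pytest.mark.parametrize("p,expected", [
        (0.5, 0.0),
        (0.75, math.log(3.0)),
        (0.25, -math.log(3.0)),
    ])
    def test_values(self, p, expected):
        assert logit(p) == pytest.approx(expected, abs=1e-12)

    def test_boundary_drop_gives_nonfinite(self):
        assert np.isinf(logit(1.0, "drop"))
        assert np.isinf(logit(0.0, "drop"))

    def test_boundary_clamp_is_finite(self):
        y = logit(1.0, "epsilon_clamp", epsilon=1e-6)
        assert np.isfinite(y)
        assert y == pytest.approx(math.log((1 - 1e-6) / 1e-6))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            logit(1.5)


class TestAlleleTrajectory:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            AlleleTrajectory("x", "r", (1, 1), (0.5, 0.6))  # not increasing
        with pytest.raises(ValueError):
            AlleleTrajectory("x", "r", (1, 3), (0.5,))  # length mismatch
        with pytest.raises(ValueError):
            AlleleTrajectory("x", "r", (1, 3), (0.5, 1.7))  # out of range


class TestFitRelativeFitness:
    def test_noiseless_inversion(self, noiseless_trajectories):
        est = fit_relative_fitness(noiseless_trajectories)
        assert abs(est.log_w_hat - math.log(1.3)) < 1e-10
        assert est.s_hat == pytest.approx(0.3, abs=1e-10)
        assert est.n_replicates == 3
        assert est.n_points_total == 12

    def test_neutral_gives_zero_s(self):
        gens = (1, 3, 5, 7)
        props = tuple(predict_frequency(0.5, 1.0, t) for t in gens)
        trajs = [AlleleTrajectory("n", f"r{i}", gens, props) for i in range(3)]
        est = fit_relative_fitness(trajs)
        assert est.s_hat == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_antisymmetry(self, noiseless_trajectories):
        """Swapping which strain is 'A' inverts the fitted fitness."""
        swapped = [
            AlleleTrajectory(t.pair_label, t.replicate_id, t.generations,
                             tuple(1 - p for p in t.proportions))
            for t in noiseless_trajectories
        ]
        est = fit_relative_fitness(noiseless_trajectories)
        est_sw = fit_relative_fitness(swapped)
        assert est_sw.log_w_hat == pytest.approx(-est.log_w_hat, abs=1e-9)

    def test_free_intercept_absorbs_founding_bias(self):
        """An unequal founding proportion shifts the intercept, not the slope."""
        gens = (1, 3, 5, 7)
        props = tuple(predict_frequency(0.37, 1.2, t) for t in gens)
        trajs = [AlleleTrajectory("b", "r1", gens, props),
                 AlleleTrajectory("b", "r2", gens, props)]
        est = fit_relative_fitness(trajs)
        assert est.w_hat == pytest.approx(1.2, abs=1e-10)

    def test_pooled_fixed_intercepts_matches_on_noiseless(
            self, noiseless_trajectories):
        est = fit_relative_fitness(
            noiseless_trajectories,
            FitConfig(method="pooled_fixed_intercepts"))
        assert est.w_hat == pytest.approx(1.3, abs=1e-9)
        assert est.ci_low <= est.s_hat <= est.ci_high

    def test_pooled_handles_unequal_intercepts(self):
        gens = (1, 3, 5, 7)
        trajs = [
            AlleleTrajectory("b", f"r{i}", gens,
                             tuple(predict_frequency(p0, 1.25, t) for t in gens))
            for i, p0 in enumerate([0.3, 0.5, 0.7])
        ]
        est = fit_relative_fitness(
            trajs, FitConfig(method="pooled_fixed_intercepts"))
        assert est.w_hat == pytest.approx(1.25, abs=1e-9)

    def test_ci_contains_estimate(self, noiseless_trajectories, rng):
        noisy = [
            AlleleTrajectory(t.pair_label, t.replicate_id, t.generations,
                             tuple(np.clip(p + rng.normal(0, 0.01), 0, 1)
                                   for p in t.proportions))
            for t in noiseless_trajectories
        ]
        est = fit_relative_fitness(noisy)
        assert est.ci_low <= est.s_hat <= est.ci_high

    def test_bootstrap_ci_is_seeded_and_ordered(self, noiseless_trajectories, rng):
        noisy = [
            AlleleTrajectory(t.pair_label, t.replicate_id, t.generations,
                             tuple(np.clip(p + rng.normal(0, 0.02), 0, 1)
                                   for p in t.proportions))
            for t in noiseless_trajectories
        ]
        cfg = FitConfig(ci_method="bootstrap", bootstrap_n=500, seed=42)
        est1 = fit_relative_fitness(noisy, cfg)
        est2 = fit_relative_fitness(noisy, cfg)
        assert (est1.ci_low, est1.ci_high) == (est2.ci_low, est2.ci_high)
        assert est1.ci_low <= est1.s_hat <= est1.ci_high

    def test_single_replicate_has_no_t_interval(self, noiseless_trajectories):
        with pytest.warns(UserWarning, match="single replicate"):
            est = fit_relative_fitness(noiseless_trajectories[:1])
        assert est.ci_low is None and est.ci_high is None
        assert est.w_hat == pytest.approx(1.3, abs=1e-10)

    def test_all_boundary_points_unfittable(self):
        trajs = [AlleleTrajectory("f", "r1", (1, 3, 5), (1.0, 1.0, 1.0))]
        with pytest.raises(UnfittableTrajectoryError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit_relative_fitness(trajs)

    def test_boundary_points_dropped_not_fatal(self):
        gens = (1, 3, 5, 7)
        props = tuple(predict_frequency(0.5, 1.3, t) for t in gens[:-1]) + (1.0,)
        trajs = [AlleleTrajectory("f", f"r{i}", gens, props) for i in range(2)]
        est = fit_relative_fitness(trajs)
        assert est.w_hat == pytest.approx(1.3, abs=1e-10)
        assert est.n_points_total == 6  # fixation points excluded

    def test_generations_per_transfer_rescales_slope(self, noiseless_trajectories):
        est = fit_relative_fitness(
            noiseless_trajectories, FitConfig(generations_per_transfer=2.0))
        # twice the generations per unit time halves the per-generation log w
        assert est.log_w_hat == pytest.approx(math.log(1.3) / 2, abs=1e-10)


class TestSelectionCoefficient:
    @pytest.mark.parametrize("w,s", [(1.0, 0.0), (1.30, 0.30), (0.5, -0.5)])
    def test_identity(self, w, s):
        assert selection_coefficient(w) == pytest.approx(s)

    def test_domain(self):
        with pytest.raises(ValueError):
            selection_coefficient(0.0)


class TestFitConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"boundary_policy": "clip"},
        {"epsilon": 0.5},
        {"bootstrap_n": 10},
        {"ci_method": "wald"},
        {"method": "bayes"},
        {"generations_per_transfer": 0},
    ])
    def test_rejects_bad_values(self, kwargs):
        with pytest.raises(ValueError):
            FitConfig(**kwargs)
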