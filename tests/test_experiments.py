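import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chisquare

from condesign import (
    CueSet,
    DesignSpace,
    PeriodicDesign,
    Stage,
    StageWiseDesign,
    sample_realization,
    unroll_schedule,
    validate_design,
)
from condesign.experiments import InvalidDesignError


class TestValidation:
    def test_backward_blocking_reference_passes(self, backward_blocking_design):
        report = validate_design(backward_blocking_design)
        assert report.ok and report.violations == ()

    def test_simplex_violation_reported(self, ab_cue_set):
        design = StageWiseDesign(
            CueSet(("A", "B")),
            (Stage(10, {"A": 0.7, "B": 0.7}, {"A": 0.5, "B": 0.5}),),
        )
        report = validate_design(design)
        assert not report.ok
        assert any("sum" in v for v in report.violations)

    def test_bounds_violation_reported(self):
        design = StageWiseDesign(
            CueSet(("A",)), (Stage(10, {"A": 1.0}, {"A": -0.1}),)
        )
        report = validate_design(design)
        assert not report.ok
        assert any("[0, 1]" in v for v in report.violations)

    def test_zero_trial_stage_rejected(self):
        design = StageWiseDesign(
            CueSet(("A",)), (Stage(0, {"A": 1.0}, {"A": 0.5}),)
        )
        assert not validate_design(design).ok
        with pytest.raises(InvalidDesignError):
            unroll_schedule(design)


class TestUnroll:
    def test_acquisition_extinction_split(self, single_cue_set):
        design = PeriodicDesign(single_cue_set, 160, {"CS": (1.0, 1.0)},
                                {"CS": (0.5, 0.0)}, 0.5)
        sched = unroll_schedule(design)
        assert np.all(sched.outcome_probs[:80, 0] == 0.5)
        assert np.all(sched.outcome_probs[80:, 0] == 0.0)

    def test_full_period_is_constant(self, single_cue_set):
        design = PeriodicDesign(single_cue_set, 64, {"CS": (1.0, 1.0)},
                                {"CS": (0.3, 0.9)}, 1.0)
        sched = unroll_schedule(design)
        assert np.all(sched.outcome_probs[:, 0] == 0.3)

    def test_quarter_period_switch_points(self, single_cue_set):
        design = PeriodicDesign(single_cue_set, 100, {"CS": (1.0, 1.0)},
                                {"CS": (0.8, 0.2)}, 0.25)
        sched = unroll_schedule(design)
        probs = sched.outcome_probs[:, 0]
        switches = np.nonzero(np.diff(probs))[0] + 1
        assert list(switches) == [25, 50, 75]

    def test_stagewise_matches_periodic_half_period(self, single_cue_set):
        stagewise = StageWiseDesign(
            single_cue_set,
            (Stage(30, {"CS": 1.0}, {"CS": 0.6}),
             Stage(30, {"CS": 1.0}, {"CS": 0.2})),
        )
        periodic = PeriodicDesign(single_cue_set, 60, {"CS": (1.0, 1.0)},
                                  {"CS": (0.6, 0.2)}, 0.5)
        a, b = unroll_schedule(stagewise), unroll_schedule(periodic)
        np.testing.assert_array_equal(a.cue_probs, b.cue_probs)
        np.testing.assert_array_equal(a.outcome_probs, b.outcome_probs)


class TestSampling:
    def test_certain_reinforcement(self, single_cue_set):
        design = StageWiseDesign(single_cue_set,
                                 (Stage(10, {"CS": 1.0}, {"CS": 1.0}),))
        real = sample_realization(unroll_schedule(design), seed=3)
        assert np.all(real.outcomes == 1)

    def test_empirical_reinforcement_rate(self, single_cue_set):
        design = StageWiseDesign(single_cue_set,
                                 (Stage(10_000, {"CS": 1.0}, {"CS": 0.5}),))
        real = sample_realization(unroll_schedule(design), seed=11)
        assert abs(real.outcomes.mean() - 0.5) < 0.015  # 3-sigma binomial band

    def test_seed_determinism(self, backward_blocking_design):
        sched = unroll_schedule(backward_blocking_design)
        a = sample_realization(sched, seed=42)
        b = sample_realization(sched, seed=42)
        np.testing.assert_array_equal(a.stimulus_idx, b.stimulus_idx)
        np.testing.assert_array_equal(a.outcomes, b.outcomes)

    def test_cue_frequencies_match_probabilities(self):
        """Chi-square goodness of fit on sampled cue frequencies: at alpha=.01
        over 20 seeds at most ~1 rejection is expected; allow 2."""
        cue_set = CueSet(("A", "B", "C"))
        probs = {"A": 0.5, "B": 0.3, "C": 0.2}
        design = StageWiseDesign(cue_set, (Stage(10_000, probs,
                                                 dict.fromkeys(probs, 0.5)),))
        sched = unroll_schedule(design)
        expected = np.array([0.5, 0.3, 0.2]) * 10_000
        rejections = 0
        for seed in range(20):
            real = sample_realization(sched, seed=seed)
            counts = np.bincount(real.stimulus_idx, minlength=3)
            _, p = chisquare(counts, expected)
            rejections += p < 0.01
        assert rejections <= 2


class TestDesignSpace:
    def test_scenario_dimensionalities(self, ab_cue_set):
        two_stage_compound = DesignSpace("stage_wise", ab_cue_set,
                                         trials_per_stage=(25, 25))
        assert two_stage_compound.dim == 10
        two_stage_elemental = DesignSpace("stage_wise", CueSet(("A", "B")),
                                          trials_per_stage=(60, 60))
        assert two_stage_elemental.dim == 6
        periodic_single = DesignSpace("periodic", CueSet(("CS",)), n_trials=160)
        assert periodic_single.dim == 3

    def test_out_of_bounds_vector_rejected(self, ab_cue_set):
        space = DesignSpace("stage_wise", ab_cue_set, trials_per_stage=(10, 10))
        v = np.full(space.dim, 0.5)
        v[0] = 1.2
        with pytest.raises(ValueError):
            space.from_vector(v)

    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        space = DesignSpace("stage_wise", CueSet(("A", "B"), (("A", "B"),)),
                            trials_per_stage=(25, 25))
        v = rng.uniform(0.01, 0.99, space.dim)
        np.testing.assert_allclose(space.to_vector(space.from_vector(v)), v,
                                   atol=1e-12)

    def test_periodic_round_trip(self, single_cue_set):
        space = DesignSpace("periodic", single_cue_set, n_trials=160)
        rng = np.random.default_rng(7)
        v = rng.uniform(0.05, 0.95, space.dim)
        np.testing.assert_allclose(space.to_vector(space.from_vector(v)), v,
                                   atol=1e-12)

    def test_from_vector_always_valid(self, ab_cue_set):
        """Stick-breaking decoding covers exactly the feasible set: fuzz over
        1,000 random box points, every decoded design validates."""
        rng = np.random.default_rng(123)
        spaces = [
            DesignSpace("stage_wise", ab_cue_set, trials_per_stage=(25, 25)),
            DesignSpace("periodic", CueSet(("CS",)), n_trials=100),
        ]
        for space in spaces:
            for _ in range(500):
                design = space.from_vector(rng.random(space.dim))
                assert validate_design(design).ok
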