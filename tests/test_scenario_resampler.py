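"""Resampling composition, permutations, subsampling, bootstrap bookkeeping."""

import numpy as np
import pytest

from fpdiag.errors import ResamplingError, ValidationError
from fpdiag.rt_data import TemporalPart, Trial, TrialTable
from fpdiag.scenario_resampler import (
    ScenarioSpec,
    bootstrap_polarity,
    build_negative,
    build_positive,
    enumerate_permutations,
    run_bootstrap,
    subsample,
)


class TestScenarioSpec:
    def test_defaults_follow_the_design(self):
        assert ScenarioSpec().effective_n_boot == 1000
        assert ScenarioSpec(scenario="sample_size").effective_n_boot == 10_000
        assert ScenarioSpec(n_boot=7).effective_n_boot == 7

    @pytest.mark.parametrize("bad", [dict(mixture_proportion=45.0), dict(mixture_proportion=101.0), dict(n_trials=1), dict(scenario="bogus")])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValidationError):
            ScenarioSpec(**bad)


class TestBuildPositive:
    @pytest.mark.parametrize(
        "p, exp_a, exp_c",
        [(100.0, (40, 0), (0, 40)), (60.0, (24, 16), (16, 24)), (50.0, (20, 20), (20, 20))],
    )
    def test_mixture_composition(self, small_table, rng, p, exp_a, exp_c):
        spec = ScenarioSpec(mixture_proportion=p, n_trials=40, seed=0)
        ds = build_positive(small_table, spec, rng)
        for pid in ds.participants:
            comp_a = ds.composition(pid, "A")
            comp_b = ds.composition(pid, "B")
            comp_c = ds.composition(pid, "C")
            assert (comp_a["CA"], comp_a["PR"]) == exp_a
            assert (comp_b["CA"], comp_b["PR"]) == (20, 20)
            assert (comp_c["CA"], comp_c["PR"]) == exp_c
            # reciprocity: C's CA count equals A's PR count
            assert comp_c["CA"] == comp_a["PR"]

    def test_every_condition_has_n_trials(self, small_table, rng):
        ds = build_positive(small_table, ScenarioSpec(n_trials=17, seed=0), rng)
        assert all(ds.rts(p, c).size == 17 for p in ds.participants for c in "ABC")

    def test_time_on_task_draws_respect_assigned_thirds(self, small_table, rng):
        perm = enumerate_permutations()[3]
        spec = ScenarioSpec(scenario="time_on_task", permutation=perm, n_trials=10, seed=0)
        ds = build_positive(small_table, spec, rng)
        from fpdiag.rt_data import split_into_parts

        for pid in ds.participants:
            parts = split_into_parts(small_table, pid)
            for cond in "ABC":
                pool = {t.rt_ms for t in parts[perm[cond]]}
                assert set(ds.rts(pid, cond)) <= pool


class TestBuildNegative:
    def test_half_half_from_each_third(self, small_table, rng):
        spec = ScenarioSpec(n_trials=12, seed=0)
        ds = build_negative(small_table, spec, rng)
        from fpdiag.rt_data import split_into_parts

        order = [TemporalPart.BEGINNING, TemporalPart.MIDDLE, TemporalPart.END]
        for pid in ds.participants:
            parts = split_into_parts(small_table, pid)
            for cond, part in zip("ABC", order):
                comp = ds.composition(pid, cond)
                assert comp == {"CA": 6, "PR": 6}
                assert set(ds.rts(pid, cond)) <= {t.rt_ms for t in parts[part]}

    def test_missing_pool_is_named(self, rng):
        # one participant whose middle third has no PR trials
        trials = []
        for i in range(30):
            cond = "CA" if 10 <= i < 20 else ("CA" if i % 2 else "PR")
            trials.append(Trial("s1", cond, i // 5 + 1, i + 1, 1000.0 + i))
        table = TrialTable(trials=trials)
        with pytest.raises(ResamplingError, match="middle"):
            build_negative(table, ScenarioSpec(n_trials=10, seed=0), rng)

    def test_same_seed_same_dataset(self, small_table):
        spec = ScenarioSpec(n_trials=20, seed=5)
        d1 = build_negative(small_table, spec, np.random.default_rng(3))
        d2 = build_negative(small_table, spec, np.random.default_rng(3))
        for pid in d1.participants:
            for c in "ABC":
                np.testing.assert_array_equal(d1.rts(pid, c), d2.rts(pid, c))


class TestEnumeratePermutations:
    def test_six_distinct_bijections_with_identity_first(self):
        perms = enumerate_permutations()
        assert len(perms) == 6
        assert perms[0] == {
            "A": TemporalPart.BEGINNING,
            "B": TemporalPart.MIDDLE,
            "C": TemporalPart.END,
        }
        seen = {tuple(sorted((k, v.value) for k, v in p.items())) for p in perms}
        assert len(seen) == 6
        for p in perms:
            assert set(p.values()) == set(TemporalPart)


class TestSubsample:
    def test_all_and_partial_and_overflow(self, small_table, rng):
        assert len(subsample(small_table, 6, rng).participants) == 6
        sub = subsample(small_table, 3, rng)
        assert len(sub.participants) == 3
        assert set(sub.participants) <= set(small_table.participants)
        with pytest.raises(ValidationError):
            subsample(small_table, 7, rng)


class TestRunBootstrap:
    def test_bookkeeping_and_determinism(self, small_table):
        spec = ScenarioSpec(n_trials=20, seed=11)
        outs = run_bootstrap(small_table, spec, n_boot=4)
        assert len(outs) == 8
        assert [o.replicate for o in outs] == [1, 1, 2, 2, 3, 3, 4, 4]
        assert {o.polarity for o in outs} == {"positive", "negative"}
        outs2 = run_bootstrap(small_table, spec, n_boot=4)
        for a, b in zip(outs, outs2):
            assert a.pairwise_log_bf10 == b.pairwise_log_bf10
            assert a.fixed_point_log_bf == b.fixed_point_log_bf

    def test_polarity_split_matches_paired_run(self, small_table):
        spec = ScenarioSpec(n_trials=20, seed=11)
        paired = run_bootstrap(small_table, spec, n_boot=3)
        pos = bootstrap_polarity(small_table, spec, "positive", n_boot=3)
        neg = bootstrap_polarity(small_table, spec, "negative", n_boot=3)
        assert [o.fixed_point_log_bf for o in paired if o.polarity == "positive"] == [
            o.fixed_point_log_bf for o in pos
        ]
        assert [o.fixed_point_log_bf for o in paired if o.polarity == "negative"] == [
            o.fixed_point_log_bf for o in neg
        ]

    def test_failures_recorded_not_dropped(self):
        # a base table too small to resample 40 trials without replacement
        trials = [
            Trial("s1", "CA" if i % 2 else "PR", i // 4 + 1, i + 1, 1000.0 + i) for i in range(12)
        ]
        # three participants so the pipeline would otherwise run
        all_trials = []
        for pid in ("s1", "s2", "s3"):
            all_trials += [
                Trial(pid, t.condition, t.block_index, t.trial_index, t.rt_ms) for t in trials
            ]
        table = TrialTable(trials=all_trials)
        spec = ScenarioSpec(n_trials=40, seed=0, with_replacement=False)
        outs = run_bootstrap(table, spec, n_boot=2)
        assert len(outs) == 4
        assert all(o.error is not None for o in outs)
        assert all(o.pairwise_log_bf10 is None for o in outs)

    def test_screen_passes_uses_strict_inequality(self, small_table):
        spec = ScenarioSpec(n_trials=20, seed=1)
        out = run_bootstrap(small_table, spec, n_boot=1)[0]
        assert out.screen_passes(0.0)
        assert not out.screen_passes(float(np.exp(max(out.pairwise_log_bf10))))
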