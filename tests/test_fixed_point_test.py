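"""The four-step test: screening, crossings, and the sequential decision."""

import numpy as np
import pytest

from fpdiag.errors import ValidationError
from fpdiag.fixed_point_test import compute_crossings, condition_screen, run_fixed_point_test
from fpdiag.scenario_resampler import ResampledDataset, ScenarioSpec, build_negative, build_positive


def _mixture_dataset(n_participants=8, n_trials=200, separation=800.0, polarity="positive", seed=0):
    """Hand-built dataset: conditions are lognormal mixtures (positive) or
    per-condition shifted copies of one base (negative)."""
    rng = np.random.default_rng(seed)
    data, sources = {}, {}
    for i in range(n_participants):
        mu_a = 1200.0 + rng.normal(0, 60)
        mu_b = mu_a + separation
        draws = {}
        for cond, p_mix in (("A", 1.0), ("B", 0.5), ("C", 0.0)):
            if polarity == "positive":
                take_a = rng.random(n_trials) < p_mix
                x = np.where(
                    take_a,
                    mu_a * np.exp(rng.normal(0, 0.25, n_trials)),
                    mu_b * np.exp(rng.normal(0, 0.25, n_trials)),
                )
            else:  # base shift, no mixture change
                shift = {"A": 0.0, "B": separation / 2, "C": separation}[cond]
                x = (mu_a + shift) * np.exp(rng.normal(0, 0.25, n_trials))
            draws[cond] = x
        data[f"s{i}"] = draws
        sources[f"s{i}"] = {c: np.array(["CA"] * n_trials) for c in "ABC"}
    return ResampledDataset(polarity=polarity, data=data, sources=sources, spec=ScenarioSpec())


class TestConditionScreen:
    def test_zero_criterion_always_passes(self):
        ds = _mixture_dataset(separation=5.0)  # nearly identical conditions
        _, passed = condition_screen(ds, 0.0)
        assert passed

    def test_separated_conditions_pass_stringent_criterion(self):
        ds = _mixture_dataset(n_participants=20, separation=800.0)
        bfs, passed = condition_screen(ds, 64.0)
        assert passed
        assert all(b.log_bf10 > np.log(64) for b in bfs)

    def test_identical_b_and_c_fail(self, rng):
        ds = _mixture_dataset(n_participants=20, separation=800.0)
        for pid in ds.participants:  # make C a fresh draw from B's law
            ds.data[pid]["C"] = ds.data[pid]["B"] * np.exp(rng.normal(0, 0.001, ds.data[pid]["B"].size))
        bfs, passed = condition_screen(ds, 1.0)
        bc = [b for b in bfs if b.pair == ("B", "C")][0]
        assert bc.bf10 < 1.0
        assert not passed


class TestComputeCrossings:
    def test_three_crossings_per_participant(self):
        ds = _mixture_dataset(n_participants=6)
        table, excluded = compute_crossings(ds)
        assert excluded == ()
        assert len(table) == 6
        for triple in table.values():
            assert [c.pair for c in triple] == [("A", "B"), ("B", "C"), ("A", "C")]

    def test_mixture_crossings_near_component_intersection(self):
        """With pure-mixture conditions the estimated crossings concentrate
        near the intersection of the two base densities."""
        ds = _mixture_dataset(n_participants=10, n_trials=1000, seed=3)
        table, _ = compute_crossings(ds)
        # base densities: lognormal(log mu_a, .25) vs lognormal(log mu_b, .25)
        # per participant; the crossing of the two base pdfs:
        import scipy.stats as st

        errs, hs = [], []
        rng = np.random.default_rng(3)
        for pid, triple in table.items():
            mu_a = 1200.0 + rng.normal(0, 60)  # same stream as the builder
            mu_b = mu_a + 800.0
            f_a = st.lognorm(s=0.25, scale=mu_a)
            f_b = st.lognorm(s=0.25, scale=mu_b)
            xs = np.linspace(mu_a * 0.5, mu_b * 1.5, 20000)
            diff = f_a.pdf(xs) - f_b.pdf(xs)
            sgn = np.sign(diff)
            i = np.flatnonzero(sgn[:-1] * sgn[1:] < 0)[0]
            truth = xs[i]
            errs.extend(abs(c.rt_ms - truth) for c in triple)
        assert np.median(errs) < 100.0  # ≈ a quarter of the typical bandwidth

    def test_non_crossing_participant_excluded(self):
        ds = _mixture_dataset(n_participants=4)
        pid = ds.participants[0]
        # move one condition far outside the shared grid's mass so the pair
        # densities never intersect at a usable height... instead make the
        # densities disjoint enough that A-B crossing exists but force an
        # exact degenerate equality for one pair:
        ds.data[pid]["A"] = ds.data[pid]["B"].copy()  # identical samples -> zero difference
        table, excluded = compute_crossings(ds)
        assert pid in excluded
        assert pid not in table
        assert len(table) == 3


class TestRunFixedPointTest:
    def test_failed_screen_short_circuits(self):
        ds = _mixture_dataset(n_participants=6, separation=2.0)  # no condition effect
        res = run_fixed_point_test(ds, condition_criterion=64.0, fixed_point_criterion=3.0)
        assert not res.passed_condition_screen
        assert not res.detected
        assert res.fixed_point_bf is None
        assert res.crossings is None

    def test_positive_control_detected(self):
        ds = _mixture_dataset(n_participants=16, n_trials=100, seed=0)
        res = run_fixed_point_test(ds, 1.0, 3.0)
        assert res.passed_condition_screen
        assert res.detected
        assert res.fixed_point_bf.bf_present > 3.0

    def test_negative_control_rejected(self):
        ds = _mixture_dataset(n_participants=16, n_trials=400, polarity="negative", seed=5)
        res = run_fixed_point_test(ds, 1.0, 3.0)
        assert res.passed_condition_screen  # conditions do differ
        assert res.fixed_point_bf.bf_present < 1.0  # strong evidence against
        assert not res.detected

    def test_participant_order_irrelevant(self):
        ds = _mixture_dataset(n_participants=6, seed=9)
        res1 = run_fixed_point_test(ds, 1.0, 3.0)
        ds2 = ResampledDataset(
            polarity=ds.polarity,
            data=dict(reversed(list(ds.data.items()))),
            sources=dict(reversed(list(ds.sources.items()))),
            spec=ds.spec,
        )
        res2 = run_fixed_point_test(ds2, 1.0, 3.0)
        assert res1.fixed_point_bf.log_bf_present == pytest.approx(
            res2.fixed_point_bf.log_bf_present, abs=1e-9
        )

    def test_report_dict_is_serialisable(self):
        import json

        ds = _mixture_dataset(n_participants=6)
        res = run_fixed_point_test(ds, 1.0, 3.0)
        blob = json.dumps(res.to_dict())
        assert "pairwise_bf10" in blob

    def test_detection_monotone_in_criteria(self):
        """Raising either criterion can only turn detections off."""
        ds = _mixture_dataset(n_participants=10, seed=2)
        res = run_fixed_point_test(ds, 1.0, 1.0, force_steps=True)
        fp = res.fixed_point_bf.bf_present
        detections = []
        for cc, fpc in [(0.0, 0.0), (1.0, 1.0), (1.0, fp + 1), (1e300, 0.0)]:
            r = run_fixed_point_test(ds, cc, fpc, force_steps=True)
            detections.append(r.detected)
        assert detections[0]  # both criteria at zero always detect when screened
        assert not detections[2]  # fpc above the realised BF
        assert not detections[3]  # unattainable condition criterion


class TestRealDataPipeline:
    def test_resampled_synthetic_experiment_runs_cleanly(self, small_table, rng):
        spec = ScenarioSpec(n_trials=30, seed=1)
        pos = build_positive(small_table, spec, rng)
        neg = build_negative(small_table, spec, rng)
        for ds in (pos, neg):
            res = run_fixed_point_test(ds, 0.0, 3.0)
            assert res.fixed_point_bf is not None
            assert len(res.crossings) + len(res.excluded) == 6
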