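"""Generator contracts: session layout, SCR kernel shape, trace and
rating synthesis, ground-truth bookkeeping."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

import edaflow as ef
from edaflow.errors import ConfigurationError, ResourceError
from edaflow.synth import scr_kernel_peak_time


class TestLayout:
    def test_exp1_defaults_give_two_baselines_and_70_thirty_second_trials(
        self, exp1_design
    ):
        layout = ef.build_layout(exp1_design)
        assert len(layout.baselines()) == 2
        trials = layout.trials()
        assert len(trials) == 70
        assert all(iv.duration == 30.0 for iv in trials)
        assert all(iv.run in (1, 2) for iv in trials)
        assert sorted(iv.excerpt_id for iv in trials) == list(range(70))

    def test_exp2_run2_repeats_run1_in_different_order(self, exp2_design):
        layout = ef.build_layout(exp2_design, rng=np.random.default_rng(5))
        run1 = [iv.excerpt_id for iv in layout.trials() if iv.run == 1]
        run2 = [iv.excerpt_id for iv in layout.trials() if iv.run == 2]
        assert sorted(run1) == sorted(run2)
        assert run1 != run2
        assert all(iv.exposure == 2 for iv in layout.trials() if iv.run == 2)

    def test_intervals_are_ordered_and_disjoint(self, exp2_design):
        layout = ef.build_layout(exp2_design)
        bounds = [(iv.start, iv.end) for iv in layout.intervals]
        for (s0, e0), (s1, e1) in zip(bounds, bounds[1:]):
            assert e0 <= s1

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ConfigurationError, match="trials_per_run"):
            ef.build_layout(ef.DesignSpec(trials_per_run=0))
        with pytest.raises(ConfigurationError, match="n_runs"):
            ef.DesignSpec(experiment="exp2", n_runs=3).validate()


class TestKernel:
    def test_zero_at_onset_and_for_negative_time(self):
        assert ef.scr_kernel(0.0, 0.75, 2.0) == 0.0
        assert ef.scr_kernel(-1.0, 0.75, 2.0) == 0.0

    def test_peak_location_matches_closed_form(self):
        rise, decay = 0.75, 2.0
        t = np.linspace(0, 20, 200001)
        values = ef.scr_kernel(t, rise, decay)
        t_num = t[np.argmax(values)]
        t_closed = decay * rise / (decay - rise) * math.log(decay / rise)
        assert t_num == pytest.approx(t_closed, abs=1e-3)
        assert scr_kernel_peak_time(rise, decay) == pytest.approx(t_closed)

    def test_unit_peak_normalization(self):
        t = np.linspace(0, 20, 200001)
        assert np.max(ef.scr_kernel(t, 0.75, 2.0)) == pytest.approx(1.0, abs=1e-9)

    def test_rise_not_less_than_decay_rejected(self):
        with pytest.raises(ConfigurationError):
            ef.scr_kernel(1.0, 2.0, 2.0)


class TestTrace:
    def test_all_stochastic_terms_off_gives_tonic_plus_exposure_step(
        self, exp2_design
    ):
        config = ef.SimConfig(
            sampling_rate=32.0,
            noise_sd=0.0,
            scr_rate_base=0.0,
            drift_slope_per_run=(0.0, 0.0),
            exposure_scl_delta=0.25,
            exposure_rate_delta=0.0,
        )
        layout = ef.build_layout(exp2_design)
        trace, gt = ef.simulate_trace(config, layout)
        times = trace.times()
        in_exp2 = np.zeros(trace.n_samples, dtype=bool)
        for iv in layout.trials():
            if iv.exposure == 2:
                in_exp2 |= (times >= iv.start) & (times < iv.end)
        assert np.allclose(trace.samples[~in_exp2], 10.0)
        assert np.allclose(trace.samples[in_exp2], 10.25)
        assert np.allclose(gt.trials.query("exposure == 2").tonic_mean, 10.25)

    def test_same_seed_gives_identical_traces(self, scaled_config, exp1_design):
        layout = ef.build_layout(exp1_design)
        t1, _ = ef.simulate_trace(scaled_config, layout)
        t2, _ = ef.simulate_trace(scaled_config, layout)
        assert np.array_equal(t1.samples, t2.samples)

    def test_event_count_within_three_sd_of_poisson_mean(self, exp1_design):
        # 6 events/min over 35 x 30-s trials (one run): mean 105 events.
        config = ef.SimConfig(sampling_rate=32.0, scr_rate_base=6.0, seed=2)
        layout = ef.build_layout(exp1_design)
        _, gt = ef.simulate_trace(config, layout)
        n_trial_events = int(gt.trials.query("run == 1").n_events.sum())
        assert abs(n_trial_events - 105) <= 3 * math.sqrt(105)

    def test_trial_event_counts_are_poisson(self, exp1_design):
        """Chi-square goodness of fit over 2000 trials at alpha = 0.01."""
        config = ef.SimConfig(sampling_rate=32.0, scr_rate_base=6.0)
        layout = ef.build_layout(exp1_design)
        counts = []
        for s in range(29):  # 29 x 70 = 2030 trials
            rng = np.random.default_rng(900 + s)
            _, gt = ef.simulate_trace(config, layout, rng=rng)
            counts.extend(gt.trials.n_events.tolist())
        counts = np.asarray(counts)
        mean = 6.0 * 30 / 60
        edges = np.arange(0, 8)
        observed = np.array(
            [np.sum(counts == e) for e in edges[:-1]] + [np.sum(counts >= edges[-1])]
        )
        expected = np.array(
            [sst.poisson.pmf(e, mean) for e in edges[:-1]]
            + [sst.poisson.sf(edges[-1] - 1, mean)]
        ) * len(counts)
        stat = float(np.sum((observed - expected) ** 2 / expected))
        p = float(sst.chi2.sf(stat, len(observed) - 1))
        assert p > 0.01

    def test_ground_truth_events_reconstruct_the_trace(self, exp1_design):
        """Subtracting rendered kernels at ground-truth times/amplitudes
        leaves only tonic + noise."""
        config = ef.SimConfig(sampling_rate=32.0, noise_sd=0.01, seed=5)
        layout = ef.build_layout(exp1_design)
        trace, gt = ef.simulate_trace(config, layout)
        times = trace.times()
        phasic = np.zeros_like(times)
        for t_ev, amp in zip(gt.event_times, gt.event_amplitudes):
            tt = times - t_ev
            phasic += amp * np.where(
                tt >= 0, ef.scr_kernel(np.maximum(tt, 0), 0.75, 2.0), 0.0
            )
        residual = trace.samples - phasic
        tonic_bounds = (10.0 + config.drift_slope_per_run[1] * 30, 10.0)
        # residual must stay within the drifting-tonic envelope + noise slack
        assert np.all(residual > tonic_bounds[0] - 5 * config.noise_sd - 5e-4)
        assert np.all(residual < tonic_bounds[1] + 5 * config.noise_sd + 5e-4)

    def test_span_exceeding_max_duration_raises(self, exp1_design):
        config = ef.SimConfig(sampling_rate=32.0, max_duration_s=100.0)
        layout = ef.build_layout(exp1_design)
        with pytest.raises(ResourceError):
            ef.simulate_trace(config, layout)


class TestRatings:
    def test_no_noise_no_slope_gives_constant_pleasure(self, exp1_design):
        config = ef.SimConfig(
            rating_noise_sd=0.0,
            familiarity_pleasure_slope=0.0,
            familiarity_arousal_slope=0.0,
            base_pleasure=2.0,
        )
        layout = ef.build_layout(exp1_design)
        ratings = ef.simulate_ratings(config, layout)
        assert (ratings.pleasure == 2).all()

    def test_pleasure_increases_across_familiarity_bins(self, exp1_design):
        config = ef.SimConfig(familiarity_pleasure_slope=2.0, seed=3)
        layout = ef.build_layout(exp1_design)
        frames = [
            ef.simulate_ratings(config, layout, rng=np.random.default_rng(100 + i))
            for i in range(15)  # ~1000 trials
        ]
        ratings = pd.concat(frames)
        bins = ratings.familiarity.map(ef.bin_familiarity)
        means = ratings.groupby(bins).pleasure.mean()
        ordered = [means[lbl] for lbl in
                   ("Unfamiliar", "Somewhat Familiar", "Very Familiar")]
        assert ordered[0] < ordered[1] < ordered[2]

    def test_clipping_keeps_ratings_on_scale(self, exp1_design):
        config = ef.SimConfig(base_pleasure=5.0, rating_noise_sd=3.0, seed=1)
        layout = ef.build_layout(exp1_design)
        ratings = ef.simulate_ratings(config, layout)
        assert ratings.pleasure.max() <= 5
        assert ratings.pleasure.min() >= -5
        assert ratings.arousal.between(0, 10).all()
        assert ratings.familiarity.between(0, 10).all()


class TestExperiment:
    def test_exp1_shape_and_counterbalancing(self, scaled_config, exp1_design):
        datasets = ef.simulate_experiment(scaled_config, exp1_design, 3)
        assert len(datasets) == 3
        for ds in datasets:
            assert len(ds.ratings) == 70
        orders = [
            [iv.excerpt_id for iv in ds.layout.trials()] for ds in datasets
        ]
        assert orders[0] != orders[1] != orders[2]

    def test_exp2_repeats_run1(self, scaled_config, exp2_design):
        datasets = ef.simulate_experiment(scaled_config, exp2_design, 2)
        for ds in datasets:
            counts = ds.ratings.excerpt.value_counts()
            assert (counts == 2).all()

    def test_master_seed_fixes_the_dataset_list(self, scaled_config, exp2_design):
        a = ef.simulate_experiment(scaled_config, exp2_design, 2)
        b = ef.simulate_experiment(scaled_config, exp2_design, 2)
        for da, db in zip(a, b):
            assert np.array_equal(da.trace.samples, db.trace.samples)
            assert da.ratings.equals(db.ratings)

    def test_zero_subjects_rejected(self, scaled_config, exp1_design):
        with pytest.raises(ConfigurationError):
            ef.simulate_experiment(scaled_config, exp1_design, 0)

    def test_exposure_delta_recovered_in_ground_truth(self, exp2_design):
        """Exposure-2 minus exposure-1 tonic means average to the injected
        delta within Monte-Carlo error."""
        config = ef.SimConfig(
            sampling_rate=32.0, exposure_scl_delta=0.2, seed=11
        )
        diffs = []
        for ds in ef.simulate_experiment(config, exp2_design, 12):
            g = ds.ground_truth.trials.groupby("exposure").tonic_mean.mean()
            diffs.append(g[2] - g[1])
        # drift contributes a run-2 offset; compare against the no-delta case
        null_config = dataclasses.replace(config, exposure_scl_delta=0.0)
        null_diffs = []
        for ds in ef.simulate_experiment(null_config, exp2_design, 12):
            g = ds.ground_truth.trials.groupby("exposure").tonic_mean.mean()
            null_diffs.append(g[2] - g[1])
        recovered = np.mean(diffs) - np.mean(null_diffs)
        assert recovered == pytest.approx(0.2, abs=0.02)
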