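"""Neural analyses: spike density, classification, normalization,
correlations, tertiles and condition splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from scsaliency.analysis import (NeuronData, NeuronRecord, assign_tertiles,
                                 behavioural_saliency, classify_neuron,
                                 feature_dependence, goal_split_analysis,
                                 normalize_rate, per_neuron_correlation,
                                 spike_density, tertile_curves)


class TestSpikeDensity:
    def test_no_spikes_zero(self):
        _, rate = spike_density([], 1000.0)
        assert np.allclose(rate, 0.0)

    def test_single_spike_kernel_shape(self):
        t, rate = spike_density([100.0], 1000.0, kernel="epsp")
        assert rate[:100].max() == 0.0          # causal
        peak = t[np.argmax(rate)]
        assert 100.0 < peak < 140.0             # rises over ~5 ms, decays ~20 ms
        # unit kernel mass: integral equals spike count
        assert np.trapezoid(rate, t / 1000.0) == pytest.approx(1.0, rel=0.02)

    def test_superposition_of_far_spikes(self):
        _, r1 = spike_density([200.0], 2000.0)
        _, r2 = spike_density([200.0, 1500.0], 2000.0)
        assert r2.max() == pytest.approx(r1.max())
        assert np.trapezoid(r2, dx=1e-3) == pytest.approx(2.0, rel=0.02)

    def test_gauss_variant_5ms_bins(self):
        t, rate = spike_density([500.0] * 10, 2000.0, kernel="gauss")
        assert t[1] - t[0] == 5.0
        assert np.argmax(rate) == pytest.approx(100, abs=1)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            spike_density([-5.0], 100.0)


class TestClassification:
    def _trials(self, rng, base_hz, extra_hz, window, n=30, span=(-200.0, 300.0)):
        out = []
        for _ in range(n):
            t0, t1 = span
            base = rng.uniform(t0, t1, rng.poisson(base_hz * (t1 - t0) / 1000.0))
            ex = rng.uniform(*window, rng.poisson(extra_hz * (window[1] - window[0]) / 1000.0))
            out.append(np.sort(np.concatenate([base, ex])))
        return out

    def test_visual_only_is_scs(self, rng):
        stim = self._trials(rng, 10.0, 60.0, (40.0, 120.0))
        sacc = self._trials(rng, 10.0, 0.0, (-25.0, 25.0))
        v, m, layer = classify_neuron(stim, sacc)
        assert v and not m and layer == "SCs"

    def test_visuomotor_is_sci(self, rng):
        stim = self._trials(rng, 10.0, 60.0, (40.0, 120.0))
        sacc = self._trials(rng, 10.0, 80.0, (-25.0, 25.0))
        v, m, layer = classify_neuron(stim, sacc)
        assert v and m and layer == "SCi"

    def test_flat_neuron_excluded(self, rng):
        stim = self._trials(rng, 10.0, 0.0, (40.0, 120.0))
        v, _, layer = classify_neuron(stim, stim)
        assert v is False and layer is None

    def test_too_few_trials_unclassified(self, rng):
        stim = self._trials(rng, 10.0, 60.0, (40.0, 120.0), n=5)
        v, m, layer = classify_neuron(stim, None)
        assert v is None and layer is None


class TestNormalizeRate:
    def test_ramp_spans_unit_interval(self):
        t = np.arange(0.0, 500.0)
        out, flat = normalize_rate(t.copy(), t)
        assert not flat and out.min() == 0.0 and out.max() == 1.0

    def test_constant_flagged(self):
        t = np.arange(0.0, 500.0)
        out, flat = normalize_rate(np.full_like(t, 3.0), t)
        assert flat and np.allclose(out, 0.0)

    def test_scale_invariance(self, rng):
        t = np.arange(0.0, 600.0)
        x = rng.random(t.size)
        a, _ = normalize_rate(x, t)
        b, _ = normalize_rate(10.0 * x, t)
        assert np.allclose(a, b)


@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=3, max_size=200))
def test_tertile_balance_property(values):
    tert = assign_tertiles(np.asarray(values))
    counts = np.bincount(tert, minlength=3)
    assert counts.max() - counts.min() <= 1
    assert counts.sum() == len(values)


def test_tertiles_ordered_by_value(rng):
    v = rng.random(99)
    tert = assign_tertiles(v)
    assert v[tert == 0].max() <= v[tert == 1].min() + 1e-12
    assert v[tert == 1].max() <= v[tert == 2].min() + 1e-12


class TestCorrelation:
    def test_monotone_rate_gives_unit_rho(self, rng):
        sal = rng.random(100)
        rho, p = per_neuron_correlation(sal, np.exp(sal))
        assert rho == pytest.approx(1.0)

    def test_null_rho_small(self, rng):
        rho, p = per_neuron_correlation(rng.random(500), rng.random(500))
        assert abs(rho) < 0.15

    def test_min_count_enforced(self, rng):
        with pytest.raises(ValueError):
            per_neuron_correlation(rng.random(30), rng.random(30))

    def test_population_shift_with_planted_gain(self):
        from scipy import stats

        from scsaliency.synth import simulate_session

        neurons, _ = simulate_session(n_scs=12, n_sci=0, n_fixations=120, seed=3)
        rhos = [per_neuron_correlation(nd.samples["saliency"], nd.samples["rate"],
                                       min_n=50)[0] for nd in neurons]
        assert stats.wilcoxon(rhos, alternative="greater").pvalue < 0.05


def _session(**kw):
    from scsaliency.synth import simulate_session

    defaults = dict(n_scs=8, n_sci=6, n_fixations=150, seed=21)
    defaults.update(kw)
    return simulate_session(**defaults)[0]


class TestConditionAnalyses:
    def test_tertile_ordering_with_planted_gain(self):
        neurons = _session()
        curves, table = tertile_curves(neurons, alignment="fixation")
        means = table.groupby("tertile")["epoch_mean"].mean()
        assert means["high"] > means["medium"] > means["low"]

    def test_zero_gain_control_no_ordering(self):
        neurons = _session(gain_hz=0.0)
        _, table = tertile_curves(neurons, alignment="fixation")
        means = table.groupby("tertile")["epoch_mean"].mean()
        assert abs(means["high"] - means["low"]) < 0.25

    def test_epoch_mean_matches_hand_computation(self):
        neurons = _session(n_scs=1, n_sci=0)
        nd = neurons[0]
        _, table = tertile_curves([nd], alignment="fixation", norm_mode="across")
        tert = assign_tertiles(nd.samples["saliency"].to_numpy())
        m = (nd.t_fix >= 0) & (nd.t_fix < 200)
        curves = {lev: np.nanmean(nd.dens_fix[tert == lev], axis=0) for lev in (0, 1, 2)}
        allc = np.concatenate([c[(nd.t_fix >= 0) & (nd.t_fix < 500)] for c in curves.values()])
        lo, hi = allc.min(), allc.max()
        expect = np.nanmean((curves[2][m] - lo) / (hi - lo))
        got = table[table["tertile"] == "high"]["epoch_mean"].iloc[0]
        assert got == pytest.approx(expect, rel=1e-6)

    def test_goal_split_signature(self):
        neurons = _session(n_scs=12, n_sci=12, n_fixations=250)
        res = goal_split_analysis(neurons, alignment="fixation")
        assert res.tests[("SCs", "in")]["significant"]
        assert res.tests[("SCs", "opposite")]["significant"]
        assert res.tests[("SCi", "in")]["significant"]
        assert not res.tests[("SCi", "opposite")]["significant"]

    def test_goal_relabelling_swaps_curves(self):
        neurons = _session(n_scs=4, n_sci=0)
        res = goal_split_analysis(neurons, alignment="fixation")
        swapped = []
        for nd in neurons:
            s2 = nd.samples.copy()
            s2["goal"] = s2["goal"].map({"in": "opposite", "opposite": "in",
                                         "other": "other"})
            swapped.append(NeuronData(record=nd.record, samples=s2, t_fix=nd.t_fix,
                                      dens_fix=nd.dens_fix, t_sac=nd.t_sac,
                                      dens_sac=nd.dens_sac))
        res2 = goal_split_analysis(swapped, alignment="fixation")
        for lev in ("high", "low"):
            a = res.curves[("SCs", "in", lev)][1]
            b = res2.curves[("SCs", "opposite", lev)][1]
            assert np.allclose(a, b, equal_nan=True)

    def test_epoch_mean_jitter_invariance(self):
        from scsaliency.analysis import align_windows, spike_density

        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, 10_000.0, 800))
        events = np.arange(500.0, 9_000.0, 400.0)
        def epoch_means(sp):
            t, d = spike_density(sp, 10_000.0)
            rel, w = align_windows(d, t, events, (0.0, 200.0))
            return np.nanmean(w, axis=1)
        base = epoch_means(spikes)
        jit = epoch_means(np.clip(spikes + rng.uniform(-1, 1, spikes.size), 0, 10_000.0))
        assert np.abs(jit - base).max() / base.mean() < 0.05


class TestFeatureDependence:
    def _neurons_with_features(self, motion_only=False, gain=25.0):
        rng = np.random.default_rng(4)
        feats = ("lum", "rg", "by", "orientation", "flicker", "motion")
        out = []
        for i in range(10):
            n = 240
            per_feat = {f: rng.random(n) for f in feats}
            combined = np.mean([per_feat[f] for f in feats], axis=0)
            drive = per_feat["motion"] if motion_only else combined
            rate = 10.0 + gain * drive + rng.standard_normal(n)
            df = pd.DataFrame({"saliency": combined, "rate": rate,
                               "goal": rng.choice(["in", "opposite"], n),
                               "duration": np.full(n, 300.0),
                               **{f"sal_{f}": per_feat[f] for f in feats}})
            rec = NeuronRecord(id=f"n{i}", rf_centre_xy=(8.0, 0.0), layer_class="SCs")
            out.append(NeuronData(record=rec, samples=df))
        return out

    def test_combined_drive_all_positive(self):
        matrix, tests = feature_dependence(self._neurons_with_features())
        assert (matrix.mean() > 0).all()
        assert tests["significant"].all()

    def test_motion_tuned_dominates(self):
        matrix, _ = feature_dependence(self._neurons_with_features(motion_only=True))
        means = matrix.mean()
        assert means["motion"] == means.max()
        assert means["motion"] > 2 * np.delete(means.to_numpy(), 5).max()

    def test_zero_gain_near_zero(self):
        matrix, tests = feature_dependence(self._neurons_with_features(gain=0.0))
        assert np.abs(matrix.mean()).max() < 0.1
        assert not tests["significant"].any()


class TestBehavioural:
    def test_salience_seeking_direction(self):
        from scsaliency.synth import behavioural_session

        df = behavioural_session(seed=11)
        res = behavioural_saliency(df)
        assert res.n_in_high > res.n_in_low
        assert res.rt_high_mean < res.rt_low_mean
        assert res.p_counts < 0.05

    def test_rt_rank_sum_power_at_study_scale(self):
        # a 15 ms advantage at n=2000 per group is detected reliably
        from scipy import stats

        rng = np.random.default_rng(99)
        hits = 0
        reps = 20
        for _ in range(reps):
            lo = 314.0 * np.exp(0.35 * rng.standard_normal(2000))
            hi = 299.0 * np.exp(0.35 * rng.standard_normal(2000))
            p = stats.mannwhitneyu(hi, lo, alternative="less").pvalue
            hits += p < 0.05
        assert hits / reps > 0.9

    def test_unbiased_policy_null(self):
        from scsaliency.synth import behavioural_session

        df = behavioural_session(seed=13, p_salient=0.0, rt_gain=0.0)
        res = behavioural_saliency(df)
        n = res.n_in_high + res.n_in_low
        assert abs(res.n_in_high - res.n_in_low) < 4 * np.sqrt(n)
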