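import numpy as np
import pytest

from nvsleep.behavior import BinaryEventTrain
from nvsleep.core import AWAKE, NREM, REM, Event, EventCatalog, Hypnogram, TimeSeries
from nvsleep.events import (establish_baseline, extract_state_events,
                            hbt_gamma_histogram2d, median_smooth,
                            p_awake_vs_quiescence, quiescent_periods,
                            state_probability_vs_signal,
                            state_probability_vs_time, summarize_events,
                            transition_triggered_average)
from nvsleep.synthgen import GeneratorConfig, simulate_hypnogram


def _train(pairs, rate=30.0):
    pairs = np.asarray(list(pairs), float).reshape(-1, 2)
    return BinaryEventTrain((pairs[:, 0] * rate).astype(int),
                            (pairs[:, 1] * rate).astype(int), rate)


def _hyp(labels):
    return Hypnogram(np.array(labels, dtype=object))


class TestBaseline:
    def test_generator_r0_recovered(self, short_session, short_derived):
        bl = short_derived["baseline"]
        # corrected reflectance is renormalized by the drift fit's first-minute
        # level; compare against the same normalization of the truth
        drift = short_session.truth["drift"]
        expected = short_session.truth["r0"] * drift.mean() / \
            (drift[:30 * 60] / drift[:30 * 60].mean()).mean()
        rel = bl.means["reflectance_L"] / short_session.truth["r0"]
        assert 0.95 < rel < 1.10
        assert not bl.fallback_used

    def test_rest_hbt_mean_near_zero_by_construction(self, short_derived):
        bl = short_derived["baseline"]
        hbt = short_derived["hbt_L"].values
        assert abs(hbt[bl.rest_mask].mean()) < 1.5

    def test_two_days_yield_distinct_baselines(self):
        rate, nb = 30.0, 24
        n = int(nb * 5 * rate)
        ch_a = {"reflectance_L": TimeSeries(np.full(n, 1.0), rate)}
        ch_b = {"reflectance_L": TimeSeries(np.full(n, 1.3), rate)}
        awake = np.ones(nb, bool)
        empty = _train([])
        bl_a = establish_baseline(ch_a, awake, empty, None, min_total_s=30)
        bl_b = establish_baseline(ch_b, awake, empty, None, min_total_s=30)
        assert bl_a.means["reflectance_L"] != bl_b.means["reflectance_L"]

    def test_insufficient_rest_triggers_flagged_fallback(self):
        rate, nb = 30.0, 24
        n = int(nb * 5 * rate)
        ch = {"x": TimeSeries(np.arange(n, dtype=float), rate)}
        busy = _train([(i * 4.0, i * 4.0 + 3.8) for i in range(30)])
        with pytest.warns(UserWarning):
            bl = establish_baseline(ch, np.ones(nb, bool), busy, None)
        assert bl.fallback_used


class TestExtractEvents:
    def test_quiet_awake_span_yields_one_rest_event(self):
        hyp = _hyp([AWAKE] * 12)
        cat = extract_state_events(hyp, _train([(50.0, 51.0)]), None, [])
        rest = cat.of_kind("rest")
        assert len(rest) == 1
        assert rest[0].duration >= 10.0

    def test_whisk_shortly_after_stimulus_excluded(self):
        hyp = _hyp([AWAKE] * 12)
        whisks = _train([(14.0, 17.0), (40.0, 43.0)])  # 4 s and 30 s post-stim
        cat = extract_state_events(hyp, whisks, None, stim_times=[10.0])
        moderate = cat.of_kind("whisk_moderate")
        assert len(moderate) == 1
        assert moderate[0].start == pytest.approx(40.0, abs=0.05)

    def test_whisk_duration_classes(self):
        hyp = _hyp([AWAKE] * 12)
        whisks = _train([(5.0, 6.0), (15.0, 18.0), (30.0, 37.0)])
        cat = extract_state_events(hyp, whisks, None, [])
        assert len(cat.of_kind("whisk_brief")) == 1
        assert len(cat.of_kind("whisk_moderate")) == 1
        assert len(cat.of_kind("whisk_extended")) == 1

    def test_rem_event_means_recover_generator_offset(self, main_session, main_derived):
        ses, der = main_session, main_derived
        cat = extract_state_events(
            ses.truth_hypnogram, der["whisk_train"], der["move_train"],
            ses.stim_times, ses.truth["true_awake_bins"])
        by_kind = summarize_events(cat, der["hbt_L"], key="hbt")
        offsets = ses.truth_params.hbt_offset
        assert by_kind["contiguous_REM"].mean() == pytest.approx(offsets[REM], abs=3.0)

    def test_alert_and_asleep_windows_classified(self):
        lab = [AWAKE] * 180 + [NREM] * 170 + [AWAKE] * 10
        cat = extract_state_events(_hyp(lab), _train([]), None, [])
        assert len(cat.of_kind("alert15")) == 1
        assert len(cat.of_kind("asleep15")) == 1
        assert len(cat.of_kind("all15")) == 2


class TestTransitions:
    def _step_channels(self, labels, lo=0.0, hi=32.2, rate=30.0):
        codes = Hypnogram(np.array(labels, dtype=object)).as_codes()
        per = int(5 * rate)
        x = np.repeat(np.where(codes == 1, hi, lo), per).astype(float)
        return {"hbt": TimeSeries(x, rate)}

    def test_awake_to_nrem_rise_matches_offset_difference(self):
        lab = [AWAKE] * 8 + [NREM] * 8 + [AWAKE] * 4
        res = transition_triggered_average(_hyp(lab), self._step_channels(lab),
                                           (AWAKE, NREM))
        assert res["n_transitions"] == 1
        tr = res["traces"]["hbt"]
        rise = tr[-30 * 5:].mean() - tr[: 30 * 5].mean()
        assert rise == pytest.approx(32.2, abs=2.0)

    def test_reverse_transition_is_time_mirror(self):
        lab = [AWAKE] * 8 + [NREM] * 8 + [AWAKE] * 8
        ch = self._step_channels(lab)
        fwd = transition_triggered_average(_hyp(lab), ch, (AWAKE, NREM),
                                           prefilter=False)
        rev = transition_triggered_average(_hyp(lab), ch, (NREM, AWAKE),
                                           prefilter=False)
        assert np.allclose(fwd["traces"]["hbt"], rev["traces"]["hbt"][::-1],
                           atol=1e-9)

    def test_short_alternation_has_no_qualifying_transition(self):
        lab = ([AWAKE] * 5 + [NREM] * 7) * 3
        res = transition_triggered_average(_hyp(lab), self._step_channels(lab),
                                           (AWAKE, NREM))
        assert res["n_transitions"] == 0
        assert res["traces"] == {}


class TestProbabilityCurves:
    def test_state_probabilities_partition_to_one(self):
        cfg = GeneratorConfig(seed=31)
        hyps = [simulate_hypnogram(cfg, 3000.0, seed=s) for s in (1, 2, 3)]
        res = state_probability_vs_time(hyps)
        total = sum(res["probability"][s] for s in ("AWAKE", "NREM", "REM"))
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_stationary_chain_flagged_unidentifiable(self):
        flat = _hyp([AWAKE] * 200)
        res = state_probability_vs_time([flat])
        assert not res["fits"]["AWAKE"]["identifiable"]

    def test_no_sleep_curve_is_unity(self):
        hyp = _hyp([AWAKE] * 100)
        quiescent = [(10.0 * i, 10.0 * i + 7.0) for i in range(20)]
        res = p_awake_vs_quiescence(hyp, quiescent)
        occupied = res["n_events"] > 0
        assert np.all(res["p_awake"][occupied] == 1.0)

    def test_event_duration_binning_rule(self):
        hyp = _hyp([AWAKE] * 100)
        res = p_awake_vs_quiescence(hyp, [(0.0, 7.5)])
        assert res["n_events"][1] == 1  # the 5-10 s bin
        assert res["n_events"].sum() == 1

    def test_markov_survival_oracle(self):
        # quiescent events anchored at awake bin starts: P(awake through m
        # extra bins) = p_stay^m for a unit-dwell chain
        p_stay = 0.92
        p = np.array([[p_stay, 1 - p_stay, 0.0],
                      [0.10, 0.88, 0.02],
                      [0.30, 0.00, 0.70]])
        cfg = GeneratorConfig(transition_matrix=p,
                              dwell_min={AWAKE: 1, NREM: 1, REM: 1}, seed=33)
        hyp = simulate_hypnogram(cfg, 40_000 * 5.0, seed=33)
        starts = np.flatnonzero(hyp.labels[:-3] == AWAKE)
        dur = 7.5  # spans the start bin plus one more
        quiescent = [(s * 5.0, s * 5.0 + dur) for s in starts]
        res = p_awake_vs_quiescence(hyp, quiescent)
        assert res["p_awake"][1] == pytest.approx(p_stay, abs=0.05)


class TestSignalConditional:
    def test_separated_distributions_give_step_curves(self):
        rate, nb = 30.0, 120
        codes = np.array([0] * 60 + [1] * 60)
        rng = np.random.default_rng(0)
        order = rng.permutation(nb)
        codes = codes[order]
        labels = np.array(["AWAKE", "NREM"], dtype=object)[codes]
        vals = np.where(codes == 1, 30.0, 0.0)
        sig = TimeSeries(np.repeat(vals, int(5 * rate))
                         + 0.5 * rng.standard_normal(nb * int(5 * rate)), rate)
        res = state_probability_vs_signal(_hyp(labels), sig)
        c = res["bin_centers"]
        lo = res["probability"]["AWAKE"][c < 10]
        hi = res["probability"]["NREM"][c > 20]
        assert np.nanmin(lo) > 0.95
        assert np.nanmin(hi) > 0.95

    def test_empty_bins_propagate_as_nan(self):
        labels = np.array(["AWAKE"] * 4 + ["NREM"] * 4, dtype=object)
        vals = np.repeat([0.0, 0.0, 0.0, 0.0, 50.0, 50.0, 50.0, 50.0], 150)
        res = state_probability_vs_signal(_hyp(labels), TimeSeries(vals, 30.0),
                                          smooth_window=1)
        gap = (res["bin_centers"] > 5) & (res["bin_centers"] < 45)
        assert np.all(np.isnan(res["raw"]["AWAKE"][gap]))

    def test_fractions_sum_to_one_before_smoothing(self, rng):
        labels = rng.choice(["AWAKE", "NREM", "REM"], 60).astype(object)
        sig = TimeSeries(rng.standard_normal(60 * 150) * 20, 30.0)
        res = state_probability_vs_signal(_hyp(labels), sig)
        occ = res["counts_per_bin"] > 0
        total = sum(res["raw"][s] for s in ("AWAKE", "NREM", "REM"))
        assert np.allclose(total[occ], 1.0)

    def test_median_smooth_handles_constant(self):
        assert np.allclose(median_smooth(np.full(20, 3.0)), 3.0)


class TestHistogram2d:
    def test_counts_sum_to_bin_count(self, rng):
        labels = rng.choice(["AWAKE", "NREM", "REM"], 100).astype(object)
        hbt = TimeSeries(rng.standard_normal(100 * 150) * 10, 30.0)
        gam = TimeSeries(rng.standard_normal(100 * 150), 30.0)
        res = hbt_gamma_histogram2d(_hyp(labels), hbt, gam)
        total = sum(res["counts"][s].sum() for s in ("AWAKE", "NREM", "REM"))
        assert total == 100

    def test_zero_variance_occupies_single_cell(self):
        labels = np.array(["AWAKE"] * 10, dtype=object)
        hbt = TimeSeries(np.zeros(10 * 150), 30.0)
        gam = TimeSeries(np.ones(10 * 150), 30.0)
        res = hbt_gamma_histogram2d(_hyp(labels), hbt, gam, bins=5)
        assert (res["counts"]["AWAKE"] > 0).sum() == 1

    def test_rem_cluster_at_higher_hbt_than_nrem(self, main_session):
        hyp = main_session.truth_hypnogram
        hbt = main_session.truth["hbt_L"]
        env = TimeSeries(main_session.truth["gamma_env_L"], 30.0)
        res = hbt_gamma_histogram2d(hyp, hbt, env)
        centers = (res["hbt_edges"][:-1] + res["hbt_edges"][1:]) / 2
        def centroid(s):
            c = res["counts"][s].sum(axis=1)
            return np.sum(centers * c) / c.sum()
        assert centroid("REM") > centroid("NREM") > centroid("AWAKE")


def test_quiescent_periods_complement_activity():
    whisk = _train([(10.0, 12.0)])
    spans = quiescent_periods(whisk, None, 30.0, min_s=5.0)
    assert (0.0, 10.0) in [(round(a, 2), round(b, 2)) for a, b in spans]
    assert any(a >= 12.0 for a, b in spans)
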