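"""Generator correctness: determinism, closed-form consistency, sampling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sgdyn.synthetic import (CLASS_PRESETS, DecayTruth, FieldSpec, KineticTruth,
                             LogisticCurve, ParameterError, TimecourseSpec,
                             conversion_model, frap_model, gen_conversion_trace,
                             gen_ct_table, gen_decay_matrix, gen_frap_trace,
                             gen_granule_field, gen_steady_state_matrix,
                             gen_stress_timecourse, preset_truth)

LN2 = math.log(2.0)


class TestGranuleField:
    def test_zero_granules_gives_background_plus_noise_only(self):
        spec = FieldSpec(n_cells=1, granules_per_cell=(0, 0), gaussian_sd=0.0, seed=1)
        f = gen_granule_field(spec)
        assert len(f.truth) == 0
        assert np.allclose(f.image, spec.background_level)

    def test_requested_granules_all_planted_inside_cell(self):
        spec = FieldSpec(n_cells=1, granules_per_cell=(5, 5), gaussian_sd=0.0, seed=2)
        f = gen_granule_field(spec)
        assert len(f.truth) == 5
        for _, row in f.truth.iterrows():
            assert f.cell_mask[int(round(row.row)), int(round(row.col))] == row.cell_id

    def test_same_seed_bit_identical(self):
        spec = FieldSpec(seed=3)
        a, b = gen_granule_field(spec), gen_granule_field(spec)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.cell_mask, b.cell_mask)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_truth_area_is_half_maximum_disk(self):
        # pixels >= amplitude/2 lie within the half-max radius of the spot
        spec = FieldSpec(n_cells=1, granules_per_cell=(1, 1), gaussian_sd=0.0,
                         granule_radius=(2.5, 2.5), seed=4)
        f = gen_granule_field(spec)
        area = f.truth.area_px.iloc[0]
        assert abs(area - math.pi * 2.5 ** 2) / (math.pi * 2.5 ** 2) < 0.25

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            gen_granule_field(FieldSpec(sg_positive_prob=1.5))
        with pytest.raises(ParameterError):
            gen_granule_field(FieldSpec(granule_radius=(0.5, 1.0)))


class TestStressTimecourse:
    def test_zero_assembly_curve_yields_no_granules(self):
        tspec = TimecourseSpec(
            times=(30.0, 60.0),
            assembly={"off": LogisticCurve(0.0, 10, 4)},
            area_fraction={"off": LogisticCurve(0.02, 10, 4)},
            n_fields_per_point=2, seed=5)
        fields = gen_stress_timecourse(tspec, FieldSpec(seed=5))
        for f in fields.values():
            assert len(f.truth) == 0
            assert not f.cell_truth.sg_positive.any()

    def test_positivity_matches_assembly_probability(self):
        # empirical SG-positive fraction within 3 binomial SDs of the curve value
        tspec = TimecourseSpec(times=(30.0,), n_fields_per_point=100, seed=6)
        fields = gen_stress_timecourse(tspec, FieldSpec(n_cells=4, seed=6))
        truth = pd.concat([f.cell_truth.assign(**f.metadata) for f in fields.values()])
        ctrl = truth[truth.condition == "siC"]
        p = tspec.assembly["siC"](30.0)
        n = len(ctrl)
        sd = math.sqrt(p * (1 - p) / n)
        assert abs(ctrl.sg_positive.mean() - p) <= 3 * sd

    def test_identical_curves_give_indistinguishable_area_fractions(self):
        curves = {"a": LogisticCurve(0.8, 10, 4), "b": LogisticCurve(0.8, 10, 4)}
        areas = {"a": LogisticCurve(0.03, 15, 8), "b": LogisticCurve(0.03, 15, 8)}
        tspec = TimecourseSpec(times=(60.0,), assembly=curves, area_fraction=areas,
                               n_fields_per_point=40, seed=7)
        fields = gen_stress_timecourse(tspec, FieldSpec(n_cells=4, seed=7))
        truth = pd.concat([f.cell_truth.assign(**f.metadata) for f in fields.values()])
        pos = truth[truth.sg_positive]
        a = pos[pos.condition == "a"].realized_area_fraction
        b = pos[pos.condition == "b"].realized_area_fraction
        assert sps.ks_2samp(a, b).pvalue > 0.01

    def test_unreachable_area_fraction_raises(self):
        tspec = TimecourseSpec(
            times=(60.0,),
            assembly={"c": LogisticCurve(1.0, 0, 1)},
            area_fraction={"c": LogisticCurve(0.9, 0, 1)},
            n_fields_per_point=1, seed=8)
        with pytest.raises(ParameterError):
            gen_stress_timecourse(tspec, FieldSpec(seed=8))


class TestFrapTrace:
    def test_fully_immobile_pool_shows_no_recovery(self):
        truth = KineticTruth(k_exchange=0.3, immobile_fraction=1.0, seed=0)
        tr = gen_frap_trace(truth)
        post = tr.post_values
        assert np.allclose(post, 1.0 - truth.bleach_depth, atol=1e-12)

    def test_fully_mobile_pool_recovers_to_prebleach(self):
        truth = KineticTruth(k_exchange=0.5, immobile_fraction=0.0, n_post=400, seed=0)
        tr = gen_frap_trace(truth)
        assert tr.post_values[-1] == pytest.approx(1.0, abs=1e-10)

    def test_half_recovery_at_half_life(self):
        # k = ln2/2.5: at t = 2.5 s the trace is exactly halfway to the plateau
        # (0.25 s frames put t = 2.5 s on the sampling grid)
        truth = KineticTruth(k_exchange=LN2 / 2.5, immobile_fraction=0.3,
                             frame_interval=0.25, seed=0)
        tr = gen_frap_trace(truth)
        i = np.argmin(np.abs(tr.post_times - 2.5))
        assert tr.post_times[i] == pytest.approx(2.5, abs=1e-12)
        f_bleach = 1.0 - truth.bleach_depth
        f_inf = f_bleach + (1 - truth.immobile_fraction) * truth.bleach_depth
        assert tr.post_values[i] == pytest.approx((f_bleach + f_inf) / 2, abs=1e-10)

    def test_acquisition_scheme_frame_layout(self):
        tr = gen_frap_trace(KineticTruth(k_exchange=0.3, immobile_fraction=0.2))
        assert len(tr.times) == 105 and tr.n_pre == 5
        assert np.allclose(np.diff(tr.times), 0.3)
        assert tr.times[5] == 0.0

    def test_noiseless_trace_matches_closed_form_everywhere(self):
        truth = KineticTruth(k_exchange=0.2, immobile_fraction=0.4,
                             acquisition_bleach_rate=0.01, seed=0)
        tr = gen_frap_trace(truth)
        f_bleach = 1 - truth.bleach_depth
        f_inf = f_bleach + (1 - truth.immobile_fraction) * truth.bleach_depth
        model = frap_model(tr.post_times, truth.k_exchange, f_inf, f_bleach)
        damp = np.exp(-0.01 * (tr.post_times - tr.times[0]))
        assert np.max(np.abs(tr.post_values - model * damp)) < 1e-10


class TestConversionTrace:
    def test_fully_immobile_red_signal_is_retained(self):
        pair = gen_conversion_trace(KineticTruth(k_exchange=0.3, immobile_fraction=1.0,
                                                 n_post=300))
        assert np.allclose(pair.red.post_values, 1.0, atol=1e-12)

    def test_transient_preset_cleared_within_30s(self):
        pair = gen_conversion_trace(preset_truth("transient", "conversion"))
        i = np.argmin(np.abs(pair.red.post_times - 30.0))
        expected = conversion_model(30.0, LN2 / 2.5,
                                    CLASS_PRESETS["transient"]["immobile_fraction"], 1.0)
        assert pair.red.post_values[i] == pytest.approx(expected, abs=1e-10)
        assert pair.red.post_values[i] < 0.01

    def test_stable_preset_retains_majority_at_30s(self):
        pair = gen_conversion_trace(preset_truth("stable", "conversion"))
        i = np.argmin(np.abs(pair.red.post_times - 30.0))
        assert pair.red.post_values[i] >= 0.6

    def test_channels_are_complementary(self):
        pair = gen_conversion_trace(KineticTruth(k_exchange=0.2, immobile_fraction=0.5,
                                                 n_post=300))
        total = pair.red.post_values + pair.green.post_values
        assert np.allclose(total, 1.0, atol=1e-12)


class TestCtTable:
    def test_stable_gene_has_constant_ct(self):
        truth = DecayTruth(n_transcripts=1, ct_noise_sd=0.0, seed=1)
        tab = gen_ct_table(truth, half_lives={"X": float("inf")})
        for _, grp in tab.groupby(["gene", "condition"]):
            assert grp.ct.nunique() == 1

    def test_one_cycle_per_half_life(self):
        truth = DecayTruth(n_transcripts=1, ct_noise_sd=0.0,
                           times=(0.0, 60.0, 120.0), seed=1)
        tab = gen_ct_table(truth, half_lives={"X": 60.0})
        g = tab[(tab.gene == "X") & (tab.condition == "siC") & (tab.replicate == 0)]
        cts = g.sort_values("time").ct.to_numpy()
        assert np.allclose(np.diff(cts), 1.0, atol=1e-12)

    def test_same_seed_identical_table(self):
        truth = DecayTruth(n_transcripts=5, seed=9)
        pd.testing.assert_frame_equal(gen_ct_table(truth), gen_ct_table(truth))


class TestDecayMatrix:
    def test_no_condition_effect_gives_identical_truth_slopes(self):
        truth = DecayTruth(n_transcripts=20, condition_effect=1.0, seed=2)
        _, slopes = gen_decay_matrix(truth)
        piv = slopes.pivot(index="transcript", columns="condition", values="slope")
        assert np.allclose(piv.iloc[:, 0], piv.iloc[:, 1])

    def test_condition_effect_scales_decay(self):
        # for transcripts whose decay is slow relative to the sampling window,
        # a faster rate makes the fitted linear slope strictly more negative
        truth = DecayTruth(n_transcripts=20, condition_effect=2.0,
                           half_life_log_mean=math.log(240.0),
                           half_life_log_sd=0.1, seed=2)
        _, slopes = gen_decay_matrix(truth)
        piv = slopes.pivot(index="transcript", columns="condition", values="slope")
        reliable = piv.abs().sum(axis=1) > 0
        assert (piv.loc[reliable, "siSG"] < piv.loc[reliable, "siC"]).all()

    def test_truth_slope_is_least_squares_on_sampled_grid(self):
        # baseline 100 halving by the last time point: closed-form OLS slope
        truth = DecayTruth(n_transcripts=1, reliable_fraction=1.0,
                           array_log_noise_sd=0.0, array_background=0.0,
                           baseline_log_mean=math.log(100.0), baseline_log_sd=0.0,
                           times=(0.0, 40.0, 80.0, 120.0), seed=3)
        mat, slopes = gen_decay_matrix(truth)
        hl = slopes.half_life.iloc[0]
        t = np.array(truth.times)
        y = 100.0 * np.exp(-LN2 / hl * t)
        expected = np.polyfit(t, y, 1)[0]
        assert slopes.slope.iloc[0] == pytest.approx(expected, rel=1e-10)
        # noiseless matrix equals the clean curve
        ctrl_cols = [c for c in mat.intensities.columns if c.startswith("siC")]
        vals = mat.intensities[ctrl_cols].to_numpy()[0].reshape(len(t), -1)
        assert np.allclose(vals.mean(axis=1), y, rtol=1e-10)

    def test_determinism(self):
        truth = DecayTruth(n_transcripts=30, seed=4)
        m1, s1 = gen_decay_matrix(truth)
        m2, s2 = gen_decay_matrix(truth)
        pd.testing.assert_frame_equal(m1.intensities, m2.intensities)
        pd.testing.assert_frame_equal(s1, s2)


class TestSteadyStateMatrix:
    def test_planted_classes_and_determinism(self):
        truth = DecayTruth(n_transcripts=500, seed=5)
        m1, p1 = gen_steady_state_matrix(truth)
        m2, p2 = gen_steady_state_matrix(truth)
        pd.testing.assert_frame_equal(m1.intensities, m2.intensities)
        pd.testing.assert_frame_equal(p1, p2)
        counts = p1.planted_class.value_counts()
        assert counts.get("red", 0) > 0 and counts.get("blue", 0) > 0
        assert counts["none"] > 0.8 * 500
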