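"""Array decay pipeline: filtering, normalization, slopes, fold-change classes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from sgdyn.array_decay import (background_correct, classify_fold_change, decay_slopes,
                               filter_reliable, quantile_normalize, slope_correlation)
from sgdyn.synthetic import DecayTruth, ExpressionMatrix, gen_decay_matrix


def _matrix(intens: dict, detect: dict | None = None, meta_rows=None) -> ExpressionMatrix:
    idx = [f"t{i}" for i in range(len(next(iter(intens.values()))))]
    intensities = pd.DataFrame(intens, index=idx)
    detection = pd.DataFrame(detect, index=idx) if detect else \
        pd.DataFrame(0.0, index=idx, columns=intensities.columns)
    if meta_rows is None:
        meta_rows = [(c, "siC", float(i * 30), 0) for i, c in enumerate(intensities.columns)]
    meta = pd.DataFrame(meta_rows, columns=["sample", "condition", "time", "replicate"]
                        ).set_index("sample")
    return ExpressionMatrix(intensities, detection, meta)


class TestFilterReliable:
    def _mat(self, p_untreated):
        intens = {"u1": [100.0] * len(p_untreated), "u2": [100.0] * len(p_untreated)}
        detect = {"u1": [p[0] for p in p_untreated], "u2": [p[1] for p in p_untreated]}
        meta = [("u1", "siC", 0.0, 0), ("u2", "siC", 0.0, 1)]
        return _matrix(intens, detect, meta)

    def test_all_below_alpha_kept(self):
        m = self._mat([(0.0005, 0.0005)])
        assert filter_reliable(m) == ["t0"]

    def test_one_sample_above_alpha_removed(self):
        m = self._mat([(0.0005, 0.002)])
        assert filter_reliable(m) == []

    def test_alpha_one_keeps_everything(self):
        m = self._mat([(0.0005, 0.002), (0.9, 0.9)])
        assert filter_reliable(m, alpha=1.0 + 1e-9) == ["t0", "t1"]

    def test_lowering_alpha_never_adds_transcripts(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 0.01, size=(50, 2))
        m = self._mat(list(map(tuple, p)))
        kept = [set(filter_reliable(m, alpha=a)) for a in (0.01, 0.005, 0.001, 0.0001)]
        for bigger, smaller in zip(kept, kept[1:]):
            assert smaller <= bigger

    def test_no_untreated_samples_is_error(self):
        m = _matrix({"a": [1.0], "b": [2.0]},
                    meta_rows=[("a", "siC", 30.0, 0), ("b", "siC", 60.0, 0)])
        with pytest.raises(ValueError):
            filter_reliable(m)


class TestBackgroundCorrect:
    def test_known_additive_background_recovered(self):
        truth = DecayTruth(n_transcripts=10000, array_background=30.0,
                           reliable_fraction=0.85, seed=11)
        mat, _ = gen_decay_matrix(truth)
        _, offsets = background_correct(mat)
        assert np.all(np.abs(offsets - 30.0) / 30.0 < 0.10)

    def test_zero_background_correction_is_small(self):
        truth = DecayTruth(n_transcripts=10000, array_background=0.0, seed=11)
        mat, _ = gen_decay_matrix(truth)
        corrected, offsets = background_correct(mat)
        fifth = mat.intensities.quantile(0.05)
        assert np.all(offsets <= fifth + 1e-9)

    def test_all_equal_sample_floors_at_epsilon(self):
        m = _matrix({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0, 3.0]})
        corrected, _ = background_correct(m)
        assert np.allclose(corrected.intensities["a"], 1e-6)


class TestQuantileNormalize:
    def test_worked_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0, 2.0], "b": [3.0, 1.0, 2.0, 2.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(np.float64, (7, 3), elements=st.floats(0, 1e6, width=32),
                  unique=True))
    def test_columns_share_sorted_vector_and_means(self, values):
        # exact identity of sorted columns holds for tie-free data; with ties
        # the mean-quantile tie policy (the field standard) relaxes it
        df = pd.DataFrame(values, columns=["a", "b", "c"])
        out = quantile_normalize(df)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.allclose(sorted_cols - sorted_cols[:, :1], 0.0, atol=1e-10)
        means = out.mean()
        assert np.ptp(means.to_numpy()) <= 1e-10 * max(1.0, abs(means.iloc[0]))

    def test_ties_share_the_mean_of_their_quantiles(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0, 9.0], "b": [2.0, 4.0, 6.0, 8.0]})
        out = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].iloc[0] == out["a"].iloc[1] == pytest.approx((ref[0] + ref[1]) / 2)

    def test_sample_order_permutation_invariant(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(0, 100, size=(20, 4)), columns=list("abcd"))
        out1 = quantile_normalize(df)
        out2 = quantile_normalize(df[list("dcba")])
        pd.testing.assert_frame_equal(out1, out2[list("abcd")])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestDecaySlopes:
    def test_exact_linear_data(self):
        m = _matrix({"s0": [100.0], "s1": [80.0], "s2": [60.0], "s3": [40.0]})
        out = decay_slopes(m)
        assert out.slope.iloc[0] == pytest.approx(-2.0 / 3.0, rel=1e-12)
        assert out.r_squared.iloc[0] == pytest.approx(1.0)

    def test_constant_transcript_zero_slope(self):
        m = _matrix({"s0": [5.0], "s1": [5.0], "s2": [5.0]})
        assert decay_slopes(m).slope.iloc[0] == 0.0

    def test_too_few_time_points_is_error(self):
        m = _matrix({"s0": [1.0], "s1": [2.0]})
        with pytest.raises(ValueError):
            decay_slopes(m)

    def test_noiseless_matrix_matches_generative_slopes(self):
        truth = DecayTruth(n_transcripts=100, array_log_noise_sd=0.0,
                           array_background=0.0, seed=13)
        mat, truth_slopes = gen_decay_matrix(truth)
        fitted = decay_slopes(mat)
        merged = fitted.merge(truth_slopes, on=["transcript", "condition"],
                              suffixes=("_fit", "_true"))
        assert np.max(np.abs(merged.slope_fit - merged.slope_true)) <= 1e-8

    def test_replicate_mean_and_per_replicate_agree_on_balanced_design(self):
        truth = DecayTruth(n_transcripts=20, seed=14)
        mat, _ = gen_decay_matrix(truth)
        a = decay_slopes(mat, on_replicate_means=True)
        b = decay_slopes(mat, on_replicate_means=False)
        assert np.allclose(a.slope, b.slope, rtol=1e-9)


class TestSlopeCorrelation:
    def test_identical_vectors(self):
        s = pd.Series([1.0, -2.0, 3.0], index=list("abc"))
        r, _ = slope_correlation(s, s)
        assert r == pytest.approx(1.0)

    def test_negated_vectors(self):
        s = pd.Series([1.0, -2.0, 3.0], index=list("abc"))
        r, _ = slope_correlation(s, -s)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_gives_nan_with_warning(self, caplog):
        s = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with caplog.at_level("WARNING"):
            r, _ = slope_correlation(s, pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert math.isnan(r)

    def test_null_condition_effect_gives_high_between_condition_r(self):
        truth = DecayTruth(n_transcripts=2000, condition_effect=1.0, seed=15)
        mat, _ = gen_decay_matrix(truth)
        kept = filter_reliable(mat)
        corrected, _ = background_correct(mat)
        slopes = decay_slopes(corrected, transcripts=kept)
        r, _ = slope_correlation(slopes[slopes.condition == "siC"],
                                 slopes[slopes.condition == "siSG"])
        assert r >= 0.9


class TestFoldChange:
    def _steady(self, ratios):
        """ratios: transcript -> (fold no-stress, fold stress) of knockdown/control."""
        base = 100.0
        intens, meta = {}, []
        for cond in ("siC", "siSG"):
            for stress in (False, True):
                col = f"{cond}_{'s' if stress else 'n'}"
                vals = []
                for (fn, fs) in ratios:
                    f = 1.0 if cond == "siC" else (fs if stress else fn)
                    vals.append(base * f)
                intens[col] = vals
                meta.append((col, cond, 0.0, 0, stress))
        idx = [f"t{i}" for i in range(len(ratios))]
        intensities = pd.DataFrame(intens, index=idx)
        detection = pd.DataFrame(0.0, index=idx, columns=intensities.columns)
        sm = pd.DataFrame(meta, columns=["sample", "condition", "time", "replicate",
                                         "stress"]).set_index("sample")
        return ExpressionMatrix(intensities, detection, sm)

    def test_hand_checkable_cases(self):
        m = self._steady([(1.0, 0.4), (1.0, 1.0), (4.0, 4.0)])
        records, counts, quadrants = classify_fold_change(m)
        assert records["class"].tolist() == ["red", "none", "green"]
        assert counts == {"green": 1, "red": 1, "blue": 0, "none": 1}
        assert quadrants["I"] == 1

    def test_blue_requires_stress_up_only(self):
        m = self._steady([(1.0, 3.0), (3.0, 3.0)])
        records, _, _ = classify_fold_change(m)
        assert records["class"].tolist() == ["blue", "green"]

    def test_partition_covers_every_transcript_once(self):
        rng = np.random.default_rng(17)
        ratios = [(2.0 ** rng.normal(0, 1), 2.0 ** rng.normal(0, 1)) for _ in range(300)]
        m = self._steady(ratios)
        records, counts, _ = classify_fold_change(m)
        assert len(records) == 300
        assert sum(counts.values()) == 300
        assert set(records["class"]) <= {"green", "red", "blue", "none"}

    def test_euclidean_mode_is_wider_than_chebyshev(self):
        m = self._steady([(2.0 ** 0.8, 2.0 ** 0.8)])   # |x|=|y|=0.8 < 1, hypot ~1.13
        cheb, _, _ = classify_fold_change(m, mode="chebyshev")
        eucl, _, _ = classify_fold_change(m, mode="euclidean")
        assert cheb["class"].iloc[0] == "none"
        assert eucl["class"].iloc[0] == "green"

    def test_nonpositive_mean_excluded_with_warning(self, caplog):
        m = self._steady([(1.0, 1.0), (1.0, 1.0)])
        m.intensities.iloc[0, :] = 0.0
        with caplog.at_level("WARNING"):
            records, _, _ = classify_fold_change(m)
        assert len(records) == 1
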