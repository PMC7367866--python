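"""MR / TMM / UQ factors against hand-executed oracles; ladder anchoring."""

import numpy as np
import pandas as pd
import pytest

from cnladder.normalize import (CountMatrix, evaluate_normalization,
                                ladder_scaling, median_of_ratios,
                                normalize_counts, rle_statistics, tmm,
                                upper_quartile)


def geomean(v):
    return float(np.exp(np.mean(np.log(v))))


class TestMedianOfRatios:
    def test_identical_samples_give_unit_factors(self):
        df = pd.DataFrame({"a": [3, 7, 11], "b": [3, 7, 11]})
        assert np.allclose(median_of_ratios(df), 1.0)

    def test_scaling_equivariance(self):
        df = pd.DataFrame({"a": [10, 20, 30, 40], "b": [20, 40, 60, 80]})
        f = median_of_ratios(df)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_five_feature_toy_matches_hand_computation(self):
        """Hand MR: ref_i = sqrt(a_i*b_i); factor_j = median_i(x_ij/ref_i)."""
        a = np.array([10, 20, 30, 40, 55.0])
        b = np.array([22, 41, 58, 85, 110.0])
        ref = np.sqrt(a * b)
        expected_a = float(np.median(a / ref))
        expected_b = float(np.median(b / ref))
        f = median_of_ratios(pd.DataFrame({"a": a, "b": b}))
        assert f["a"] == pytest.approx(expected_a)
        assert f["b"] == pytest.approx(expected_b)

    def test_matches_deseq2_size_factors(self):
        """Frozen from DESeq2 1.42.0 estimateSizeFactorsForMatrix on the
        same matrix (Rscript oracle run during development)."""
        df = pd.DataFrame({"s1": [10, 20, 30, 40, 55], "s2": [22, 41, 58, 85, 110]})
        f = median_of_ratios(df)
        assert f["s1"] == pytest.approx(0.6984303, abs=1e-6)
        assert f["s2"] == pytest.approx(1.4317821, abs=1e-6)

    def test_zero_rows_excluded_from_reference(self):
        df = pd.DataFrame({"a": [0, 10, 20], "b": [5, 10, 20]})
        f = median_of_ratios(df)
        assert np.allclose(f, 1.0)  # the zero row would otherwise break symmetry

    def test_all_zero_features_rejected(self):
        df = pd.DataFrame({"a": [0, 1], "b": [1, 0]})
        with pytest.raises(ValueError):
            median_of_ratios(df)


class TestUpperQuartile:
    def test_identical_samples(self):
        df = pd.DataFrame({"a": [1, 5, 9], "b": [1, 5, 9]})
        assert np.allclose(upper_quartile(df), 1.0)

    def test_order_statistic_oracle(self):
        """Nonzero counts 1..8: 75th percentile by linear interpolation is
        6.25 (between the 6th and 7th order statistics)."""
        counts = np.arange(1.0, 9.0)
        assert np.percentile(counts, 75) == 6.25  # convention pinned
        df = pd.DataFrame({"a": counts, "b": counts * 4})
        f = upper_quartile(df)
        # raw UQs 6.25 and 25, rescaled to geometric mean 1
        g = geomean([6.25, 25.0])
        assert f["a"] == pytest.approx(6.25 / g)
        assert f["b"] == pytest.approx(25.0 / g)

    def test_equivariance_of_factor_ratios(self):
        base = pd.DataFrame({"a": [1, 5, 9.0], "b": [1, 5, 9.0]})
        scaled = base.copy()
        scaled["b"] = scaled["b"] * 3
        f0, f1 = upper_quartile(base), upper_quartile(scaled)
        assert (f1["b"] / f1["a"]) / (f0["b"] / f0["a"]) == pytest.approx(3.0)

    def test_zeros_ignored(self):
        df = pd.DataFrame({"a": [0, 0, 4.0], "b": [4, 4, 4.0]})
        f = upper_quartile(df)
        assert np.allclose(f, 1.0)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [0, 0.0], "b": [1, 2.0]})
        with pytest.raises(ValueError):
            upper_quartile(df)


def tmm_oracle(x, ref, trim_m=0.30, trim_a=0.05, weighted=True):
    """Hand-executed TMM for one sample vs a reference, written independently:
    explicit M/A computation, quantile trimming, precision-weighted mean."""
    keep = (x > 0) & (ref > 0)
    x, ref = x[keep], ref[keep]
    m = np.log2(x) - np.log2(ref)
    a = (np.log2(x) + np.log2(ref)) / 2
    lo_m, hi_m = np.quantile(m, trim_m), np.quantile(m, 1 - trim_m)
    lo_a, hi_a = np.quantile(a, trim_a), np.quantile(a, 1 - trim_a)
    sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if weighted:
        w = 1.0 / (1.0 / x[sel] + 1.0 / ref[sel])
        return 2.0 ** (np.sum(w * m[sel]) / np.sum(w))
    return 2.0 ** np.mean(m[sel])


class TestTmm:
    def test_sample_vs_itself_is_unit(self):
        df = pd.DataFrame({"a": [5, 9, 14, 20.0], "b": [5, 9, 14, 20.0]})
        assert np.allclose(tmm(df, reference="a"), 1.0)

    def test_ten_feature_toy_matches_hand_oracle(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(5, 200, 10).astype(float)
        x = (ref * rng.uniform(0.5, 2.0, 10)).round()
        df = pd.DataFrame({"r": ref, "x": x})
        raw = tmm_oracle(x, ref)
        g = geomean([1.0, raw])
        f = tmm(df, reference="r")
        assert f["r"] == pytest.approx(1.0 / g)
        assert f["x"] == pytest.approx(raw / g)

    def test_unweighted_flag(self):
        rng = np.random.default_rng(4)
        ref = rng.integers(5, 200, 30).astype(float)
        x = (ref * rng.uniform(0.5, 2.0, 30)).round()
        df = pd.DataFrame({"r": ref, "x": x})
        raw = tmm_oracle(x, ref, weighted=False)
        g = geomean([1.0, raw])
        assert tmm(df, reference="r", weighted=False)["x"] == pytest.approx(raw / g)

    def test_depth_factor_recovered(self):
        rng = np.random.default_rng(5)
        base = rng.integers(10, 500, 200).astype(float)
        df = pd.DataFrame({"a": base, "b": base * 3})
        f = tmm(df)
        assert f["b"] / f["a"] == pytest.approx(3.0, rel=1e-6)

    def test_default_reference_choice(self):
        rng = np.random.default_rng(6)
        base = rng.integers(10, 500, 100).astype(float)
        df = pd.DataFrame({"a": base, "b": base * 2, "c": base * 1.1})
        # 'c' has the upper quartile closest to the mean of the three
        f = tmm(df)
        assert np.allclose(geomean(f.to_numpy()), 1.0)


def ladder_matrix(sample_rows, ladder_rows):
    counts = pd.concat([sample_rows, ladder_rows], axis=0)
    ladder = pd.Series([False] * len(sample_rows) + [True] * len(ladder_rows),
                       index=counts.index)
    return CountMatrix(counts=counts, ladder=ladder)


class TestLadderScaling:
    def test_invariant_ladder_gives_unit_factors(self):
        sample = pd.DataFrame({"a": [100, 5, 9.0], "b": [3, 700, 2.0]},
                              index=["s1", "s2", "s3"])
        lad = pd.DataFrame({"a": [10, 20, 40.0], "b": [10, 20, 40.0]},
                           index=["l1", "l2", "l3"])
        res = ladder_scaling(ladder_matrix(sample, lad), method="mr")
        assert np.allclose(res.factors, 1.0)
        # sample rows are untouched even though they differ wildly
        assert np.allclose(res.normalized.loc[["s1", "s2", "s3"]], sample)

    def test_doubled_library_recovered(self):
        rng = np.random.default_rng(7)
        s = rng.integers(1, 200, 50).astype(float)
        l = rng.integers(10, 100, 20).astype(float)
        sample = pd.DataFrame({"a": s, "b": 2 * s},
                              index=[f"s{i}" for i in range(50)])
        lad = pd.DataFrame({"a": l, "b": 2 * l},
                           index=[f"l{i}" for i in range(20)])
        res = ladder_scaling(ladder_matrix(sample, lad), method="mr")
        assert res.factors["b"] / res.factors["a"] == pytest.approx(2.0)
        va = res.normalized["a"].to_numpy()
        vb = res.normalized["b"].to_numpy()
        assert np.allclose(va, vb)

    def test_factors_ignore_non_ladder_rows(self):
        rng = np.random.default_rng(8)
        l = rng.integers(10, 100, 20).astype(float)
        lad = pd.DataFrame({"a": l, "b": l * 1.5},
                           index=[f"l{i}" for i in range(20)])
        s1 = pd.DataFrame({"a": rng.integers(1, 50, 30).astype(float),
                           "b": rng.integers(1, 50, 30).astype(float)},
                          index=[f"s{i}" for i in range(30)])
        s2 = s1 * rng.uniform(0.1, 10, size=(30, 1))
        f1 = ladder_scaling(ladder_matrix(s1, lad)).factors
        f2 = ladder_scaling(ladder_matrix(s2, lad)).factors
        assert np.allclose(f1, f2)

    def test_missing_ladder_rows_rejected(self):
        sample = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["s1"])
        lad = pd.DataFrame({"a": [5.0], "b": [0.0]}, index=["l1"])
        with pytest.raises(ValueError):
            ladder_scaling(ladder_matrix(sample, lad))


class TestRle:
    def test_identical_samples_have_zero_medians(self):
        df = pd.DataFrame({"a": [4, 9, 16.0], "b": [4, 9, 16.0]})
        rle = rle_statistics(df)
        assert np.allclose(rle["rle_median"], 0.0)

    def test_three_by_two_toy_hand_computation(self):
        df = pd.DataFrame({"a": [4, 10, 16.0], "b": [8, 10, 4.0]})
        rle = rle_statistics(df)
        # feature medians: 6, 10, 10 -> RLE_a = log2([4/6, 1, 1.6])
        expected_a = np.median(np.log2(np.array([4 / 6, 1.0, 1.6])))
        expected_b = np.median(np.log2(np.array([8 / 6, 1.0, 0.4])))
        assert rle.set_index("sample").loc["a", "rle_median"] == pytest.approx(expected_a)
        assert rle.set_index("sample").loc["b", "rle_median"] == pytest.approx(expected_b)

    def test_zero_median_features_excluded(self):
        df = pd.DataFrame({"a": [0, 5.0], "b": [0, 5.0]})
        rle = rle_statistics(df)
        assert (rle["n_excluded_zero_median"] == 1).all()
        assert (rle["n_features"] == 1).all()


class TestEvaluation:
    def test_perfect_normalization_large_effects_reach_auc_one(self, rng):
        n = 300
        lam = np.full(n, 50.0)
        fc = np.concatenate([np.full(n // 3, 8.0), np.ones(n - n // 3)])
        a = rng.poisson(lam).astype(float)
        b = rng.poisson(lam * fc).astype(float)
        lam_l = np.repeat([25.0, 50, 100, 200], 200)
        la = rng.poisson(lam_l).astype(float)
        lb = rng.poisson(lam_l).astype(float)
        counts = pd.DataFrame({
            "a": np.concatenate([a, la]), "b": np.concatenate([b, lb])},
            index=[f"f{i}" for i in range(n + 800)])
        ladder = pd.Series([False] * n + [True] * 800, index=counts.index)
        cm = CountMatrix(counts=counts, ladder=ladder)
        res = normalize_counts(cm, "mr", "ladder")
        units = pd.Series(np.repeat([1, 2, 4, 8], 200), index=counts.index[n:])
        truth = pd.Series(fc, index=counts.index[:n])
        ev = evaluate_normalization(res, cm, truth, units)
        assert ev.auc > 0.99
        rec = ev.recovery.set_index("designed_fc")["median_observed_fc"]
        assert rec[8.0] == pytest.approx(8.0, rel=0.15)
        assert rec[1.0] == pytest.approx(1.0, abs=0.1)

    def test_balanced_pair_sample_and_ladder_modes_agree(self, rng):
        """With a balanced design, sample-anchored MR and ladder-anchored MR
        give the same factors up to sampling noise."""
        n = 4000
        # balanced: sum of log fold changes is 0 and the median feature is
        # unchanged, as in the balanced mock-community design
        fc = np.concatenate([np.full(n // 4, 2.0), np.full(n // 4, 0.5),
                             np.ones(n // 2)])
        lam = np.full(n, 40.0)
        a = rng.poisson(lam).astype(float) + 1
        b = rng.poisson(lam * fc).astype(float) + 1
        l = rng.poisson(np.full(600, 60.0)).astype(float) + 1
        counts = pd.DataFrame(
            {"a": np.concatenate([a, l]), "b": np.concatenate([b, l])},
            index=[f"f{i}" for i in range(n + 600)])
        ladder = pd.Series([False] * n + [True] * 600, index=counts.index)
        cm = CountMatrix(counts=counts, ladder=ladder)
        f_sample = normalize_counts(cm, "mr", "sample").factors
        f_ladder = normalize_counts(cm, "mr", "ladder").factors
        r_sample = f_sample["b"] / f_sample["a"]
        r_ladder = f_ladder["b"] / f_ladder["a"]
        assert r_sample == pytest.approx(r_ladder, rel=0.05)
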