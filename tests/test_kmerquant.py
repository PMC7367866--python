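"""Counting, cataloguing, partitioning and ladder-structure statistics."""

import numpy as np
import pytest
from scipy import stats

from cnladder import kmerquant, simulate
from cnladder._codec import canonical_codes, encode, revcomp
from cnladder.kmerquant import (CnProfile, KmerCountTable, build_catalog,
                                count_kmers, equalize_ladder_depth,
                                ladder_metrics, overlap_fraction,
                                partition_reads, profile_cn)


def brute_force_counts(reads, k):
    """Per-read enumeration with string reverse complements (oracle)."""
    table = {}
    for r in reads:
        for i in range(len(r) - k + 1):
            w = r[i:i + k]
            if set(w) - set("ACGT"):
                continue
            canon = min(w, revcomp(w))
            table[canon] = table.get(canon, 0) + 1
    return table


class TestCounting:
    def test_single_kmer_read(self):
        t = count_kmers(["A" * 15 + "CGT" * 5 + "G"], k=31)
        assert t.total() == 1
        assert len(t) == 1

    def test_window_count_per_read(self):
        t = count_kmers(["ACGT" * 40][:1], k=31)  # 160 nt -> 130 windows
        assert t.total() == 160 - 31 + 1

    def test_canonical_invariance_under_reverse_complement(self, rng):
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        reads = [lut[rng.integers(0, 4, 80)].tobytes().decode() for _ in range(50)]
        fwd = count_kmers(reads, k=31)
        rev = count_kmers([revcomp(r) for r in reads], k=31)
        assert np.array_equal(fwd.codes, rev.codes)
        assert np.array_equal(fwd.counts, rev.counts)

    def test_matches_per_read_enumeration_oracle(self, rng):
        lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
        reads = [lut[rng.integers(0, 5, 60)].tobytes().decode() for _ in range(120)]
        k = 13
        t = count_kmers(reads, k=k)
        oracle = brute_force_counts(reads, k)
        got = dict(zip(kmerquant.codes_to_kmers(t.codes, k), t.counts.tolist()))
        assert got == oracle

    def test_count_conservation(self, rng):
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        reads = [lut[rng.integers(0, 4, 100)].tobytes().decode() for _ in range(200)]
        t = count_kmers(reads, k=31)
        assert t.total() == 200 * (100 - 31 + 1)
        assert t.n_invalid_windows == 0

    def test_short_reads_skipped_with_counter(self):
        t = count_kmers(["ACGT", "A" * 31], k=31)
        assert t.n_short_reads == 1
        assert t.total() == 1

    def test_table_lookup_absent_is_zero(self):
        t = count_kmers(["A" * 40], k=31)
        q = kmerquant.kmers_to_codes(["C" * 31], 31)
        assert t.get(q)[0] == 0


class TestCatalog:
    def test_600nt_element_yields_570_entries(self, ladder_set_small, catalog_small):
        per_elem = np.bincount(catalog_small.element_idx)
        assert (per_elem == 570).all()

    def test_multiplicity_equals_cn(self, ladder_set_small, catalog_small):
        for ladder in ladder_set_small:
            for elem in ladder.elements:
                codes = canonical_codes(encode(elem.sequence), 31)
                rows = catalog_small.lookup(codes)
                assert (rows >= 0).all()
                assert (catalog_small.cn[rows] == elem.assigned_cn).all()

    def test_disjoint_from_spacer_and_flank_kmers(self, ladder_set_small, catalog_small):
        others = []
        for ladder in ladder_set_small:
            for s in ladder.spacer_sequences + [ladder.flank_5p, ladder.flank_3p]:
                others.append(canonical_codes(encode(s), 31))
        others = np.unique(np.concatenate([o for o in others if o.size]))
        assert np.intersect1d(others, catalog_small.codes).size == 0

    def test_junction_kmers_not_catalogued(self, ladder_set_small, catalog_small):
        ladder = ladder_set_small.ladders[0]
        full_codes = np.unique(canonical_codes(encode(ladder.full_sequence), 31))
        elem_codes = np.unique(np.concatenate(
            [canonical_codes(encode(e.sequence), 31) for e in ladder.elements]))
        junction = np.setdiff1d(full_codes, elem_codes)
        assert junction.size > 0
        assert np.intersect1d(junction, catalog_small.codes).size == 0


class TestPartition:
    def test_pure_ladder_library_assignment(self, ladder_set_small, catalog_small):
        """Every pair carrying element sequence is assigned unambiguously.

        Pairs lying wholly within the common flanks carry no ladder-specific
        k-mers and stay in the residual bin (a small fraction set by the
        flank-to-molecule length ratio).
        """
        cfg = simulate.SimulationConfig(error_rate=0.0)
        batch = simulate.simulate_ladder_library(ladder_set_small, 3.0, cfg, seed=7)
        part = partition_reads(batch, catalog_small)
        assert part.n_ambiguous == 0
        assigned = sum(len(b) for b in part.bins.values())
        assert assigned / len(batch) > 0.95
        # residual pairs really have < min_hits catalogued k-mers
        for r1, r2 in zip(part.residual.r1, part.residual.r2):
            codes = np.concatenate([canonical_codes(encode(r1), 31),
                                    canonical_codes(encode(r2), 31)])
            assert (catalog_small.lookup(codes) >= 0).sum() < part.min_hits

    def test_min_hits_threshold_contract(self, ladder_set_small, catalog_small, rng):
        elem = ladder_set_small.ladders[0].elements[0]
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        neutral = lut[rng.integers(0, 4, 40)].tobytes().decode()
        five = simulate.ReadBatch(["p5"], [elem.sequence[:35]], [neutral])
        four = simulate.ReadBatch(["p4"], [elem.sequence[:34]], [neutral])
        assert len(partition_reads(five, catalog_small, min_hits=5).residual) == 0
        assert len(partition_reads(four, catalog_small, min_hits=5).residual) == 1

    def test_spiked_mixture_recovers_spike_fraction(self, ladder_set_small,
                                                    catalog_small, rng):
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        genome = lut[rng.integers(0, 4, 120_000)].tobytes().decode()
        recs = ladder_set_small.records()
        templates = [("g", genome)] + recs
        lad_len = sum(len(s) for _, s in recs)
        weights = [0.99 / len(genome)] + [0.01 / lad_len] * len(recs)
        batch = simulate.simulate_reads(templates, weights, 20_000,
                                        simulate.SimulationConfig(), rng)
        part = partition_reads(batch, catalog_small)
        frac = sum(len(b) for b in part.bins.values()) / len(batch)
        assert frac == pytest.approx(0.01, abs=0.004)


class TestEqualize:
    def test_bins_cut_to_minimum(self, ladder_set_small):
        cfg = simulate.SimulationConfig(error_rate=0.0)
        batch = simulate.simulate_ladder_library(ladder_set_small, 20.0, cfg, seed=8)
        assert len(batch) >= 3000
        bins = {"a": batch.subset(np.arange(0, 2000)),
                "b": batch.subset(np.arange(2000, 3000))}
        out = equalize_ladder_depth(bins, seed=1)
        assert {len(v) for v in out.values()} == {1000}

    def test_equal_bins_unchanged(self, ladder_set_small):
        cfg = simulate.SimulationConfig(error_rate=0.0)
        batch = simulate.simulate_ladder_library(ladder_set_small, 1.0, cfg, seed=9)
        bins = {"a": batch, "b": batch}
        out = equalize_ladder_depth(bins)
        assert out["a"] is batch and out["b"] is batch

    def test_all_empty_rejected(self):
        empty = simulate.ReadBatch([], [], [])
        with pytest.raises(ValueError):
            equalize_ladder_depth({"a": empty})

    def test_equalization_converges_unequal_molarities(self, ladder_set_small,
                                                       catalog_small):
        """2-fold molarity imbalance disappears after depth equalization.

        Per-ladder 1-cn medians carry sampling noise at the level of read
        pairs per element, so agreement is asserted within that tolerance
        and contrasted with the unequalized imbalance.
        """
        cfg = simulate.SimulationConfig(error_rate=0.0)
        batch = simulate.simulate_ladder_library(
            ladder_set_small, 150.0, cfg, weights=[1.0, 2.0, 1.0], seed=10)

        def one_cn_medians(b):
            prof = profile_cn(count_kmers(b), catalog_small)
            return [float(np.median(prof.per_ladder[(lid, 1)]))
                    for lid in prof.ladder_ids]

        raw = one_cn_medians(batch)
        assert max(raw) / min(raw) > 1.6  # the injected 2-fold imbalance

        part = partition_reads(batch, catalog_small)
        eq = equalize_ladder_depth(part.bins, seed=2)
        merged = simulate.ReadBatch([], [], [])
        for b in eq.values():
            merged = merged + b
        meds = one_cn_medians(merged)
        assert max(meds) / min(meds) < 1.3


def synthetic_profile(counts_by_cn, catalog=None):
    pooled = {cn: np.asarray(v) for cn, v in counts_by_cn.items()}
    per_ladder = {("L1", cn): np.asarray(v) for cn, v in counts_by_cn.items()}
    return CnProfile(k=31, pooled=pooled, per_ladder=per_ladder, ladder_ids=["L1"])


class TestProfileAndMetrics:
    def test_constant_counts_have_zero_cv(self):
        prof = synthetic_profile({1: [7] * 10, 2: [14] * 10})
        summ = prof.summary().set_index("cn")
        assert (summ["cv"] == 0).all()

    def test_poisson_cv_decreases_with_cn(self, rng):
        mu = 40
        prof = synthetic_profile(
            {cn: rng.poisson(cn * mu, 4000) for cn in (1, 2, 4, 8)})
        summ = prof.summary().set_index("cn")
        cvs = summ["cv"].to_numpy()
        assert (np.diff(cvs) < 0).all()
        expected = 1 / np.sqrt(np.array([1, 2, 4, 8]) * mu)
        assert np.allclose(cvs, expected, rtol=0.1)

    def test_exact_proportional_counts(self):
        prof = synthetic_profile({cn: [10 * cn] * 5 for cn in (1, 2, 4, 8)})
        met = ladder_metrics(prof)
        assert met.slope == pytest.approx(10.0)
        assert met.r_squared == pytest.approx(1.0)
        assert met.ratio_mean == pytest.approx(2.0)
        assert met.ratio_sd == pytest.approx(0.0)

    def test_toy_table_matches_closed_form_ols(self):
        data = {1: [9, 11], 2: [19, 21], 4: [39, 41], 8: [79, 81]}
        prof = synthetic_profile(data)
        met = ladder_metrics(prof)
        x = np.repeat([1, 2, 4, 8], 2).astype(float)
        y = np.array([9, 11, 19, 21, 39, 41, 79, 81], dtype=float)
        # closed-form ordinary least squares, written out
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - (intercept + slope * x)
        r2 = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert met.slope == pytest.approx(slope)
        assert met.intercept == pytest.approx(intercept)
        assert met.r_squared == pytest.approx(r2)

    def test_degenerate_constant_counts(self):
        prof = synthetic_profile({1: [5, 5], 2: [5, 5]})
        met = ladder_metrics(prof)
        assert np.isnan(met.r_squared)

    def test_median_mode_regression(self):
        prof = synthetic_profile({cn: [10 * cn + d for d in (-1, 0, 1)]
                                  for cn in (1, 2, 4, 8)})
        met = ladder_metrics(prof, mode="medians")
        assert met.slope == pytest.approx(10.0)
        assert met.r_squared == pytest.approx(1.0)


class TestOverlap:
    def test_disjoint_supports(self):
        prof = synthetic_profile({1: [1, 2, 3], 2: [10, 11, 12]})
        assert overlap_fraction(prof, 1, 2) == 0.0

    def test_identical_distributions(self):
        prof = synthetic_profile({1: [3, 4, 4, 5], 2: [3, 4, 4, 5]})
        assert overlap_fraction(prof, 1, 2) == pytest.approx(1.0)

    def test_poisson_overlap_matches_pmf_sum(self, rng):
        a = rng.poisson(16, 30_000)
        b = rng.poisson(32, 30_000)
        prof = synthetic_profile({1: a, 2: b})
        got = overlap_fraction(prof, 1, 2)
        grid = np.arange(0, 200)
        expected = np.minimum(stats.poisson.pmf(grid, 16),
                              stats.poisson.pmf(grid, 32)).sum()
        assert got == pytest.approx(expected, abs=0.02)

    def test_empty_unit_rejected(self):
        prof = synthetic_profile({1: [1, 2]})
        with pytest.raises(ValueError):
            overlap_fraction(prof, 1, 2)


class TestSweep:
    def test_error_sweep_slope_decreases(self, ladder_set_small):
        df = kmerquant.sweep_technical_variables(
            "error", [0.0, 0.02, 0.05], ladder_set_small, depth=20.0, seed=3)
        assert list(df["setting"]) == [0.0, 0.02, 0.05]
        assert (np.diff(df["slope"]) < 0).all()

    def test_depth_sweep_slope_proportional(self, ladder_set_small):
        df = kmerquant.sweep_technical_variables(
            "depth", [1.0, 0.5, 0.25], ladder_set_small, depth=40.0, seed=4)
        s = df.set_index("setting")["slope"]
        assert s[0.5] / s[1.0] == pytest.approx(0.5, rel=0.1)
        assert s[0.25] / s[1.0] == pytest.approx(0.25, rel=0.15)

    def test_unknown_variable_rejected(self, ladder_set_small):
        with pytest.raises(ValueError):
            kmerquant.sweep_technical_variables("gc", [0.1], ladder_set_small)
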