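"""Window tiling, quantile binning, trend summaries and the statistical
primitives, each checked against brute-force oracles or closed forms."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import dvnpchrom as dc
from dvnpchrom.stats import chi2_contingency_closed_2x2


class TestTileWindows:
    @pytest.mark.parametrize("L,expected_starts", [
        (1500, [0, 250, 500, 750, 1000]),
        (499, []),
        (500, [0]),
    ])
    def test_window_counts_closed_form(self, L, expected_starts):
        tab = dc.tile_windows(dc.Genome({"c": L}), size=500, step=250)
        assert list(tab["start"]) == expected_starts

    def test_count_formula_random_sizes(self):
        rng = np.random.default_rng(30)
        for _ in range(30):
            L = int(rng.integers(1, 5000))
            size = int(rng.integers(1, 600))
            step = int(rng.integers(1, size + 1))
            tab = dc.tile_windows(dc.Genome({"c": L}), size=size, step=step)
            expected = (L - size) // step + 1 if L >= size else 0
            assert len(tab) == expected

    def test_step_larger_than_size_rejected(self, tiny_genome):
        with pytest.raises(ValueError):
            dc.tile_windows(tiny_genome, size=100, step=200)


class TestWindowSignal:
    def test_constant_track(self, two_chrom_genome):
        track = dc.CoverageTrack({"chrI": np.full(1500, 2.0),
                                  "chrII": np.full(499, 2.0)})
        tab = dc.tile_windows(two_chrom_genome)
        np.testing.assert_allclose(dc.window_signal(track, tab), 2.0)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(31)
        v = rng.random(2000)
        genome = dc.Genome({"c": 2000})
        track = dc.CoverageTrack({"c": v})
        tab = dc.tile_windows(genome, size=170, step=60)
        got = dc.window_signal(track, tab)
        oracle = [v[s:e].mean() for s, e in zip(tab["start"], tab["end"])]
        np.testing.assert_allclose(got, oracle, rtol=1e-12)

    def test_disjoint_windows_conserve_total(self):
        rng = np.random.default_rng(32)
        v = rng.random(1000)
        track = dc.CoverageTrack({"c": v})
        tab = dc.tile_windows(dc.Genome({"c": 1000}), size=100, step=100)
        assert (dc.window_signal(track, tab) * 100).sum() == pytest.approx(v.sum())


class TestOccupancyChange:
    def test_identical_conditions_zero(self):
        x = np.array([1.2, 0.8, 1.0])
        np.testing.assert_array_equal(dc.occupancy_change(x, x), 0.0)

    def test_positive_is_loss(self):
        assert dc.occupancy_change(np.array([1.2]), np.array([0.9]))[0] == \
            pytest.approx(0.3)

    def test_zero_genome_mean_at_full_tiling(self, assoc_study):
        """Mean of occ_change over disjoint windows tiling the genome is 0
        when both tracks are genome-mean normalized."""
        ctrl = dc.mnase_occupancy_track(assoc_study.mnase_control, assoc_study.genome)
        dvnp = dc.mnase_occupancy_track(assoc_study.mnase_dvnp, assoc_study.genome)
        tab = dc.tile_windows(assoc_study.genome, size=500, step=500)
        change = dc.occupancy_change(dc.window_signal(ctrl, tab),
                                     dc.window_signal(dvnp, tab))
        # windows cover all but the sub-window chromosome remainder
        assert abs(change.mean()) < 5e-3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dc.occupancy_change(np.ones(3), np.ones(4))


class TestQuantileBins:
    def test_deciles_of_ten(self):
        labels = dc.quantile_bins(np.arange(1, 11), 5)
        assert list(labels[:2]) == [0, 0] and list(labels[-2:]) == [4, 4]

    def test_all_tied_stable_split(self):
        with pytest.warns(UserWarning):
            labels = dc.quantile_bins(np.ones(10), 5)
        assert list(labels) == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(33)
        v = rng.random(997)
        labels = dc.quantile_bins(v, 5)
        order = np.argsort(v, kind="stable")
        oracle = np.empty(len(v), dtype=int)
        for k, i in enumerate(order):
            oracle[i] = k * 5 // len(v)
        np.testing.assert_array_equal(labels, oracle)
        sizes = np.bincount(labels)
        assert sizes.max() - sizes.min() <= 1

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=rng.integers(10, 300))
        a = dc.quantile_bins(v, 5)
        b = dc.quantile_bins(np.exp(2.0 * v), 5)
        np.testing.assert_array_equal(a, b)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            dc.quantile_bins([1.0, 2.0], 5)


class TestBoxplotStats:
    def test_closed_form_one_to_hundred(self):
        s = dc.boxplot_stats(np.arange(1, 101))
        assert s.median == 50.5
        assert s.q3 - s.q1 == pytest.approx(50.0)
        assert s.notch_hi - s.median == pytest.approx(1.58 * 50 / 10)

    def test_midpoint_quartiles_of_three(self):
        s = dc.boxplot_stats([1.0, 2.0, 3.0])
        assert (s.q1, s.median, s.q3) == (1.5, 2.0, 2.5)

    def test_single_value_degenerate(self):
        s = dc.boxplot_stats([4.0])
        assert s.median == s.q1 == s.q3 == 4.0
        assert s.notch_lo == s.notch_hi == 4.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_whiskers_within_data_range_and_ordering(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_cauchy(rng.integers(2, 200))  # heavy tails
        s = dc.boxplot_stats(v)
        assert v.min() <= s.whisker_lo <= s.q1 <= s.median <= s.q3 \
            <= s.whisker_hi <= v.max()


class TestWelch:
    def test_identical_samples(self):
        r = dc.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_hand_example(self):
        r = dc.welch_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert r.t == pytest.approx(-1.0954451, abs=1e-6)
        assert r.df == pytest.approx(6.0, abs=1e-12)
        ref = sps.ttest_ind([1, 2, 3, 4], [2, 3, 4, 5], equal_var=False)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_antisymmetry(self):
        rng = np.random.default_rng(34)
        a, b = rng.normal(size=20), rng.normal(1, 2, 15)
        r1, r2 = dc.welch_t(a, b), dc.welch_t(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            dc.welch_t([1.0], [1.0, 2.0])


class TestChi2ClosedForm:
    def test_perfect_separation_table(self):
        assert chi2_contingency_closed_2x2(10, 0, 0, 10) == pytest.approx(20.0)

    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(35)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 50, 4)
            ours = chi2_contingency_closed_2x2(a, b, c, d)
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)[0]
            assert ours == pytest.approx(ref, rel=1e-12)


class TestPredictedOccupancy:
    @pytest.mark.parametrize("base,expected", [("G", 1.0), ("A", 0.0)])
    def test_homopolymer_windows(self, base, expected):
        genome = dc.Genome({"c": 300}, {"c": base * 300})
        sites = pd.DataFrame({"chrom": ["c"], "dyad": [150]})
        assert dc.predicted_occupancy_gc(genome, sites)[0] == expected

    def test_matches_manual_count(self):
        rng = np.random.default_rng(36)
        seq = "".join(rng.choice(list("ACGTN"), 400, p=[.3, .2, .2, .25, .05]))
        genome = dc.Genome({"c": 400}, {"c": seq})
        sites = pd.DataFrame({"chrom": ["c"], "dyad": [200]})
        got = dc.predicted_occupancy_gc(genome, sites)[0]
        w = seq[200 - 73:200 + 74]
        informative = [x for x in w if x != "N"]
        manual = sum(1 for x in informative if x in "GC") / len(informative)
        assert got == pytest.approx(manual)

    def test_off_chromosome_site_dropped_with_warning(self):
        genome = dc.Genome({"c": 200}, {"c": "A" * 200})
        sites = pd.DataFrame({"chrom": ["c", "c"], "dyad": [10, 100]})
        with pytest.warns(UserWarning):
            got = dc.predicted_occupancy_gc(genome, sites)
        assert np.isnan(got[0]) and got[1] == 0.0


class TestStrata:
    def test_strata_sizes_near_equal(self):
        rng = np.random.default_rng(37)
        labels = dc.input_strata(rng.random(503), 5)
        sizes = np.bincount(labels)
        assert sizes.max() - sizes.min() <= 1

    def test_confounded_enrichment_nullified_by_stratification(self):
        """If apparent enrichment is driven purely by accessibility (input)
        while loss is independent noise, the within-stratum association is
        null even though a naive pooled ranking would correlate with
        input."""
        rng = np.random.default_rng(38)
        n = 5000
        accessibility = rng.lognormal(0, 0.5, n)
        enrichment = accessibility * rng.lognormal(0, 0.05, n)  # input-driven
        loss = rng.normal(0, 1, n)  # no true coupling
        strat = dc.stratified_association(loss, enrichment, accessibility)
        ps = [r.welch_top_vs_bottom.p for r in strat.values()]
        assert min(ps) > 1e-3  # no stratum shows a strong spurious trend


def test_bin_association_reports_summaries_and_welch():
    rng = np.random.default_rng(39)
    vals = np.concatenate([rng.normal(i * 0.5, 1, 200) for i in range(5)])
    bins = np.repeat(np.arange(5), 200)
    rep = dc.bin_association(vals, bins)
    assert rep.monotone_increasing()
    assert rep.welch_top_vs_bottom.p < 1e-10
    assert rep.n_per_bin == [200] * 5


def test_bin_association_empty_bin_rejected():
    with pytest.raises(ValueError):
        dc.bin_association(np.ones(4), np.array([0, 0, 1, 3]))
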