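"""Synthetic-data generator: determinism, planted-structure contracts, and
distributional properties at tiny n."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dvnpchrom as dc


class TestSimulateGenome:
    def test_deterministic_under_seed(self):
        a = dc.simulate_genome(2, [5000, 3000], seed=5)
        b = dc.simulate_genome(2, [5000, 3000], seed=5)
        assert a.sequence == b.sequence

    def test_gc_close_to_target(self):
        g = dc.simulate_genome(1, [100_000], gc_mean=0.5, seed=5)
        seq = g.sequence["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1])
    def test_invalid_gc_mean_rejected(self, gc):
        with pytest.raises(ValueError):
            dc.simulate_genome(1, [1000], gc_mean=gc)


class TestSimulateGenes:
    def test_zero_genes_gives_empty_annotation(self):
        g = dc.simulate_genome(1, [50_000], seed=5)
        assert len(dc.simulate_genes(g, 0)) == 0

    def test_bodies_disjoint_with_upstream_flank_clear(self):
        g = dc.simulate_genome(1, [100_000], seed=5)
        genes = dc.simulate_genes(g, 30, seed=5)
        t = genes.table
        bodies = sorted((min(r.tss, r.polya), max(r.tss, r.polya))
                        for r in t.itertuples())
        for (s1, e1), (s2, e2) in zip(bodies, bodies[1:]):
            assert s2 - e1 >= 500  # >= flank bp between bodies
        # every gene's 500 bp upstream region avoids all other bodies
        for r in t.itertuples():
            up = (r.tss, r.tss + 500) if r.strand == "-" else (r.tss - 500, r.tss)
            for s, e in bodies:
                if (s, e) == (min(r.tss, r.polya), max(r.tss, r.polya)):
                    continue
                assert up[1] <= s or e <= up[0]

    def test_minus_strand_has_tss_greater_than_polya(self):
        g = dc.simulate_genome(1, [100_000], seed=6)
        genes = dc.simulate_genes(g, 30, seed=6)
        minus = genes.table[genes.table.strand == "-"]
        assert (minus.tss > minus.polya).all()
        genes.validate(g)

    def test_overfull_request_raises_with_achievable_count(self):
        g = dc.simulate_genome(1, [20_000], seed=5)
        with pytest.raises(RuntimeError, match="only"):
            dc.simulate_genes(g, 50, seed=5)


class TestNucleosomeMap:
    def test_gamma_zero_gives_equal_weights(self):
        g = dc.simulate_genome(1, [60_000], seed=7)
        genes = dc.simulate_genes(g, 15, seed=7)
        m = dc.build_nucleosome_map(genes, g, stability_coupling=0.0)
        assert m.sites["occupancy_weight"].nunique() == 1

    def test_phased_dyad_count_for_known_length(self):
        """A 1650 bp gene with 165 bp spacing carries 10 genic dyads plus
        the -1 nucleosome."""
        genome = dc.Genome({"c": 10_000}, {"c": "ACGT" * 2500})
        genes = dc.GeneAnnotation(pd.DataFrame(
            [{"id": "g", "chrom": "c", "strand": "+", "tss": 3000,
              "polya": 4650}]))
        m = dc.build_nucleosome_map(genes, genome, spacing=165)
        mine = m.sites[m.sites.gene == "g"]
        assert (mine.role >= 1).sum() == 10
        assert (mine.role == -1).sum() == 1

    def test_positive_gamma_couples_weight_to_gc(self):
        g = dc.simulate_genome(1, [150_000], seed=8)
        genes = dc.simulate_genes(g, 40, seed=8)
        m = dc.build_nucleosome_map(genes, g, stability_coupling=1.5)
        gc = dc.predicted_occupancy_gc(g, m.sites)
        r = np.corrcoef(m.sites["occupancy_weight"], gc)[0, 1]
        assert r > 0.5

    def test_weights_in_unit_interval(self, default_study):
        w = default_study.nucmap.sites["occupancy_weight"]
        assert ((w > 0) & (w <= 1)).all()


@pytest.fixture(scope="module")
def small_map():
    g = dc.simulate_genome(1, [120_000], seed=9)
    genes = dc.simulate_genes(g, 30, seed=9)
    m = dc.build_nucleosome_map(genes, g)
    truth = dc.SimulationTruth(
        dvnp_affinity=dc.build_affinity_track(m, g), loss_coupling=0.0)
    return g, m, truth


class TestSimulateMnase:
    def test_null_condition_matches_control_rates(self, small_map):
        """With beta=0 the dvnp per-site sampling matches the planted
        weights (chi-square goodness of fit at n=1e5)."""
        g, m, truth = small_map
        frags = dc.simulate_mnase(m, truth, 100_000, g, condition="dvnp",
                                  seed=10, jitter_sd=0.0, background=0.0)
        mids = (frags.records.start + frags.records.end) // 2
        counts = mids.value_counts().reindex(m.sites.dyad, fill_value=0).to_numpy()
        w = m.sites.occupancy_weight.to_numpy()
        expected = counts.sum() * w / w.sum()
        p = sps.chisquare(counts, expected).pvalue
        assert p > 0.01

    def test_fragment_length_mean_near_target(self, small_map):
        g, m, truth = small_map
        frags = dc.simulate_mnase(m, truth, 100_000, g, seed=11)
        assert frags.lengths.mean() == pytest.approx(147.0, abs=1.0)
        assert frags.lengths.min() >= 120 and frags.lengths.max() <= 200

    def test_seed_determinism(self, small_map):
        g, m, truth = small_map
        a = dc.simulate_mnase(m, truth, 5000, g, seed=12)
        b = dc.simulate_mnase(m, truth, 5000, g, seed=12)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_all_zero_weights_rejected(self, small_map):
        g, m, _ = small_map
        hot = dc.SimulationTruth(
            dvnp_affinity=dc.uniform_affinity(g, 1.0), loss_coupling=5.0)
        with pytest.raises(ValueError):
            dc.simulate_mnase(m, hot, 100, g, condition="dvnp",
                              stability_protection=False, background=0.0)


class TestSimulateChip:
    def test_uniform_affinity_gives_flat_metagene(self):
        g = dc.simulate_genome(1, [150_000], seed=13)
        genes = dc.simulate_genes(g, 40, seed=13)
        truth = dc.SimulationTruth(dvnp_affinity=dc.uniform_affinity(g))
        ip, _ = dc.simulate_dvnp_chip(truth, g, 200_000, 0, seed=13)
        track = dc.mnase_occupancy_track(ip, g, size_range=(50, 500))
        prof = dc.metagene_profile(track, genes, upstream=300, downstream=500)
        m = prof.n_genes == len(genes)
        vals = prof.mean_signal[m]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - 1.0) < 3 * max(se, 0.01) + 0.05

    def test_nucleosomal_affinity_enriched_at_dyads_vs_ndr(self, default_study):
        sc = default_study
        ip = dc.mnase_occupancy_track(sc.chip_ip, sc.genome, size_range=(50, 500))
        inp = dc.mnase_occupancy_track(sc.chip_input, sc.genome,
                                       size_range=(50, 500))
        dyad_sig = dc.site_signal(ip, sc.nucmap.sites).mean() / \
            dc.site_signal(inp, sc.nucmap.sites).mean()
        ndr = sc.nucmap.ndr.rename(columns={"center": "dyad"})
        ndr_sig = dc.site_signal(ip, ndr[["chrom", "dyad"]]).mean() / \
            dc.site_signal(inp, ndr[["chrom", "dyad"]]).mean()
        assert dyad_sig > 2 * ndr_sig

    def test_empty_ip_allowed(self):
        g = dc.simulate_genome(1, [50_000], seed=14)
        truth = dc.SimulationTruth(dvnp_affinity=dc.uniform_affinity(g))
        ip, inp = dc.simulate_dvnp_chip(truth, g, 0, 100, seed=14)
        assert len(ip) == 0 and len(inp) == 100


@pytest.fixture(scope="module")
def rpb3_setup():
    g = dc.simulate_genome(1, [400_000], seed=15)
    genes = dc.simulate_genes(g, 120, seed=15)
    return g, genes


class TestSimulateRpb3:
    def test_equal_ratio_gives_equal_spike_fractions(self, rpb3_setup):
        g, genes = rpb3_setup
        truth = dc.SimulationTruth(dvnp_affinity={}, rpb3_global_ratio=1.0)
        _, _, counts = dc.simulate_rpb3(genes, truth, g, n_reads=50_000, seed=16)
        frac = counts.spike_reads / counts.genomic_reads
        assert frac.iloc[1] == pytest.approx(frac.iloc[0], rel=0.05)

    def test_spike_ratio_reflects_inverse_global_ratio(self, rpb3_setup):
        g, genes = rpb3_setup
        truth = dc.SimulationTruth(dvnp_affinity={}, rpb3_global_ratio=0.65)
        _, _, counts = dc.simulate_rpb3(genes, truth, g, n_reads=100_000, seed=17)
        odds = (counts.spike_reads / counts.genomic_reads)
        assert odds.iloc[1] / odds.iloc[0] == pytest.approx(1 / 0.65, rel=0.05)

    def test_genomic_libraries_depth_matched_exactly(self, rpb3_setup):
        g, genes = rpb3_setup
        truth = dc.SimulationTruth(dvnp_affinity={}, rpb3_global_ratio=0.5)
        ctrl, treat, _ = dc.simulate_rpb3(genes, truth, g, n_reads=30_000, seed=18)
        assert len(ctrl) == len(treat) == 30_000

    def test_invalid_ratio_rejected(self, rpb3_setup):
        g, genes = rpb3_setup
        truth = dc.SimulationTruth(dvnp_affinity={}, rpb3_global_ratio=0.0)
        with pytest.raises(ValueError):
            dc.simulate_rpb3(genes, truth, g, n_reads=100, seed=19)


class TestSimulateSga:
    def test_null_tail_fraction_matches_gaussian(self):
        tab = dc.simulate_sga(5000, {}, noise_sd=0.05, seed=20)
        rg = dc.relative_growth(tab)
        frac = ((rg > 1.1) | (rg < 0.9)).mean()
        assert frac == pytest.approx(0.0455, abs=0.012)

    def test_planted_rescuers_all_above_threshold(self):
        tab = dc.simulate_sga(2000, {"histone_down": (42, 0.3)},
                              noise_sd=0.05, seed=21)
        rg = dc.relative_growth(tab)
        sets = tab.groupby("gene", sort=False)["set_label"].first()
        assert (rg[sets == "histone_down"] > 1.15).all()

    def test_seed_determinism(self):
        a = dc.simulate_sga(200, {}, seed=22)
        b = dc.simulate_sga(200, {}, seed=22)
        pd.testing.assert_frame_equal(a, b)

    def test_hit_sets_exceeding_strains_rejected(self):
        with pytest.raises(ValueError):
            dc.simulate_sga(10, {"big": (20, 0.3)})


def test_control_mnase_metagene_recovers_planted_phasing(default_study):
    """Peak-to-peak distance of the simulated control profile equals the
    planted repeat length within 5 bp."""
    ctrl = dc.mnase_occupancy_track(default_study.mnase_control,
                                    default_study.genome)
    prof = dc.metagene_profile(ctrl, default_study.genes)
    assert dc.genic_peak_spacing(prof) == pytest.approx(
        default_study.nucmap.spacing, abs=5)
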