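import numpy as np
import pytest
from scipy import stats

from chemnuc import synthetic_data as sd
from chemnuc.io_formats import GenomicInterval, ValidationError, gc_content


class TestMakeGenome:
    def test_deterministic_bytes(self, tmp_path):
        fa = []
        for rep in range(2):
            g, _ = sd.make_genome(2, [3000, 2500], gc=0.45, seed=1)
            p = tmp_path / f"g{rep}.fa"
            g.write_fasta(p)
            fa.append(p.read_bytes())
        assert fa[0] == fa[1]

    def test_gc_within_binomial_bound(self):
        g, _ = sd.make_genome(1, 100_000, gc=0.5, seed=3)
        assert abs(gc_content(g) - 0.5) < 0.02

    def test_length_and_gc_validation(self):
        with pytest.raises(ValidationError):
            sd.make_genome(1, 500, gc=0.5)
        with pytest.raises(ValidationError):
            sd.make_genome(1, 5000, gc=1.5)

    def test_ww_planting_recorded_in_manifest(self):
        g, manifest = sd.make_genome(1, 20_000, gc=0.5, seed=5,
                                     periodic_dinucleotides=True)
        assert manifest["plant_dyads"]["chr1"]
        # enrichment check: WW frequency at planted offsets beats background
        from chemnuc.feature_profiles import dinucleotide_profile
        dyads = {"chr1": np.array(manifest["plant_dyads"]["chr1"])}
        prof = dinucleotide_profile(g, dyads, flank=70)
        offs = np.arange(-70, 70)
        on = prof[offs % 10 == 0].mean()
        off = prof[offs % 10 == 5].mean()
        assert on > off + 0.2


class TestLinkerMixture:
    def test_sample_matches_pmf_chi_square(self):
        n = 10_000
        mix = sd.LinkerMixture()
        rng = np.random.default_rng(0)
        draws = mix.sample(rng, n)
        support = np.arange(0, 200)
        probs = mix.pmf(support)
        counts = np.bincount(draws, minlength=200)[:200].astype(float)
        # pool cells with small expected counts (chi-square validity)
        big = probs * n >= 5
        obs = np.append(counts[big], counts[~big].sum())
        exp = np.append(probs[big], probs[~big].sum()) * n
        chi2, p = stats.chisquare(obs, exp)
        assert p > 0.01

    def test_short_mixture_mostly_short(self):
        draws = sd.SHORT_LINKER_MIXTURE.sample(np.random.default_rng(1), 10_000)
        assert (draws <= 30).mean() >= 0.70

    def test_mean_matches_monte_carlo(self):
        mix = sd.SHORT_LINKER_MIXTURE
        draws = mix.sample(np.random.default_rng(2), 50_000)
        assert abs(draws.mean() - mix.mean()) < 0.5


class TestPlantLandscape:
    def test_no_features_means_identical_conditions(self, stable_only_landscape):
        ls = stable_only_landscape
        a, b = ls.conditions["A"], ls.conditions["B"]
        assert np.array_equal(a.dyads["chr1"], b.dyads["chr1"])
        assert np.array_equal(a.weights["chr1"], b.weights["chr1"])
        assert not a.fragile["chr1"].any()

    def test_min_truth_spacing_invariant(self, small_landscape):
        for cond in "AB":
            for pos in small_landscape.conditions[cond].dyads.values():
                assert np.diff(pos).min() >= 147

    def test_barrier_anchor_present_in_A_absent_in_B(self, small_landscape):
        ls = small_landscape
        for chrom, anchor in ls.barrier_anchors:
            da = ls.conditions["A"].dyads[chrom]
            db = ls.conditions["B"].dyads[chrom]
            assert np.abs(da - anchor).min() <= 5
            assert np.abs(db - anchor).min() >= 60

    def test_fragile_only_in_regulatory_A(self, small_landscape):
        ls = small_landscape
        a = ls.conditions["A"]
        for chrom in a.dyads:
            frag_classes = a.region_class[chrom][a.fragile[chrom]]
            assert all(c == "regulatory" for c in frag_classes)
            assert not ls.conditions["B"].fragile[chrom].any()

    def test_deterministic_for_seed(self):
        lengths = {"chr1": 100_000}
        regions = sd.default_regions(lengths, block=10_000,
                                     regulatory_every=4, barrier_every=4)
        l1 = sd.plant_landscape(lengths, regions, seed=3)
        l2 = sd.plant_landscape(lengths, regions, seed=3)
        assert np.array_equal(l1.conditions["A"].dyads["chr1"],
                              l2.conditions["A"].dyads["chr1"])
        assert np.array_equal(l1.conditions["A"].weights["chr1"],
                              l2.conditions["A"].weights["chr1"])

    def test_overlapping_regions_rejected(self):
        regions = {"stable": [GenomicInterval("chr1", 0, 5000)],
                   "regulatory": [GenomicInterval("chr1", 4000, 9000)],
                   "barrier": []}
        with pytest.raises(ValidationError, match="overlap"):
            sd.plant_landscape({"chr1": 10_000}, regions)

    def test_too_small_region_names_it(self):
        regions = {"stable": [], "barrier": [],
                   "regulatory": [GenomicInterval("chr1", 1000, 1100)]}
        with pytest.raises(ValidationError, match="chr1:1000-1100"):
            sd.plant_landscape({"chr1": 10_000}, regions)


class TestChemicalFragments:
    def test_noise_free_ends_sit_on_cleavage_offsets(self, small_landscape,
                                                     noise_free_model):
        frags, truth = sd.simulate_chemical_fragments(
            small_landscape, "A", noise_free_model, 20_000, seed=4)
        cond = small_landscape.conditions["A"]
        for chrom in frags.chroms:
            anchors = np.union1d(cond.dyads[chrom],
                                 np.array(truth["aux_anchors"][chrom],
                                          dtype=np.int64))
            # Watson 5' ends at anchor-1 or anchor+6
            w_sites = np.union1d(anchors - 1, anchors + 6)
            assert np.isin(frags.starts[chrom], w_sites).all()
            # Crick 5' ends (e-1) at anchor+1 or anchor-6
            c_sites = np.union1d(anchors + 1, anchors - 6)
            assert np.isin(frags.ends[chrom] - 1, c_sites).all()

    def test_fragment_lengths_in_bounds(self, small_landscape):
        frags, _ = sd.simulate_chemical_fragments(
            small_landscape, "A", sd.CleavageModel(), 20_000, seed=5)
        for chrom in frags.chroms:
            lens = frags.ends[chrom] - frags.starts[chrom]
            assert lens.min() >= 100 and lens.max() <= 300

    def test_deterministic_bed_bytes(self, small_landscape, tmp_path):
        beds = []
        for rep in range(2):
            frags, _ = sd.simulate_chemical_fragments(
                small_landscape, "A", sd.CleavageModel(), 5000, seed=9)
            p = tmp_path / f"f{rep}.bed"
            frags.write_bed(p)
            beds.append(p.read_bytes())
        assert beds[0] == beds[1]

    def test_truth_links_most_fragments_to_dyads(self, small_landscape):
        frags, truth = sd.simulate_chemical_fragments(
            small_landscape, "A", sd.CleavageModel(background_rate=0.05),
            50_000, seed=6)
        linked = sum(int((v >= 0).sum()) for v in truth["dyad_index"].values())
        assert linked / frags.n >= 0.94

    def test_empty_landscape_rejected(self):
        regions = {"stable": [], "regulatory": [], "barrier": []}
        ls = sd.plant_landscape({"chr1": 10_000}, regions)
        with pytest.raises(ValidationError, match="empty"):
            sd.simulate_chemical_fragments(ls, "A", n_fragments=10)


class TestMnaseFragments:
    def test_protection_zero_drops_fragile(self, small_landscape):
        frags = sd.simulate_mnase_fragments(small_landscape, "A",
                                            protection=0.0,
                                            n_fragments=20_000, seed=3)
        cond = small_landscape.conditions["A"]
        for chrom in frags.chroms:
            fragile_pos = set(cond.dyads[chrom][cond.fragile[chrom]].tolist())
            ids = [int(x.split(":")[-1]) for x in frags.labels[chrom]]
            sampled = set(cond.dyads[chrom][ids].tolist())
            assert not (sampled & fragile_pos)

    def test_protection_one_counts_track_chemical(self, small_landscape):
        n = 100_000
        chem, truth = sd.simulate_chemical_fragments(
            small_landscape, "A", sd.CleavageModel(background_rate=0.0),
            n, seed=8)
        mnase = sd.simulate_mnase_fragments(small_landscape, "A",
                                            protection=1.0, n_fragments=n,
                                            seed=9)
        cond = small_landscape.conditions["A"]
        chrom = "chr1"
        nd = len(cond.dyads[chrom])
        c_counts = np.bincount(truth["dyad_index"][chrom], minlength=nd)
        m_ids = np.array([int(x.split(":")[-1]) for x in mnase.labels[chrom]])
        m_counts = np.bincount(m_ids, minlength=nd)
        r = np.corrcoef(c_counts, m_counts)[0, 1]
        assert r > 0.9

    def test_midpoints_near_dyads(self, small_landscape):
        frags = sd.simulate_mnase_fragments(small_landscape, "A",
                                            n_fragments=10_000, seed=10,
                                            jitter_sd=5.0)
        cond = small_landscape.conditions["A"]
        chrom = "chr1"
        mids = frags.starts[chrom] + (frags.ends[chrom]
                                      - frags.starts[chrom] - 1) // 2
        dyads = cond.dyads[chrom]
        idx = np.searchsorted(dyads, mids)
        lo = np.clip(idx - 1, 0, len(dyads) - 1)
        hi = np.clip(idx, 0, len(dyads) - 1)
        dist = np.minimum(np.abs(dyads[lo] - mids), np.abs(dyads[hi] - mids))
        assert np.median(dist) <= 5
        assert (dist <= 20).mean() > 0.99


class TestCScoreTrack:
    def test_zero_amplitude_flat(self, small_landscape):
        track = sd.make_cscore_track(small_landscape, "A", amplitude=0.0,
                                     noise_sd=0.05, seed=1)
        v = track.values["chr1"]
        assert abs(v.mean()) < 0.01 and v.std() < 0.1

    def test_unknown_mode_rejected(self, small_landscape):
        with pytest.raises(ValidationError):
            sd.make_cscore_track(small_landscape, "A", modes="sideways")
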