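import numpy as np
import pytest

from chemnuc.feature_profiles import (
    PositionWeightMatrix,
    anchor_profile,
    detect_periodicity,
    dinucleotide_profile,
    kmeans_profiles,
    refine_motif_centers,
    stratify_by_expression,
    unique_count_difference,
)
from chemnuc.io_formats import (
    GenomeSequence,
    GenomicInterval,
    PointAnchor,
    ValidationError,
)
from chemnuc.nucleosome_maps import NucleosomeMap


def anchors_at(*positions, strand="+", chrom="chr1"):
    return [PointAnchor(chrom, p, strand, f"a{i}")
            for i, p in enumerate(positions)]


class TestAnchorProfile:
    def test_delta_track_gives_delta_at_zero(self):
        track = {"chr1": np.zeros(1000)}
        track["chr1"][[100, 500, 900]] = 1.0
        prof = anchor_profile(track, anchors_at(100, 500, 900), flank=50)
        mean = prof.mean_profile()
        assert mean[50] == 1.0
        assert mean[:50].sum() == 0 and mean[51:].sum() == 0

    def test_minus_strand_row_is_reversed(self):
        track = {"chr1": np.arange(100, dtype=float)}
        plus = anchor_profile(track, anchors_at(50), flank=5)
        minus = anchor_profile(track, anchors_at(50, strand="-"), flank=5)
        assert np.array_equal(minus.matrix[0], plus.matrix[0][::-1])

    def test_mean_is_hand_average(self):
        track = {"chr1": np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9.0])}
        prof = anchor_profile(track, anchors_at(3, 6), flank=1)
        assert np.allclose(prof.mean_profile(), [(2 + 5) / 2, (3 + 6) / 2,
                                                 (4 + 7) / 2])

    def test_out_of_range_anchor_dropped_and_counted(self):
        track = {"chr1": np.zeros(100)}
        prof = anchor_profile(track, anchors_at(2, 50), flank=10)
        assert prof.matrix.shape[0] == 1
        assert prof.n_dropped == 1

    def test_strand_randomized_on_symmetric_track(self):
        # a symmetric bump looks identical with and without orientation
        track = {"chr1": np.zeros(2000)}
        d = np.arange(-30, 31)
        for p in (300, 900, 1500):
            track["chr1"][p - 30: p + 31] += np.exp(-d ** 2 / 100)
        mixed = [PointAnchor("chr1", p, s, "x")
                 for p, s in [(300, "+"), (900, "-"), (1500, "+")]]
        unoriented = anchor_profile(track, mixed, 50, strand_aware=False)
        oriented = anchor_profile(track, mixed, 50, strand_aware=True)
        assert np.allclose(oriented.mean_profile(), unoriented.mean_profile())

    def test_all_out_of_range_is_error(self):
        with pytest.raises(ValidationError):
            anchor_profile({"chr1": np.zeros(10)}, anchors_at(5), flank=50)


class TestExpressionStrata:
    def test_zero_and_quartiles(self):
        anchors = anchors_at(10, 20, 30, 40, 50)
        fpkm = {f"a{i}": v for i, v in enumerate([0, 1, 2, 3, 4])}
        labels, missing, sizes = stratify_by_expression(anchors, fpkm)
        assert labels == ["no_expression", "Q1", "Q2", "Q3", "Q4"]
        assert missing == 0

    def test_all_zero_is_error(self):
        anchors = anchors_at(10, 20)
        with pytest.raises(ValidationError):
            stratify_by_expression(anchors, {"a0": 0.0, "a1": 0.0})

    def test_boundary_tie_goes_to_lower_group(self):
        anchors = anchors_at(*range(0, 80, 10))
        values = [1, 1, 1, 2, 2, 2, 3, 3]  # q25 == 1
        fpkm = {f"a{i}": v for i, v in enumerate(values)}
        labels, _, _ = stratify_by_expression(anchors, fpkm)
        assert all(lab == "Q1" for lab in labels[:3])

    def test_missing_fpkm_excluded_and_counted(self):
        anchors = anchors_at(10, 20, 30)
        labels, missing, _ = stratify_by_expression(
            anchors, {"a0": 1.0, "a2": 2.0})
        assert missing == 1 and labels[1] is None


class TestKmeans:
    def _two_archetype_matrix(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        width = 101
        base_a = np.sin(np.linspace(0, 3 * np.pi, width))
        base_b = np.cos(np.linspace(0, 2 * np.pi, width)) + 1.0
        rows, truth = [], []
        for i in range(n):
            kind = i % 2
            base = base_a if kind == 0 else base_b
            rows.append(base + 0.1 * rng.standard_normal(width))
            truth.append(kind)
        from chemnuc.feature_profiles import ProfileMatrix
        m = np.vstack(rows)
        return ProfileMatrix(m, np.ones_like(m, dtype=bool), 50), np.array(truth)

    def test_recovers_planted_archetypes(self):
        prof, truth = self._two_archetype_matrix()
        labels, _, dropped = kmeans_profiles(prof, k=2, seed=0)
        assert dropped == 0
        agreement = max((labels == truth).mean(), (labels != truth).mean())
        assert agreement >= 0.98

    def test_k1_centroid_is_column_mean(self):
        prof, _ = self._two_archetype_matrix(n=50)
        _, centroids, _ = kmeans_profiles(prof, k=1, seed=0)
        assert np.allclose(centroids[0], prof.matrix.mean(axis=0))

    def test_duplicate_rows_same_cluster(self):
        prof, _ = self._two_archetype_matrix(n=20)
        prof.matrix[3] = prof.matrix[1]
        labels, _, _ = kmeans_profiles(prof, k=2, seed=1)
        assert labels[3] == labels[1]

    def test_deterministic_for_seed(self):
        prof, _ = self._two_archetype_matrix()
        l1, c1, _ = kmeans_profiles(prof, k=3, seed=5)
        l2, c2, _ = kmeans_profiles(prof, k=3, seed=5)
        assert np.array_equal(l1, l2) and np.allclose(c1, c2)

    def test_too_few_rows_rejected(self):
        prof, _ = self._two_archetype_matrix(n=4)
        with pytest.raises(ValidationError):
            kmeans_profiles(prof, k=10)


class TestUniqueCountDifference:
    def _map(self, positions):
        pos = np.asarray(positions, dtype=np.int64)
        return NucleosomeMap("unique", {"chr1": pos},
                             {"chr1": np.ones(len(pos))})

    def test_identical_maps_all_zero(self):
        m = self._map([100, 300, 500])
        _, hist, mean = unique_count_difference(m, self._map([100, 300, 500]),
                                                anchors_at(300), flank=1000)
        assert hist == {0: 1} and mean == 0.0

    def test_one_extra_dyad_everywhere(self):
        a = self._map([100, 300, 500, 2100, 2300, 2500])
        b = self._map([100, 300, 2100, 2300])
        deltas, _, mean = unique_count_difference(
            a, b, anchors_at(300, 2300), flank=300)
        assert deltas.tolist() == [1, 1] and mean == 1.0

    def test_window_closed_on_both_ends(self):
        a = self._map([1000, 3000])  # exactly at pos -/+ flank
        b = self._map([999, 3001])   # just outside
        deltas, _, _ = unique_count_difference(a, b, anchors_at(2000),
                                               flank=1000)
        assert deltas.tolist() == [2]


class TestDinucleotideProfile:
    def test_all_A_genome(self):
        g = GenomeSequence({"chr1": "A" * 500})
        f = dinucleotide_profile(g, {"chr1": np.array([250])}, flank=50)
        assert np.all(f == 1.0)

    def test_cg_genome_zero(self):
        g = GenomeSequence({"chr1": "CG" * 250})
        f = dinucleotide_profile(g, {"chr1": np.array([250])}, flank=50)
        assert np.all(f == 0.0)

    def test_partition_sums_to_one(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        g = GenomeSequence({"chr1": seq})
        dyads = {"chr1": rng.integers(200, 1800, 50)}
        total = np.zeros(100)
        bases = "ACGT"
        for b1 in bases:
            for b2 in bases:
                total += dinucleotide_profile(g, dyads, 50, {b1 + b2})
        assert np.allclose(total, 1.0)

    def test_no_in_range_dyads_error(self):
        g = GenomeSequence({"chr1": "ACGT" * 10})
        with pytest.raises(ValidationError):
            dinucleotide_profile(g, {"chr1": np.array([20])}, flank=50)


class TestDetectPeriodicity:
    def test_pure_cosine(self):
        x = np.arange(0, 61)
        y = np.cos(2 * np.pi * (x - 5) / 10)
        res = detect_periodicity(y, period_range=(8, 12), x=x)
        assert res["period"] == pytest.approx(10, abs=0.2)
        assert res["phase"] == pytest.approx(5, abs=0.5)
        assert res["significant"]

    def test_flat_series_not_significant(self):
        res = detect_periodicity(np.ones(100), period_range=(8, 12))
        assert not res["significant"]

    def test_linker_histogram_from_mixture(self):
        from chemnuc.synthetic_data import LinkerMixture

        mix = LinkerMixture()
        draws = mix.sample(np.random.default_rng(3), 10_000)
        lo, hi = draws.min(), draws.max()
        hist = np.bincount(draws - lo)
        res = detect_periodicity(hist, period_range=(8, 12),
                                 x=np.arange(lo, hi + 1))
        assert abs(res["period"] - 10) <= 0.5
        assert min(abs(res["phase"] - 5), abs(res["phase"] - 5 - res["period"]),
                   abs(res["phase"] - 5 + res["period"])) <= 1.0

    def test_too_short_series_error(self):
        with pytest.raises(ValidationError):
            detect_periodicity(np.ones(10), period_range=(8, 12))


def brute_force_best_hit(seq: str, pwm: PositionWeightMatrix):
    """Independent scorer: every placement, both strands; ties (within float
    tolerance) go to the leftmost start with + before -."""
    comp = str.maketrans("ACGT", "TGCA")
    L = pwm.length
    lookup = {b: i for i, b in enumerate("ACGT")}
    scored = []
    for start in range(len(seq) - L + 1):
        window = seq[start:start + L]
        if any(b not in lookup for b in window):
            continue
        fwd = sum(pwm.log_odds[lookup[b], i] for i, b in enumerate(window))
        rc = window.translate(comp)[::-1]
        rev = sum(pwm.log_odds[lookup[b], i] for i, b in enumerate(rc))
        scored.append((start, "+", fwd))
        scored.append((start, "-", rev))
    top = max(s for _, _, s in scored)
    tol = 1e-9 * max(1.0, abs(top))
    for start, strand, score in sorted(
            scored, key=lambda t: (t[0], t[1] != "+")):
        if score >= top - tol:
            return score, start, strand
    raise AssertionError("unreachable")


class TestMotifRefinement:
    def _pwm_for(self, motif: str) -> PositionWeightMatrix:
        counts = np.ones((4, len(motif)))
        lookup = {b: i for i, b in enumerate("ACGT")}
        for i, b in enumerate(motif):
            counts[lookup[b], i] = 20
        return PositionWeightMatrix.from_pfm(counts)

    def test_forward_plant(self):
        genome = GenomeSequence({"chr1": "TTACGTT"})
        pwm = self._pwm_for("ACG")
        [a] = refine_motif_centers([GenomicInterval("chr1", 0, 7)], genome, pwm)
        assert a.pos == 3 and a.strand == "+"  # center of ACG at index 2+1

    def test_reverse_complement_plant_same_center(self):
        pwm = self._pwm_for("ACG")
        fwd = GenomeSequence({"chr1": "TTACGTT"})
        rc = GenomeSequence({"chr1": "TTCGTTT"})  # revcomp(ACG)=CGT at 2..4
        [a_f] = refine_motif_centers([GenomicInterval("chr1", 0, 7)], fwd, pwm)
        [a_r] = refine_motif_centers([GenomicInterval("chr1", 0, 7)], rc, pwm)
        assert a_r.pos == a_f.pos and a_r.strand == "-"

    def test_uniform_pwm_tie_leftmost_plus(self):
        pwm = PositionWeightMatrix.from_pfm(np.ones((4, 3)))
        genome = GenomeSequence({"chr1": "ACGTACGT"})
        [a] = refine_motif_centers([GenomicInterval("chr1", 0, 8)], genome, pwm)
        assert a.pos == 1 and a.strand == "+"

    def test_narrow_peak_skipped_with_warning(self):
        pwm = self._pwm_for("ACGTA")
        genome = GenomeSequence({"chr1": "ACGTACGTAC"})
        with pytest.warns(UserWarning, match="narrower"):
            out = refine_motif_centers([GenomicInterval("chr1", 0, 3)],
                                       genome, pwm)
        assert out == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_peaks(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(4, 9))
        counts = rng.integers(0, 30, size=(4, L)).astype(float)
        pwm = PositionWeightMatrix.from_pfm(counts)
        seq = "".join(rng.choice(list("ACGT"), 60))
        genome = GenomeSequence({"chr1": seq})
        [a] = refine_motif_centers([GenomicInterval("chr1", 5, 55)],
                                   genome, pwm)
        score, start, strand = brute_force_best_hit(seq[5:55], pwm)
        assert a.pos == 5 + start + L // 2
        assert a.strand == strand
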