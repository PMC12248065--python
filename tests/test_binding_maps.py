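import numpy as np
import pandas as pd
import pytest

from _oracles import fisher_two_tail_oracle, overlap_oracle
from apamap.binding_maps import (
    PASAnchor,
    binding_fraction_3utr,
    expressed_utrs,
    fisher_two_tailed,
    jaccard_overlap,
    peak_feature_fractions,
    positional_fisher,
    rna_map,
)
from apamap.io_core import GeneModel, GenomicInterval, Peak, PeakSet


def _peakset(intervals, tier="any"):
    return PeakSet("exp", [Peak(iv) for iv in intervals], tier=tier)


def _anchor(pos, strand="+", chrom="c", reads=np.inf):
    return PASAnchor(chrom, pos, strand, reads)


class TestBindingFraction:
    def _utrs(self, n=10):
        return [GenomicInterval("c", 100 * i, 100 * i + 50, "+")
                for i in range(n)]

    def test_all_covered(self):
        utrs = self._utrs()
        peaks = _peakset([GenomicInterval("c", 0, 2000, "+")])
        assert binding_fraction_3utr(peaks, utrs) == 1.0

    def test_no_peaks(self):
        assert binding_fraction_3utr(_peakset([]), self._utrs()) == 0.0

    def test_random_equals_brute_force(self):
        rng = np.random.default_rng(6)
        utrs = self._utrs(50)
        peaks = []
        for _ in range(60):
            s = int(rng.integers(0, 5000))
            peaks.append(GenomicInterval("c", s, s + int(rng.integers(1, 80)),
                                         str(rng.choice(["+", "-"]))))
        frac = binding_fraction_3utr(_peakset(peaks), utrs)
        hit = {j for _, j in overlap_oracle(peaks, utrs)}
        assert frac == len(hit) / len(utrs)

    def test_expressed_utr_filter_uses_median_tpm(self):
        genes = []
        for i, gid in enumerate(["hi", "lo"]):
            te = GenomicInterval("c", 1000 * i, 1000 * i + 200, "+")
            genes.append(GeneModel(gid, "c", "+", (1000 * i, 1000 * i + 200),
                                   {"terminal_exon": [te],
                                    "three_prime_utr": [te]}))
        tpm = pd.DataFrame({"gene_id": ["hi", "lo"],
                            "r1": [5.0, 0.2], "r2": [4.0, 3.0], "r3": [6.0, 0.1]})
        utrs = expressed_utrs(genes, tpm, threshold=1.0)
        assert [u.start for u in utrs] == [0]  # median of lo = 0.2 < 1


class TestFeatureFractions:
    def _gene(self):
        feats = {
            "terminal_exon": [GenomicInterval("c", 300, 500, "+")],
            "three_prime_utr": [GenomicInterval("c", 350, 500, "+")],
            "cds": [GenomicInterval("c", 100, 360, "+")],
            "intron": [GenomicInterval("c", 200, 250, "+")],
        }
        return GeneModel("g", "c", "+", (100, 500), feats)

    def test_priority_prefers_three_prime_utr(self):
        # peak overlapping CDS and 3'UTR is assigned to the 3'UTR class
        peaks = _peakset([GenomicInterval("c", 355, 365, "+")], "reproducible")
        frac = peak_feature_fractions(peaks, [self._gene()])
        assert frac["three_prime_utr"] == 1.0

    def test_intergenic_goes_to_other(self):
        peaks = _peakset([GenomicInterval("c", 9000, 9010, "+")], "reproducible")
        frac = peak_feature_fractions(peaks, [self._gene()])
        assert frac["other"] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        ivs = []
        for _ in range(50):
            s = int(rng.integers(0, 600))
            ivs.append(GenomicInterval("c", s, s + 10, "+"))
        frac = peak_feature_fractions(_peakset(ivs, "reproducible"),
                                      [self._gene()])
        assert np.isclose(frac.sum(), 1.0)


class TestRnaMap:
    def test_planted_peak_covers_expected_positions(self):
        anchors = [_anchor(1000)]
        peaks = _peakset([GenomicInterval("c", 950, 961, "+")])  # [-50,-40]
        prof = rna_map(peaks, anchors, window=(100, 100), min_anchor_reads=0)
        pos = prof.positions
        expected = ((pos >= -50) & (pos <= -40)).astype(float)
        assert np.array_equal(prof.values, expected)

    def test_no_peaks_all_zero(self):
        prof = rna_map(_peakset([]), [_anchor(1000)], window=(50, 50),
                       min_anchor_reads=0)
        assert not prof.values.any()

    def test_minus_strand_orientation_flipped(self):
        anchors = [_anchor(1000, strand="-")]
        # genomically downstream (higher coords) = transcript upstream on minus
        peaks = _peakset([GenomicInterval("c", 1040, 1051, "-")])
        prof = rna_map(peaks, anchors, window=(100, 100), min_anchor_reads=0)
        pos = prof.positions
        assert np.array_equal(np.flatnonzero(prof.values),
                              np.flatnonzero((pos >= -50) & (pos <= -40)))

    def test_read_support_filter(self):
        anchors = [_anchor(1000, reads=50), _anchor(3000, reads=200)]
        peaks = _peakset([GenomicInterval("c", 2990, 3011, "+")])
        prof = rna_map(peaks, anchors, window=(20, 20), min_anchor_reads=100)
        assert prof.n_anchors == 1
        assert prof.values.max() == 1.0

    def test_random_matches_per_position_oracle(self):
        rng = np.random.default_rng(8)
        anchors = [_anchor(int(rng.integers(500, 4000)),
                           str(rng.choice(["+", "-"]))) for _ in range(20)]
        ivs = []
        for _ in range(40):
            s = int(rng.integers(0, 4500))
            ivs.append(GenomicInterval("c", s, s + int(rng.integers(1, 60)),
                                       str(rng.choice(["+", "-"]))))
        up = down = 80
        prof = rna_map(_peakset(ivs), anchors, window=(up, down),
                       min_anchor_reads=0)
        for i, rel in enumerate(range(-up, down + 1)):
            n_hit = 0
            for a in anchors:
                g = a.position + (rel if a.strand == "+" else -rel)
                n_hit += any(iv.start <= g < iv.end and iv.strand == a.strand
                             for iv in ivs)
            assert prof.values[i] == n_hit / len(anchors)

    def test_invariant_to_peak_splitting(self):
        anchors = [_anchor(1000)]
        whole = _peakset([GenomicInterval("c", 950, 990, "+")])
        split = _peakset([GenomicInterval("c", 950, 970, "+"),
                          GenomicInterval("c", 970, 990, "+")])
        p1 = rna_map(whole, anchors, window=(100, 100), min_anchor_reads=0)
        p2 = rna_map(split, anchors, window=(100, 100), min_anchor_reads=0)
        assert np.array_equal(p1.values, p2.values)


class TestPositionalFisher:
    @pytest.mark.parametrize("k1,n1,k2,n2", [
        (10, 100, 5, 200),
        (0, 20, 0, 20),
        (20, 20, 0, 20),
        (3, 10, 7, 10),
        (5, 50, 20, 200),  # identical fractions
    ])
    def test_p_matches_enumeration_oracle(self, k1, n1, k2, n2):
        assert fisher_two_tailed(k1, n1, k2, n2) == pytest.approx(
            fisher_two_tail_oracle(k1, n1, k2, n2), rel=1e-9)

    def test_identical_fractions_give_p_one(self):
        assert fisher_two_tailed(5, 50, 20, 200) == pytest.approx(1.0)

    def test_complete_separation_closed_form(self):
        from math import comb
        p = fisher_two_tailed(20, 20, 0, 20)
        assert p == pytest.approx(2 / comb(40, 20), rel=1e-9)

    def test_zero_bound_convention(self):
        assert fisher_two_tailed(0, 30, 0, 10) == 1.0

    def test_planted_offset_recovered(self):
        rng = np.random.default_rng(5)
        reg, ctl, ivs = [], [], []
        for i in range(60):
            pos = 2000 + 3000 * i
            reg.append(_anchor(pos))
            off = -50 + int(rng.integers(-10, 11))
            ivs.append(GenomicInterval("c", pos + off - 15, pos + off + 16, "+"))
        for i in range(60):
            ctl.append(_anchor(1000000000 + 3000 * i))
        heat = positional_fisher(_peakset(ivs), reg, ctl, window=(150, 50))
        argmax = heat.positions[np.argmax(heat.signed_neglog10_p)]
        assert abs(argmax - (-50)) <= 10
        # depletion positions (none here) would be signed negative
        assert heat.signed_neglog10_p.max() > 10

    def test_input_validation(self):
        a = [_anchor(100)]
        with pytest.raises(ValueError, match="non-empty"):
            positional_fisher(_peakset([]), a, [], window=(10, 10))
        with pytest.raises(ValueError, match="share"):
            positional_fisher(_peakset([]), a, list(a), window=(10, 10))


class TestJaccard:
    def test_identical_sets(self):
        ps = _peakset([GenomicInterval("c", 0, 100, "+")])
        assert jaccard_overlap(ps, ps) == 1.0

    def test_disjoint_sets(self):
        a = _peakset([GenomicInterval("c", 0, 100, "+")])
        b = _peakset([GenomicInterval("c", 200, 300, "+")])
        assert jaccard_overlap(a, b) == 0.0

    def test_half_overlap_arithmetic(self):
        a = _peakset([GenomicInterval("c", 0, 100, "+")])
        b = _peakset([GenomicInterval("c", 50, 150, "+")])
        assert jaccard_overlap(a, b) == pytest.approx(1 / 3)

    def test_stranded(self):
        a = _peakset([GenomicInterval("c", 0, 100, "+")])
        b = _peakset([GenomicInterval("c", 0, 100, "-")])
        assert jaccard_overlap(a, b) == 0.0

    def test_internal_merging(self):
        a = _peakset([GenomicInterval("c", 0, 60, "+"),
                      GenomicInterval("c", 40, 100, "+")])
        b = _peakset([GenomicInterval("c", 0, 100, "+")])
        assert jaccard_overlap(a, b) == 1.0
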