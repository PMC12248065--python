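import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import cluster_scan_oracle, overlap_oracle
from apamap.endseq_clustering import (
    EndCluster,
    apply_filters,
    assign_pas,
    call_clusters,
    filter_a_content,
    filter_a_run,
    filter_hexamer,
    filter_reference,
)
from apamap.io_core import GenomicInterval, reverse_complement
from conftest import reads_from_coverage


def make_cluster(coverage, chrom="chrT", strand="+", start=100, counts=None):
    cov = np.asarray(coverage, dtype=int)
    cl = EndCluster(
        GenomicInterval(chrom, start, start + cov.size, strand), cov,
        counts or {"s1": int(cov.sum())}, int(cov.sum()))
    cl.pas_position = assign_pas(cl)
    return cl


class TestCallClusters:
    @pytest.mark.parametrize("coverage,expected", [
        # (start offset, end offset, total) of retained clusters
        ([0, 12, 15, 11, 0], [(1, 4, 38)]),
        ([0, 11, 11, 0], [(1, 3, 22)]),
        ([0, 11, 8, 11, 0], []),  # two 11-read runs, both below 20 total
        ([10, 10, 10], []),  # "more than 10" is strict
        ([], []),
    ])
    def test_threshold_examples(self, coverage, expected):
        reads = reads_from_coverage(coverage)
        got = [(c.interval.start - 100, c.interval.end - 100, c.total_reads)
               for c in call_clusters(reads)]
        assert got == expected

    def test_empty_input(self):
        assert call_clusters({}) == []

    def test_pooling_across_samples(self):
        """Cluster definition pools coverage over every sample."""
        a = reads_from_coverage([6, 6, 6], sample="a")
        b = reads_from_coverage([6, 6, 6], sample="b")
        merged = {**a, **b}
        clusters = call_clusters(merged)
        assert len(clusters) == 1
        assert clusters[0].counts == {"a": 18, "b": 18}
        assert call_clusters(a) == []

    @given(st.lists(st.integers(min_value=0, max_value=100),
                    min_size=20, max_size=200))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_scan_oracle(self, coverage):
        reads = reads_from_coverage(coverage)
        got = [(c.interval.start - 100, c.interval.end - 100, c.total_reads)
               for c in call_clusters(reads)]
        assert got == cluster_scan_oracle(coverage)

    def test_per_strand_separation(self):
        plus = reads_from_coverage([15] * 3, strand="+", sample="a")
        minus = reads_from_coverage([15] * 3, strand="-", sample="b")
        clusters = call_clusters({**plus, **minus})
        assert sorted(c.interval.strand for c in clusters) == ["+", "-"]


class TestAssignPas:
    def test_tie_goes_to_three_prime_most_on_plus(self):
        cl = make_cluster([12, 30, 30, 11], strand="+")
        assert cl.pas_position == 100 + 2

    def test_tie_goes_to_three_prime_most_on_minus(self):
        cl = make_cluster([12, 30, 30, 11], strand="-")
        assert cl.pas_position == 100 + 1

    def test_single_position(self):
        cl = make_cluster([25])
        assert cl.pas_position == 100


class TestARunFilter:
    def _genome_with_downstream(self, downstream, strand="+", width=4):
        """Cluster at [100, 104) with given sense-downstream sequence."""
        if strand == "+":
            seq = "C" * 104 + downstream + "C" * 20
        else:
            seq = "C" * (100 - len(downstream)) + reverse_complement(downstream) + "C" * 24
        return {"chrT": seq}

    def test_seven_a_removed_six_kept(self):
        for downstream, flagged in [("AAAAAAAC", True), ("AAAAAAC", False)]:
            cl = make_cluster([20, 20, 20, 25])  # PAS at 103
            genome = self._genome_with_downstream(downstream)
            assert filter_a_run(cl, genome) is flagged

    def test_minus_strand_uses_sense_adenosines(self):
        """7 sense A appear as 7 T upstream on the reference strand."""
        cl = make_cluster([25, 20, 20, 20], strand="-")  # PAS at 100
        genome = self._genome_with_downstream("AAAAAAAG", strand="-")
        assert filter_a_run(cl, genome) is True
        genome = self._genome_with_downstream("AAAAAAGG", strand="-")
        assert filter_a_run(cl, genome) is False


class TestAContentFilter:
    def test_boundary_counts(self):
        for window, flagged in [("AAAAAAAAGC", True), ("AAAAAAAGGC", False)]:
            cl = make_cluster([20, 20])
            genome = {"chrT": "C" * 102 + window + "C" * 10}
            assert filter_a_content(cl, genome) is flagged

    def test_random_windows_match_counting_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            window = "".join(rng.choice(list("ACGT"), size=10))
            cl = make_cluster([20, 20])
            genome = {"chrT": "C" * 102 + window + "C" * 10}
            assert filter_a_content(cl, genome) is (window.count("A") > 7)


class TestHexamerFilter:
    def test_contained_hexamer_kept_and_recorded(self):
        genome = {"chrT": "C" * 100 + "GGAATAAAGG" + "C" * 20}
        cl = make_cluster([20] * 10)
        assert filter_hexamer(cl, genome) is False
        assert cl.hexamer_found == "AAUAAA"

    def test_no_hexamer_removed(self):
        genome = {"chrT": "C" * 140}
        cl = make_cluster([20] * 10)
        assert filter_hexamer(cl, genome) is True
        assert cl.hexamer_found == "none"

    def test_straddling_hexamer_needs_upstream_margin(self):
        """A hexamer starting 2 nt before the cluster is rejected under
        strict containment (margin 0) but found with the default margin."""
        genome = {"chrT": "C" * 98 + "AATAAA" + "C" * 40}
        cl = make_cluster([20] * 10)  # cluster [100, 110)
        assert filter_hexamer(cl, genome, upstream_margin=0) is True
        assert filter_hexamer(cl, genome) is False

    def test_minus_strand_scans_sense(self):
        # sense AATAAA = reference TTTATT for a minus-strand cluster
        genome = {"chrT": "C" * 102 + "TTTATT" + "C" * 20}
        cl = make_cluster([20] * 10, strand="-")
        assert filter_hexamer(cl, genome) is False


class TestReferenceFilter:
    def test_one_nt_overlap_kept(self):
        cl = make_cluster([20, 20])  # [100, 102)
        ref = [GenomicInterval("chrT", 101, 120, "+")]
        assert filter_reference([cl], ref) == [False]

    def test_empty_reference_flags_all_and_warns(self):
        cl = make_cluster([20, 20])
        with pytest.warns(UserWarning, match="empty reference"):
            assert filter_reference([cl], []) == [True]

    def test_strand_mismatch_not_kept(self):
        cl = make_cluster([20, 20], strand="+")
        ref = [GenomicInterval("chrT", 100, 102, "-")]
        assert filter_reference([cl], ref) == [True]

    def test_random_against_all_pairs_oracle(self):
        rng = np.random.default_rng(4)
        clusters = [make_cluster([20, 20], start=int(rng.integers(0, 500)),
                                 strand=str(rng.choice(["+", "-"])))
                    for _ in range(40)]
        refs = []
        for _ in range(30):
            s = int(rng.integers(0, 500))
            refs.append(GenomicInterval("chrT", s, s + int(rng.integers(1, 30)),
                                        str(rng.choice(["+", "-"]))))
        flags = filter_reference(clusters, refs)
        hits = overlap_oracle([c.interval for c in clusters], refs)
        overlapped = {i for i, _ in hits}
        assert [i not in overlapped for i in range(len(clusters))] == flags


class TestFilterBattery:
    def test_filters_are_order_independent(self, scenario):
        from apamap.synthetic_data import reference_pas_records
        genome = scenario["genome"]
        ref = reference_pas_records(scenario["truth"])
        clusters = scenario["clusters"][:40]
        baseline = None
        steps = {
            "a_run": lambda cl: filter_a_run(cl, genome),
            "a_content": lambda cl: filter_a_content(cl, genome),
            "hexamer": lambda cl: filter_hexamer(cl, genome),
        }
        for order in itertools.permutations(steps):
            for cl in clusters:
                for name in order:
                    steps[name](cl)
            filter_reference(clusters, ref)
            surviving = tuple(cl.survives for cl in clusters)
            if baseline is None:
                baseline = surviving
            assert surviving == baseline

    def test_planted_recovery(self, scenario):
        """Every true PAS yields exactly one surviving cluster within 5 nt;
        every decoy is removed by an internal-priming filter."""
        truth = scenario["truth"]
        surviving = scenario["surviving"]
        true_pas = [(gt.chrom, p.position, gt.strand)
                    for gt in truth.genes.values() for p in gt.pas]
        surv_pos = [(c.interval.chrom, c.pas_position, c.interval.strand)
                    for c in surviving]
        assert len(surviving) == len(true_pas)
        for chrom, pos, strand in true_pas:
            matches = [p for c, p, s in surv_pos
                       if c == chrom and s == strand and abs(p - pos) <= 5]
            assert len(matches) == 1
        decoys = {(gt.chrom, gt.decoy_position, gt.strand)
                  for gt in truth.genes.values()
                  if gt.decoy_position is not None}
        removed_by_a = [c for c in scenario["clusters"]
                        if c.filter_flags["a_run_fail"]
                        or c.filter_flags["a_content_fail"]]
        for chrom, pos, strand in decoys:
            assert any(c.interval.chrom == chrom
                       and c.interval.strand == strand
                       and abs(c.pas_position - pos) <= 5
                       for c in removed_by_a)
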