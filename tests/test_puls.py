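import pytest

from rumencaz.model import BinQcRecord
from rumencaz.puls import (
    detect_puls,
    extend_pul,
    find_sus_pairs,
    merge_puls,
    summarize_puls,
)

from conftest import make_contig_genes


def _qc(bin_id):
    return BinQcRecord(bin_id, 1_000_000, 48.0, 5, 90.0, 2.0, 0.0, "Bacteroidetes")


class TestFindSusPairs:
    def test_adjacent_pair(self):
        genes, anns = make_contig_genes("c1", ["SusC", "SusD"])
        assert find_sus_pairs(genes, anns) == [(genes[0].gene_id, genes[1].gene_id)]

    def test_reversed_order_pairs_too(self):
        genes, anns = make_contig_genes("c1", ["SusD", "SusC"])
        assert find_sus_pairs(genes, anns) == [(genes[1].gene_id, genes[0].gene_id)]

    def test_gap_rule_boundary(self):
        genes, anns = make_contig_genes("c1", ["SusC", "GH2", "SusD"])
        assert find_sus_pairs(genes, anns, max_pair_gap_genes=0) == []
        assert find_sus_pairs(genes, anns, max_pair_gap_genes=1) == [
            (genes[0].gene_id, genes[2].gene_id)
        ]

    def test_lone_susc_makes_no_pair(self):
        genes, anns = make_contig_genes("c1", ["SusC", "GH2", "GH5"])
        assert find_sus_pairs(genes, anns) == []

    def test_susd_like_counts_as_susd(self):
        genes, anns = make_contig_genes("c1", ["SusC", "SusD-like_3"])
        assert len(find_sus_pairs(genes, anns)) == 1

    def test_each_gene_in_at_most_one_pair(self):
        genes, anns = make_contig_genes("c1", ["SusC", "SusD", "SusD"])
        pairs = find_sus_pairs(genes, anns, max_pair_gap_genes=1)
        assert pairs == [(genes[0].gene_id, genes[1].gene_id)]


class TestExtendPul:
    def test_flanking_cazymes_join(self):
        genes, anns = make_contig_genes(
            "c1", [None, "GH2", "SusC", "SusD", "GH43", None]
        )
        (pair,) = find_sus_pairs(genes, anns)
        pul = extend_pul(pair, genes, anns)
        assert pul.member_gene_ids == [g.gene_id for g in genes[1:5]]
        assert sorted(set(pul.cazyme_families) - {"SusC", "SusD"}) == ["GH2", "GH43"]

    def test_bare_pair_stays_bare(self):
        genes, anns = make_contig_genes("c1", [None] * 6 + ["SusC", "SusD"] + [None] * 6)
        (pair,) = find_sus_pairs(genes, anns)
        pul = extend_pul(pair, genes, anns)
        assert pul.member_gene_ids == [genes[6].gene_id, genes[7].gene_id]
        assert pul.n_unknown_function == 0

    def test_interior_unknowns_kept_and_counted(self):
        genes, anns = make_contig_genes(
            "c1", ["SusC", "SusD", None, None, "GH43"]
        )
        (pair,) = find_sus_pairs(genes, anns)
        pul = extend_pul(pair, genes, anns)
        assert len(pul.member_gene_ids) == 5
        assert pul.n_unknown_function == 2

    def test_extension_stops_after_window(self):
        layout = ["SusC", "SusD"] + [None] * 5 + ["GH43"]
        genes, anns = make_contig_genes("c1", layout)
        (pair,) = find_sus_pairs(genes, anns)
        assert len(extend_pul(pair, genes, anns, window_genes=5).member_gene_ids) == 2
        assert len(extend_pul(pair, genes, anns, window_genes=6).member_gene_ids) == 8

    def test_window_monotonicity(self):
        layout = ["GH5", None, None, "SusC", "SusD", None, "CE6", None, None, None, "GH43"]
        genes, anns = make_contig_genes("c1", layout)
        (pair,) = find_sus_pairs(genes, anns)
        sizes = [
            len(extend_pul(pair, genes, anns, window_genes=w).member_gene_ids)
            for w in range(1, 8)
        ]
        assert sizes == sorted(sizes)

    def test_multi_pair_locus_merges_with_families(self):
        layout = (
            [None] * 6
            + ["SusC", "SusD", "SusC", "SusD", None, "CE6", "GH10", "GH43", "GH67", "GH5"]
            + [None] * 6
        )
        genes, anns = make_contig_genes("c1", layout)
        puls = detect_puls(genes, anns)
        assert len(puls) == 1
        (pul,) = puls
        assert len(pul.sus_pairs) == 2
        for fam in ("CE6", "GH10", "GH43", "GH67", "GH5"):
            assert fam in pul.cazyme_families
        assert pul.n_unknown_function == 1  # the unannotated gene inside


class TestMergePuls:
    def test_distant_loci_stay_distinct(self):
        layout = (
            ["SusC", "SusD", "GH2"]
            + [None] * 20
            + ["SusC", "SusD", "GH43"]
        )
        genes, anns = make_contig_genes("c1", layout)
        puls = detect_puls(genes, anns)
        assert len(puls) == 2

    def test_adjacent_loci_merge(self):
        layout = ["SusC", "SusD", "GH2", None, "GH43", "SusD", "SusC"]
        genes, anns = make_contig_genes("c1", layout)
        puls = detect_puls(genes, anns, merge_gap_genes=2)
        assert len(puls) == 1
        assert len(puls[0].sus_pairs) == 2

    def test_merge_gap_monotone_in_locus_count(self):
        layout = (
            ["SusC", "SusD", "GH2"]
            + [None] * 4
            + ["GH43", "SusC", "SusD"]
            + [None] * 9
            + ["SusD", "SusC", "CE6"]
        )
        genes, anns = make_contig_genes("c1", layout)
        counts = [
            len(detect_puls(genes, anns, merge_gap_genes=gap, window_genes=3))
            for gap in range(0, 12)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_input(self):
        genes, _ = make_contig_genes("c1", [None, None])
        assert merge_puls([], genes) == []

    def test_every_pul_keeps_a_sus_pair(self, clean_dataset):
        dataset, _ = clean_dataset
        from rumencaz.classify import annotate

        anns = annotate(dataset.domain_hits, dataset.genes)
        for pul in detect_puls(dataset.genes, anns, bin_map=dataset.bin_map):
            assert len(pul.sus_pairs) >= 1


class TestSummarizePuls:
    def test_min_max_mean(self):
        genes, anns = make_contig_genes("c1", ["SusC", "SusD"])
        pul = detect_puls(genes, anns, bin_map={"c1": "b1"})[0]
        import copy

        others = []
        for i in range(2):
            q = copy.deepcopy(pul)
            q.bin_id = "b2"
            others.append(q)
        summary = summarize_puls([pul] + others, bins=[_qc("b1"), _qc("b2"), _qc("b3")])
        assert summary.per_bin == {"b1": 1, "b2": 2, "b3": 0}
        assert summary.min_puls == 1 and summary.max_puls == 2
        assert summary.mean_puls == pytest.approx(1.5)

    def test_single_bin_stats_collapse(self):
        genes, anns = make_contig_genes("c1", ["SusC", "SusD"])
        puls = detect_puls(genes, anns, bin_map={"c1": "b1"})
        s = summarize_puls(puls)
        assert s.min_puls == s.max_puls == s.mean_puls == 1

    def test_no_puls_anywhere(self):
        s = summarize_puls([], bins=[_qc("b1")])
        assert s.per_bin == {"b1": 0}
        assert s.mean_puls == 0.0
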