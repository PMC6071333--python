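import pytest

from rumencaz.bins import (
    abundance,
    bin_cazyme_matrix,
    build_bin_profiles,
    cellulosome_screen,
    qc_gate,
)
from rumencaz.classify import annotate
from rumencaz.model import BinQcRecord

from conftest import make_contig_genes


def _qc(bin_id, completeness, contamination):
    return BinQcRecord(bin_id, 2_000_000, 48.0, 10, completeness, contamination, 0.0)


class TestQcGate:
    @pytest.mark.parametrize(
        "completeness,contamination,retained",
        [
            (60.0, 5.0, True),
            (85.0, 15.0, False),   # complete but too contaminated
            (50.0, 5.0, False),    # boundary is strict
            (50.1, 9.9, True),
            (60.0, 10.0, False),   # boundary is strict
        ],
    )
    def test_strict_thresholds(self, completeness, contamination, retained):
        (profile,) = qc_gate([_qc("b1", completeness, contamination)])
        assert profile.retained is retained

    def test_relaxing_gate_is_monotone(self):
        records = [
            _qc(f"b{i}", c, x)
            for i, (c, x) in enumerate(
                [(45, 2), (55, 2), (75, 12), (95, 5), (51, 9)]
            )
        ]
        strict = {p.bin_id for p in qc_gate(records, 70, 5) if p.retained}
        default = {p.bin_id for p in qc_gate(records) if p.retained}
        assert strict <= default


class TestAbundance:
    def test_raw_mode_fractions(self):
        out = abundance(
            {"b1": 900, "b2": 100}, {"b1": 1_000_000, "b2": 1_000_000},
            total_reads=100_000, mode="raw",
        )
        assert out["b1"] == pytest.approx(0.9)
        assert out["b2"] == pytest.approx(0.1)

    def test_per_bp_rescales_by_size(self):
        sizes = {"big": 2_000_000, "small": 1_000_000}
        reads = {"big": 500, "small": 500}
        raw = abundance(reads, sizes, 100_000, mode="raw")
        norm = abundance(reads, sizes, 100_000, mode="per_bp")
        assert raw["big"] == raw["small"]
        # equal read counts on half the genome -> twice the normalized score
        assert norm["small"] == pytest.approx(2 * norm["big"])

    def test_zero_reads_zero_abundance(self):
        out = abundance({"b1": 0}, {"b1": 1_000_000}, 1000, mode="raw")
        assert out["b1"] == 0.0

    def test_missing_size_is_an_error(self):
        with pytest.raises(ValueError, match="b2"):
            abundance({"b2": 10}, {"b1": 1_000_000}, 1000)

    def test_raw_mode_sums_below_100(self, clean_dataset):
        dataset, _ = clean_dataset
        sizes = {b.bin_id: b.size_bp for b in dataset.bin_qc}
        out = abundance(dataset.read_counts, sizes, dataset.total_reads, mode="raw")
        assert sum(out.values()) <= 100.0 + 1e-9


class TestBinCazymeMatrix:
    def test_planted_category_counts(self):
        genes, anns = make_contig_genes("c1", ["GH5", "GH5", "GH10"])
        anns = annotate(
            [h for a in anns for h in a.retained_hits], genes
        )
        cat_df, fam_df = bin_cazyme_matrix(anns, genes, {"c1": "b1"})
        assert cat_df.loc["b1", "cellulases"] == 2
        assert cat_df.loc["b1", "endohemicellulases"] == 1
        assert fam_df.loc["b1", "GH5"] == 2

    def test_bin_without_ghs_has_zero_row(self):
        genes, anns = make_contig_genes("c1", ["CE1", None])
        anns = annotate([h for a in anns for h in a.retained_hits], genes)
        cat_df, _ = bin_cazyme_matrix(anns, genes, {"c1": "b1"})
        assert (cat_df.loc["b1"] == 0).all()

    def test_fibrolytic_bin_lacks_debranching_signal(self):
        # cellulases + hemicellulases planted, no debranching families
        layout = ["GH5", "GH9", "GH45", "GH74", "GH8", "GH10", "GH11", "GH26", "GH53"]
        genes, anns = make_contig_genes("c1", layout)
        anns = annotate([h for a in anns for h in a.retained_hits], genes)
        cat_df, _ = bin_cazyme_matrix(anns, genes, {"c1": "fib"})
        assert cat_df.loc["fib", "cellulases"] == 4
        assert cat_df.loc["fib", "endohemicellulases"] == 5
        assert cat_df.loc["fib", "debranching"] == 0
        assert cat_df.loc["fib", "oligosaccharide_degrading"] == 0

    def test_binwise_gh_counts_bounded_by_global(self, clean_dataset):
        dataset, _ = clean_dataset
        anns = annotate(dataset.domain_hits, dataset.genes)
        _, fam_df = bin_cazyme_matrix(anns, dataset.genes, dataset.bin_map)
        global_gh = sum(
            1
            for a in anns
            if any(f.startswith("GH") for f in a.distinct_families)
        )
        binned = fam_df.drop(index="unassigned", errors="ignore")
        assert int(binned.sum().sum()) <= sum(
            len([f for f in a.distinct_families if f.startswith("GH")]) for a in anns
        )
        assert int(fam_df.max(axis=None)) <= global_gh


class TestCellulosomeScreen:
    def test_planted_component_counts(self):
        layout = (
            [["GH5", "dockerin"]]
            + [["dockerin"]] * 20
            + [["cohesin", "cohesin", "cohesin"]]
            + [["cohesin"]] * 3
            + ["SLH"]
        )
        genes, anns = make_contig_genes("c1", layout)
        anns = annotate([h for a in anns for h in a.retained_hits], genes)
        screen = cellulosome_screen(anns, genes, {"c1": "b81"})
        entry = screen["b81"]
        assert entry["n_dockerin"] == 21
        assert entry["n_cohesin"] == 4
        assert entry["n_SLH"] == 1
        assert entry["n_scaffoldin_candidates"] == 1
        assert entry["gh_dockerin_fusions"] == 1
        assert entry["tandem_cohesin_proteins"][0][1] == 3

    def test_empty_bin_is_all_zero(self):
        genes, _ = make_contig_genes("c1", [None, None])
        screen = cellulosome_screen([], genes, {"c1": "b1"})
        assert screen["b1"]["n_dockerin"] == 0
        assert screen["b1"]["tandem_cohesin_proteins"] == []


def test_build_bin_profiles_end_to_end(clean_dataset):
    dataset, truth = clean_dataset
    anns = annotate(dataset.domain_hits, dataset.genes)
    profiles = build_bin_profiles(
        dataset.bin_qc,
        anns,
        dataset.genes,
        dataset.bin_map,
        read_counts=dataset.read_counts,
        total_reads=dataset.total_reads,
    )
    by_bin = {p.bin_id: p for p in profiles}
    for bin_id, expected in truth.class_counts_by_bin.items():
        if bin_id == "unassigned":
            continue
        assert by_bin[bin_id].per_class_counts == expected
    fib = by_bin["fib_1"]
    assert fib.n_dockerin == 0 and fib.n_cohesin == 0
    firm = by_bin["firm_1"]
    assert firm.n_scaffoldin_candidates == len(
        [k for k in truth.families_by_protein.values() if k.count("cohesin") >= 2]
    )
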