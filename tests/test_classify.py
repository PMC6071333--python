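import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rumencaz.classify import (
    annotate,
    call_scaffoldins,
    categorize_gh,
    classify,
    filter_hits,
    resolve_overlaps,
)
from rumencaz.families import SubstrateCategoryMap
from rumencaz.model import GeneRecord

from conftest import make_hit


class TestFilterHits:
    @pytest.mark.parametrize(
        "ali_len,e_value,coverage,kept",
        [
            (100, 1e-6, 0.40, True),   # long alignment under the strict cutoff
            (100, 1.0, 0.10, False),   # fails both gates
            (80, 1e-4, 0.50, True),    # at the length boundary: lenient regime
            (81, 1e-4, 0.50, False),   # one residue longer: strict regime
            (100, 1e-6, 0.29, False),  # coverage just below the gate
            (100, 1e-6, 0.30, True),   # coverage exactly at the gate
            (50, 1e-3, 0.90, True),    # short-regime cutoff is inclusive
            (200, 1e-5, 0.90, True),   # long-regime cutoff is inclusive
        ],
    )
    def test_two_regime_gate(self, ali_len, e_value, coverage, kept):
        hit = make_hit(
            ali_start=1, ali_end=ali_len, e_value=e_value, model_coverage=coverage
        )
        assert (filter_hits([hit]) == [hit]) is kept

    def test_idempotent(self):
        hits = [
            make_hit("p1", "GH5", e_value=1e-6),
            make_hit("p1", "GH9", e_value=1e-2),
            make_hit("p2", "CE1", model_coverage=0.1),
        ]
        once = filter_hits(hits)
        assert filter_hits(once) == once

    def test_empty_in_empty_out(self):
        assert filter_hits([]) == []


class TestResolveOverlaps:
    def test_single_hit_retained(self):
        h = make_hit()
        assert resolve_overlaps([h]) == [h]

    def test_overlapping_hits_keep_lower_evalue(self):
        better = make_hit("p1", "GH5", e_value=1e-10, ali_start=1, ali_end=100)
        worse = make_hit("p1", "GH9", e_value=1e-5, ali_start=50, ali_end=150)
        assert resolve_overlaps([worse, better]) == [better]

    def test_disjoint_hits_both_survive(self):
        a = make_hit("p1", "GH5", ali_start=1, ali_end=100)
        b = make_hit("p1", "CBM6", ali_start=120, ali_end=200, e_value=1e-8)
        kept = resolve_overlaps([a, b])
        assert set(kept) == {a, b}
        (ann,) = classify(kept)
        assert ann.is_multidomain

    def test_no_overlapping_pair_remains(self):
        rng = random.Random(5)
        hits = [
            make_hit(
                f"p{rng.randrange(4)}",
                "GH5",
                e_value=rng.random(),
                ali_start=(s := rng.randrange(1, 300)),
                ali_end=s + rng.randrange(10, 120),
            )
            for _ in range(120)
        ]
        kept = resolve_overlaps(hits)
        per_protein = {}
        for h in kept:
            per_protein.setdefault(h.protein_id, []).append(h)
        for phits in per_protein.values():
            for i, a in enumerate(phits):
                for b in phits[i + 1 :]:
                    assert a.ali_end < b.ali_start or b.ali_end < a.ali_start

    @given(st.permutations(range(8)))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_under_input_permutation(self, order):
        base = [
            make_hit(
                "p1",
                fam,
                e_value=e,
                ali_start=start,
                ali_end=start + 60,
            )
            for fam, e, start in [
                ("GH5", 1e-12, 1),
                ("GH9", 1e-9, 40),
                ("CBM6", 1e-8, 120),
                ("CE1", 1e-7, 150),
                ("GH43", 1e-6, 300),
                ("GT2", 1e-5, 320),
                ("PL1", 1e-4, 500),
                ("AA6", 1e-4, 510),
            ]
        ]
        shuffled = [base[i] for i in order]
        assert resolve_overlaps(shuffled) == resolve_overlaps(base)


class TestClassify:
    def test_primary_class_is_best_evalue(self):
        gh = make_hit("p1", "GH5", e_value=1e-20, ali_start=1, ali_end=100)
        cbm = make_hit("p1", "CBM6", e_value=1e-8, ali_start=150, ali_end=250)
        (ann,) = classify([gh, cbm])
        assert ann.primary_class == "GH"
        assert ann.is_multidomain

    def test_dockerin_only_protein(self):
        (ann,) = classify([make_hit("p1", "dockerin")])
        assert ann.primary_class == "cellulosome"
        assert ann.has_dockerin and not ann.has_cohesin

    def test_gh_dockerin_fusion_flags(self):
        hits = [
            make_hit("p1", "GH13", e_value=1e-15, ali_start=1, ali_end=100),
            make_hit("p1", "dockerin", e_value=1e-6, ali_start=150, ali_end=200),
        ]
        (ann,) = classify(hits)
        assert ann.primary_class == "GH"
        assert ann.has_dockerin

    def test_unknown_protein_raises(self):
        gene = GeneRecord("g1", "c1", 1, 900, "+", 0, 299)
        with pytest.raises(ValueError, match="p9"):
            classify([make_hit("p9")], [gene])

    def test_tandem_cohesin_count(self):
        hits = [
            make_hit("p1", "cohesin", ali_start=1 + 100 * i, ali_end=90 + 100 * i)
            for i in range(3)
        ]
        (ann,) = classify(hits)
        assert ann.n_tandem_cohesins == 3


class TestCategorizeGh:
    @pytest.mark.parametrize(
        "family,category",
        [
            ("GH5", "cellulases"),
            ("GH43", "oligosaccharide_degrading"),
            ("GH28", "endohemicellulases"),
            ("GH78", "debranching"),
            ("GH57", "uncategorized"),
        ],
    )
    def test_default_map(self, family, category):
        anns = classify([make_hit("p1", family)])
        assert categorize_gh(anns) == {"p1": category}

    def test_best_evalue_gh_decides(self):
        hits = [
            make_hit("p1", "GH43", e_value=1e-30, ali_start=1, ali_end=100),
            make_hit("p1", "GH5", e_value=1e-10, ali_start=150, ali_end=250),
        ]
        assert categorize_gh(classify(hits)) == {"p1": "oligosaccharide_degrading"}

    def test_non_gh_protein_omitted(self):
        anns = classify([make_hit("p1", "CE1")])
        assert categorize_gh(anns) == {}

    def test_overlapping_categories_rejected(self):
        with pytest.raises(ValueError):
            SubstrateCategoryMap({"a": {"GH5"}, "b": {"GH5"}})


class TestCallScaffoldins:
    def test_score_cutoff_boundary(self):
        scores = {"p1": ("CipA", 750.0), "p2": ("CipA", 699.0)}
        calls = call_scaffoldins([], template_scores=scores)
        assert [(c.protein_id, c.mode) for c in calls] == [("p1", "score_cutoff")]

    def test_multi_cohesin_route(self):
        hits = [
            make_hit("p1", "cohesin", ali_start=1 + 100 * i, ali_end=90 + 100 * i)
            for i in range(3)
        ]
        calls = call_scaffoldins(classify(hits))
        assert [(c.protein_id, c.mode, c.evidence) for c in calls] == [
            ("p1", "multi_cohesin", 3)
        ]

    def test_single_cohesin_not_called(self):
        assert call_scaffoldins(classify([make_hit("p1", "cohesin")])) == []


def test_full_cascade_is_permutation_invariant(noisy_dataset):
    dataset, _ = noisy_dataset
    hits = list(dataset.domain_hits)
    rng = random.Random(3)
    rng.shuffle(hits)
    assert annotate(hits) == annotate(dataset.domain_hits)
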