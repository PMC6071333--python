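"""Genome-wide CAZyme census: per-class/per-family counts, densities and
fraction-of-ORF statistics.

The census counts proteins by their primary class so that class percentages
sum over proteins; family-level counts are per sequence per family (a
protein with two distinct families contributes to both family tallies, once
each), matching how family totals are reported in metagenome comparisons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

from .model import CazymeAnnotation, ContigRecord, GeneRecord


@dataclass
class CazymeCensus:
    n_orfs_total: int = 0
    n_cazyme_proteins: int = 0
    per_class_counts: Dict[str, int] = field(default_factory=dict)
    per_family_counts: Dict[str, int] = field(default_factory=dict)
    n_multidomain: int = 0
    assembled_mbp: float = 0.0
    gh_per_mbp: float = 0.0
    pct_cazyme_of_orfs: float = 0.0
    pct_gh_of_orfs: float = 0.0
    per_class_pct_of_cazymes: Dict[str, float] = field(default_factory=dict)
    n_full_length: int = 0
    pct_full_length: float = 0.0
    db_match_counts: Dict[str, Tuple[int, float]] = field(default_factory=dict)


def density(count: int, assembled_bp: int) -> float:
    """Features per Mbp of assembled sequence (unrounded)."""
    if assembled_bp <= 0:
        raise ValueError("assembled_bp must be positive")
    return count / (assembled_bp / 1e6)


def fraction_report(
    numerators: Mapping[str, int], denominator: int
) -> Dict[str, Tuple[int, float]]:
    """Counts and percentages over a named denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return {
        label: (n, 100.0 * n / denominator) for label, n in numerators.items()
    }


def census(
    annotations: Iterable[CazymeAnnotation],
    genes: Iterable[GeneRecord],
    assembled_bp: int,
    min_contig_bp: int = 0,
    contigs: Optional[Mapping[str, ContigRecord]] = None,
    db_matches: Optional[Mapping[str, int]] = None,
) -> CazymeCensus:
    """Summarize a CAZyme annotation set against its ORF universe.

    When ``min_contig_bp`` > 0, genes (and their annotations) on contigs
    shorter than the cutoff are excluded first; this requires ``contigs``
    for the length lookup.  Densities and percentages are kept unrounded;
    display rounding (1 decimal) is the writer's concern.
    """
    if assembled_bp <= 0:
        raise ValueError("assembled_bp must be positive")
    genes = list(genes)
    if min_contig_bp > 0:
        if contigs is None:
            raise ValueError("min_contig_bp filtering requires contig records")
        genes = [
            g for g in genes if contigs[g.contig_id].length_bp >= min_contig_bp
        ]
    gene_ids = {g.gene_id for g in genes}
    anns = [a for a in annotations if a.protein_id in gene_ids]

    class_counts: Counter = Counter()
    family_counts: Counter = Counter()
    n_multi = 0
    for a in anns:
        if a.primary_class == "none":
            continue
        class_counts[a.primary_class] += 1
        for fam in sorted(a.distinct_families):
            family_counts[fam] += 1
        if a.is_multidomain:
            n_multi += 1

    n_caz = sum(class_counts.values())
    n_orfs = len(genes)
    n_full = sum(1 for g in genes if g.is_full_length)
    mbp = assembled_bp / 1e6
    gh_count = class_counts.get("GH", 0)

    result = CazymeCensus(
        n_orfs_total=n_orfs,
        n_cazyme_proteins=n_caz,
        per_class_counts=dict(class_counts),
        per_family_counts=dict(family_counts),
        n_multidomain=n_multi,
        assembled_mbp=mbp,
        gh_per_mbp=gh_count / mbp,
        pct_cazyme_of_orfs=100.0 * n_caz / n_orfs if n_orfs else 0.0,
        pct_gh_of_orfs=100.0 * gh_count / n_orfs if n_orfs else 0.0,
        per_class_pct_of_cazymes={
            cls: 100.0 * n / n_caz for cls, n in class_counts.items()
        }
        if n_caz
        else {},
        n_full_length=n_full,
        pct_full_length=100.0 * n_full / n_orfs if n_orfs else 0.0,
    )
    if db_matches and n_orfs:
        result.db_match_counts = fraction_report(db_matches, n_orfs)
    return result


def census_to_rows(c: CazymeCensus, denominator_label: str = "all ORFs"):
    """Flatten a census into (section, key, count, value) display rows with
    1-decimal rounding; the percentage denominator is named explicitly."""
    rows = [
        ("summary", "n_orfs_total", c.n_orfs_total, ""),
        ("summary", "n_cazyme_proteins", c.n_cazyme_proteins, ""),
        ("summary", "n_multidomain", c.n_multidomain, ""),
        ("summary", "assembled_mbp", "", round(c.assembled_mbp, 1)),
        ("summary", "gh_per_mbp", "", round(c.gh_per_mbp, 1)),
        ("summary", f"pct_cazyme_of_{denominator_label}", "", round(c.pct_cazyme_of_orfs, 1)),
        ("summary", f"pct_gh_of_{denominator_label}", "", round(c.pct_gh_of_orfs, 1)),
        ("summary", "n_full_length", c.n_full_length, round(c.pct_full_length, 1)),
    ]
    for cls in sorted(c.per_class_counts):
        rows.append(
            ("class", cls, c.per_class_counts[cls], round(c.per_class_pct_of_cazymes[cls], 1))
        )
    for fam in sorted(c.per_family_counts):
        rows.append(("family", fam, c.per_family_counts[fam], ""))
    return rows
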