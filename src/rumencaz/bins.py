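"""Per-genome-bin profiling: QC gating, relative abundance, substrate
capability matrices and cellulosome-potential screening.

Genome bins (metagenome-assembled genomes) arrive with externally computed
completeness/contamination estimates and taxonomy labels; this module gates
them, normalizes read-mapping abundance by bin size, and aggregates the
CAZyme annotation per bin.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import pandas as pd

from .families import SubstrateCategoryMap, UNCATEGORIZED, family_class
from .classify import categorize_gh
from .model import BinQcRecord, CazymeAnnotation, GeneRecord

#: QC gate defaults: strictly more complete than 50%, strictly less than
#: 10% contaminated.
MIN_COMPLETENESS = 50.0
MAX_CONTAMINATION = 10.0


@dataclass
class BinProfile:
    qc: BinQcRecord
    retained: bool
    abundance_pct: float = 0.0
    n_genes: int = 0
    per_class_counts: Dict[str, int] = field(default_factory=dict)
    per_family_counts: Dict[str, int] = field(default_factory=dict)
    substrate_matrix_row: Dict[str, int] = field(default_factory=dict)
    n_dockerin: int = 0
    n_cohesin: int = 0
    n_SLH: int = 0
    n_scaffoldin_candidates: int = 0
    gh_dockerin_fusions: int = 0

    @property
    def bin_id(self) -> str:
        return self.qc.bin_id


def qc_gate(
    bins: Iterable[BinQcRecord],
    min_completeness: float = MIN_COMPLETENESS,
    max_contamination: float = MAX_CONTAMINATION,
) -> List[BinProfile]:
    """Flag bins passing the QC gate (strict inequalities on both sides)."""
    return [
        BinProfile(
            qc=b,
            retained=(
                b.completeness > min_completeness
                and b.contamination < max_contamination
            ),
        )
        for b in bins
    ]


def abundance(
    read_counts: Mapping[str, int],
    bin_sizes: Mapping[str, int],
    total_reads: int,
    mode: str = "per_bp",
) -> Dict[str, float]:
    """Relative abundance (%) per bin from mapped-read counts.

    ``raw`` mode is the plain mapped-read fraction.  ``per_bp`` mode
    rescales each bin's read fraction by (mean bin size / bin size), so
    equally covered bins of different sizes score equally — the
    size-normalization applied when bins of very different lengths are
    compared.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if mode not in ("per_bp", "raw"):
        raise ValueError(f"unknown abundance mode {mode!r}")
    for bin_id in read_counts:
        if bin_id not in bin_sizes:
            raise ValueError(f"bin {bin_id!r} has reads but no recorded size")
        if bin_sizes[bin_id] <= 0:
            raise ValueError(f"bin {bin_id!r} has non-positive size")
    sizes = [bin_sizes[b] for b in read_counts]
    mean_size = sum(sizes) / len(sizes) if sizes else 0.0
    out: Dict[str, float] = {}
    for bin_id, reads in read_counts.items():
        frac = 100.0 * reads / total_reads
        if mode == "per_bp":
            frac *= mean_size / bin_sizes[bin_id]
        out[bin_id] = frac
    return out


def _bin_of_protein(
    genes: Iterable[GeneRecord], bin_map: Mapping[str, str]
) -> Dict[str, str]:
    return {g.gene_id: bin_map.get(g.contig_id, "unassigned") for g in genes}


def bin_cazyme_matrix(
    annotations: Iterable[CazymeAnnotation],
    genes: Iterable[GeneRecord],
    bin_map: Mapping[str, str],
    category_map: Optional[SubstrateCategoryMap] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Bin x substrate-category and bin x GH-family count matrices.

    Returns ``(category_matrix, family_matrix)`` with bins as rows.  Only
    categorized GH proteins contribute to the category matrix; the family
    matrix covers every GH family observed.
    """
    category_map = category_map or SubstrateCategoryMap()
    genes = list(genes)
    annotations = list(annotations)
    protein_bin = _bin_of_protein(genes, bin_map)
    categories = categorize_gh(annotations, category_map)
    cat_counts: Dict[str, Counter] = defaultdict(Counter)
    fam_counts: Dict[str, Counter] = defaultdict(Counter)
    for ann in annotations:
        bin_id = protein_bin.get(ann.protein_id, "unassigned")
        cat = categories.get(ann.protein_id)
        if cat is not None and cat != UNCATEGORIZED:
            cat_counts[bin_id][cat] += 1
        for fam in sorted(ann.distinct_families):
            if family_class(fam) == "GH":
                fam_counts[bin_id][fam] += 1
    all_bins = sorted(set(bin_map.values()) | set(cat_counts) | set(fam_counts))
    cat_df = pd.DataFrame(
        [[cat_counts[b].get(c, 0) for c in category_map.names()] for b in all_bins],
        index=all_bins,
        columns=category_map.names(),
        dtype=int,
    )
    fams = sorted({f for c in fam_counts.values() for f in c})
    fam_df = pd.DataFrame(
        [[fam_counts[b].get(f, 0) for f in fams] for b in all_bins],
        index=all_bins,
        columns=fams,
        dtype=int,
    )
    return cat_df, fam_df


def cellulosome_screen(
    annotations: Iterable[CazymeAnnotation],
    genes: Iterable[GeneRecord],
    bin_map: Mapping[str, str],
) -> Dict[str, dict]:
    """Per-bin cellulosome-component tallies.

    For each bin: counts of dockerin-, cohesin- and SLH-bearing proteins,
    tandem-cohesin scaffoldin candidates (>= 2 cohesin domains, listed with
    their domain counts), and GH+dockerin fusion proteins.
    """
    protein_bin = _bin_of_protein(genes, bin_map)
    out: Dict[str, dict] = {}
    for bin_id in sorted(set(bin_map.values())):
        out[bin_id] = {
            "n_dockerin": 0,
            "n_cohesin": 0,
            "n_SLH": 0,
            "n_scaffoldin_candidates": 0,
            "gh_dockerin_fusions": 0,
            "tandem_cohesin_proteins": [],
        }
    for ann in annotations:
        bin_id = protein_bin.get(ann.protein_id, "unassigned")
        entry = out.setdefault(
            bin_id,
            {
                "n_dockerin": 0,
                "n_cohesin": 0,
                "n_SLH": 0,
                "n_scaffoldin_candidates": 0,
                "gh_dockerin_fusions": 0,
                "tandem_cohesin_proteins": [],
            },
        )
        if ann.has_dockerin:
            entry["n_dockerin"] += 1
        if ann.has_cohesin:
            entry["n_cohesin"] += 1
        if ann.has_SLH:
            entry["n_SLH"] += 1
        if ann.n_tandem_cohesins >= 2:
            entry["n_scaffoldin_candidates"] += 1
            entry["tandem_cohesin_proteins"].append(
                (ann.protein_id, ann.n_tandem_cohesins)
            )
        has_gh = any(family_class(f) == "GH" for f in ann.families)
        if has_gh and ann.has_dockerin:
            entry["gh_dockerin_fusions"] += 1
    return out


def build_bin_profiles(
    bins: Iterable[BinQcRecord],
    annotations: Iterable[CazymeAnnotation],
    genes: Iterable[GeneRecord],
    bin_map: Mapping[str, str],
    read_counts: Optional[Mapping[str, int]] = None,
    total_reads: Optional[int] = None,
    category_map: Optional[SubstrateCategoryMap] = None,
    min_completeness: float = MIN_COMPLETENESS,
    max_contamination: float = MAX_CONTAMINATION,
    abundance_mode: str = "per_bp",
) -> List[BinProfile]:
    """Assemble full per-bin profiles (QC, abundance, CAZyme census)."""
    genes = list(genes)
    annotations = list(annotations)
    profiles = qc_gate(bins, min_completeness, max_contamination)
    abund: Dict[str, float] = {}
    if read_counts is not None and total_reads:
        sizes = {p.bin_id: p.qc.size_bp for p in profiles}
        abund = abundance(read_counts, sizes, total_reads, abundance_mode)
    protein_bin = _bin_of_protein(genes, bin_map)
    class_counts: Dict[str, Counter] = defaultdict(Counter)
    family_counts: Dict[str, Counter] = defaultdict(Counter)
    for ann in annotations:
        b = protein_bin.get(ann.protein_id, "unassigned")
        class_counts[b][ann.primary_class] += 1
        for fam in sorted(ann.distinct_families):
            family_counts[b][fam] += 1
    cat_df, _ = bin_cazyme_matrix(annotations, genes, bin_map, category_map)
    screen = cellulosome_screen(annotations, genes, bin_map)
    genes_per_bin = Counter(protein_bin.values())
    for p in profiles:
        b = p.bin_id
        p.abundance_pct = abund.get(b, 0.0)
        p.n_genes = genes_per_bin.get(b, 0)
        p.per_class_counts = dict(class_counts.get(b, {}))
        p.per_family_counts = dict(family_counts.get(b, {}))
        if b in cat_df.index:
            p.substrate_matrix_row = {
                c: int(cat_df.loc[b, c]) for c in cat_df.columns
            }
        cs = screen.get(b)
        if cs:
            p.n_dockerin = cs["n_dockerin"]
            p.n_cohesin = cs["n_cohesin"]
            p.n_SLH = cs["n_SLH"]
            p.n_scaffoldin_candidates = cs["n_scaffoldin_candidates"]
            p.gh_dockerin_fusions = cs["gh_dockerin_fusions"]
    return profiles
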