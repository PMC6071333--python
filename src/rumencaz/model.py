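"""Core record types shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Set, Tuple

UNASSIGNED = "unassigned"

#: Taxonomic ranks in canonical order, domain to species.
RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


@dataclass(frozen=True)
class ContigRecord:
    """An assembled contig/scaffold; only header-level metadata is kept."""

    contig_id: str
    length_bp: int
    gc_fraction: Optional[float] = None
    bin_id: str = UNASSIGNED

    def __post_init__(self):
        if self.length_bp < 1:
            raise ValueError(f"contig {self.contig_id}: length_bp must be >= 1")


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene call on a contig (1-based inclusive bp)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    rank_on_contig: int
    protein_length_aa: int
    gene_symbols: frozenset = frozenset()
    is_full_length: bool = True

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end < start")
        if self.protein_length_aa < 1:
            raise ValueError(f"gene {self.gene_id}: protein_length_aa must be >= 1")


def gene_sort_key(gene: GeneRecord) -> Tuple[int, int, str]:
    """Deterministic within-contig ordering: start, then end, then gene_id."""
    return (gene.start, gene.end, gene.gene_id)


@dataclass(frozen=True)
class DomainHit:
    """One HMM-profile match on a protein.

    ``model_coverage`` is the fraction of the HMM model spanned by the
    alignment, the dbCAN-style query-coverage statistic used for filtering.
    """

    protein_id: str
    family_id: str
    e_value: float
    bit_score: float
    ali_start: int
    ali_end: int
    model_coverage: float
    hmm_start: int = 1
    hmm_end: Optional[int] = None
    hmm_length: Optional[int] = None

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        if self.ali_end < self.ali_start:
            raise ValueError("ali_end must be >= ali_start")

    @property
    def ali_length(self) -> int:
        return self.ali_end - self.ali_start + 1


@dataclass(frozen=True)
class SimilarityHit:
    """A protein similarity-search hit carrying a taxonomic lineage.

    ``lineage`` is an ordered list of ``(rank, taxon)`` pairs from
    superkingdom down to (at most) species; it may be truncated at any depth.
    """

    protein_id: str
    subject_id: str
    bit_score: float
    e_value: float
    lineage: Tuple[Tuple[str, str], ...]

    def __post_init__(self):
        depth = -1
        for rank, _ in self.lineage:
            try:
                idx = RANKS.index(rank)
            except ValueError:
                raise ValueError(f"unknown rank {rank!r} in lineage")
            if idx <= depth:
                raise ValueError("lineage ranks out of order")
            depth = idx


@dataclass
class BinQcRecord:
    """QC and provenance metadata for one genome bin."""

    bin_id: str
    size_bp: int
    gc_percent: float
    n_contigs: int
    completeness: float
    contamination: float
    strain_heterogeneity: float
    taxonomy_label: str = ""

    def __post_init__(self):
        if self.size_bp <= 0:
            raise ValueError(f"bin {self.bin_id}: size_bp must be positive")
        if not (0 <= self.completeness <= 100):
            raise ValueError(f"bin {self.bin_id}: completeness outside [0,100]")
        if self.contamination < 0:
            raise ValueError(f"bin {self.bin_id}: contamination must be >= 0")


@dataclass
class CazymeAnnotation:
    """A protein's retained CAZyme domains and derived classification."""

    protein_id: str
    retained_hits: List[DomainHit] = field(default_factory=list)
    families: List[str] = field(default_factory=list)
    primary_class: str = "none"
    is_multidomain: bool = False
    has_dockerin: bool = False
    has_cohesin: bool = False
    n_tandem_cohesins: int = 0
    has_SLH: bool = False

    @property
    def distinct_families(self) -> Set[str]:
        return set(self.families)


@dataclass(frozen=True)
class ScaffoldinCall:
    """A candidate cellulosomal scaffoldin protein.

    ``mode`` records the evidence route: ``score_cutoff`` (iterative
    similarity search against known scaffoldin templates, score above the
    cutoff) or ``multi_cohesin`` (two or more cohesin domains on one
    protein).
    """

    protein_id: str
    mode: str
    evidence: float
    template_id: Optional[str] = None
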