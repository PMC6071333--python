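"""Polysaccharide utilization locus (PUL) detection.

A PUL is a cluster of physically linked genes anchored on a tandem
SusC-SusD gene pair (the TonB-dependent transporter and glycan-binding
lipoprotein of the starch utilization system) together with nearby
CAZyme-encoding genes.  Detection proceeds in three steps:

1. ``find_sus_pairs`` — scan each contig for SusC/SusD genes separated by at
   most a configurable number of intervening genes, pairing greedily left to
   right (each gene joins at most one pair).
2. ``extend_pul`` — walk outward from the pair, recruiting CAZyme genes
   (GH/CE/PL/CBM/Sus) and the interior genes between them; extension stops
   in a direction once ``window_genes`` consecutive non-CAZyme genes are
   seen.
3. ``merge_puls`` — loci on one contig whose member ranks come within
   ``merge_gap_genes`` of one another are merged into multi-pair loci.

Strand is ignored for pairing and extension but reported per member.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .families import family_class, is_susc, is_susd
from .model import UNASSIGNED, BinQcRecord, CazymeAnnotation, GeneRecord

logger = logging.getLogger(__name__)

#: Default locus parameters.
MAX_PAIR_GAP_GENES = 0
WINDOW_GENES = 5
MERGE_GAP_GENES = 2

#: Classes whose genes are recruited during extension.
EXTENSION_CLASSES = frozenset({"GH", "CE", "PL", "CBM", "Sus"})


@dataclass
class PUL:
    pul_id: str
    contig_id: str
    bin_id: str = UNASSIGNED
    member_gene_ids: List[str] = field(default_factory=list)
    sus_pairs: List[Tuple[str, str]] = field(default_factory=list)
    cazyme_families: List[str] = field(default_factory=list)
    span: Tuple[int, int] = (0, 0)
    n_unknown_function: int = 0
    first_rank: int = 0
    last_rank: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.member_gene_ids)


@dataclass
class PulSummary:
    per_bin: Dict[str, int]
    min_puls: float
    max_puls: float
    mean_puls: float


def _genes_by_contig(genes: Iterable[GeneRecord]) -> Dict[str, List[GeneRecord]]:
    by_contig: Dict[str, List[GeneRecord]] = defaultdict(list)
    for g in genes:
        by_contig[g.contig_id].append(g)
    for contig in by_contig.values():
        contig.sort(key=lambda g: g.rank_on_contig)
    return by_contig


def _ann_index(annotations: Iterable[CazymeAnnotation]) -> Dict[str, CazymeAnnotation]:
    return {a.protein_id: a for a in annotations}


def _has_susc(ann: Optional[CazymeAnnotation]) -> bool:
    return ann is not None and any(is_susc(f) for f in ann.families)


def _has_susd(ann: Optional[CazymeAnnotation]) -> bool:
    return ann is not None and any(is_susd(f) for f in ann.families)


def _is_extension_cazyme(ann: Optional[CazymeAnnotation]) -> bool:
    return ann is not None and any(
        family_class(f) in EXTENSION_CLASSES for f in ann.families
    )


def find_sus_pairs(
    genes: Iterable[GeneRecord],
    annotations: Iterable[CazymeAnnotation],
    max_pair_gap_genes: int = MAX_PAIR_GAP_GENES,
) -> List[Tuple[str, str]]:
    """Find tandem SusC-SusD gene pairs per contig.

    A pair is a SusC gene and a SusD gene (SusD-like profiles count as
    SusD) on the same contig with at most ``max_pair_gap_genes`` genes
    between them, in either order; pairing is greedy left to right and each
    gene joins at most one pair.  Pairs are returned as
    ``(susC_gene_id, susD_gene_id)``.
    """
    ann = _ann_index(annotations)
    by_contig = _genes_by_contig(genes)
    pairs: List[Tuple[str, str]] = []
    for contig_id in sorted(by_contig):
        contig = by_contig[contig_id]
        used = [False] * len(contig)
        for i, gi in enumerate(contig):
            if used[i]:
                continue
            ai = ann.get(gi.gene_id)
            i_is_c, i_is_d = _has_susc(ai), _has_susd(ai)
            if not (i_is_c or i_is_d):
                continue
            for j in range(i + 1, min(i + 2 + max_pair_gap_genes, len(contig))):
                if used[j]:
                    continue
                aj = ann.get(contig[j].gene_id)
                if i_is_c and _has_susd(aj):
                    pairs.append((gi.gene_id, contig[j].gene_id))
                elif i_is_d and _has_susc(aj):
                    pairs.append((contig[j].gene_id, gi.gene_id))
                else:
                    continue
                used[i] = used[j] = True
                break
    return pairs


def extend_pul(
    pair: Tuple[str, str],
    genes: Iterable[GeneRecord],
    annotations: Iterable[CazymeAnnotation],
    window_genes: int = WINDOW_GENES,
    bin_map: Optional[Mapping[str, str]] = None,
    pul_id: str = "PUL",
) -> PUL:
    """Grow a locus outward from a SusC-SusD pair.

    A gene joins the locus if it is CAZyme-annotated (GH/CE/PL/CBM/Sus) or
    lies between the pair and a joining gene; extension stops in a direction
    after ``window_genes`` consecutive non-CAZyme genes.  Interior genes
    without a CAZyme annotation are kept and counted as unknown-function.
    """
    gene_list = list(genes)
    ann = _ann_index(annotations)
    by_id = {g.gene_id: g for g in gene_list}
    contig_id = by_id[pair[0]].contig_id
    contig = _genes_by_contig(gene_list)[contig_id]
    pos = {g.gene_id: idx for idx, g in enumerate(contig)}
    lo, hi = sorted((pos[pair[0]], pos[pair[1]]))

    def _walk(start: int, step: int) -> int:
        edge = start
        pending = 0
        idx = start + step
        while 0 <= idx < len(contig) and pending < window_genes:
            if _is_extension_cazyme(ann.get(contig[idx].gene_id)):
                edge = idx
                pending = 0
            else:
                pending += 1
            idx += step
        return edge

    lo = _walk(lo, -1)
    hi = _walk(hi, +1)
    members = contig[lo : hi + 1]
    families: List[str] = []
    n_unknown = 0
    for g in members:
        a = ann.get(g.gene_id)
        if a is None or not a.families:
            n_unknown += 1
        else:
            families.extend(a.families)
    bin_id = (bin_map or {}).get(contig_id, UNASSIGNED)
    return PUL(
        pul_id=pul_id,
        contig_id=contig_id,
        bin_id=bin_id,
        member_gene_ids=[g.gene_id for g in members],
        sus_pairs=[pair],
        cazyme_families=sorted(families),
        span=(min(g.start for g in members), max(g.end for g in members)),
        n_unknown_function=n_unknown,
        first_rank=members[0].rank_on_contig,
        last_rank=members[-1].rank_on_contig,
    )


def merge_puls(
    puls: Sequence[PUL],
    genes: Iterable[GeneRecord],
    merge_gap_genes: int = MERGE_GAP_GENES,
) -> List[PUL]:
    """Merge loci on one contig separated by <= ``merge_gap_genes`` genes.

    Merging takes the union of members and Sus pairs; inputs on distinct
    contigs are never merged.
    """
    if not puls:
        return []
    by_contig_genes = _genes_by_contig(genes)
    by_contig: Dict[str, List[PUL]] = defaultdict(list)
    for p in puls:
        by_contig[p.contig_id].append(p)
    merged: List[PUL] = []
    for contig_id in sorted(by_contig):
        contig = by_contig_genes[contig_id]
        ordered = sorted(by_contig[contig_id], key=lambda p: p.first_rank)
        current = ordered[0]
        for nxt in ordered[1:]:
            if nxt.first_rank - current.last_rank - 1 <= merge_gap_genes:
                lo, hi = current.first_rank, max(current.last_rank, nxt.last_rank)
                members = contig[lo : hi + 1]
                current = PUL(
                    pul_id=current.pul_id,
                    contig_id=contig_id,
                    bin_id=current.bin_id,
                    member_gene_ids=[g.gene_id for g in members],
                    sus_pairs=current.sus_pairs + nxt.sus_pairs,
                    cazyme_families=sorted(
                        current.cazyme_families + nxt.cazyme_families
                    ),
                    span=(min(g.start for g in members), max(g.end for g in members)),
                    n_unknown_function=0,  # recomputed below
                    first_rank=lo,
                    last_rank=hi,
                )
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    return merged


def _recount_unknown(
    puls: List[PUL], annotations: Iterable[CazymeAnnotation]
) -> None:
    ann = _ann_index(annotations)
    for p in puls:
        p.n_unknown_function = sum(
            1
            for gid in p.member_gene_ids
            if gid not in ann or not ann[gid].families
        )


def detect_puls(
    genes: Iterable[GeneRecord],
    annotations: Iterable[CazymeAnnotation],
    bin_map: Optional[Mapping[str, str]] = None,
    max_pair_gap_genes: int = MAX_PAIR_GAP_GENES,
    window_genes: int = WINDOW_GENES,
    merge_gap_genes: int = MERGE_GAP_GENES,
    merge: bool = True,
) -> List[PUL]:
    """Full detection: pair scan, extension, and (optionally) merging."""
    gene_list = list(genes)
    ann_list = list(annotations)
    pairs = find_sus_pairs(gene_list, ann_list, max_pair_gap_genes)
    puls = [
        extend_pul(pair, gene_list, ann_list, window_genes, bin_map)
        for pair in pairs
    ]
    if merge:
        puls = merge_puls(puls, gene_list, merge_gap_genes)
    _recount_unknown(puls, ann_list)
    for i, p in enumerate(puls, start=1):
        p.pul_id = f"PUL_{i:04d}"
    return puls


def summarize_puls(
    puls: Sequence[PUL],
    bins: Optional[Iterable[BinQcRecord]] = None,
) -> PulSummary:
    """Per-bin PUL counts with min/max/mean over bins holding >= 1 PUL.

    Bins supplied via ``bins`` but holding no PUL are listed explicitly
    with a zero count.
    """
    per_bin: Dict[str, int] = {}
    if bins is not None:
        for b in bins:
            per_bin[b.bin_id] = 0
    for p in puls:
        per_bin[p.bin_id] = per_bin.get(p.bin_id, 0) + 1
    nonzero = [n for n in per_bin.values() if n > 0]
    if not nonzero:
        logger.info("no PULs detected in any bin")
        return PulSummary(per_bin=per_bin, min_puls=0.0, max_puls=0.0, mean_puls=0.0)
    return PulSummary(
        per_bin=per_bin,
        min_puls=float(min(nonzero)),
        max_puls=float(max(nonzero)),
        mean_puls=sum(nonzero) / len(nonzero),
    )
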