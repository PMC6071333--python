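"""Lowest-common-ancestor (LCA) taxonomy for CAZyme ORFs.

Each protein's similarity hits (pre-filtered upstream at e <= 1e-3, at most
20 per protein) are reduced to the hits within a bit-score band of the best
hit (MEGAN-style "top percent" filter, default 10%), and the protein is
assigned to the deepest taxon shared by all retained lineages.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .classify import categorize_gh
from .families import SubstrateCategoryMap, UNCATEGORIZED
from .model import RANKS, UNASSIGNED, CazymeAnnotation, SimilarityHit

TOP_PERCENT = 10.0


@dataclass(frozen=True)
class TaxonAssignment:
    protein_id: str
    lineage: Tuple[Tuple[str, str], ...]
    assigned_rank: str

    def taxon_at(self, rank: str) -> Optional[str]:
        for r, name in self.lineage:
            if r == rank:
                return name
        return None


def lca(
    hits: Sequence[SimilarityHit],
    top_percent: float = TOP_PERCENT,
    min_hits: int = 1,
) -> TaxonAssignment:
    """Assign one protein by the LCA of its retained similarity hits.

    Hits scoring at least ``(1 - top_percent/100)`` of the best bit score
    are retained; the assignment is the deepest rank at which every
    retained lineage agrees.  With no hits (or fewer than ``min_hits``
    retained) the protein is unassigned.
    """
    hits = list(hits)
    if not hits:
        return TaxonAssignment("", (), UNASSIGNED)
    protein_id = hits[0].protein_id
    best = max(h.bit_score for h in hits)
    retained = [h for h in hits if h.bit_score >= (1 - top_percent / 100.0) * best]
    if len(retained) < min_hits:
        return TaxonAssignment(protein_id, (), UNASSIGNED)
    prefix = list(retained[0].lineage)
    for h in retained[1:]:
        depth = 0
        for a, b in zip(prefix, h.lineage):
            if a != b:
                break
            depth += 1
        del prefix[depth:]
        if not prefix:
            break
    if not prefix:
        return TaxonAssignment(protein_id, (), UNASSIGNED)
    return TaxonAssignment(protein_id, tuple(prefix), prefix[-1][0])


def assign_all(
    hits_by_protein: Mapping[str, Sequence[SimilarityHit]],
    top_percent: float = TOP_PERCENT,
    min_hits: int = 1,
) -> Dict[str, TaxonAssignment]:
    return {
        pid: lca(hits_by_protein[pid], top_percent, min_hits)
        for pid in sorted(hits_by_protein)
    }


def taxon_breakdown(
    assignments: Mapping[str, TaxonAssignment],
    annotations: Iterable[CazymeAnnotation],
    category_map: Optional[SubstrateCategoryMap] = None,
    rank: str = "phylum",
) -> pd.DataFrame:
    """Percent contribution of each taxon to each GH substrate category.

    For each category, percentages are taken over all proteins in the
    category; proteins lacking an assignment at the requested rank fall in
    an explicit ``unassigned`` row, so each column sums to 100 (up to
    rounding).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    category_map = category_map or SubstrateCategoryMap()
    annotations = list(annotations)
    categories = categorize_gh(annotations, category_map)
    counts: Dict[str, Dict[str, int]] = defaultdict(lambda: defaultdict(int))
    totals: Dict[str, int] = defaultdict(int)
    for pid, cat in categories.items():
        if cat == UNCATEGORIZED:
            continue
        assignment = assignments.get(pid)
        taxon = assignment.taxon_at(rank) if assignment else None
        counts[cat][taxon if taxon is not None else UNASSIGNED] += 1
        totals[cat] += 1
    taxa = sorted({t for c in counts.values() for t in c} - {UNASSIGNED})
    rows = taxa + [UNASSIGNED]
    cats = category_map.names()
    data = []
    for taxon in rows:
        data.append(
            [
                100.0 * counts[cat].get(taxon, 0) / totals[cat] if totals[cat] else 0.0
                for cat in cats
            ]
        )
    return pd.DataFrame(data, index=rows, columns=cats)
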