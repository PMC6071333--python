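"""Per-protein CAZyme annotation from HMM domain hits.

The annotation cascade mirrors the dbCAN-style post-processing used in rumen
metagenome surveys:

1. ``filter_hits`` — keep hits with model coverage >= 30% and an e-value
   below a length-dependent cutoff (1e-5 for alignments longer than 80
   residues, 1e-3 for shorter ones).
2. ``resolve_overlaps`` — per protein, sort by e-value and greedily keep the
   best hit in each alignment region, so multi-domain proteins retain all
   their non-overlapping domains.
3. ``classify`` — derive a single primary class per protein (for census
   percentages that sum to ~100) plus the full domain inventory, cellulosome
   flags (dockerin/cohesin/SLH) and tandem-cohesin counts.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .families import CLASS_PRIORITY, UNCATEGORIZED, SubstrateCategoryMap, family_class
from .model import CazymeAnnotation, DomainHit, GeneRecord, ScaffoldinCall

#: Default filtering thresholds.
COVERAGE_MIN = 0.30
EVALUE_LONG = 1e-5
EVALUE_SHORT = 1e-3
LENGTH_THRESHOLD = 80

#: Scaffoldin template-score cutoff for the similarity-search route.
SCAFFOLDIN_SCORE_THRESHOLD = 700.0


def filter_hits(
    hits: Iterable[DomainHit],
    coverage_min: float = COVERAGE_MIN,
    evalue_long: float = EVALUE_LONG,
    evalue_short: float = EVALUE_SHORT,
    length_threshold: int = LENGTH_THRESHOLD,
) -> List[DomainHit]:
    """Apply the coverage and two-regime e-value gates.

    A hit is retained iff its model coverage is >= ``coverage_min`` and its
    e-value is <= ``evalue_long`` when the alignment is strictly longer than
    ``length_threshold`` residues, or <= ``evalue_short`` otherwise.
    """
    kept = []
    for h in hits:
        if h.model_coverage < coverage_min:
            continue
        cutoff = evalue_long if h.ali_length > length_threshold else evalue_short
        if h.e_value <= cutoff:
            kept.append(h)
    return kept


def _hit_priority(h: DomainHit) -> Tuple[float, float, str]:
    # e-value ascending, then bit score descending, then family id.
    return (h.e_value, -h.bit_score, h.family_id)


def _overlaps(a: DomainHit, b: DomainHit) -> bool:
    return a.ali_start <= b.ali_end and b.ali_start <= a.ali_end


def resolve_overlaps(hits: Iterable[DomainHit]) -> List[DomainHit]:
    """Greedy per-protein overlap resolution, best e-value first.

    A hit is accepted iff its alignment interval shares no residue with a
    previously accepted hit on the same protein; disjoint domains on one
    protein all survive.  The result is independent of input row order.
    """
    by_protein: Dict[str, List[DomainHit]] = defaultdict(list)
    for h in hits:
        by_protein[h.protein_id].append(h)
    retained: List[DomainHit] = []
    for pid in sorted(by_protein):
        accepted: List[DomainHit] = []
        for h in sorted(by_protein[pid], key=_hit_priority):
            if not any(_overlaps(h, a) for a in accepted):
                accepted.append(h)
        accepted.sort(key=lambda h: h.ali_start)
        retained.extend(accepted)
    return retained


def classify(
    hits: Iterable[DomainHit],
    genes: Optional[Iterable[GeneRecord]] = None,
) -> List[CazymeAnnotation]:
    """Build per-protein annotations from filtered, overlap-resolved hits.

    The primary class is the class of the retained hit with the lowest
    e-value (ties broken by higher bit score, then by class priority
    GH < PL < CE < CBM < GT < AA < cellulosome < SLH < Sus).  When a gene
    table is supplied, a hit referencing an unknown protein is an error.
    """
    known = None
    if genes is not None:
        known = {g.gene_id for g in genes}
    by_protein: Dict[str, List[DomainHit]] = defaultdict(list)
    for h in hits:
        if known is not None and h.protein_id not in known:
            raise ValueError(f"domain hit references unknown protein {h.protein_id!r}")
        by_protein[h.protein_id].append(h)

    annotations = []
    for pid in sorted(by_protein):
        phits = sorted(by_protein[pid], key=_hit_priority)
        best = min(
            phits,
            key=lambda h: (
                h.e_value,
                -h.bit_score,
                CLASS_PRIORITY.index(family_class(h.family_id)),
            ),
        )
        families = [h.family_id for h in phits]
        classes = {family_class(f) for f in families}
        n_cohesin = sum(1 for f in families if f == "cohesin")
        annotations.append(
            CazymeAnnotation(
                protein_id=pid,
                retained_hits=phits,
                families=families,
                primary_class=family_class(best.family_id),
                is_multidomain=len(set(families)) >= 2,
                has_dockerin="dockerin" in families,
                has_cohesin="cohesin" in families,
                n_tandem_cohesins=n_cohesin,
                has_SLH="SLH" in families,
            )
        )
    return annotations


def annotate(
    hits: Iterable[DomainHit],
    genes: Optional[Iterable[GeneRecord]] = None,
    **filter_kwargs,
) -> List[CazymeAnnotation]:
    """Full cascade: filter, resolve overlaps, classify."""
    return classify(resolve_overlaps(filter_hits(hits, **filter_kwargs)), genes)


def categorize_gh(
    annotations: Iterable[CazymeAnnotation],
    category_map: Optional[SubstrateCategoryMap] = None,
) -> Dict[str, str]:
    """Map each GH-bearing protein to the substrate category of its
    best-e-value GH family; GH families outside the map go to
    ``uncategorized``.  Proteins without a GH hit are omitted.
    """
    category_map = category_map or SubstrateCategoryMap()
    out: Dict[str, str] = {}
    for ann in annotations:
        gh_hits = [h for h in ann.retained_hits if family_class(h.family_id) == "GH"]
        if not gh_hits:
            continue
        best = min(gh_hits, key=_hit_priority)
        out[ann.protein_id] = category_map.category_of(best.family_id)
    return out


def call_scaffoldins(
    annotations: Iterable[CazymeAnnotation],
    template_scores: Optional[Mapping[str, Tuple[str, float]]] = None,
    score_threshold: float = SCAFFOLDIN_SCORE_THRESHOLD,
) -> List[ScaffoldinCall]:
    """Identify candidate scaffoldin proteins by two evidence routes.

    Score route: the protein's best score against the known-scaffoldin
    templates is >= ``score_threshold``.  Multi-cohesin route: the protein
    carries two or more cohesin domains.  The union of both routes is
    reported, one call per protein per mode.
    """
    calls: List[ScaffoldinCall] = []
    if template_scores:
        for pid in sorted(template_scores):
            template_id, score = template_scores[pid]
            if score >= score_threshold:
                calls.append(
                    ScaffoldinCall(
                        protein_id=pid,
                        mode="score_cutoff",
                        evidence=score,
                        template_id=template_id,
                    )
                )
    for ann in annotations:
        if ann.n_tandem_cohesins >= 2:
            calls.append(
                ScaffoldinCall(
                    protein_id=ann.protein_id,
                    mode="multi_cohesin",
                    evidence=ann.n_tandem_cohesins,
                )
            )
    return calls


__all__ = [
    "filter_hits",
    "resolve_overlaps",
    "classify",
    "annotate",
    "categorize_gh",
    "call_scaffoldins",
    "COVERAGE_MIN",
    "EVALUE_LONG",
    "EVALUE_SHORT",
    "LENGTH_THRESHOLD",
    "SCAFFOLDIN_SCORE_THRESHOLD",
    "UNCATEGORIZED",
]
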