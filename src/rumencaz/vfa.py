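"""Volatile fatty acid (VFA) pathway screening from marker-gene presence.

Rumen fermentation end-products are tracked per genome bin through a small
marker-gene scheme:

* acetate — requires both ``ackA`` (acetate kinase) and ``pta``
  (phosphotransacetylase);
* propionate via the succinate route — ``mmdA`` (methylmalonyl-CoA
  decarboxylase);
* propionate via the acrylate route — ``lcdA`` (lactoyl-CoA dehydratase);
* propionate via the propanediol route — ``pduP`` or ``pduQ``;
* butyrate via butyrate kinase — ``buk``;
* butyrate via butyryl-CoA:acetate CoA-transferase — ``but``.

Markers are matched by exact, case-insensitive gene-symbol token: the
symbol must appear as a whole annotation token ("but" in free text never
matches), and no homology search is performed here — symbols come from the
upstream annotation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping

import pandas as pd

from .model import GeneRecord

PATHWAY_FLAGS = (
    "acetate",
    "propionate_succinate",
    "propionate_acrylate",
    "propionate_propanediol",
    "butyrate_buk",
    "butyrate_but",
)

#: Markers consulted per pathway (all lowercased tokens).
PATHWAY_MARKERS: Dict[str, tuple] = {
    "acetate": ("acka", "pta"),
    "propionate_succinate": ("mmda",),
    "propionate_acrylate": ("lcda",),
    "propionate_propanediol": ("pdup", "pduq"),
    "butyrate_buk": ("buk",),
    "butyrate_but": ("but",),
}

#: Pathways whose markers are alternatives rather than a required set.
_ANY_OF = {"propionate_propanediol"}


@dataclass
class PathwayCall:
    bin_id: str
    acetate: bool = False
    propionate_succinate: bool = False
    propionate_acrylate: bool = False
    propionate_propanediol: bool = False
    butyrate_buk: bool = False
    butyrate_but: bool = False
    evidence: Dict[str, List[str]] = field(default_factory=dict)

    def flag(self, name: str) -> bool:
        return getattr(self, name)


def screen_bin(genes: Iterable[GeneRecord], bin_id: str = "") -> PathwayCall:
    """Call VFA pathway capabilities for one bin's gene set.

    Acetate needs both of its markers; the propanediol route needs either
    of its two; every other pathway has a single diagnostic marker.
    Evidence lists the gene ids carrying each observed marker.
    """
    evidence: Dict[str, List[str]] = defaultdict(list)
    for g in genes:
        for sym in g.gene_symbols:
            evidence[sym.lower()].append(g.gene_id)
    call = PathwayCall(bin_id=bin_id)
    relevant = {m for markers in PATHWAY_MARKERS.values() for m in markers}
    call.evidence = {m: sorted(evidence[m]) for m in sorted(relevant) if evidence[m]}
    for pathway, markers in PATHWAY_MARKERS.items():
        present = [bool(evidence[m]) for m in markers]
        setattr(call, pathway, any(present) if pathway in _ANY_OF else all(present))
    return call


def pathway_summary(
    calls: Iterable[PathwayCall], taxonomy: Mapping[str, str]
) -> pd.DataFrame:
    """Per-phylum capability counts plus the dominant butyrate route.

    The dominant route per phylum is the butyrate flag true in more of its
    bins (``mixed`` on a non-zero tie, ``none`` when neither occurs).
    """
    per_phylum: Dict[str, Dict[str, int]] = defaultdict(
        lambda: {f: 0 for f in PATHWAY_FLAGS} | {"n_bins": 0}
    )
    for call in calls:
        phylum = taxonomy.get(call.bin_id, "unassigned")
        row = per_phylum[phylum]
        row["n_bins"] += 1
        for flag in PATHWAY_FLAGS:
            if call.flag(flag):
                row[flag] += 1
    records = []
    for phylum in sorted(per_phylum):
        row = dict(per_phylum[phylum])
        buk, but = row["butyrate_buk"], row["butyrate_but"]
        if buk == but == 0:
            dominant = "none"
        elif buk > but:
            dominant = "buk"
        elif but > buk:
            dominant = "but"
        else:
            dominant = "mixed"
        row["phylum"] = phylum
        row["dominant_butyrate_route"] = dominant
        records.append(row)
    columns = ["phylum", "n_bins", *PATHWAY_FLAGS, "dominant_butyrate_route"]
    return pd.DataFrame(records, columns=columns)
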