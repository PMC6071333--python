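"""CAZy family catalog, class assignment and substrate-category maps.

Carbohydrate-active enzymes (CAZymes) are organized into sequence-based
families within six classes: glycoside hydrolases (GH), glycosyltransferases
(GT), polysaccharide lyases (PL), carbohydrate esterases (CE),
carbohydrate-binding modules (CBM) and auxiliary activities (AA).  On top of
those, this package tracks the accessory domains relevant to fibre
degradation in gut microbiomes: dockerin and cohesin (cellulosome assembly),
S-layer homology (SLH, cell-wall anchoring) and the starch-utilization-system
transporter/binding pair SusC/SusD (including the SusD-like profiles), whose
tandem gene pairs anchor polysaccharide utilization loci.
"""

from __future__ import annotations

import re
from typing import Dict, FrozenSet, Mapping, Set

# Classes a protein can be assigned to.  "cellulosome" covers dockerin and
# cohesin domains; "Sus" covers SusC and the SusD/SusD-like profiles.
CAZY_CLASSES = ("GH", "GT", "CE", "PL", "CBM", "AA", "cellulosome", "SLH", "Sus")

# Tie-break order used when a protein's best hits are otherwise equal.
CLASS_PRIORITY = ("GH", "PL", "CE", "CBM", "GT", "AA", "cellulosome", "SLH", "Sus")

SPECIAL_FAMILIES = (
    "dockerin",
    "cohesin",
    "SLH",
    "SusC",
    "SusD",
    "SusD-like",
    "SusD-like_2",
    "SusD-like_3",
)

# Numbered-family ranges, chosen to span the families currently described in
# the CAZy database (with headroom for new families).
_FAMILY_RANGES = {"GH": 180, "GT": 120, "PL": 45, "CE": 20, "CBM": 95, "AA": 17}

_NUMBERED_RE = re.compile(r"^(GH|GT|CE|PL|CBM|AA)(\d+)$")


def build_catalog() -> FrozenSet[str]:
    """Controlled vocabulary of recognized family identifiers."""
    fams: Set[str] = set(SPECIAL_FAMILIES)
    for prefix, upper in _FAMILY_RANGES.items():
        fams.update(f"{prefix}{i}" for i in range(1, upper + 1))
    return frozenset(fams)


FAMILY_CATALOG: FrozenSet[str] = build_catalog()


def family_class(family_id: str) -> str:
    """Map a family identifier to its CAZyme class.

    Raises ``ValueError`` for identifiers outside the catalog grammar.
    """
    if family_id in ("dockerin", "cohesin"):
        return "cellulosome"
    if family_id == "SLH":
        return "SLH"
    if family_id == "SusC" or family_id.startswith("SusD"):
        return "Sus"
    m = _NUMBERED_RE.match(family_id)
    if m:
        return m.group(1)
    raise ValueError(f"unrecognized CAZy family identifier: {family_id!r}")


def is_susc(family_id: str) -> bool:
    return family_id == "SusC"


def is_susd(family_id: str) -> bool:
    # SusD-like profiles are tallied together with SusD.
    return family_id == "SusD" or family_id.startswith("SusD-like")


# GH substrate categories following the standard grouping of rumen
# metagenome surveys: cellulases (endo/exo-glucanases), endohemicellulases
# (xylanases, mannanases, polygalacturonases), side-chain debranching
# enzymes, and oligosaccharide-degrading enzymes.
DEFAULT_SUBSTRATE_CATEGORIES: Dict[str, FrozenSet[str]] = {
    "cellulases": frozenset({"GH5", "GH9", "GH44", "GH45", "GH48", "GH74"}),
    "endohemicellulases": frozenset(
        {"GH8", "GH10", "GH11", "GH12", "GH26", "GH28", "GH53"}
    ),
    "debranching": frozenset({"GH51", "GH54", "GH67", "GH78"}),
    "oligosaccharide_degrading": frozenset(
        {"GH1", "GH2", "GH3", "GH29", "GH35", "GH38", "GH39", "GH42", "GH43", "GH94"}
    ),
}

UNCATEGORIZED = "uncategorized"


class SubstrateCategoryMap:
    """Disjoint grouping of GH families by principal substrate.

    Parameters
    ----------
    categories:
        Mapping of category name to a set of GH family identifiers.  The
        sets must be pairwise disjoint and contain only GH families.
    """

    def __init__(self, categories: Mapping[str, Set[str]] | None = None):
        cats = categories if categories is not None else DEFAULT_SUBSTRATE_CATEGORIES
        self.categories: Dict[str, FrozenSet[str]] = {
            name: frozenset(fams) for name, fams in cats.items()
        }
        self._by_family: Dict[str, str] = {}
        for name, fams in self.categories.items():
            for fam in fams:
                if family_class(fam) != "GH":
                    raise ValueError(
                        f"substrate category {name!r} contains non-GH family {fam!r}"
                    )
                if fam in self._by_family:
                    raise ValueError(
                        f"family {fam!r} appears in categories "
                        f"{self._by_family[fam]!r} and {name!r}"
                    )
                self._by_family[fam] = name

    def category_of(self, family_id: str) -> str:
        """Category of a GH family, or ``uncategorized``."""
        return self._by_family.get(family_id, UNCATEGORIZED)

    def names(self):
        return list(self.categories)

    def __eq__(self, other):
        return (
            isinstance(other, SubstrateCategoryMap)
            and self.categories == other.categories
        )
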