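"""Cross-metagenome enrichment statistics for CAZyme family profiles.

Each family is tested with a two-sided Fisher's exact test on the 2x2 table

    [[count_a, total_a - count_a],
     [count_b, total_b - count_b]]

where the totals are the sizes of the two gene universes being compared
(all predicted ORFs by default, or total CAZyme genes).  P-values are
corrected across the family set with the Benjamini-Hochberg false discovery
rate, and significance tiers follow the usual convention: ``***`` q < 0.001,
``**`` q < 0.01, ``*`` q < 0.05, ``ns`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ComparisonResult:
    family_id: str
    count_a: int
    count_b: int
    total_a: int
    total_b: int
    odds_ratio: float
    p_value: float
    q_value: float
    tier: str
    direction: str


def _odds_ratio(count_a: int, total_a: int, count_b: int, total_b: int) -> float:
    num = count_a * (total_b - count_b)
    den = (total_a - count_a) * count_b
    if den == 0:
        return 1.0 if num == 0 else math.inf
    return num / den


def fisher_family(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> Tuple[float, float]:
    """Two-sided Fisher's exact test for one family.

    Returns ``(odds_ratio, p_value)``.  The odds ratio uses the sample
    convention ``a*d / (b*c)`` with 0/0 -> 1 and x/0 -> inf.
    """
    if count_a > total_a or count_b > total_b:
        raise ValueError("family count exceeds its total")
    if count_a < 0 or count_b < 0 or total_a <= 0 or total_b <= 0:
        raise ValueError("counts must be non-negative and totals positive")
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return _odds_ratio(count_a, total_a, count_b, total_b), float(p)


def _tier(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return "ns"


def compare_profiles(
    families: Mapping[str, Tuple[int, int]], total_a: int, total_b: int
) -> List[ComparisonResult]:
    """Per-family Fisher tests with BH-FDR correction over the family set.

    ``families`` maps family id to ``(count_a, count_b)``.  Direction
    compares the family's proportion in A against B.
    """
    if not families:
        raise ValueError("family set is empty")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    fam_ids = sorted(families)
    ors: Dict[str, float] = {}
    pvals: List[float] = []
    for fam in fam_ids:
        ca, cb = families[fam]
        or_, p = fisher_family(ca, total_a, cb, total_b)
        ors[fam] = or_
        pvals.append(p)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    results = []
    for fam, p, q in zip(fam_ids, pvals, qvals):
        ca, cb = families[fam]
        prop_a, prop_b = ca / total_a, cb / total_b
        if prop_a > prop_b:
            direction = "over_in_a"
        elif prop_a < prop_b:
            direction = "under_in_a"
        else:
            direction = "equal"
        results.append(
            ComparisonResult(
                family_id=fam,
                count_a=ca,
                count_b=cb,
                total_a=total_a,
                total_b=total_b,
                odds_ratio=ors[fam],
                p_value=float(p),
                q_value=float(q),
                tier=_tier(float(q)),
                direction=direction,
            )
        )
    return results


COMPARISON_COLUMNS = [
    "family",
    "count_a",
    "count_b",
    "total_a",
    "total_b",
    "odds_ratio",
    "p",
    "q",
    "tier",
    "direction",
]


def write_comparison(results: List[ComparisonResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(COMPARISON_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.family_id,
                        str(r.count_a),
                        str(r.count_b),
                        str(r.total_a),
                        str(r.total_b),
                        str(r.odds_ratio),
                        str(r.p_value),
                        str(r.q_value),
                        r.tier,
                        r.direction,
                    ]
                )
                + "\n"
            )
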