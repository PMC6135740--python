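"""Blastocyst lineage-balance classification from imaging counts.

For each imaged blastocyst a 2×2 table per marker (marker+/marker− ×
embryonic/abembryonic pole) yields an odds ratio; an embryo is *balanced*
for a marker when 1/3 < OR < 3 (strictly) and *unbalanced* when any
evaluated marker falls outside the band. Three counting methods are
supported: include embryos with ≥1/3 of cells marker+ (``one_third``),
≥1/2 (``half``), or include everyone and use the simpler marker+ pole-count
ratio n1/n2 instead of the OR (``all``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .io import EmbryoImageCounts

METHODS = ("one_third", "half", "all")
#: strict balance band on the odds ratio / pole ratio
BAND = (1 / 3, 3.0)


@dataclass
class BalanceResult:
    embryo_id: str
    method: str
    included: bool
    ratios: dict[str, Optional[float]] = field(default_factory=dict)
    classification: str = "not_included"  # balanced | unbalanced | not_included

    def __post_init__(self) -> None:
        if (self.classification == "not_included") != (not self.included):
            raise ValueError("classification=not_included iff included=False")


def inclusion(counts: EmbryoImageCounts, min_frac: float) -> bool:
    """Include an embryo iff ≥ min_frac of all its cells express GFP or RFP."""
    pos = sum(tab[0] + tab[2] for tab in counts.counts.values())
    return pos / counts.total_cells >= min_frac


def odds_ratio(table: tuple[int, int, int, int]) -> float:
    """OR of one marker's 2×2 pole table, Haldane–Anscombe corrected.

    Table order: (pos_embryonic, neg_embryonic, pos_abembryonic,
    neg_abembryonic). When any cell is 0, 0.5 is added to all four cells so
    the OR stays finite.
    """
    a, b, c, d = table
    if a == b == c == d == 0:
        raise ValueError("all four cells are zero; odds ratio undefined")
    if min(table) == 0:
        a, b, c, d = (x + 0.5 for x in table)
    return (a * d) / (b * c)


def classify(or_value: float) -> str:
    """Balanced iff the ratio lies strictly inside (1/3, 3)."""
    return "balanced" if BAND[0] < or_value < BAND[1] else "unbalanced"


def pole_ratio(table: tuple[int, int, int, int]) -> float:
    """Marker+ embryonic/abembryonic count ratio n1/n2 (0.5 added when a
    pole count is 0)."""
    n1, n2 = table[0], table[2]
    if n1 == 0 or n2 == 0:
        n1, n2 = n1 + 0.5, n2 + 0.5
    return n1 / n2


def pole_ratio_classify(table: tuple[int, int, int, int]) -> str:
    return classify(pole_ratio(table))


def classify_embryo(counts: EmbryoImageCounts, method: str) -> BalanceResult:
    """Classify one embryo under one counting method.

    ``one_third``/``half`` filter on the marker+ cell fraction and use the
    odds ratio; ``all`` includes every embryo and uses the pole-count ratio.
    An embryo is unbalanced when ANY evaluated marker is unbalanced. A
    marker whose table is all zero is skipped.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if method == "one_third":
        included = inclusion(counts, 1 / 3)
    elif method == "half":
        included = inclusion(counts, 1 / 2)
    else:
        included = True
    if not included:
        return BalanceResult(counts.embryo_id, method, False)

    ratios: dict[str, Optional[float]] = {}
    calls = []
    for marker, tab in sorted(counts.counts.items()):
        if method == "all":
            if tab[0] == 0 and tab[2] == 0 and sum(tab) == 0:
                ratios[marker] = None
                continue
            r = pole_ratio(tab)
        else:
            try:
                r = odds_ratio(tab)
            except ValueError:
                ratios[marker] = None
                continue
        ratios[marker] = r
        calls.append(classify(r))
    if not calls:
        return BalanceResult(counts.embryo_id, method, False)
    cls = "unbalanced" if "unbalanced" in calls else "balanced"
    return BalanceResult(counts.embryo_id, method, True, ratios, cls)


def classify_all(
    counts: Iterable[EmbryoImageCounts], methods: Iterable[str] = METHODS
) -> list[BalanceResult]:
    return [classify_embryo(c, m) for c in counts for m in methods]


def percent_unbalanced(n_unbalanced: int, n_included: int) -> int:
    """Truncated integer percentage (8/12 → 66, not 67)."""
    if n_included == 0:
        raise ZeroDivisionError("no embryos included")
    return int(100 * n_unbalanced / n_included)


def summarize(results: Iterable[BalanceResult]) -> pd.DataFrame:
    """Per-method counts of included/unbalanced embryos with truncated
    integer percentages; methods with no included embryo are omitted."""
    rows = []
    frame = pd.DataFrame(
        [(r.method, r.included, r.classification) for r in results],
        columns=["method", "included", "classification"],
    )
    for method, grp in frame.groupby("method", sort=False):
        inc = grp[grp["included"]]
        if inc.empty:
            continue
        n_unb = int((inc["classification"] == "unbalanced").sum())
        rows.append(
            dict(method=method, n_included=len(inc), n_unbalanced=n_unb,
                 percent_unbalanced=percent_unbalanced(n_unb, len(inc)))
        )
    return pd.DataFrame(
        rows, columns=["method", "n_included", "n_unbalanced",
                       "percent_unbalanced"],
    )
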