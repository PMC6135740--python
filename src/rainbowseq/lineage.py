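"""Marker-based lineage assignment and per-cell QC.

Each blastomere of a traced embryo expresses exactly one Brainbow marker
gene inherited from its 2-cell-stage ancestor. Reads mapped to the marker
construct identify the expressed marker; within an embryo the two observed
markers partition cells into division lineages A and B. The A/B labels are
arbitrary per embryo, so the alphabetically smaller marker is always A —
a deterministic convention, nothing more.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import MARKERS, CellRecord

#: minimum reads on the winning marker
DEFAULT_MIN_READS = 10
#: winning marker must exceed every other marker by this factor
DEFAULT_DOMINANCE = 5.0
#: QC floor on uniquely mapped read pairs ("fewer than 3 million" fails)
DEFAULT_MIN_PAIRS = 3_000_000


def call_marker(
    cell: CellRecord,
    min_reads: int = DEFAULT_MIN_READS,
    dominance: float = DEFAULT_DOMINANCE,
) -> Optional[str]:
    """Call the expressed marker of one cell, or None.

    A marker is called when its read count reaches ``min_reads`` and is at
    least ``dominance`` times every other marker's count (ambient reads and
    index hopping produce low-level counts on unexpressed markers).
    """
    for m, n in cell.marker_reads.items():
        if n < 0:
            raise ValueError(f"{cell.cell_id}: negative read count for {m}")
    counts = sorted(cell.marker_reads.items(), key=lambda kv: -kv[1])
    best_m, best = counts[0]
    runner = counts[1][1]
    if best >= min_reads and best >= dominance * runner and best > runner:
        return best_m
    return None


def assign_lineages(
    cells: Iterable[CellRecord],
    min_reads: int = DEFAULT_MIN_READS,
    dominance: float = DEFAULT_DOMINANCE,
) -> list[CellRecord]:
    """Partition one embryo's cells into lineages A/B by called marker.

    Exactly two distinct markers must be called across the embryo; the
    alphabetically smaller one becomes lineage A. Cells with no call stay
    unresolved; if fewer or more than two markers are seen, the whole embryo
    is unresolved (the two founding lineages cannot be told apart).
    """
    cells = list(cells)
    if not cells:
        raise ValueError("assign_lineages: empty input")
    embryos = {c.embryo_id for c in cells}
    if len(embryos) != 1:
        raise ValueError(f"cells span multiple embryos: {sorted(embryos)}")

    calls = {c.cell_id: call_marker(c, min_reads, dominance) for c in cells}
    seen = sorted({m for m in calls.values() if m is not None})
    if len(seen) != 2:
        return [dataclasses.replace(c, lineage="unresolved") for c in cells]
    a_marker = seen[0]
    out = []
    for c in cells:
        m = calls[c.cell_id]
        if m is None:
            lin = "unresolved"
        else:
            lin = "A" if m == a_marker else "B"
        out.append(dataclasses.replace(c, lineage=lin))
    return out


def assign_all(
    cells: Iterable[CellRecord],
    min_reads: int = DEFAULT_MIN_READS,
    dominance: float = DEFAULT_DOMINANCE,
) -> list[CellRecord]:
    """Apply :func:`assign_lineages` embryo by embryo, preserving order."""
    cells = list(cells)
    by_embryo: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_embryo.setdefault(c.embryo_id, []).append(c)
    assigned: dict[str, CellRecord] = {}
    for group in by_embryo.values():
        for c in assign_lineages(group, min_reads, dominance):
            assigned[c.cell_id] = c
    return [assigned[c.cell_id] for c in cells]


def qc_filter(
    cells: Iterable[CellRecord], min_pairs: int = DEFAULT_MIN_PAIRS
) -> tuple[list[CellRecord], list[CellRecord]]:
    """Split cells into (kept, dropped) by uniquely mapped read pairs.

    The boundary is inclusive: exactly ``min_pairs`` passes.
    """
    kept, dropped = [], []
    for c in cells:
        (kept if c.uniquely_mapped_pairs >= min_pairs else dropped).append(c)
    return kept, dropped


def call_expressed_genes(
    matrix: pd.DataFrame, threshold: float = 1.0
) -> tuple[pd.Series, int]:
    """Count expressed genes per cell and in the union across cells.

    A gene is expressed in a cell iff FPKM is strictly greater than
    ``threshold``. The matrix should already be restricted to the cells of
    one stage; the union counts genes expressed in at least one of them.
    """
    expressed = matrix.values > threshold
    per_cell = pd.Series(expressed.sum(axis=0), index=matrix.columns,
                         name="n_expressed")
    union = int(expressed.any(axis=1).sum())
    return per_cell, union
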