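"""Transposon-Related Novel Isoform (TRENI) calling and support statistics.

A novel isoform of a known gene is a TRENI when at least one RepeatMasker
repeat copy overlaps its exons by a minimum number of bases. Each embedded
repeat is classified by placement relative to the host gene's annotated
start codon (5′UTR vs downstream, strand-aware, straddling repeats count in
both) and supported by a junction ratio JR: among reads overlapping the
repeat, the fraction that are spliced into the nearest annotated exon of
the host gene. Family-level enrichment uses per-family 2×2 tables of repeat
copies in/out of TRENIs with Haldane-corrected odds ratios, Woolf 95% CIs
and chi-square p-values; families with few TRENI copies have their OR
suppressed. Per-repeat copies are the accounting unit throughout (one
isoform may carry several repeats).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import ReadBlocks, RepeatFeature, TranscriptModel

DEFAULT_MIN_OVERLAP = 10
DEFAULT_JR_THRESHOLD = 0.9
DEFAULT_MIN_COPIES = 20

FIVE_PRIME_UTR = "five_prime_utr"
DOWNSTREAM = "downstream_of_start"


@dataclass
class TreniRecord:
    transcript_id: str
    gene_id: str
    repeat_hits: list[tuple[RepeatFeature, int]]          # (repeat, overlap bp)
    placements: dict[RepeatFeature, frozenset] = field(default_factory=dict)
    jr: dict[RepeatFeature, Optional[float]] = field(default_factory=dict)

    @property
    def placement(self) -> frozenset:
        out: set[str] = set()
        for p in self.placements.values():
            out |= p
        return frozenset(out)


@dataclass
class FamilyEnrichment:
    family: str
    in_treni_copies: int
    out_treni_copies: int
    other_in: int
    other_out: int
    odds_ratio: Optional[float]
    ci95: Optional[tuple[float, float]]
    chi2_p: Optional[float]


# ---------------------------------------------------------------------------
# novelty
# ---------------------------------------------------------------------------

def _chain(t: TranscriptModel) -> tuple:
    return tuple(t.introns)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _exonic_overlap(t: TranscriptModel, u: TranscriptModel) -> int:
    return sum(_overlap(e, f) for e in t.exons for f in u.exons)


def _is_subchain(sub: tuple, full: tuple) -> bool:
    if not sub:
        return False
    n, m = len(sub), len(full)
    return any(full[i:i + n] == sub for i in range(m - n + 1))


def find_novel(
    transcripts: Iterable[TranscriptModel],
    reference: Sequence[TranscriptModel],
) -> list[TranscriptModel]:
    """Identify novel isoforms against a reference annotation.

    A multi-exon transcript is novel iff its ordered intron chain does not
    occur (as a contiguous run) in any reference transcript it shares
    exonic sequence with; a monoexonic transcript is novel iff it is not
    contained within any reference exon. Each novel isoform is attributed
    to the reference gene with maximal exonic overlap (returned transcripts
    carry that gene_id and ``is_novel=True``).
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for r in reference:
        by_chrom.setdefault(r.chrom, []).append(r)

    out = []
    for t in transcripts:
        refs = [
            r for r in by_chrom.get(t.chrom, []) if _exonic_overlap(t, r) > 0
        ]
        if len(t.exons) == 1:
            exon = t.exons[0]
            contained = any(
                s <= exon[0] and exon[1] <= e
                for r in refs for s, e in r.exons
            )
            novel = not contained
        else:
            chain = _chain(t)
            novel = not any(_is_subchain(chain, _chain(r)) for r in refs)
        if not novel:
            continue
        gene_id = t.gene_id
        if refs:
            gene_id = max(refs, key=lambda r: _exonic_overlap(t, r)).gene_id
        out.append(
            TranscriptModel(
                transcript_id=t.transcript_id, gene_id=gene_id,
                chrom=t.chrom, strand=t.strand, exons=list(t.exons),
                start_codon=t.start_codon, is_novel=True,
            )
        )
    return out


# ---------------------------------------------------------------------------
# TRENI calling and placement
# ---------------------------------------------------------------------------

def call_treni(
    novel: Iterable[TranscriptModel],
    repeats: Iterable[RepeatFeature],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[TreniRecord]:
    """Call TRENIs: novel isoforms whose exons overlap ≥1 repeat by
    ``min_overlap`` bp (summed across exons per repeat). All qualifying
    repeats are recorded per isoform."""
    trees: dict[str, IntervalTree] = {}
    for rep in repeats:
        trees.setdefault(rep.chrom, IntervalTree()).addi(rep.start, rep.end, rep)

    out = []
    for t in novel:
        tree = trees.get(t.chrom)
        if tree is None:
            continue
        per_repeat: dict[RepeatFeature, int] = {}
        for exon in t.exons:
            for iv in tree.overlap(*exon):
                rep = iv.data
                per_repeat[rep] = per_repeat.get(rep, 0) + _overlap(
                    exon, (rep.start, rep.end)
                )
        hits = [(rep, bp) for rep, bp in per_repeat.items() if bp >= min_overlap]
        if hits:
            hits.sort(key=lambda h: (h[0].start, h[0].end))
            out.append(TreniRecord(t.transcript_id, t.gene_id, hits))
    return out


def classify_placement(
    transcript: TranscriptModel,
    repeat: RepeatFeature,
    start_codon: Optional[int] = None,
) -> frozenset:
    """Classify one repeat's exonic overlap relative to the start codon.

    Overlap bases strictly 5′ of the start codon (in transcript
    orientation) are 5′UTR; bases at or 3′ of it are downstream. A repeat
    straddling the codon contributes both. On the − strand "5′ of" means a
    greater genomic coordinate. Empty when no start codon is known.
    """
    sc = transcript.start_codon if start_codon is None else start_codon
    if sc is None:
        return frozenset()
    tags: set[str] = set()
    for exon in transcript.exons:
        s = max(exon[0], repeat.start)
        e = min(exon[1], repeat.end)
        if e <= s:
            continue
        if transcript.strand == "+":
            if s < sc:
                tags.add(FIVE_PRIME_UTR)
            if e > sc:
                tags.add(DOWNSTREAM)
        else:
            if e > sc + 1:
                tags.add(FIVE_PRIME_UTR)
            if s <= sc:
                tags.add(DOWNSTREAM)
    return frozenset(tags)


def annotate_placements(
    records: Iterable[TreniRecord],
    transcripts: dict[str, TranscriptModel],
) -> list[TreniRecord]:
    """Fill ``placements`` for every repeat hit of every record."""
    out = []
    for rec in records:
        t = transcripts[rec.transcript_id]
        rec.placements = {
            rep: classify_placement(t, rep) for rep, _ in rec.repeat_hits
        }
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# junction ratio
# ---------------------------------------------------------------------------

def nearest_reference_exon(
    repeat: RepeatFeature,
    reference_exons: Sequence[tuple[int, int]],
    strand: str,
) -> tuple[int, int]:
    """Nearest annotated exon of the host gene to a repeat interval.

    Nearest = minimal genomic gap (0 when overlapping); ties broken toward
    the 3′ side in transcript orientation.
    """
    if not reference_exons:
        raise ValueError("no reference exons for host gene")

    def gap(exon):
        if exon[1] <= repeat.start:
            return repeat.start - exon[1]
        if exon[0] >= repeat.end:
            return exon[0] - repeat.end
        return 0

    best = min(gap(e) for e in reference_exons)
    cands = [e for e in reference_exons if gap(e) == best]
    if strand == "+":
        return max(cands, key=lambda e: e[0])
    return min(cands, key=lambda e: e[0])


def junction_ratio(
    repeat: RepeatFeature,
    host: TranscriptModel,
    reference_exons: Sequence[tuple[int, int]],
    reads: Iterable[ReadBlocks],
) -> Optional[float]:
    """Junction ratio (JR) of one repeat inside one isoform.

    Denominator: reads with ≥1 bp overlapping the repeat. Numerator: the
    spliced subset with one block on the repeat and another on the nearest
    reference exon of the host gene. None when no read overlaps the repeat.
    """
    target = nearest_reference_exon(repeat, reference_exons, host.strand)
    rep_iv = (repeat.start, repeat.end)
    denom = num = 0
    for read in reads:
        if read.chrom != repeat.chrom:
            continue
        on_repeat = [b for b in read.blocks if _overlap(b, rep_iv) > 0]
        if not on_repeat:
            continue
        denom += 1
        if len(read.blocks) >= 2 and any(
            _overlap(b, target) > 0 for b in read.blocks if b not in on_repeat
        ):
            num += 1
    if denom == 0:
        return None
    return num / denom


def jr_filter(
    jr_by_repeat: dict[RepeatFeature, Optional[float]],
    threshold: float = DEFAULT_JR_THRESHOLD,
) -> list[RepeatFeature]:
    """High-confidence repeats: JR ≥ threshold (inclusive); undefined JR
    is dropped."""
    return [rep for rep, jr in jr_by_repeat.items()
            if jr is not None and jr >= threshold]


# ---------------------------------------------------------------------------
# family enrichment
# ---------------------------------------------------------------------------

def _odds_ratio_ci(a: int, b: int, c: int, d: int):
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if min(a, b, c, d) == 0
        else (a, b, c, d)
    )
    oratio = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = math.exp(math.log(oratio) - 1.96 * se)
    hi = math.exp(math.log(oratio) + 1.96 * se)
    return oratio, (lo, hi)


def enrichment_from_table(
    family: str, a: int, b: int, c: int, d: int,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> FamilyEnrichment:
    """Enrichment of one family from its 2×2 copy table.

    ``a`` = family copies in TRENIs, ``b`` = family copies outside, ``c``/
    ``d`` = other-family copies in/outside. OR, Woolf CI and chi-square p
    are suppressed when a < min_copies.
    """
    if a < min_copies:
        return FamilyEnrichment(family, a, b, c, d, None, None, None)
    oratio, ci = _odds_ratio_ci(a, b, c, d)
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        p = None
    else:
        p = float(stats.chi2_contingency(table, correction=False)[1])
    return FamilyEnrichment(family, a, b, c, d, oratio, ci, p)


def family_enrichment(
    all_repeats: Iterable[RepeatFeature],
    treni_repeats: Iterable[RepeatFeature],
    min_copies: int = DEFAULT_MIN_COPIES,
) -> list[FamilyEnrichment]:
    """Per-family enrichment of repeat copies in TRENIs.

    For family f the 2×2 table is {f vs other families} × {copy in a TRENI
    vs not}, over all genome-wide copies. OR = (a·d)/(b·c) with 0.5 added
    to every cell when any is zero; 95% CI by the Woolf (log-OR normal)
    method; p from a chi-square test without continuity correction. The OR
    (and CI/p) is suppressed — reported as None — when fewer than
    ``min_copies`` copies of f lie in TRENIs. Results are sorted by OR
    (descending, suppressed last).
    """
    all_list = list(all_repeats)
    in_treni = set(treni_repeats)
    fams = sorted({r.family for r in all_list})
    n_in = sum(1 for r in all_list if r in in_treni)
    n_all = len(all_list)

    out = []
    for fam in fams:
        fam_total = sum(1 for r in all_list if r.family == fam)
        a = sum(1 for r in all_list if r.family == fam and r in in_treni)
        b = fam_total - a
        c = n_in - a
        d = (n_all - fam_total) - c
        out.append(enrichment_from_table(fam, a, b, c, d, min_copies))
    out.sort(key=lambda fe: (fe.odds_ratio is None,
                             -(fe.odds_ratio or 0.0), fe.family))
    return out


def utr_family_enrichment(
    all_repeats: Iterable[RepeatFeature],
    records: Iterable[TreniRecord],
    min_copies: int = DEFAULT_MIN_COPIES,
) -> list[FamilyEnrichment]:
    """Family enrichment restricted to repeats placed in 5′UTRs."""
    utr_reps = {
        rep
        for rec in records
        for rep, placement in rec.placements.items()
        if FIVE_PRIME_UTR in placement
    }
    return family_enrichment(all_repeats, utr_reps, min_copies)


# ---------------------------------------------------------------------------
# lineage tests on TRENI expression
# ---------------------------------------------------------------------------

def treni_lineage_tests(
    treni_matrix: pd.DataFrame,
    cells,
    stage: str,
    n_shuffles: int = 1,
    seed: int = 0,
    q_star: float = 0.01,
    expressed_threshold: float = 1.0,
):
    """Lineage ANOVA + shuffled background on isoform-level expression.

    Delegates wholesale to :mod:`rainbowseq.difftest`; rows of
    ``treni_matrix`` are TRENI isoforms. Returns
    ``(tests, background_q, comparison)``.
    """
    from . import difftest

    if treni_matrix.empty:
        raise ValueError("empty TRENI expression matrix")
    tests = difftest.test_features(
        treni_matrix, cells, stage, expressed_threshold=expressed_threshold
    )
    bg = difftest.shuffle_background(
        treni_matrix, cells, stage, n_shuffles=n_shuffles, seed=seed,
        expressed_threshold=expressed_threshold,
    )
    comp = difftest.compare_distributions(tests["q"].values, bg, q_star=q_star)
    return tests, bg, comp


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[TreniRecord]) -> pd.DataFrame:
    """One row per transcript-repeat hit (placement and JR included)."""
    rows = []
    for rec in records:
        for rep, bp in rec.repeat_hits:
            rows.append(
                dict(
                    transcript_id=rec.transcript_id, gene_id=rec.gene_id,
                    chrom=rep.chrom, repeat_start=rep.start,
                    repeat_end=rep.end, repeat_name=rep.repeat_name,
                    family=rep.family, overlap_bp=bp,
                    placement=",".join(sorted(rec.placements.get(rep, ()))),
                    jr=rec.jr.get(rep),
                )
            )
    return pd.DataFrame(rows)


def enrichment_to_frame(rows: Iterable[FamilyEnrichment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                family=fe.family, in_treni=fe.in_treni_copies,
                out_treni=fe.out_treni_copies, other_in=fe.other_in,
                other_out=fe.other_out, odds_ratio=fe.odds_ratio,
                ci_low=fe.ci95[0] if fe.ci95 else None,
                ci_high=fe.ci95[1] if fe.ci95 else None,
                chi2_p=fe.chi2_p,
            )
            for fe in rows
        ]
    )
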