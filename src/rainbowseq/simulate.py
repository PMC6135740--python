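"""Synthetic data generator for every pipeline input.

Emulates the study design this package analyses: cleavage-stage embryos
(4-cell split 2/2 and 8-cell split 4/4 between the two division lineages
founded at the 2-cell stage), heritable fluorescent-marker read counts with
dropout, a log-normal-style FPKM matrix with embryo and planted lineage
effects, blastocyst imaging counts in two pole-bias regimes, and an annotated
toy genome with reference transcripts, novel isoforms, repeat copies and
spliced/contained reads over each repeat.

Every generator is a pure function of a :class:`SyntheticConfig`; a fixed
seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    MARKERS,
    CellRecord,
    EmbryoImageCounts,
    ReadBlocks,
    RepeatFeature,
    TranscriptModel,
)

_DEFAULT_FAMILY_WEIGHTS = {
    # murine Alu (B1) dominates, echoing its outsized share of repeat-bearing
    # novel isoforms in early embryos
    "Alu": 0.45,
    "B2": 0.15,
    "B4": 0.12,
    "ID": 0.08,
    "L1": 0.12,
    "ERVK": 0.08,
}

_FAMILY_CLASS = {
    "Alu": "SINE", "B2": "SINE", "B4": "SINE", "ID": "SINE",
    "L1": "LINE", "ERVK": "LTR",
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study.

    Defaults mirror the analysed design: 9 four-cell and 4 eight-cell
    embryos, two lineages per embryo, 18 imaged blastocysts of 32–64 cells
    with roughly two-thirds unbalanced, and log2-FPKM noise with comparable
    embryo and cell components.
    """

    seed: int = 0
    # expression
    n_embryos_4cell: int = 9
    n_embryos_8cell: int = 4
    n_genes: int = 2000
    frac_lineage_genes: float = 0.1
    lineage_effect: float = 2.0      # log2-FPKM mean shift A vs B
    embryo_sd: float = 0.5           # log2-FPKM scale
    cell_sd: float = 0.5
    marker_mean_reads: float = 50.0
    marker_dropout: float = 0.1
    mean_mapped_pairs: float = 21e6  # per-cell uniquely mapped read pairs
    sd_mapped_pairs: float = 6e6
    # imaging
    n_image_embryos: int = 18
    unbalanced_frac: float = 2 / 3
    # annotation / reads
    n_transcripts: int = 200         # reference transcripts (one per gene)
    frac_novel: float = 0.5
    frac_repeat_bearing: float = 0.18
    utr_frac: float = 0.2            # repeat-bearing isoforms with 5'UTR repeat
    family_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FAMILY_WEIGHTS)
    )
    n_background_repeats: int = 400
    reads_per_repeat: int = 20
    junction_frac_range: tuple[float, float] = (0.6, 1.0)

    def __post_init__(self) -> None:
        for name in ("frac_lineage_genes", "marker_dropout", "unbalanced_frac",
                     "frac_novel", "frac_repeat_bearing", "utr_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.embryo_sd < 0 or self.cell_sd <= 0:
            raise ValueError("sds must be positive (embryo_sd may be 0)")
        lo, hi = self.junction_frac_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("junction_frac_range must be ordered within [0,1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent streams per generator so adding one does not shift another
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# cells + expression
# ---------------------------------------------------------------------------

def simulate_cells_and_expression(
    config: SyntheticConfig,
) -> tuple[list[CellRecord], pd.DataFrame, pd.DataFrame]:
    """Simulate blastomeres and their FPKM matrix.

    Model on the log2(FPKM+1) scale: per-gene baseline Uniform(2, 9), plus a
    per-(gene, embryo) effect N(0, embryo_sd), plus for planted lineage genes
    ±lineage_effect/2 with the up-lineage drawn per gene and embryo, plus
    cell noise N(0, cell_sd). FPKM = max(2^x − 1, 0).

    Returns ``(cells, fpkm, truth)`` where ``fpkm`` is a gene×cell DataFrame
    and ``truth`` lists the planted lineage genes with their effect size.
    """
    rng = _rng(config, 1)
    G = config.n_genes

    embryos = [("E4_%02d" % (i + 1), 4) for i in range(config.n_embryos_4cell)]
    embryos += [("E8_%02d" % (i + 1), 8) for i in range(config.n_embryos_8cell)]
    E = len(embryos)
    if E < 1:
        raise ValueError("need at least one embryo")

    gene_ids = [f"gene_{i:05d}" for i in range(G)]
    n_planted = int(round(config.frac_lineage_genes * G))
    planted_idx = np.sort(rng.choice(G, size=n_planted, replace=False))
    planted_mask = np.zeros(G, dtype=bool)
    planted_mask[planted_idx] = True

    baseline = rng.uniform(2.0, 9.0, size=G)
    embryo_eff = rng.normal(0.0, config.embryo_sd, size=(G, E))
    # which lineage carries the + sign, per (gene, embryo)
    signs = rng.choice([-1.0, 1.0], size=(G, E))

    cells: list[CellRecord] = []
    cols: list[np.ndarray] = []
    half = config.lineage_effect / 2.0

    for ei, (eid, n_cells) in enumerate(embryos):
        stage = "four_cell" if n_cells == 4 else "eight_cell"
        marker_by_lineage = {
            "A": MARKERS[rng.integers(4)], "B": MARKERS[rng.integers(4)],
        }
        for ci in range(n_cells):
            lineage = "A" if ci < n_cells // 2 else "B"
            sgn = 1.0 if lineage == "A" else -1.0
            x = (
                baseline
                + embryo_eff[:, ei]
                + np.where(planted_mask, sgn * signs[:, ei] * half, 0.0)
                + rng.normal(0.0, config.cell_sd, size=G)
            )
            cols.append(np.maximum(np.exp2(x) - 1.0, 0.0))

            marker = marker_by_lineage[lineage]
            reads = {m: 0 for m in MARKERS}
            count = int(rng.poisson(config.marker_mean_reads))
            if rng.uniform() < config.marker_dropout:
                count = 0
            reads[marker] = count
            pairs = int(
                max(1e5, rng.normal(config.mean_mapped_pairs,
                                    config.sd_mapped_pairs))
            )
            cells.append(
                CellRecord(
                    cell_id=f"{eid}_c{ci + 1}", embryo_id=eid, stage=stage,
                    marker_reads=reads, uniquely_mapped_pairs=pairs,
                )
            )

    fpkm = pd.DataFrame(
        np.column_stack(cols), index=gene_ids,
        columns=[c.cell_id for c in cells],
    )
    truth = pd.DataFrame(
        {
            "gene_id": [gene_ids[i] for i in planted_idx],
            "lineage_effect": config.lineage_effect,
        }
    )
    return cells, fpkm, truth


# ---------------------------------------------------------------------------
# imaging counts
# ---------------------------------------------------------------------------

def truth_lineages(cells: list[CellRecord]) -> list[CellRecord]:
    """Return copies of generated cells with their constructed lineage set.

    The generator places each embryo's first half of cells in lineage A and
    the second half in B; this bypasses marker-based assignment and is the
    ground truth against which assignment is checked.
    """
    import dataclasses

    by_embryo: dict[str, list[CellRecord]] = {}
    for c in cells:
        by_embryo.setdefault(c.embryo_id, []).append(c)
    out = {}
    for group in by_embryo.values():
        half = len(group) // 2
        for i, c in enumerate(group):
            out[c.cell_id] = dataclasses.replace(
                c, lineage="A" if i < half else "B"
            )
    return [out[c.cell_id] for c in cells]


def simulate_image_counts(config: SyntheticConfig) -> list[EmbryoImageCounts]:
    """Simulate blastocyst imaging tables for the GFP and RFP channels.

    ``unbalanced_frac`` of embryos place marker+ cells with a pole odds ratio
    of about 6 (GFP toward the embryonic pole, RFP away — the two lineages
    are complementary); the remainder sit at OR ≈ 1. Pole allocations are the
    rounded expected counts for the target odds ratio plus ±1 jitter, so the
    two regimes are cleanly separated at blastocyst-scale cell totals.
    """
    rng = _rng(config, 2)
    n = config.n_image_embryos
    n_unbal = int(round(config.unbalanced_frac * n))
    unbalanced = np.zeros(n, dtype=bool)
    unbalanced[rng.choice(n, size=n_unbal, replace=False)] = True

    out = []
    for i in range(n):
        total = int(rng.integers(32, 65))
        f = rng.uniform(0.30, 0.40)              # embryonic-pole share
        n_gfp = int(round(rng.uniform(0.30, 0.42) * total))
        n_rfp = int(round(rng.uniform(0.30, 0.42) * total))
        n_neg = total - n_gfp - n_rfp
        if n_neg < 4:                            # keep some unlabeled cells
            n_rfp -= 4 - n_neg
            n_neg = 4

        if unbalanced[i]:
            theta = rng.uniform(5.0, 8.0)
            p_g = theta * f / (1 - f + theta * f)      # GFP toward embryonic
            p_r = f / (theta * (1 - f) + f)            # RFP toward abembryonic
        else:
            p_g = p_r = f
        jitter = lambda: int(rng.integers(-1, 2))
        g_emb = min(n_gfp, max(0, int(round(n_gfp * p_g)) + jitter()))
        r_emb = min(n_rfp, max(0, int(round(n_rfp * p_r)) + jitter()))
        neg_emb = min(n_neg, max(0, int(round(n_neg * f)) + jitter()))

        gfp = (g_emb, r_emb + neg_emb, n_gfp - g_emb,
               (n_rfp - r_emb) + (n_neg - neg_emb))
        rfp = (r_emb, g_emb + neg_emb, n_rfp - r_emb,
               (n_gfp - g_emb) + (n_neg - neg_emb))
        out.append(
            EmbryoImageCounts(
                embryo_id=f"img_{i + 1:02d}",
                counts={"GFP": gfp, "RFP": rfp},
                total_cells=total,
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotation + reads
# ---------------------------------------------------------------------------

def simulate_annotation_and_reads(
    config: SyntheticConfig,
) -> tuple[list[TranscriptModel], list[RepeatFeature], list[ReadBlocks], pd.DataFrame]:
    """Simulate a toy annotated genome with repeat-bearing novel isoforms.

    Produces one multi-exon reference transcript per gene, novel isoforms for
    a subset of genes (repeat-bearing ones gain a spliced-in repeat exon
    either upstream of the start codon or inside a downstream intron;
    repeat-free ones skip an internal exon), background repeat copies with
    families drawn uniformly (so the weighted family is genuinely enriched in
    repeat-bearing isoforms), and per-repeat reads split between junction
    reads (repeat block + nearest-reference-exon block) and reads contained
    in the repeat.

    Returns ``(transcripts, repeats, reads, truth)``; ``truth`` has one row
    per novel isoform with its repeat placement and true junction fraction.
    """
    rng = _rng(config, 3)
    chrom = "chr1"
    families = sorted(config.family_weights)
    weights = np.array([config.family_weights[f] for f in families], dtype=float)
    weights = weights / weights.sum()

    # --- reference gene models ------------------------------------------
    refs: list[TranscriptModel] = []
    cursor = 10_000
    for gi in range(config.n_transcripts):
        strand = "+" if rng.uniform() < 0.5 else "-"
        n_ex = int(rng.integers(3, 6))
        exons = []
        pos = cursor
        for _ in range(n_ex):
            length = int(rng.integers(120, 301))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(600, 1501))
        # start codon in the second exon in transcript orientation,
        # leaving the first exon as annotated 5'UTR
        if strand == "+":
            s, e = exons[1]
            sc = s + int(rng.integers(10, min(50, e - s - 3)))
        else:
            s, e = exons[-2]
            sc = e - 1 - int(rng.integers(10, min(50, e - s - 3)))
        refs.append(
            TranscriptModel(
                transcript_id=f"ref_{gi:04d}", gene_id=f"g{gi:04d}",
                chrom=chrom, strand=strand, exons=exons, start_codon=sc,
                is_novel=False,
            )
        )
        cursor = exons[-1][1] + int(rng.integers(4000, 8001))

    # --- novel isoforms --------------------------------------------------
    n_novel = int(round(config.frac_novel * config.n_transcripts))
    n_treni = int(round(config.frac_repeat_bearing * n_novel))
    host_idx = rng.choice(config.n_transcripts, size=n_novel, replace=False)

    novels: list[TranscriptModel] = []
    repeats: list[RepeatFeature] = []
    reads: list[ReadBlocks] = []
    truth_rows = []
    read_serial = 0

    for k, hi in enumerate(host_idx):
        host = refs[hi]
        tid = f"nov_{k:04d}"
        if k >= n_treni:
            # repeat-free novel isoform: skip one internal exon
            skip = 1 if len(host.exons) == 3 else int(
                rng.integers(1, len(host.exons) - 1)
            )
            exons = [e for j, e in enumerate(host.exons) if j != skip]
            novels.append(
                TranscriptModel(
                    transcript_id=tid, gene_id=host.gene_id, chrom=chrom,
                    strand=host.strand, exons=exons,
                    start_codon=_carried_start(host, exons), is_novel=True,
                )
            )
            truth_rows.append(
                dict(transcript_id=tid, is_treni=False, placement="",
                     family="", repeat_start=-1, repeat_end=-1,
                     true_junction_fraction=np.nan, n_reads=0)
            )
            continue

        fam = families[int(rng.choice(len(families), p=weights))]
        is_utr = rng.uniform() < config.utr_frac
        rep_len = int(rng.integers(150, 251))
        tx_exons = host.exons if host.strand == "+" else host.exons[::-1]

        if is_utr:
            gap = int(rng.integers(300, 801))
            if host.strand == "+":
                first = host.exons[0]
                rep = (first[0] - gap - rep_len, first[0] - gap)
                nearest = first
            else:
                last = host.exons[-1]
                rep = (last[1] + gap, last[1] + gap + rep_len)
                nearest = last
            exons = sorted(host.exons + [rep])
            placement = "five_prime_utr"
        else:
            # insert into an intron 3' of the start-codon exon (tx index 1)
            n_introns = len(host.exons) - 1
            tx_j = int(rng.integers(1, n_introns))
            gj = tx_j if host.strand == "+" else n_introns - 1 - tx_j
            istart, iend = host.introns[gj]
            room = iend - istart - rep_len - 100
            off = int(rng.integers(50, max(51, room)))
            rep = (istart + off, istart + off + rep_len)
            gap_left = rep[0] - istart
            gap_right = iend - rep[1]
            left_exon = host.exons[gj]
            right_exon = host.exons[gj + 1]
            if gap_left < gap_right:
                nearest = left_exon
            elif gap_right < gap_left:
                nearest = right_exon
            else:  # break the tie 3'-ward in transcript orientation
                nearest = right_exon if host.strand == "+" else left_exon
            exons = sorted(host.exons + [rep])
            placement = "downstream_of_start"

        rep_feat = RepeatFeature(
            chrom, rep[0], rep[1],
            "+" if rng.uniform() < 0.5 else "-",
            f"{fam}_rep{k:04d}", fam, _FAMILY_CLASS.get(fam, "SINE"),
        )
        repeats.append(rep_feat)
        novels.append(
            TranscriptModel(
                transcript_id=tid, gene_id=host.gene_id, chrom=chrom,
                strand=host.strand, exons=exons,
                start_codon=host.start_codon, is_novel=True,
            )
        )

        # reads over this repeat
        lo, hi_f = config.junction_frac_range
        frac = rng.uniform(lo, hi_f)
        n_junc = int(round(frac * config.reads_per_repeat))
        for ri in range(config.reads_per_repeat):
            read_serial += 1
            rid = f"read_{read_serial:06d}"
            if ri < n_junc:
                blk_rep = (rep[0], rep[0] + min(60, rep_len))
                width = min(40, nearest[1] - nearest[0])
                if nearest[0] > rep[1]:      # exon right of repeat
                    blk_ex = (nearest[0], nearest[0] + width)
                else:                        # exon left of repeat
                    blk_ex = (nearest[1] - width, nearest[1])
                blocks = sorted([blk_rep, blk_ex])
            else:
                off = int(rng.integers(0, max(1, rep_len - 60)))
                blocks = [(rep[0] + off, rep[0] + off + min(60, rep_len))]
            reads.append(ReadBlocks(rid, chrom, blocks))

        truth_rows.append(
            dict(transcript_id=tid, is_treni=True, placement=placement,
                 family=fam, repeat_start=rep[0], repeat_end=rep[1],
                 true_junction_fraction=n_junc / config.reads_per_repeat,
                 n_reads=config.reads_per_repeat)
        )

    # --- background repeats (uniform families, outside every transcript) --
    bg_cursor = cursor + 50_000
    for bi in range(config.n_background_repeats):
        fam = families[int(rng.integers(len(families)))]
        length = int(rng.integers(150, 301))
        repeats.append(
            RepeatFeature(
                chrom, bg_cursor, bg_cursor + length,
                "+" if rng.uniform() < 0.5 else "-",
                f"{fam}_bg{bi:04d}", fam, _FAMILY_CLASS.get(fam, "SINE"),
            )
        )
        bg_cursor += length + int(rng.integers(500, 2001))

    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "is_treni", "placement", "family",
                 "repeat_start", "repeat_end", "true_junction_fraction",
                 "n_reads"],
    )
    return refs + novels, repeats, reads, truth


def _carried_start(host: TranscriptModel, exons: list[tuple[int, int]]):
    sc = host.start_codon
    if sc is not None and any(s <= sc < e for s, e in exons):
        return sc
    return None
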