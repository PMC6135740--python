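"""Domain types and file readers/writers.

All genomic intervals inside the package are 0-based half-open. GTF and
RepeatMasker ``.out`` files are 1-based closed on disk and are converted at
read time — this module is the single conversion point. TSV is the canonical
exchange format for matrices and per-cell/per-embryo metadata; spliced read
alignments may arrive either as BED12 or as BAM/SAM (CIGAR ``N`` gaps split
blocks).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
import pysam

MARKERS = ("CFP", "GFP", "RFP", "YFP")
STAGES = ("four_cell", "eight_cell")
LINEAGES = ("A", "B", "unresolved")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CellRecord:
    """One blastomere: embryo membership, lineage-marker reads and QC stats.

    ``marker_reads`` always carries exactly the four Brainbow marker genes
    (GFP/CFP/RFP/YFP) mapped to read counts. ``lineage`` is ``"unresolved"``
    until (and unless) marker-based assignment succeeds.
    """

    cell_id: str
    embryo_id: str
    stage: str  # "four_cell" | "eight_cell"
    marker_reads: dict[str, int]
    uniquely_mapped_pairs: int
    lineage: str = "unresolved"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if set(self.marker_reads) != set(MARKERS):
            raise ValueError(
                f"marker_reads must have exactly the keys {MARKERS}, "
                f"got {sorted(self.marker_reads)}"
            )
        for m, n in self.marker_reads.items():
            if n < 0:
                raise ValueError(f"negative read count for {m}")
        if self.uniquely_mapped_pairs < 0:
            raise ValueError("uniquely_mapped_pairs must be non-negative")
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")


@dataclass
class EmbryoImageCounts:
    """Per-embryo imaging counts: marker+/marker− cells in the two poles.

    ``counts`` maps a marker (GFP or RFP) to a 4-tuple
    ``(pos_embryonic, neg_embryonic, pos_abembryonic, neg_abembryonic)``.
    The four entries of each marker's table sum to ``total_cells``.
    """

    embryo_id: str
    counts: dict[str, tuple[int, int, int, int]]
    total_cells: int

    def __post_init__(self) -> None:
        if self.total_cells <= 0:
            raise ValueError("total_cells must be positive")
        for marker, tab in self.counts.items():
            if len(tab) != 4 or any(x < 0 for x in tab):
                raise ValueError(f"bad 2x2 table for {marker}: {tab}")
            if sum(tab) != self.total_cells:
                raise ValueError(
                    f"{self.embryo_id}/{marker}: table sums to {sum(tab)}, "
                    f"expected total_cells={self.total_cells}"
                )


@dataclass
class TranscriptModel:
    """An exon-structured transcript on a genome.

    ``exons`` are 0-based half-open, sorted, non-overlapping. ``start_codon``
    is the 0-based genomic coordinate of the first base of the start codon in
    transcript orientation (highest coordinate of the codon on ``-``).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    exons: list[tuple[int, int]]
    start_codon: Optional[int] = None
    is_novel: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript with zero exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.start_codon is not None and not any(
            s <= self.start_codon < e for s, e in self.exons
        ):
            raise ValueError(f"{self.transcript_id}: start_codon outside exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]


@dataclass(frozen=True)
class RepeatFeature:
    """One RepeatMasker repeat copy (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    family: str
    repeat_class: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty repeat interval [{self.start},{self.end})")

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class ReadBlocks:
    """Aligned blocks of one read; ≥2 blocks means a spliced alignment."""

    read_id: str
    chrom: str
    blocks: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"{self.read_id}: read with zero blocks")
        self.blocks = sorted(tuple(b) for b in self.blocks)
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"{self.read_id}: empty block [{s},{e})")
        for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError(f"{self.read_id}: overlapping blocks")

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) >= 2


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Recognises ``exon`` and ``start_codon`` features; coordinates are
    converted from the 1-based closed GTF convention to 0-based half-open.
    A transcript tagged with attribute ``novel "true"`` (or class_code "j"
    style attribute ``is_novel``) is marked ``is_novel``.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    start_codons: dict[str, tuple[str, int, int]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(
                    f"{path}: malformed GTF line {lineno}: expected 9 fields"
                )
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:  # malformed line
                raise FormatError(f"{path}: malformed GTF line {lineno}: {exc}")
            if feat.featuretype not in ("exon", "start_codon"):
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
            except KeyError:
                raise FormatError(
                    f"{path}: line {lineno} lacks transcript_id attribute"
                )
            gid = feat.attributes.get("gene_id", [tid])[0]
            novel = feat.attributes.get("novel", ["false"])[0].lower() in (
                "true", "1", "yes",
            )
            if feat.featuretype == "exon":
                exons.setdefault(tid, []).append((feat.start - 1, feat.end))
                meta.setdefault(tid, {})
                meta[tid].update(
                    gene_id=gid, chrom=feat.seqid, strand=feat.strand,
                    is_novel=novel,
                )
            else:
                start_codons[tid] = (feat.strand, feat.start - 1, feat.end)

    out = []
    for tid, ex in exons.items():
        m = meta[tid]
        sc = None
        if tid in start_codons:
            strand, s0, e1 = start_codons[tid]
            sc = s0 if strand == "+" else e1 - 1
        out.append(
            TranscriptModel(
                transcript_id=tid, gene_id=m["gene_id"], chrom=m["chrom"],
                strand=m["strand"], exons=ex, start_codon=sc,
                is_novel=m["is_novel"],
            )
        )
    for tid in start_codons:
        if tid not in exons:
            raise FormatError(f"{path}: transcript {tid} has zero exons")
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF (exon + start_codon features, 1-based closed)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'novel "{"true" if t.is_novel else "false"}";'
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\trainbowseq\texon\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
            if t.start_codon is not None:
                if t.strand == "+":
                    s, e = t.start_codon, t.start_codon + 3
                else:
                    s, e = t.start_codon - 2, t.start_codon + 1
                fh.write(
                    f"{t.chrom}\trainbowseq\tstart_codon\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker
# ---------------------------------------------------------------------------

def read_repeatmasker(path: str | Path) -> list[RepeatFeature]:
    """Read repeats from RepeatMasker ``.out`` or from BED6.

    ``.out`` layout: two header lines, a blank line, then whitespace-delimited
    records with 1-based closed positions in columns 6–7, strand in column 9
    (``C`` = complement), repeat name in column 10 and ``class/family`` in
    column 11. BED records carry ``name#family/class`` in the name field.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("track") or (first and first.split("\t")[0].startswith("chr")):
        return _read_repeat_bed(path)
    return _read_repeat_out(path)


def _split_class_family(tag: str) -> tuple[str, str]:
    # RepeatMasker writes "class/family"; family defaults to class when absent
    if "/" in tag:
        cls, fam = tag.split("/", 1)
    else:
        cls = fam = tag
    return fam, cls


def _read_repeat_out(path: Path) -> list[RepeatFeature]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            # header lines start with "SW"/"score" labels
            if not fields[0].replace(".", "").isdigit():
                continue
            try:
                chrom = fields[4]
                begin, end = int(fields[5]), int(fields[6])
                strand = "-" if fields[8] == "C" else "+"
                name = fields[9]
                fam, cls = _split_class_family(fields[10])
            except (IndexError, ValueError) as exc:
                raise FormatError(
                    f"{path}: unparseable RepeatMasker record at line {lineno}: {exc}"
                )
            out.append(
                RepeatFeature(chrom, begin - 1, end, strand, name, fam, cls)
            )
    return out


def _read_repeat_bed(path: Path) -> list[RepeatFeature]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "."
                strand = fields[5] if len(fields) > 5 else "+"
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: bad BED record at line {lineno}: {exc}")
            if "#" in name:
                rep_name, tag = name.split("#", 1)
                fam, cls = _split_class_family(tag)
            else:
                rep_name = fam = cls = name
            out.append(RepeatFeature(chrom, start, end, strand, rep_name, fam, cls))
    return out


def write_repeat_bed(repeats: Iterable[RepeatFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            name = f"{r.repeat_name}#{r.repeat_class}/{r.family}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# TSV matrices / metadata
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene×cell FPKM matrix (TSV, first column = gene id)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index.name = None
    if mat.index.duplicated().any():
        dup = mat.index[mat.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    if mat.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate cell ids")
    if (mat.values < 0).any():
        raise FormatError(f"{path}: negative expression values")
    return mat


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


_CELL_COLS = [
    "cell_id", "embryo_id", "stage",
    *(f"reads_{m}" for m in MARKERS),
    "uniquely_mapped_pairs", "lineage",
]


def cells_to_frame(cells: Iterable[CellRecord]) -> pd.DataFrame:
    rows = []
    for c in cells:
        row = {
            "cell_id": c.cell_id, "embryo_id": c.embryo_id, "stage": c.stage,
            "uniquely_mapped_pairs": c.uniquely_mapped_pairs,
            "lineage": c.lineage,
        }
        for m in MARKERS:
            row[f"reads_{m}"] = c.marker_reads[m]
        rows.append(row)
    return pd.DataFrame(rows, columns=_CELL_COLS)


def frame_to_cells(frame: pd.DataFrame) -> list[CellRecord]:
    cells = []
    for _, row in frame.iterrows():
        cells.append(
            CellRecord(
                cell_id=str(row["cell_id"]), embryo_id=str(row["embryo_id"]),
                stage=str(row["stage"]),
                marker_reads={m: int(row[f"reads_{m}"]) for m in MARKERS},
                uniquely_mapped_pairs=int(row["uniquely_mapped_pairs"]),
                lineage=str(row["lineage"]),
            )
        )
    ids = [c.cell_id for c in cells]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate cell_id in cell table")
    return cells


def write_cells(cells: Iterable[CellRecord], path: str | Path) -> None:
    cells_to_frame(cells).to_csv(path, sep="\t", index=False)


def read_cells(path: str | Path) -> list[CellRecord]:
    return frame_to_cells(pd.read_csv(path, sep="\t"))


_IMG_COLS = ["embryo_id", "marker", "pos_embryonic", "neg_embryonic",
             "pos_abembryonic", "neg_abembryonic", "total_cells"]


def write_image_counts(counts: Iterable[EmbryoImageCounts], path: str | Path) -> None:
    rows = []
    for ec in counts:
        for marker, tab in sorted(ec.counts.items()):
            rows.append([ec.embryo_id, marker, *tab, ec.total_cells])
    pd.DataFrame(rows, columns=_IMG_COLS).to_csv(path, sep="\t", index=False)


def read_image_counts(path: str | Path) -> list[EmbryoImageCounts]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for eid, grp in frame.groupby("embryo_id", sort=False):
        counts = {}
        totals = set(grp["total_cells"])
        if len(totals) != 1:
            raise FormatError(f"{path}: inconsistent total_cells for {eid}")
        for _, row in grp.iterrows():
            tab = tuple(
                int(row[c]) for c in _IMG_COLS[2:6]
            )
            if any(x < 0 for x in tab):
                raise FormatError(f"{path}: negative count for {eid}")
            counts[str(row["marker"])] = tab
        out.append(EmbryoImageCounts(str(eid), counts, int(totals.pop())))
    return out


# ---------------------------------------------------------------------------
# read blocks (BED12 / BAM / SAM)
# ---------------------------------------------------------------------------

def read_read_blocks(path: str | Path) -> list[ReadBlocks]:
    """Read spliced-alignment blocks from BED12 or BAM/SAM.

    For BAM/SAM, blocks are reconstructed from the CIGAR: ``N`` gaps split
    blocks; ``M``/``=``/``X``/``D`` extend the current block; insertions and
    clips do not consume reference.
    """
    path = Path(path)
    if path.suffix.lower() in (".bam", ".sam"):
        return _read_blocks_bam(path)
    return _read_blocks_bed12(path)


def _read_blocks_bed12(path: Path) -> list[ReadBlocks]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            try:
                chrom, start, name = f[0], int(f[1]), f[3]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: bad BED12 record at line {lineno}: {exc}")
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(
                    f"{path}: line {lineno}: blockCount disagrees with block lists"
                )
            blocks = [
                (start + off, start + off + size)
                for off, size in zip(offsets, sizes)
            ]
            out.append(ReadBlocks(name, chrom, blocks))
    return out


def _read_blocks_bam(path: Path) -> list[ReadBlocks]:
    out = []
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            blocks = _blocks_from_cigar(aln.reference_start, aln.cigartuples)
            out.append(ReadBlocks(aln.query_name, aln.reference_name, blocks))
    return out


# CIGAR ops consuming reference: M=0, D=2, N=3, =7, X=8; N splits blocks
def _blocks_from_cigar(pos: int, cigartuples) -> list[tuple[int, int]]:
    blocks = []
    block_start = pos
    cur = pos
    for op, length in cigartuples:
        if op in (0, 2, 7, 8):
            cur += length
        elif op == 3:
            if cur > block_start:
                blocks.append((block_start, cur))
            cur += length
            block_start = cur
    if cur > block_start:
        blocks.append((block_start, cur))
    return blocks


def write_read_blocks_bed12(reads: Iterable[ReadBlocks], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            start = r.blocks[0][0]
            end = r.blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in r.blocks)
            offsets = ",".join(str(s - start) for s, _ in r.blocks)
            fh.write(
                f"{r.chrom}\t{start}\t{end}\t{r.read_id}\t0\t+\t{start}\t{end}"
                f"\t0\t{len(r.blocks)}\t{sizes}\t{offsets}\n"
            )
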