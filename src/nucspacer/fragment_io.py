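"""Fragment, gene-annotation and signal-track I/O.

All coordinates are BED-style: 0-based, half-open intervals. A sequenced
paired-end fragment is an interval [start, end); its midpoint is taken as
the nucleosome dyad. Gene records carry TSS/TTS in transcription order, so
minus-strand genes have tss > tts (the TSS is the rightmost transcribed
base of the annotated interval).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_GFF3_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")
_GFF3_NAME_RE = re.compile(r"(?:^|;)\s*Name=([^;]+)")


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced MNase-protected fragment as a genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("fragment chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SizeClassConfig:
    """Fragment-length gates for mono- and dinucleosome classes.

    Defaults follow the conventional MNase-seq size selection:
    mononucleosomes 120-180 bp, close-packed dinucleosomes 250-350 bp,
    both bounds inclusive.
    """

    mono_min: int = 120
    mono_max: int = 180
    di_min: int = 250
    di_max: int = 350
    bounds_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (self.mono_min <= self.mono_max < self.di_min <= self.di_max):
            raise ValueError(
                "size-class bounds must satisfy mono_min <= mono_max < di_min <= di_max"
            )

    def classify_length(self, length: int) -> str:
        """Return 'mono', 'di' or 'other' for a fragment length."""
        if self.bounds_inclusive:
            if self.mono_min <= length <= self.mono_max:
                return "mono"
            if self.di_min <= length <= self.di_max:
                return "di"
        else:
            if self.mono_min < length < self.mono_max:
                return "mono"
            if self.di_min < length < self.di_max:
                return "di"
        return "other"


@dataclass
class GeneRecord:
    """Gene anchor data: TSS, TTS, strand and (optionally) the +1 dyad.

    tss/tts follow transcription order: for '+' genes tss < tts, for '-'
    genes tss > tts. plus1_dyad, when set, is the genomic position of the
    major +1 nucleosome dyad for this gene.
    """

    gene_id: str
    chrom: str
    tss: int
    tts: int
    strand: str
    plus1_dyad: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id}: '+' gene requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"gene {self.gene_id}: '-' gene requires tss > tts")

    @property
    def gene_length(self) -> int:
        return abs(self.tts - self.tss)

    @property
    def direction(self) -> int:
        """+1 for plus-strand genes, -1 for minus-strand genes."""
        return 1 if self.strand == "+" else -1


@dataclass
class SignalTrack:
    """Per-interval numeric signal (e.g. Pol II ChIP density) over a genome.

    Intervals are half-open, non-overlapping per chromosome, stored as a
    DataFrame with columns chrom/start/end/value. genomic_mean is total
    signal over total covered length.
    """

    intervals: pd.DataFrame
    genomic_mean: float = field(init=False)

    def __post_init__(self) -> None:
        df = self.intervals
        if df.empty:
            raise ValueError("no signal: track has zero intervals")
        if (df["value"] < 0).any():
            raise ValueError("signal values must be >= 0")
        lengths = df["end"] - df["start"]
        if (lengths <= 0).any():
            raise ValueError("signal intervals must have end > start")
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise ValueError(f"overlapping signal intervals on {chrom}")
        total = float((lengths * df["value"]).sum())
        covered = int(lengths.sum())
        self.genomic_mean = total / covered
        if self.genomic_mean == 0:
            logger.warning("signal track genomic mean is 0")

    def mean_over(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """Mean signal over [start, end) and the number of covered bases."""
        sub = self.intervals[self.intervals["chrom"] == chrom]
        total = 0.0
        covered = 0
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            lo, hi = max(s, start), min(e, end)
            if hi > lo:
                total += (hi - lo) * v
                covered += hi - lo
        if covered == 0:
            return 0.0, 0
        return total / covered, covered


def fragment_dyad(f: FragmentRecord) -> int:
    """Dyad position = fragment midpoint, floor((start+end)/2).

    For even-length fragments the left-of-center base is chosen; the choice
    is deterministic and translation-invariant.
    """
    return (f.start + f.end) // 2


def classify_by_size(
    fragments: Iterable[FragmentRecord], cfg: SizeClassConfig | None = None
) -> tuple[list[FragmentRecord], list[FragmentRecord], list[FragmentRecord]]:
    """Partition fragments into (mono, di, other) by length gates.

    The partition is total and exhaustive: every fragment lands in exactly
    one class.
    """
    cfg = cfg or SizeClassConfig()
    mono: list[FragmentRecord] = []
    di: list[FragmentRecord] = []
    other: list[FragmentRecord] = []
    bins = {"mono": mono, "di": di, "other": other}
    for f in fragments:
        bins[cfg.classify_length(f.length)].append(f)
    logger.info(
        "size classes: mono=%d di=%d other=%d", len(mono), len(di), len(other)
    )
    return mono, di, other


def read_fragments(path: str | Path, format: str = "bed") -> list[FragmentRecord]:
    """Read fragments from BED3+ or from name-sorted paired alignments.

    format='bed': first three columns chrom/start/end, extra columns ignored.
    format='paired-alignments': SAM/BAM of properly paired reads; the
    template interval of each proper pair becomes one fragment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"fragments not found: {path}")
    if format == "bed":
        return _read_fragments_bed(path)
    if format == "paired-alignments":
        return _read_fragments_pairs(path)
    raise ValueError(f"unknown fragment format: {format!r}")


def _read_fragments_bed(path: Path) -> list[FragmentRecord]:
    records: list[FragmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {line!r}") from exc
            if end <= start:
                raise ValueError(f"end <= start at line {lineno}")
            records.append(FragmentRecord(chrom, start, end))
    if not records:
        logger.warning("no fragments read from %s", path)
    logger.info("read %d fragments from %s", len(records), path)
    return records


def _read_fragments_pairs(path: Path) -> list[FragmentRecord]:
    import pysam

    records: list[FragmentRecord] = []
    pending: dict[str, object] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af:
            if (
                read.is_unmapped
                or read.mate_is_unmapped
                or not read.is_proper_pair
                or read.is_secondary
                or read.is_supplementary
            ):
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            start = min(read.reference_start, mate.reference_start)
            end = max(read.reference_end, mate.reference_end)
            if end > start:
                records.append(FragmentRecord(read.reference_name, start, end))
    if pending:
        logger.warning("%d unpaired proper-pair reads ignored", len(pending))
    logger.info("read %d fragment pairs from %s", len(records), path)
    return records


def write_fragments_bed(fragments: Sequence[FragmentRecord], path: str | Path) -> None:
    """Write fragments as BED3 (0-based, half-open)."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\n")


def read_genes(path: str | Path, format: str = "tsv") -> list[GeneRecord]:
    """Read a gene annotation as BED6, GFF3 (feature 'gene') or TSV.

    The TSV format is this package's native table with header columns
    gene_id/chrom/tss/tts/strand and optional plus1_dyad. For BED6 and GFF3
    the TSS/TTS convention is applied: minus-strand TSS = interval end - 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genes not found: {path}")
    if format == "tsv":
        genes = _read_genes_tsv(path)
    elif format == "bed6":
        genes = _read_genes_bed6(path)
    elif format == "gff3":
        genes = _read_genes_gff3(path)
    else:
        raise ValueError(f"unknown gene format: {format!r}")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id: {g.gene_id}")
        seen.add(g.gene_id)
    logger.info("read %d genes from %s", len(genes), path)
    return genes


def _interval_to_tss_tts(start: int, end: int, strand: str) -> tuple[int, int]:
    # minus-strand TSS is the rightmost transcribed base (end - 1)
    if strand == "+":
        return start, end
    return end - 1, start


def _read_genes_bed6(path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"BED6 requires 6 columns at line {lineno}")
            chrom, start, end, name, _score, strand = parts[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"missing/invalid strand at line {lineno}")
            tss, tts = _interval_to_tss_tts(int(start), int(end), strand)
            genes.append(GeneRecord(name, chrom, tss, tts, strand))
    return genes


def _read_genes_gff3(path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line {lineno}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"gene without strand at line {lineno}")
            m = _GFF3_ID_RE.search(attrs) or _GFF3_NAME_RE.search(attrs)
            if m is None:
                raise ValueError(f"gene without ID at line {lineno}")
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            tss, tts = _interval_to_tss_tts(int(start) - 1, int(end), strand)
            genes.append(GeneRecord(m.group(1), chrom, tss, tts, strand))
    return genes


def _read_genes_tsv(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "tss", "tts", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene TSV missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        plus1 = getattr(row, "plus1_dyad", None)
        if plus1 is not None and pd.isna(plus1):
            plus1 = None
        genes.append(
            GeneRecord(
                str(row.gene_id),
                str(row.chrom),
                int(row.tss),
                int(row.tts),
                str(row.strand),
                int(plus1) if plus1 is not None else None,
            )
        )
    return genes


def write_genes_tsv(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write genes as the native TSV table (0-based coordinates)."""
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "tss": [g.tss for g in genes],
            "tts": [g.tts for g in genes],
            "strand": [g.strand for g in genes],
            "plus1_dyad": [g.plus1_dyad for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_signal_track(path: str | Path) -> SignalTrack:
    """Read a bedGraph signal track (chrom, start, end, value)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal track not found: {path}")
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        skiprows=_count_bedgraph_header(path),
    )
    if df.empty:
        raise ValueError(f"no signal in {path}")
    return SignalTrack(df)


def _count_bedgraph_header(path: Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_signal_bedgraph(track: SignalTrack, path: str | Path) -> None:
    track.intervals.to_csv(path, sep="\t", index=False, header=False)
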