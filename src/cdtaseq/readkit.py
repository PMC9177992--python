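"""Read trimming, filtration, UMI deduplication and transcript assignment.

Operates on 3'-end reads from a UMI-barcoded polyA library. Reads carry an
8-base UMI (and sample barcode) in the read name; after back-conversion each
read is summarized by its genomic-T count ``X``, conversion count ``Y``,
non-conversion error count ``E`` and the number of loci it aligned to.
Filtration keeps reads with X <= 30, at most 5 loci and at most 3 errors
(T->C conversions excluded); duplicates sharing (contig, strand, position,
UMI) are collapsed to the copy with the fewest total deviations from the
reference. Surviving reads are assigned to transcripts by intersection with
a 400-base window around each annotated transcription termination site
(300 upstream, 100 downstream, in transcription orientation).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "ReadRecord",
    "TtsWindow",
    "FilterReport",
    "trim_polya",
    "filter_reads",
    "dedup_umis",
    "assign_to_transcripts",
    "umi_stats",
    "tts_windows_from_bed",
    "tts_windows_from_gff",
    "records_from_sam",
    "records_to_tsv",
    "records_from_tsv",
]

MAX_GENOMIC_T = 30
MAX_LOCI = 5
MAX_ERRORS = 3
MIN_TRIMMED_LEN = 26  # "> 25 bases remaining"
TTS_UPSTREAM = 300
TTS_DOWNSTREAM = 100


@dataclass(frozen=True)
class ReadRecord:
    """One filtered, back-converted read.

    ``position`` is the 5' alignment position in transcription
    orientation (plus-strand reads span [position, position+length),
    minus-strand reads [position-length, position)); 3'-end libraries
    share their fragmentation site, so the 5' end is the discriminative
    coordinate for deduplication. ``X``: genomic Ts in the aligned span
    (transcribed strand), ``Y``: T->C conversions, ``E``: other
    mismatches, ``n_loci``: reported alignment loci for this read.
    """

    id: str
    barcode: str
    umi: str
    contig: str
    strand: str
    position: int
    X: int
    Y: int
    E: int = 0
    n_loci: int = 1
    length: int = 45

    def __post_init__(self) -> None:
        if not (0 <= self.Y <= self.X):
            raise ValueError(f"need 0 <= Y <= X, got X={self.X}, Y={self.Y}")
        if self.E < 0 or self.n_loci < 1:
            raise ValueError("E must be >= 0 and n_loci >= 1")

    @property
    def deviations(self) -> int:
        """Total deviations from the reference (errors + conversions)."""
        return self.E + self.Y

    @property
    def dedup_key(self) -> tuple:
        return (self.contig, self.strand, self.position, self.umi)

    @property
    def interval(self) -> tuple[int, int]:
        """Aligned span as a plus-strand half-open interval."""
        if self.strand == "+":
            return self.position, self.position + self.length
        return self.position - self.length, self.position


@dataclass(frozen=True)
class TtsWindow:
    """Assignment window around a transcription termination site.

    ``start``/``end`` are 0-based half-open plus-strand coordinates; the
    window spans 300 bases upstream through 100 downstream of the TTS in
    the direction of transcription.
    """

    transcript_id: str
    contig: str
    strand: str
    start: int
    end: int

    @classmethod
    def from_tts(cls, transcript_id: str, contig: str, strand: str, tts: int) -> "TtsWindow":
        if strand == "+":
            start, end = tts - TTS_UPSTREAM, tts + TTS_DOWNSTREAM
        elif strand == "-":
            start, end = tts - TTS_DOWNSTREAM, tts + TTS_UPSTREAM
        else:
            raise ValueError(f"bad strand {strand!r}")
        return cls(transcript_id, contig, strand, start, end)


_POLYA_RE = re.compile(r"A+$")


def trim_polya(seq: str) -> str | None:
    """Strip a trailing polyA run; reject reads with <= 25 bases left.

    Returns the trimmed sequence, or None if the read is rejected.
    """
    if not seq:
        return None
    trimmed = _POLYA_RE.sub("", seq.upper())
    return trimmed if len(trimmed) >= MIN_TRIMMED_LEN else None


@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    reasons: Counter = None

    def __post_init__(self):
        if self.reasons is None:
            self.reasons = Counter()


def filter_reads(
    records: Iterable[ReadRecord],
    max_t: int = MAX_GENOMIC_T,
    max_loci: int = MAX_LOCI,
    max_errors: int = MAX_ERRORS,
) -> tuple[list[ReadRecord], FilterReport]:
    """Apply the read-level filters; thresholds are inclusive.

    Keeps records with X <= ``max_t``, n_loci <= ``max_loci`` and
    E <= ``max_errors`` (conversions do not count as errors). A record
    failing several filters is counted once per failed filter in the
    report.
    """
    report = FilterReport()
    kept = []
    for rec in records:
        report.n_input += 1
        ok = True
        if rec.X > max_t:
            report.reasons["too_many_genomic_t"] += 1
            ok = False
        if rec.n_loci > max_loci:
            report.reasons["multimapper"] += 1
            ok = False
        if rec.E > max_errors:
            report.reasons["too_many_errors"] += 1
            ok = False
        if ok:
            kept.append(rec)
    report.n_retained = len(kept)
    return kept, report


def dedup_umis(records: Iterable[ReadRecord]) -> list[ReadRecord]:
    """Collapse duplicates sharing (contig, strand, position, UMI).

    In each group the record with the fewest total deviations from the
    reference (E + Y) is kept; ties break on the lexicographically
    smallest read id, so the result is deterministic.
    """
    best: dict[tuple, ReadRecord] = {}
    for rec in records:
        key = rec.dedup_key
        cur = best.get(key)
        if cur is None or (rec.deviations, rec.id) < (cur.deviations, cur.id):
            best[key] = rec
    return list(best.values())


def umi_stats(records: Iterable[ReadRecord]) -> dict:
    """Reads-per-UMI-group summary on pre-dedup records."""
    sizes = Counter(rec.dedup_key for rec in records)
    counts = list(sizes.values())
    if not counts:
        return {"n_reads": 0, "n_groups": 0, "mean_reads_per_umi": float("nan"), "size_distribution": {}}
    return {
        "n_reads": sum(counts),
        "n_groups": len(counts),
        "mean_reads_per_umi": sum(counts) / len(counts),
        "size_distribution": dict(Counter(counts)),
    }


def assign_to_transcripts(
    records: Sequence[ReadRecord],
    windows: Sequence[TtsWindow],
    known_contigs: set[str] | None = None,
    unique: bool = False,
) -> tuple[list[tuple[str, ReadRecord]], list[ReadRecord]]:
    """Assign reads to every TTS window they intersect on the same strand.

    Returns ``(assigned, unassigned)`` where ``assigned`` is a list of
    (transcript id, record) pairs. With ``unique=True`` a read overlapping
    several windows goes only to the window with the largest overlap
    (ties: lexicographically smallest transcript id).
    """
    if known_contigs is not None:
        for w in windows:
            if w.contig not in known_contigs:
                raise KeyError(f"window {w.transcript_id} on unknown contig {w.contig!r}")
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for w in windows:
        if w.end > w.start:
            trees[(w.contig, w.strand)][w.start:w.end] = w
    assigned: list[tuple[str, ReadRecord]] = []
    unassigned: list[ReadRecord] = []
    for rec in records:
        tree = trees.get((rec.contig, rec.strand))
        lo, hi = rec.interval
        hits = tree[lo:hi] if tree else ()
        if not hits:
            unassigned.append(rec)
            continue
        if unique and len(hits) > 1:
            def overlap(iv):
                return min(iv.end, hi) - max(iv.begin, lo)
            best = min(hits, key=lambda iv: (-overlap(iv), iv.data.transcript_id))
            assigned.append((best.data.transcript_id, rec))
        else:
            for iv in sorted(hits, key=lambda iv: iv.data.transcript_id):
                assigned.append((iv.data.transcript_id, rec))
    return assigned, unassigned


def tts_windows_from_bed(path) -> list[TtsWindow]:
    """TTS windows from a BED file (0-based half-open).

    Single-base features are taken as the TTS itself; for longer features
    the TTS is the transcription-orientation end (end-1 on '+', start
    on '-'). Requires at least 6 columns (name in col 4, strand in col 6).
    """
    windows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            tts = end - 1 if strand == "+" else start
            windows.append(TtsWindow.from_tts(name, chrom, strand, tts))
    return windows


def tts_windows_from_gff(path, id_attr: str = "ID") -> list[TtsWindow]:
    """TTS windows from a GFF3 file (1-based inclusive, converted on read)."""
    windows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            m = re.search(rf"{id_attr}=([^;]+)", attrs)
            name = m.group(1) if m else f"{chrom}:{start}-{end}"
            # to 0-based half-open: [start-1, end)
            tts = end - 1 if strand == "+" else start - 1
            windows.append(TtsWindow.from_tts(name, chrom, strand, tts))
    return windows


_NAME_RE = re.compile(r"^(?P<id>.+)_(?P<bc>[ACGTN]+)_(?P<umi>[ACGTN]{8})$")


def _parse_read_name(name: str) -> tuple[str, str, str]:
    m = _NAME_RE.match(name)
    if not m:
        return name, "", ""
    return m.group("id"), m.group("bc"), m.group("umi")


def records_from_sam(path, reference=None) -> list[ReadRecord]:
    """Read back-converted alignments from SAM/BAM into ReadRecords.

    Expects alignments in *original* reference coordinates with the read
    name carrying ``<id>_<barcode>_<umi>``. Per-read statistics are taken
    from tags when present: ``XT`` (genomic Ts), ``XC`` (conversions),
    ``XE`` (other errors), ``NH`` (loci). If the tags are absent and a
    :class:`~cdtaseq.genomekit.ReferenceSet` is supplied, X/Y/E are
    recomputed by comparing the stored sequence to the reference.
    """
    import pysam

    from .genomekit import revcomp as _rc

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            rid, bc, umi = _parse_read_name(aln.query_name)
            strand = "-" if aln.is_reverse else "+"
            if aln.has_tag("XT"):
                x, y = aln.get_tag("XT"), aln.get_tag("XC")
                e = aln.get_tag("XE") if aln.has_tag("XE") else 0
            elif reference is not None:
                seq = aln.query_sequence
                ref_seg = reference.contigs[aln.reference_name][
                    aln.reference_start : aln.reference_start + len(seq)
                ]
                if strand == "-":
                    seq, ref_seg = _rc(seq), _rc(ref_seg)
                x = sum(1 for b in ref_seg if b == "T")
                y = sum(1 for rb, qb in zip(ref_seg, seq) if rb == "T" and qb == "C")
                e = sum(1 for rb, qb in zip(ref_seg, seq) if rb != qb) - y
            else:
                raise ValueError("SAM lacks XT/XC tags and no reference was given")
            n_loci = aln.get_tag("NH") if aln.has_tag("NH") else 1
            records.append(
                ReadRecord(
                    id=rid,
                    barcode=bc,
                    umi=umi,
                    contig=aln.reference_name,
                    strand=strand,
                    position=aln.reference_start if strand == "+" else aln.reference_end,
                    X=x,
                    Y=y,
                    E=e,
                    n_loci=n_loci,
                    length=aln.query_length or 45,
                )
            )
    return records


_COLUMNS = ["id", "barcode", "umi", "contig", "strand", "position", "X", "Y", "E", "n_loci", "length"]


def records_to_tsv(records: Iterable[ReadRecord], path) -> None:
    df = pd.DataFrame([[getattr(r, c) for c in _COLUMNS] for r in records], columns=_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def records_from_tsv(path) -> list[ReadRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "umi": str})
    return [
        ReadRecord(**{c: (row[c] if not pd.isna(row[c]) else "") for c in _COLUMNS})
        for _, row in df.iterrows()
    ]
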