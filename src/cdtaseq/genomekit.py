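"""Conversion-aware and spike-in-redacted reference genomes.

Nucleotide-conversion sequencing reads 4tU-marked uracils as cytosines, so
reads from labeled molecules carry T->C mismatches that defeat ordinary
alignment. The standard remedy is a *three-letter* reference: every T on
each strand is rewritten to C, giving an ACG-only genome with one contig
per strand. Reads are T->C-collapsed the same way before alignment, and a
back-conversion step restores original coordinates and classifies each
mismatch of the *original* read against the *original* reference as either
a T->C conversion (on the transcribed strand) or an ordinary error.

A second concern is the cross-species spike-in used for normalization:
reads from genome regions shared between host and spike species are
ambiguous. We therefore *redact* the spike genome by masking to 'N' every
position covered by a k-mer (default k=18) that occurs anywhere in the
host genome, on either strand. Masking preserves coordinates, and aligners
treat N as unmatchable, so redacted-genome alignments are spike-specific.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceSet",
    "Discrepancy",
    "BackconvertedAlignment",
    "revcomp",
    "convert_three_letter",
    "redact_spike_genome",
    "backconvert_alignment",
    "FWD_SUFFIX",
    "REV_SUFFIX",
]

FWD_SUFFIX = "__fwd"
REV_SUFFIX = "__rev"

_VALID = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceSet:
    """A named collection of contigs with a provenance tag.

    Parameters
    ----------
    contigs
        Mapping of contig name to upper-case nucleotide string.
    provenance
        One of ``original``, ``three_letter``, ``redacted``.
    k
        Redaction k-mer length; only meaningful for ``redacted`` sets.
    """

    contigs: dict[str, str]
    provenance: str = "original"
    k: int | None = None

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}
        for name, seq in self.contigs.items():
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.contigs)

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @classmethod
    def from_fasta(cls, path, provenance: str = "original") -> "ReferenceSet":
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(contigs, provenance=provenance)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
            writer.write_file(records)


@dataclass(frozen=True)
class Discrepancy:
    """One mismatch of the original read vs the original reference.

    ``offset`` indexes into the read (transcription orientation);
    ``kind`` is ``"conversion"`` for reference-T read-C on the transcribed
    strand, else ``"other"``.
    """

    offset: int
    ref_base: str
    read_base: str
    kind: str


@dataclass
class BackconvertedAlignment:
    """An alignment restored to original reference coordinates.

    ``start``/``end`` are 0-based half-open on the plus strand of the
    original contig; ``strand`` is the transcribed strand of the read.
    """

    read_id: str
    contig: str
    strand: str
    start: int
    end: int
    sequence: str
    discrepancies: list[Discrepancy] = field(default_factory=list)

    @property
    def n_conversions(self) -> int:
        return sum(1 for d in self.discrepancies if d.kind == "conversion")

    @property
    def n_other(self) -> int:
        return sum(1 for d in self.discrepancies if d.kind == "other")

    @property
    def n_genomic_t(self) -> int:
        """Ts in the reference over the aligned span, transcribed strand."""
        return self._n_genomic_t

    _n_genomic_t: int = 0


def convert_three_letter(ref: ReferenceSet) -> ReferenceSet:
    """Build the ACG-only (three-letter) genome: one contig per strand.

    For each input contig ``c`` emits ``c__fwd`` (plus strand, T->C) and
    ``c__rev`` (reverse complement, T->C). Lengths are preserved.
    """
    if ref.provenance != "original":
        raise ValueError(f"expected original provenance, got {ref.provenance!r}")
    out: dict[str, str] = {}
    for name, seq in ref.contigs.items():
        out[name + FWD_SUFFIX] = seq.replace("T", "C")
        out[name + REV_SUFFIX] = revcomp(seq).replace("T", "C")
    converted = ReferenceSet.__new__(ReferenceSet)
    converted.contigs = out
    converted.provenance = "three_letter"
    converted.k = None
    return converted


def _kmer_set(contigs: Iterable[str], k: int) -> set[str]:
    kmers: set[str] = set()
    for seq in contigs:
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i : i + k])
    return kmers


def redact_spike_genome(
    spike: ReferenceSet, host: ReferenceSet, k: int = 18
) -> tuple[ReferenceSet, float]:
    """Mask every spike position covered by a k-mer present in the host.

    Host k-mers are collected from both strands. Any spike k-mer (checked
    on the plus strand; the host set already covers both orientations)
    found in the host set masks all k of its positions to 'N'. Returns the
    redacted reference and the fraction of bases masked.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if spike.provenance != "original" or host.provenance != "original":
        raise ValueError("both references must have original provenance")

    if all(len(s) < k for s in spike.contigs.values()):
        warnings.warn(f"k={k} exceeds every spike contig length; output is all-N")
        out = {name: "N" * len(seq) for name, seq in spike.contigs.items()}
        red = ReferenceSet(out, provenance="redacted", k=k)
        return red, 1.0 if spike.total_length() else 0.0

    host_kmers = _kmer_set(host.contigs.values(), k)
    host_kmers |= _kmer_set((revcomp(s) for s in host.contigs.values()), k)

    out = {}
    masked = 0
    total = 0
    for name, seq in spike.contigs.items():
        total += len(seq)
        n = len(seq)
        mask = bytearray(n)
        for i in range(n - k + 1):
            if seq[i : i + k] in host_kmers:
                for j in range(i, i + k):
                    mask[j] = 1
        if any(mask):
            chars = list(seq)
            for i, m in enumerate(mask):
                if m:
                    chars[i] = "N"
            out[name] = "".join(chars)
            masked += sum(mask)
        else:
            out[name] = seq
    red = ReferenceSet(out, provenance="redacted", k=k)
    return red, masked / total if total else 0.0


def backconvert_alignment(
    read_id: str,
    contig: str,
    start: int,
    read_original_seq: str,
    ref: ReferenceSet,
) -> BackconvertedAlignment:
    """Map a three-letter-contig alignment back to original coordinates.

    Parameters
    ----------
    contig
        Three-letter contig name (``<orig>__fwd`` or ``<orig>__rev``).
    start
        0-based start on the three-letter contig.
    read_original_seq
        The read's *unconverted* sequence, in the orientation it was
        aligned (i.e. as T->C-collapsed and placed on the contig).
    ref
        The original (unconverted) reference.

    The aligned span is compared base-by-base against the original
    reference in transcription orientation; reference-T read-C mismatches
    are conversions, everything else an error.
    """
    if contig.endswith(FWD_SUFFIX):
        orig_name, strand = contig[: -len(FWD_SUFFIX)], "+"
    elif contig.endswith(REV_SUFFIX):
        orig_name, strand = contig[: -len(REV_SUFFIX)], "-"
    else:
        raise ValueError(f"{contig!r} is not a three-letter contig name")
    if orig_name not in ref.contigs:
        raise KeyError(f"contig {orig_name!r} not in original reference")
    orig = ref.contigs[orig_name]
    n = len(read_original_seq)
    if strand == "+":
        g_start, g_end = start, start + n
        ref_seg = orig[g_start:g_end]
    else:
        # position on the revcomp contig maps to the far end of the plus strand
        g_start = len(orig) - (start + n)
        g_end = g_start + n
        ref_seg = revcomp(orig[g_start:g_end])
    if g_start < 0 or g_end > len(orig):
        raise ValueError("alignment extends past contig boundary")

    discrepancies = []
    n_t = 0
    for i, (rb, qb) in enumerate(zip(ref_seg, read_original_seq)):
        if rb == "T":
            n_t += 1
        if rb != qb:
            kind = "conversion" if (rb == "T" and qb == "C") else "other"
            discrepancies.append(Discrepancy(i, rb, qb, kind))
    aln = BackconvertedAlignment(
        read_id=read_id,
        contig=orig_name,
        strand=strand,
        start=g_start,
        end=g_end,
        sequence=read_original_seq,
        discrepancies=discrepancies,
    )
    aln._n_genomic_t = n_t
    return aln
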