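"""Alignment and reference input.

All downstream stages consume :class:`ReadAlignment` and
:class:`ReferenceWindow` records rather than raw files. Coordinates are
0-based half-open everywhere inside the package; conversion to 1-based
happens only in the VCF writer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional

import pysam
from pyfaidx import Fasta

log = logging.getLogger(__name__)

# CIGAR ops by what they consume
QUERY_OPS = frozenset("M=XIS")
REF_OPS = frozenset("M=XD")
_CIGAR_CODES = "MIDNSHP=XB"

#: MAPQ floor for discovery-time signature scanning. Genotyping-time read
#: scoring uses 0 so every local read can vote.
DEFAULT_MIN_MAPQ = 10

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadAlignment:
    """One BAM record (primary or supplementary) in internal form."""

    read_id: str
    sample_id: str
    contig: str
    start: int  # 0-based reference position of first aligned base
    cigar: list  # list of (op: str, length: int)
    seq: str  # as stored (reference-forward orientation), may be ""
    mapq: int
    is_reverse: bool
    supplementary_of: Optional[str] = None  # read_id link for split segments

    @property
    def is_supplementary(self) -> bool:
        return self.supplementary_of is not None

    @property
    def end(self) -> int:
        """0-based exclusive reference end."""
        return self.start + sum(n for op, n in self.cigar if op in REF_OPS)

    @property
    def query_length(self) -> int:
        """Length of the full query including soft and hard clips."""
        return sum(n for op, n in self.cigar if op in QUERY_OPS or op == "H")

    def query_interval(self) -> tuple[int, int]:
        """Aligned query interval in original-read coordinates (half-open).

        Soft and hard clips count toward the read length; for reverse-strand
        records the stored orientation is flipped back to as-sequenced.
        """
        lead = 0
        for op, n in self.cigar:
            if op in "SH":
                lead += n
            else:
                break
        aligned = sum(n for op, n in self.cigar if op in "M=XI")
        qlen = self.query_length
        if self.is_reverse:
            return qlen - lead - aligned, qlen - lead
        return lead, lead + aligned


@dataclass
class ReferenceWindow:
    contig: str
    start: int  # 0-based half-open
    end: int
    seq: str  # uppercase

    def __post_init__(self):
        assert len(self.seq) == self.end - self.start


class ReferenceGenome:
    """Thin accessor around an indexed FASTA."""

    def __init__(self, path: str):
        self._fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    @property
    def contigs(self) -> list[str]:
        return list(self._fa.keys())

    def contig_length(self, contig: str) -> int:
        return len(self._fa[contig])

    def window(self, contig: str, start: int, end: int) -> ReferenceWindow:
        if contig not in self._fa:
            raise KeyError(f"unknown contig {contig!r} in reference")
        clen = len(self._fa[contig])
        if end > clen:
            log.warning("window end %d beyond %s length %d; clamping", end, contig, clen)
            end = clen
        start = max(0, min(start, end))
        seq = str(self._fa[contig][start:end]) if end > start else ""
        return ReferenceWindow(contig, start, end, seq)


def fetch_reference(fasta_path: str, contig: str, start: int, end: int) -> ReferenceWindow:
    """Fetch an uppercase half-open reference window (end clamped with warning)."""
    return ReferenceGenome(fasta_path).window(contig, start, end)


def _to_internal(rec: pysam.AlignedSegment, sample_id: str) -> ReadAlignment:
    cigar = [(_CIGAR_CODES[op], n) for op, n in rec.cigartuples]
    return ReadAlignment(
        read_id=rec.query_name,
        sample_id=sample_id,
        contig=rec.reference_name,
        start=rec.reference_start,
        cigar=cigar,
        seq=rec.query_sequence or "",
        mapq=rec.mapping_quality,
        is_reverse=rec.is_reverse,
        supplementary_of=rec.query_name if rec.is_supplementary else None,
    )


def load_alignments(
    path: str,
    sample_id: str,
    region: Optional[tuple] = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> Iterator[ReadAlignment]:
    """Stream primary + supplementary alignments from a sorted, indexed BAM.

    ``region`` is ``(contig,)`` or ``(contig, start, end)`` with 0-based
    half-open coordinates. Secondary and unmapped records are excluded; split
    segments of one read share ``read_id`` and supplementary records carry a
    ``supplementary_of`` link.
    """
    bam = pysam.AlignmentFile(str(path), "rb")
    hd = bam.header.to_dict().get("HD", {})
    if hd.get("SO") != "coordinate":
        raise ValueError(
            f"{path}: BAM must be coordinate-sorted (found SO={hd.get('SO')!r}); "
            "run `samtools sort` first"
        )
    try:
        bam.check_index()
    except (ValueError, AttributeError) as e:
        raise FileNotFoundError(
            f"{path}: missing BAM index; run `samtools index {path}`"
        ) from e
    it = bam.fetch(*region) if region else bam.fetch()
    for rec in it:
        if rec.is_secondary or rec.is_unmapped:
            continue
        if rec.mapping_quality < min_mapq:
            continue
        yield _to_internal(rec, sample_id)
    bam.close()
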