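"""SV-associated alignment signatures.

A signature is one read-level observation pointing at a structural variant:
a large CIGAR indel run, a split-read junction between two alignment
segments of the same read, or a long terminal soft-clip. Signatures are the
input to clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .alignio import ReadAlignment

#: Seed threshold for indel signatures. Deliberately below the 50 bp SV size
#: definition so events fragmented into smaller CIGAR runs still seed a
#: cluster; the final |SVLEN| >= 50 filter is applied after refinement.
DEFAULT_MIN_SIGNATURE_SIZE = 35
#: Soft-clips shorter than this are treated as noise.
DEFAULT_MIN_CLIP_SIZE = 200
#: Same-kind indel runs on one read closer than this merge into one signature.
DEFAULT_MAX_GAP = 50


class SigKind(str, Enum):
    INDEL_DEL = "INDEL_DEL"
    INDEL_INS = "INDEL_INS"
    SPLIT_JUNCTION = "SPLIT_JUNCTION"
    SOFTCLIP = "SOFTCLIP"


class Orient(str, Enum):
    #: retained (aligned) sequence lies left of ``pos``; ``pos`` is the
    #: exclusive end of the retained segment.
    LEFT_ANCHOR = "left_anchor"
    #: retained sequence lies right of ``pos``; ``pos`` is its first base.
    RIGHT_ANCHOR = "right_anchor"


@dataclass(frozen=True)
class Breakend:
    contig: str
    pos: int  # 0-based base adjacent to the junction
    orient: Orient


@dataclass
class SvSignature:
    kind: SigKind
    contig: str
    pos: int  # 0-based; for deletions the first deleted base
    size: int
    read_id: str
    sample_id: str
    ins_seq: Optional[str] = None
    mate: Optional[Breakend] = None  # for SPLIT_JUNCTION
    orient: Optional[Orient] = None  # this side's orientation (SPLIT/SOFTCLIP)

    def __post_init__(self):
        if self.kind == SigKind.INDEL_INS and self.ins_seq is not None:
            assert len(self.ins_seq) == self.size
        if self.kind == SigKind.SPLIT_JUNCTION:
            assert self.mate is not None


def extract_signatures(
    aln: ReadAlignment,
    min_signature_size: int = DEFAULT_MIN_SIGNATURE_SIZE,
    min_clip_size: int = DEFAULT_MIN_CLIP_SIZE,
) -> list[SvSignature]:
    """Scan one alignment's CIGAR for indel and soft-clip signatures.

    Split-read junctions need all segments of a read and are produced by
    :func:`extract_split_junctions`.
    """
    sigs: list[SvSignature] = []
    ref = aln.start
    q = 0
    n_ops = len(aln.cigar)
    for i, (op, n) in enumerate(aln.cigar):
        if op in "M=X":
            ref += n
            q += n
        elif op == "D":
            if n >= min_signature_size:
                sigs.append(
                    SvSignature(SigKind.INDEL_DEL, aln.contig, ref, n, aln.read_id, aln.sample_id)
                )
            ref += n
        elif op == "I":
            if n >= min_signature_size:
                ins = aln.seq[q : q + n] if aln.seq else None
                sigs.append(
                    SvSignature(
                        SigKind.INDEL_INS, aln.contig, ref, n, aln.read_id, aln.sample_id,
                        ins_seq=ins,
                    )
                )
            q += n
        elif op == "S":
            terminal = i == 0 or i == n_ops - 1
            if terminal and n >= min_clip_size:
                orient = Orient.RIGHT_ANCHOR if i == 0 else Orient.LEFT_ANCHOR
                sigs.append(
                    SvSignature(
                        SigKind.SOFTCLIP, aln.contig, ref, n, aln.read_id, aln.sample_id,
                        orient=orient,
                    )
                )
            q += n
        # H consumes neither; N/P unused for long-read DNA alignments
    sigs.sort(key=lambda s: s.pos)
    return sigs


def _segment_breakends(aln: ReadAlignment) -> tuple[Breakend, Breakend]:
    """(query-start side, query-end side) breakends of one segment."""
    if aln.is_reverse:
        # query start of the as-sequenced read maps to the high reference end
        return (
            Breakend(aln.contig, aln.end, Orient.LEFT_ANCHOR),
            Breakend(aln.contig, aln.start, Orient.RIGHT_ANCHOR),
        )
    return (
        Breakend(aln.contig, aln.start, Orient.RIGHT_ANCHOR),
        Breakend(aln.contig, aln.end, Orient.LEFT_ANCHOR),
    )


def extract_split_junctions(segments: list[ReadAlignment]) -> list[SvSignature]:
    """One SPLIT_JUNCTION signature per adjacent pair of split segments.

    Segments are ordered along the original read (query coordinates); each
    junction joins the query-end breakend of the upstream segment to the
    query-start breakend of the downstream one. Breakends are stored in
    canonical (contig, pos) order.
    """
    if len(segments) < 2:
        return []
    ordered = sorted(segments, key=lambda a: a.query_interval()[0])
    sigs = []
    for up, down in zip(ordered, ordered[1:]):
        be_a = _segment_breakends(up)[1]
        be_b = _segment_breakends(down)[0]
        if (be_b.contig, be_b.pos) < (be_a.contig, be_a.pos):
            be_a, be_b = be_b, be_a
        sigs.append(
            SvSignature(
                SigKind.SPLIT_JUNCTION, be_a.contig, be_a.pos, 0,
                up.read_id, up.sample_id, mate=be_b, orient=be_a.orient,
            )
        )
    sigs.sort(key=lambda s: s.pos)
    return sigs


def merge_adjacent_indels(
    sigs: list[SvSignature], max_gap: int = DEFAULT_MAX_GAP
) -> list[SvSignature]:
    """Merge same-kind indel signatures from one read separated by <= max_gap.

    Aligners fragment one SV into nearby CIGAR runs; merging re-joins them.
    Positions must be sorted; deletion sizes sum and insertion sequences
    concatenate. Idempotent.
    """
    out: list[SvSignature] = []
    for sig in sigs:
        prev = out[-1] if out else None
        if (
            prev is not None
            and sig.kind == prev.kind
            and sig.kind in (SigKind.INDEL_DEL, SigKind.INDEL_INS)
            and sig.contig == prev.contig
        ):
            prev_end = prev.pos + (prev.size if prev.kind == SigKind.INDEL_DEL else 0)
            if sig.pos - prev_end <= max_gap:
                ins = None
                if prev.kind == SigKind.INDEL_INS and prev.ins_seq is not None and sig.ins_seq is not None:
                    ins = prev.ins_seq + sig.ins_seq
                out[-1] = SvSignature(
                    prev.kind, prev.contig, prev.pos, prev.size + sig.size,
                    prev.read_id, prev.sample_id, ins_seq=ins,
                )
                continue
        out.append(sig)
    return out
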