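"""Haplotype-to-reference realignment and breakpoint refinement.

Each consensus haplotype is globally aligned to its anchor window with an
affine-gap scoring scheme chosen so that a single large indel aligns as one
gap run. Indel runs become sequence-resolved DEL/INS records; a paired
deletion+insertion run whose inserted sequence is the reverse complement of
the deleted reference segment becomes an inversion (reported as two
component breakends plus a summarizing INV event). All junctions are
left-normalized; deletion junctions carry microhomology annotation
(HOMLEN/HOMSEQ), whose length measures the interval of equivalent
breakpoint placements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import edlib
from Bio import Align

from .alignio import ReferenceWindow, revcomp
from .assembly import ConsensusHaplotype
from .signatures import Breakend, Orient

log = logging.getLogger(__name__)

#: Structural variants are defined as events of at least this size.
MIN_SV_SIZE = 50
DEFAULT_DUP_MIN_IDENTITY = 0.9
DEFAULT_INV_MAX_SPAN = 2_000_000
#: Minimum alignment identity over the anchor flanks for a haplotype to be
#: trusted.
FLANK_IDENTITY_MIN = 0.9
_FLANK_CHECK = 250


@dataclass
class Breakpoint:
    be1: Breakend
    be2: Breakend
    ins_seq: str  # untemplated/junction-inserted sequence, possibly empty
    hom_len: int
    hom_seq: str
    hap_ref: str

    def __post_init__(self):
        # homology and junction insertion are mutually exclusive annotations
        assert not (self.hom_len > 0 and self.ins_seq), "hom and ins both set"
        assert len(self.hom_seq) == self.hom_len


@dataclass
class SvRecord:
    sv_type: str  # DEL / INS / DUP / INV / BND
    contig: str
    pos: int  # 0-based canonical (leftmost) start
    end: int
    svlen: int  # signed: negative DEL, positive INS/DUP
    breakpoints: list
    hap_ref: str
    event_id: Optional[str] = None
    depth_support: Optional[bool] = None
    ins_seq: str = ""


@dataclass
class RefAlignment:
    cigar: list  # (op in M/I/D, length), hap (query) vs window (target)
    score: float


def _make_aligner() -> Align.PairwiseAligner:
    # Mismatch is priced well above gap extension so that a large event
    # (including the scrambled diagonal of an inversion) aligns as one
    # deletion run plus one insertion run instead of a mismatch stretch;
    # chance matches shorter than ~12 bp cannot split a gap run open.
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -5
    a.open_gap_score = -6
    a.extend_gap_score = -0.5
    return a


_ALIGNER = _make_aligner()


def _alignment_to_cigar(alignment) -> list[tuple[str, int]]:
    """CIGAR of query (haplotype) vs target (reference window)."""
    tgt_blocks, qry_blocks = alignment.aligned
    cigar: list[tuple[str, int]] = []
    t_prev = q_prev = 0
    tlen = len(alignment.target)
    qlen = len(alignment.query)

    def push(op, n):
        if n <= 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    for (ts, te), (qs, qe) in zip(tgt_blocks, qry_blocks):
        push("D", int(ts - t_prev))
        push("I", int(qs - q_prev))
        push("M", int(te - ts))
        t_prev, q_prev = int(te), int(qe)
    push("D", int(tlen - t_prev))
    push("I", int(qlen - q_prev))
    return cigar


def align_haplotype(hap: ConsensusHaplotype, ref: ReferenceWindow) -> Optional[RefAlignment]:
    """Global affine-gap alignment of the haplotype to its anchor window.

    Returns None (haplotype dropped as low-confidence) when alignment
    identity over the anchor flanks falls below ``FLANK_IDENTITY_MIN``.
    """
    if not hap.seq or not ref.seq:
        return None
    alns = _ALIGNER.align(ref.seq, hap.seq)
    aln = alns[0]
    cigar = _alignment_to_cigar(aln)
    # flank identity: fraction of outer reference bases aligned as matches
    matches_lo = matches_hi = 0
    t = q = 0
    lo_end = min(_FLANK_CHECK, len(ref.seq))
    hi_start = max(0, len(ref.seq) - _FLANK_CHECK)
    for op, n in cigar:
        if op == "M":
            for k in range(n):
                tp = t + k
                if ref.seq[tp] == hap.seq[q + k]:
                    if tp < lo_end:
                        matches_lo += 1
                    if tp >= hi_start:
                        matches_hi += 1
            t += n
            q += n
        elif op == "D":
            t += n
        else:
            q += n
    hi_len = len(ref.seq) - hi_start
    if lo_end and matches_lo / lo_end < FLANK_IDENTITY_MIN:
        log.info("haplotype %s dropped: left flank identity %.2f", hap.hap_id, matches_lo / lo_end)
        return None
    if hi_len and matches_hi / hi_len < FLANK_IDENTITY_MIN:
        log.info("haplotype %s dropped: right flank identity %.2f", hap.hap_id, matches_hi / hi_len)
        return None
    return RefAlignment(cigar, float(aln.score))


def compute_homology(ref_seq: str, del_start: int, del_end: int) -> tuple[int, str, int]:
    """Breakpoint microhomology of a deletion.

    Returns ``(hom_len, hom_seq, canonical_start)`` where ``hom_len`` is the
    size of the interval of breakpoint placements producing an identical
    alternate sequence, ``canonical_start`` is the leftmost such placement,
    and ``hom_seq`` is the homologous sequence there.
    """
    n = len(ref_seq)
    s, e = del_start, del_end
    left = 0
    while s - left > 0 and ref_seq[s - left - 1] == ref_seq[e - left - 1]:
        left += 1
    right = 0
    while e + right < n and ref_seq[s + right] == ref_seq[e + right]:
        right += 1
    hom_len = left + right
    canonical = s - left
    return hom_len, ref_seq[canonical : canonical + hom_len], canonical


def canonicalize_insertion(ref_seq: str, pos: int, ins: str) -> tuple[int, str, int]:
    """Leftmost-equivalent placement of an insertion.

    Returns ``(canonical_pos, canonical_ins, shift_range)`` where
    ``shift_range`` is the total number of equivalent placements minus one
    (the insertion analogue of microhomology length).
    """
    p, s = pos, ins
    left = 0
    while p > 0 and s and ref_seq[p - 1] == s[-1]:
        s = ref_seq[p - 1] + s[:-1]
        p -= 1
        left += 1
    # count rightward shifts from the original placement for the range only
    p2, s2 = pos, ins
    right = 0
    while p2 < len(ref_seq) and s2 and ref_seq[p2] == s2[0]:
        s2 = s2[1:] + ref_seq[p2]
        p2 += 1
        right += 1
    return p, s, left + right


def _alt_piece(ref_seq: str, a: int, b: int, lo: int, hi: int) -> str:
    """Local slice [lo, hi) of the alternate sequence with [a, b) inverted."""
    return ref_seq[lo:a] + revcomp(ref_seq[a:b]) + ref_seq[b:hi]


def canonical_inversion(ref_seq: str, start: int, end: int, radius: int = 6) -> tuple[int, int]:
    """Minimal (leftmost, then shortest-compatible) equivalent placement of
    an inverted interval.

    Chance base matches at the edges make inversion breakpoints ambiguous,
    including between placements of slightly different width; the canonical
    representative is the smallest ``(start, end)`` among all placements
    producing an identical alternate sequence, found by composing a
    width-preserving leftward slide with a bounded local search.
    """
    n = len(ref_seq)
    best = (start, end)
    for _ in range(64):
        a0, b0 = best
        while a0 > 0:
            lo, hi = a0 - 1, b0
            if _alt_piece(ref_seq, a0 - 1, b0 - 1, lo, hi) == _alt_piece(ref_seq, a0, b0, lo, hi):
                a0 -= 1
                b0 -= 1
            else:
                break
        cand = (a0, b0)
        for a in range(max(0, a0 - radius), a0 + radius + 1):
            for b in range(max(a + 1, b0 - radius), min(n, b0 + radius) + 1):
                if (a, b) >= cand:
                    continue
                lo, hi = min(a, cand[0]), max(b, cand[1])
                if _alt_piece(ref_seq, a, b, lo, hi) == _alt_piece(ref_seq, cand[0], cand[1], lo, hi):
                    cand = (a, b)
        if cand == best:
            break
        best = cand
    return best


def _exact_inversion_bounds(
    ref_seq: str, hap_seq: str, d1: int, d2: int, slop: int = 10
) -> tuple[int, int]:
    """Refine inversion boundaries to basepair exactness.

    Gap runs can absorb chance matches at the inversion edges; when the
    haplotype is a clean pure inversion of the window (lengths equal), the
    exact interval satisfies hap[a:b] == revcomp(ref[a:b]) with identical
    flanks, which is searched in a small neighbourhood of the gap-run
    interval. Falls back to the gap-run interval when no exact placement
    exists (e.g. residual consensus errors).
    """
    if len(hap_seq) != len(ref_seq):
        return d1, d2
    n = len(ref_seq)
    candidates = sorted(
        (
            (abs(a - d1) + abs(b - d2), a, b)
            for a in range(max(0, d1 - slop), min(n, d1 + slop) + 1)
            for b in range(max(a + MIN_SV_SIZE, d2 - slop), min(n, d2 + slop) + 1)
        )
    )
    for _, a, b in candidates:
        if (
            hap_seq[a:b] == revcomp(ref_seq[a:b])
            and hap_seq[:a] == ref_seq[:a]
            and hap_seq[b:] == ref_seq[b:]
        ):
            return a, b
    return d1, d2


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def extract_breakpoints(
    alignment: RefAlignment,
    hap: ConsensusHaplotype,
    ref: ReferenceWindow,
    min_size: int = MIN_SV_SIZE,
    dup_min_identity: float = DEFAULT_DUP_MIN_IDENTITY,
) -> list[SvRecord]:
    """Turn large gap runs of a haplotype alignment into SV records.

    A deletion-run/insertion-run pair of similar size whose inserted sequence
    reverse-complement-matches the deleted segment is emitted as two
    component BND records (an inversion candidate for :func:`pair_inversion`)
    instead of a DEL+INS pair.
    """
    runs = []  # (op, window_ref_off, hap_off, len)
    t = q = 0
    for op, n in alignment.cigar:
        if op == "M":
            t += n
            q += n
        elif op == "D":
            runs.append(("D", t, q, n))
            t += n
        else:
            runs.append(("I", t, q, n))
            q += n
    large = [r for r in runs if r[3] >= min_size]
    consumed = set()
    records: list[SvRecord] = []
    contig = ref.contig

    # inversion candidates: adjacent large D and I runs, rc-matching
    for i in range(len(large) - 1):
        a, b = large[i], large[i + 1]
        if {a[0], b[0]} != {"D", "I"}:
            continue
        if abs(b[1] - (a[1] + (a[3] if a[0] == "D" else 0))) > 20:
            continue
        drun = a if a[0] == "D" else b
        irun = a if a[0] == "I" else b
        if min(drun[3], irun[3]) / max(drun[3], irun[3]) < 0.8:
            continue
        del_seq = ref.seq[drun[1] : drun[1] + drun[3]]
        ins_seq = hap.seq[irun[2] : irun[2] + irun[3]]
        if _identity(revcomp(ins_seq), del_seq) < 0.9:
            continue
        d1, d2 = _exact_inversion_bounds(ref.seq, hap.seq, drun[1], drun[1] + drun[3])
        d1, d2 = canonical_inversion(ref.seq, d1, d2)
        p1, p2 = ref.start + d1, ref.start + d2
        bp_ll = Breakpoint(
            Breakend(contig, p1, Orient.LEFT_ANCHOR),
            Breakend(contig, p2, Orient.LEFT_ANCHOR),
            "", 0, "", hap.hap_id,
        )
        bp_rr = Breakpoint(
            Breakend(contig, p1, Orient.RIGHT_ANCHOR),
            Breakend(contig, p2, Orient.RIGHT_ANCHOR),
            "", 0, "", hap.hap_id,
        )
        records.append(SvRecord("BND", contig, p1, p2, 0, [bp_ll], hap.hap_id))
        records.append(SvRecord("BND", contig, p1, p2, 0, [bp_rr], hap.hap_id))
        consumed.update({a, b})

    for run in large:
        if run in consumed:
            continue
        op, toff, qoff, n = run
        if op == "D":
            hom_len, hom_seq, canon = compute_homology(ref.seq, toff, toff + n)
            pos = ref.start + canon
            end = pos + n
            bp = Breakpoint(
                Breakend(contig, pos, Orient.LEFT_ANCHOR),
                Breakend(contig, end, Orient.RIGHT_ANCHOR),
                "", hom_len, hom_seq, hap.hap_id,
            )
            records.append(SvRecord("DEL", contig, pos, end, -n, [bp], hap.hap_id))
        else:
            ins = hap.seq[qoff : qoff + n]
            pos, ins_canon, _shift = canonicalize_insertion(ref.seq, toff, ins)
            pos += ref.start
            bp = Breakpoint(
                Breakend(contig, pos, Orient.LEFT_ANCHOR),
                Breakend(contig, pos, Orient.RIGHT_ANCHOR),
                ins_canon, 0, "", hap.hap_id,
            )
            records.append(
                SvRecord("INS", contig, pos, pos, n, [bp], hap.hap_id, ins_seq=ins_canon)
            )
    records.sort(key=lambda r: (r.pos, r.sv_type))
    return records


def refine_inversion(
    hap: ConsensusHaplotype,
    ref: ReferenceWindow,
    p1: int,
    p2: int,
    orient: Orient,
    min_size: int = MIN_SV_SIZE,
) -> Optional[SvRecord]:
    """Breakpoint-exact BND record for an inversion-orientation junction.

    ``(p1, p2)`` are the junction breakend positions suggested by the
    cluster's split-read signatures (genome coordinates); the consensus
    haplotype is used to verify the inversion and polish the boundaries to
    the exact, then leftmost-canonical, placement. ``orient`` is the shared
    orientation of both breakends (left/left for the junction joining the
    left flank to the inverted segment, right/right for its partner).
    Returns None when the haplotype does not support an inversion here.
    """
    o1, o2 = p1 - ref.start, p2 - ref.start
    if not (0 <= o1 < o2 <= len(ref.seq)):
        return None
    a = b = None
    if len(hap.seq) == len(ref.seq):
        a, b = _exact_inversion_bounds(ref.seq, hap.seq, o1, o2, slop=25)
        if hap.seq[a:b] != revcomp(ref.seq[a:b]):
            a = None
    if a is None:
        alt = ref.seq[:o1] + revcomp(ref.seq[o1:o2]) + ref.seq[o2:]
        if _identity(hap.seq, alt) < 0.97:
            return None
        a, b = o1, o2
    if b - a < min_size:
        return None
    a, b = canonical_inversion(ref.seq, a, b)
    q1, q2 = ref.start + a, ref.start + b
    bp = Breakpoint(
        Breakend(ref.contig, q1, orient),
        Breakend(ref.contig, q2, orient),
        "", 0, "", hap.hap_id,
    )
    return SvRecord("BND", ref.contig, q1, q2, 0, [bp], hap.hap_id)


def classify_duplication(
    ins_record: SvRecord,
    ref: ReferenceWindow,
    min_identity: float = DEFAULT_DUP_MIN_IDENTITY,
) -> SvRecord:
    """Reclassify an insertion as a tandem duplication when its sequence
    matches the reference segment immediately left or right of the insertion
    point. Dispersed duplications remain INS."""
    if ins_record.sv_type != "INS":
        return ins_record
    ins = ins_record.ins_seq
    L = len(ins)
    off = ins_record.pos - ref.start
    # locate the best-matching reference copy as an infix of the window;
    # this stays basepair-exact even when residual consensus errors stop
    # the left-normalization slide partway
    res = edlib.align(ins, ref.seq, mode="HW", task="locations")
    if res["editDistance"] < 0 or L == 0:
        return ins_record
    identity = 1.0 - res["editDistance"] / L
    if identity < min_identity:
        return ins_record
    a, b = res["locations"][0]
    b += 1  # edlib locations are inclusive
    if not (a - 50 <= off <= b + 50):
        return ins_record  # dispersed copy: keep as INS
    ins_record.sv_type = "DUP"
    ins_record.pos = ref.start + a
    ins_record.end = ref.start + b
    ins_record.svlen = L
    return ins_record


def pair_inversion(
    records: list[SvRecord],
    max_span: int = DEFAULT_INV_MAX_SPAN,
    pos_tol: int = 100,
) -> list[SvRecord]:
    """Join inverted-orientation BND pairs into INV events.

    Two intra-contig BNDs — one with both breakends left-anchored, one with
    both right-anchored — whose positions agree within ``pos_tol`` and span
    at most ``max_span`` are joined under one event id and summarized by an
    INV record; the component BNDs are retained.
    """
    def orient_pair(r: SvRecord):
        bp = r.breakpoints[0]
        return bp.be1.orient, bp.be2.orient

    bnds = [r for r in records if r.sv_type == "BND"]
    others = [r for r in records if r.sv_type != "BND"]
    lls = [r for r in bnds if orient_pair(r) == (Orient.LEFT_ANCHOR, Orient.LEFT_ANCHOR)]
    rrs = [r for r in bnds if orient_pair(r) == (Orient.RIGHT_ANCHOR, Orient.RIGHT_ANCHOR)]
    used = set()
    out = list(others)
    invs = []
    for ll in lls:
        match = None
        for rr in rrs:
            if id(rr) in used:
                continue
            if ll.contig != rr.contig:
                continue
            if abs(ll.pos - rr.pos) > pos_tol or abs(ll.end - rr.end) > pos_tol:
                continue
            if ll.end - ll.pos > max_span:
                continue
            match = rr
            break
        if match is None:
            out.append(ll)
            continue
        used.add(id(match))
        pos = min(ll.pos, match.pos)
        end = max(ll.end, match.end)
        event = f"INV.{ll.contig}.{pos}"
        ll.event_id = match.event_id = event
        inv = SvRecord(
            "INV", ll.contig, pos, end, end - pos,
            ll.breakpoints + match.breakpoints, ll.hap_ref, event_id=event,
        )
        invs.append(inv)
        out.extend([ll, match])
    out.extend(r for r in rrs if id(r) not in used)
    out.extend(invs)
    out.sort(key=lambda r: (r.contig, r.pos, r.sv_type))
    return out
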