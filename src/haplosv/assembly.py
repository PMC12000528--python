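"""Local consensus assembly of SV-supporting reads.

For each signature cluster the supporting reads' query subsequences over the
padded cluster window are extracted (orientation-normalized to the reference
strand), partitioned into up to ``max_haplotypes`` allele groups by pairwise
edit-distance ratio, and each group is collapsed to a consensus sequence by
majority vote against a medoid backbone. The consensus contract is what
matters (identity of >= 2 equal inputs, error removal by majority, bounded
haplotype count), not the particular multiple-alignment engine.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignio import ReadAlignment, revcomp
from .clustering import SignatureCluster

log = logging.getLogger(__name__)

#: Flanking anchor added on each side of a cluster span; long enough for
#: confident re-alignment, short enough to stay local.
DEFAULT_FLANK = 500
#: Pairwise edit-distance / mean-length ratio above which two read segments
#: are forced into separate haplotype groups (diploid allele separation).
DEFAULT_SPLIT_THRESHOLD = 0.05
DEFAULT_MAX_HAPLOTYPES = 2


@dataclass
class ConsensusHaplotype:
    hap_id: str  # sample_id:cluster_id:index
    seq: str
    support_reads: list[str]
    cluster_ref: int
    anchor: tuple[str, int, int]  # (contig, start, end), the replaced window
    sample_id: str


def _ref_to_query_maps(aln: ReadAlignment) -> list[tuple[int, int, int]]:
    """Aligned blocks as (ref_start, ref_end, stored_query_start)."""
    blocks = []
    ref, q = aln.start, 0
    for op, n in aln.cigar:
        if op in "M=X":
            blocks.append((ref, ref + n, q))
            ref += n
            q += n
        elif op == "D":
            ref += n
        elif op in "IS":
            q += n
    return blocks


def _project(aln: ReadAlignment, ref_pos: int) -> int | None:
    """Stored-query index for a reference position covered by this record.

    Positions inside a deletion run map to the query index at the run (left
    boundary); positions outside the aligned span return None.
    """
    if not (aln.start <= ref_pos < aln.end or ref_pos == aln.end):
        return None
    blocks = _ref_to_query_maps(aln)
    for rs, re_, qs in blocks:
        if rs <= ref_pos < re_:
            return qs + (ref_pos - rs)
        if ref_pos < rs:  # inside a deletion preceding this block
            return qs
    # ref_pos at/after the last aligned base
    rs, re_, qs = blocks[-1]
    return qs + (re_ - rs)


def read_window_sequence(
    records: list[ReadAlignment], win_start: int, win_end: int
) -> str | None:
    """Reference-forward read subsequence whose alignment spans a window.

    Works for single-record reads (including fully reverse-mapped ones, whose
    stored sequence is already reference-forward) and for split reads whose
    window flanks land in forward segments. Returns None when the read does
    not fully span the window.
    """
    # single record covering the whole window: slice stored (ref-forward) seq
    for rec in records:
        if rec.seq and rec.start <= win_start and rec.end >= win_end:
            q1, q2 = _project(rec, win_start), _project(rec, win_end)
            if q1 is not None and q2 is not None and q2 > q1:
                return rec.seq[q1:q2]
            return None
    # split read: resolve each boundary in a forward segment, slice the
    # original (as-sequenced) read between them
    fwd = [r for r in records if not r.is_reverse and r.seq]
    if not fwd:
        return None
    primary = next((r for r in records if not r.is_supplementary), None)
    if primary is None or not primary.seq:
        return None
    # recover the as-sequenced read; a reverse primary stores its complement
    read_seq = revcomp(primary.seq) if primary.is_reverse else primary.seq

    def read_coord(ref_pos: int) -> int | None:
        for rec in fwd:
            if rec.start <= ref_pos <= rec.end:
                q = _project(rec, ref_pos)
                if q is not None:
                    return q  # forward record: stored == read coords
        return None

    q1, q2 = read_coord(win_start), read_coord(win_end)
    if q1 is None or q2 is None or q2 <= q1:
        return None
    return read_seq[q1:q2]


def extract_read_segments(
    cluster: SignatureCluster,
    reads: dict[str, list[ReadAlignment]],
    contig_length: int,
    flank: int = DEFAULT_FLANK,
) -> tuple[tuple[int, int], list[tuple[str, str]]]:
    """Window-spanning query segments for a cluster's supporting reads.

    Returns the anchor window actually used (cluster span padded by
    ``flank``, truncated at contig ends) and ``(read_id, sequence)`` pairs;
    reads not fully spanning the window are excluded.
    """
    lo, hi = cluster.span
    win = (max(0, lo - flank), min(contig_length, hi + flank))
    segs = []
    for rid in sorted(cluster.support_reads):
        recs = reads.get(rid)
        if not recs:
            continue
        seq = read_window_sequence(recs, win[0], win[1])
        if seq:
            segs.append((rid, seq))
    return win, segs


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _group_segments(
    seqs: list[str], split_threshold: float, max_haplotypes: int
) -> list[list[int]]:
    """Complete-linkage grouping on pairwise edit-distance ratios."""
    n = len(seqs)
    if n == 1:
        return [[0]]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mean_len = (len(seqs[i]) + len(seqs[j])) / 2
            d[i, j] = d[j, i] = _edit_distance(seqs[i], seqs[j]) / max(mean_len, 1)
    z = linkage(squareform(d, checks=False), method="complete")
    labels = fcluster(z, t=split_threshold, criterion="distance")
    groups = defaultdict(list)
    for i, lab in enumerate(labels):
        groups[lab].append(i)
    out = sorted(groups.values(), key=lambda g: (-len(g), g))
    return out[:max_haplotypes]


def _consensus_of(seqs: list[str]) -> str:
    """Majority-vote consensus against the medoid backbone."""
    if len(seqs) == 1:
        return seqs[0]
    n = len(seqs)
    totals = np.zeros(n)
    dmat = {}
    for i in range(n):
        for j in range(i + 1, n):
            dij = _edit_distance(seqs[i], seqs[j])
            dmat[(i, j)] = dij
            totals[i] += dij
            totals[j] += dij
    backbone_idx = int(np.argmin(totals))  # ties: lowest index (deterministic)
    backbone = seqs[backbone_idx]
    L = len(backbone)
    # votes[i] holds Counter of base / '-' at backbone column i;
    # ins[i] holds Counter of strings inserted before column i
    votes = [Counter() for _ in range(L)]
    ins: list[Counter] = [Counter() for _ in range(L + 1)]
    n_votes = 0
    for k, seq in enumerate(seqs):
        if k == backbone_idx:
            for i, base in enumerate(backbone):
                votes[i][base] += 1
            n_votes += 1
            continue
        res = edlib.align(seq, backbone, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, seq, backbone)
        qa, ta = nice["query_aligned"], nice["target_aligned"]
        col = 0
        pend = []
        for qc, tc in zip(qa, ta):
            if tc == "-":
                pend.append(qc)
                continue
            if pend:
                ins[col]["".join(pend)] += 1
                pend = []
            votes[col][qc if qc != "-" else "-"] += 1
            col += 1
        if pend:
            ins[col]["".join(pend)] += 1
        n_votes += 1
    out = []
    half = n_votes / 2
    for i in range(L):
        if ins[i]:
            s, c = ins[i].most_common(1)[0]
            if c > half:
                out.append(s)
        base, c = max(votes[i].items(), key=lambda kv: (kv[1], kv[0] == backbone[i], kv[0]))
        if base != "-":
            out.append(base)
    if ins[L]:
        s, c = ins[L].most_common(1)[0]
        if c > half:
            out.append(s)
    return "".join(out)


def build_consensus(
    segments: list[tuple[str, str]],
    cluster_id: int,
    sample_id: str,
    anchor: tuple[str, int, int],
    max_haplotypes: int = DEFAULT_MAX_HAPLOTYPES,
    split_threshold: float = DEFAULT_SPLIT_THRESHOLD,
    min_support: int = 2,
    seed: int = 0,
) -> list[ConsensusHaplotype]:
    """Partition segments into allele groups and build one consensus each.

    Groups below ``min_support`` are dropped; at most ``max_haplotypes``
    (diploid default 2) are returned, ordered by descending support. ``seed``
    is accepted for engine compatibility; the default engine is deterministic.
    """
    if len(segments) < min_support:
        return []
    seqs = [s for _, s in segments]
    groups = _group_segments(seqs, split_threshold, max_haplotypes)
    haps = []
    for idx, grp in enumerate(groups):
        if len(grp) < min_support:
            continue
        cons = _consensus_of([seqs[i] for i in grp])
        if not cons:
            continue
        haps.append(
            ConsensusHaplotype(
                hap_id=f"{sample_id}:{cluster_id}:{idx}",
                seq=cons,
                support_reads=[segments[i][0] for i in grp],
                cluster_ref=cluster_id,
                anchor=anchor,
                sample_id=sample_id,
            )
        )
    return haps
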