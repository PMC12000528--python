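"""Binned read-depth evidence for unbalanced (DEL/DUP) candidates.

Depth inside a large deletion or duplication deviates from flanking depth
in proportion to the alternate-allele dosage: a het deletion halves depth,
a hom deletion removes it, and duplications add half a copy per alternate
allele. Depth is raw (no GC or mappability normalization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .alignio import ReadAlignment
from .refine import SvRecord

DEFAULT_BIN_SIZE = 1000
#: Events smaller than this are decided by breakpoint evidence alone.
DEFAULT_MIN_DEPTH_EVENT_SIZE = 5000
DEFAULT_TOL = 0.25


@dataclass
class DepthTrack:
    contig: str
    bin_size: int
    bins: np.ndarray  # mean depth per bin, covering the contig


def build_depth_track(
    alns: Iterable[ReadAlignment], contig: str, contig_len: int, bin_size: int = DEFAULT_BIN_SIZE
) -> DepthTrack:
    """Mean aligned depth per bin from one sample's alignments on a contig.

    Each bin's value is the total reference-consuming aligned bases
    overlapping the bin divided by the bin size.
    """
    n_bins = (contig_len + bin_size - 1) // bin_size
    cov = np.zeros(contig_len + 1)
    for a in alns:
        if a.contig != contig:
            continue
        ref = a.start
        for op, n in a.cigar:
            if op in "M=X":
                cov[max(0, ref)] += 1
                cov[min(contig_len, ref + n)] -= 1
                ref += n
            elif op == "D":
                ref += n
    depth = np.cumsum(cov[:-1])
    bins = np.zeros(n_bins)
    for b in range(n_bins):
        lo, hi = b * bin_size, min((b + 1) * bin_size, contig_len)
        bins[b] = depth[lo:hi].sum() / bin_size
    return DepthTrack(contig, bin_size, bins)


def depth_ratio(
    track: DepthTrack, event: tuple[int, int], flank: int = 10 * DEFAULT_BIN_SIZE
) -> Optional[float]:
    """Mean depth of bins fully inside the event over mean flanking depth.

    Returns None when the event holds no full bin or the flank mean is zero
    (ratio undefined). Invariant to uniform depth scaling.
    """
    bs = track.bin_size
    lo, hi = event
    first = (lo + bs - 1) // bs
    last = hi // bs  # exclusive
    if last <= first:
        return None
    inner = track.bins[first:last]
    fl_lo = max(0, (lo - flank) // bs)
    fr_hi = min(len(track.bins), (hi + flank + bs - 1) // bs)
    flank_bins = np.concatenate([track.bins[fl_lo : lo // bs], track.bins[(hi + bs - 1) // bs : fr_hi]])
    if flank_bins.size == 0 or flank_bins.mean() == 0:
        return None
    return float(inner.mean() / flank_bins.mean())


def expected_ratio(sv_type: str, alt_dosage: int) -> float:
    """Expected depth ratio given alternate-allele dosage (0, 1, or 2)."""
    if sv_type == "DEL":
        return 1.0 - 0.5 * alt_dosage
    if sv_type == "DUP":
        return 1.0 + 0.5 * alt_dosage
    raise ValueError(sv_type)


def refine_with_depth(
    record: SvRecord,
    alt_dosage: int,
    ratio: Optional[float],
    tol: float = DEFAULT_TOL,
) -> SvRecord:
    """Annotate a DEL/DUP record with depth support; flip type if the depth
    signature contradicts the sequence-level classification.

    A candidate whose ratio fails its own expectation but falls within
    ``tol`` of the opposite (DEL <-> DUP) expectation at the same dosage is
    reclassified and flagged via ``event_id``-independent ``depth_support``.
    """
    if record.sv_type not in ("DEL", "DUP") or ratio is None or alt_dosage == 0:
        return record
    own = expected_ratio(record.sv_type, alt_dosage)
    other_type = "DUP" if record.sv_type == "DEL" else "DEL"
    other = expected_ratio(other_type, alt_dosage)
    if abs(ratio - own) <= tol:
        record.depth_support = True
    elif abs(ratio - other) <= tol:
        size = abs(record.svlen)
        record.sv_type = other_type
        record.svlen = size if other_type == "DUP" else -size
        record.depth_support = True
    else:
        record.depth_support = False
    return record
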