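"""Cross-sample haplotype merging, genotyping, and local phasing.

Haplotypes assembled per sample are compared *as sequences* over a common
reference window, so two samples carrying the same allele merge regardless
of how an aligner might have represented the variant. Each merged locus is
then genotyped per sample from the relative read support of each local
haplotype: every read spanning the locus is assigned to the allele it
matches best (with a score margin), allele-support counts feed a
binomial-mixture genotype likelihood, and genotype quality is the
phred-scaled probability that the called genotype is wrong.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import edlib
import numpy as np
from scipy.special import logsumexp

from .alignio import ReadAlignment, ReferenceGenome, revcomp
from .assembly import ConsensusHaplotype, read_window_sequence
from .refine import SvRecord

log = logging.getLogger(__name__)

DEFAULT_MAX_MERGE_DIST = 500
DEFAULT_MERGE_SIMILARITY = 0.98
#: Reference windows longer than this are genotyped with breakpoint-junction
#: probes instead of whole-window read alignment (reads must span the window
#: for whole-window scoring, which starves large events of reference reads).
WINDOW_SCORE_CAP = 5000
JUNCTION_PROBE_FLANK = 500
#: Maximum infix edit distance for a 2x500 bp probe to count as contained
#: in a read (comfortably above ~1% sequencing error, far below the ~50%
#: mismatch of a read lacking the junction).
PROBE_HIT_MAX = 100
GQ_CAP = 999


def _use_probe_scoring(locus: "SvLocus") -> bool:
    """Probe scoring when whole-window alignment would be read-length
    limited: large reference windows, long alternate alleles (reads must
    span window plus inserted sequence), or fused-junction (BND) alleles."""
    if locus.span[1] - locus.span[0] > WINDOW_SCORE_CAP:
        return True
    for a in locus.alleles:
        if len(a.seq) > WINDOW_SCORE_CAP:
            return True
        # bare breakends (fused junctions without a summarizing event, e.g.
        # translocations) have no window-resolved allele; inversion
        # components carry an event id and score fine as whole windows
        if any(r.sv_type == "BND" and r.event_id is None for r in a.records):
            return True
    return False


@dataclass
class GenotypeModelParams:
    epsilon: float = 0.05  # per-read allele mis-support probability
    min_score_margin: int = 10  # alignment-score margin for read assignment

    def __post_init__(self):
        assert 0 < self.epsilon < 0.5


@dataclass
class GenotypeCall:
    sample_id: str
    gt: Optional[tuple]  # unordered pair over {0 (ref), 1..k}; None = ./.
    ad: list  # per-allele supporting read counts, index 0 = ref
    gq: int
    ps: Optional[int] = None
    phased: bool = False
    allele_reads: dict = field(default_factory=dict)  # allele idx -> set(read_id)


@dataclass
class LocusAllele:
    index: int  # 1..k
    seq: str  # allele sequence over the locus window
    hap: ConsensusHaplotype  # representative haplotype
    records: list  # refined SvRecord list for this allele
    sample_support: dict  # sample_id -> list of supporting read ids


@dataclass
class SvLocus:
    locus_id: int
    contig: str
    span: tuple[int, int]  # locus reference window (0-based half-open)
    alleles: list  # LocusAllele, indices 1..k
    genotypes: dict = field(default_factory=dict)  # sample_id -> GenotypeCall


def _allele_window_seq(hap: ConsensusHaplotype, span: tuple[int, int], ref_seq: str, ref_start: int) -> str:
    """Haplotype sequence extended with reference flanks to cover ``span``."""
    _, a_start, a_end = hap.anchor
    left = ref_seq[span[0] - ref_start : a_start - ref_start]
    right = ref_seq[a_end - ref_start : span[1] - ref_start]
    return left + hap.seq + right


def merge_haplotypes(
    haps: list[tuple[ConsensusHaplotype, list]],
    ref: ReferenceGenome,
    max_merge_dist: int = DEFAULT_MAX_MERGE_DIST,
    merge_similarity: float = DEFAULT_MERGE_SIMILARITY,
) -> list[SvLocus]:
    """Merge per-sample haplotypes (with their refined records) into loci.

    Haplotypes whose anchors overlap within ``max_merge_dist`` are compared
    by sequence over the common window; an edit-distance/mean-length ratio of
    at most ``1 - merge_similarity`` means same allele. Allele indices are
    assigned by descending total support with lexicographic sequence
    tie-break, so numbering is reproducible across runs.
    """
    items = sorted(haps, key=lambda h: (h[0].anchor[0], h[0].anchor[1], h[0].anchor[2], h[0].hap_id))
    loci: list[SvLocus] = []
    group: list = []
    group_contig, group_end = None, -1

    def flush():
        nonlocal group
        if group:
            loci.append(_build_locus(group, ref, merge_similarity))
            group = []

    for hap, records in items:
        contig, a_start, a_end = hap.anchor
        if group and (contig != group_contig or a_start > group_end + max_merge_dist):
            flush()
        group.append((hap, records))
        group_contig = contig
        group_end = max(group_end, a_end) if len(group) > 1 else a_end
    flush()
    for i, locus in enumerate(loci):
        locus.locus_id = i
    return loci


def _build_locus(group: list, ref: ReferenceGenome, merge_similarity: float) -> SvLocus:
    contig = group[0][0].anchor[0]
    span = (min(h.anchor[1] for h, _ in group), max(h.anchor[2] for h, _ in group))
    win = ref.window(contig, span[0], span[1])
    seqs = [_allele_window_seq(h, span, win.seq, win.start) for h, _ in group]
    n = len(group)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            mean_len = (len(seqs[i]) + len(seqs[j])) / 2 or 1
            d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")["editDistance"]
            if d / mean_len <= 1 - merge_similarity:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    raw_alleles = []
    for members in clusters.values():
        support: dict[str, list[str]] = {}
        best = None
        for i in members:
            hap, recs = group[i]
            cur = support.setdefault(hap.sample_id, [])
            cur.extend(hap.support_reads)
            if best is None or len(hap.support_reads) > len(group[best][0].support_reads):
                best = i
        # cap: one sample contributes at most 2 alleles at a locus (diploid);
        # enforced later when assigning indices
        hap, recs = group[best]
        total = sum(len(v) for v in support.values())
        raw_alleles.append((total, seqs[best], hap, recs, support))
    raw_alleles.sort(key=lambda t: (-t[0], t[1]))

    per_sample_count: dict[str, int] = {}
    alleles = []
    for total, seq, hap, recs, support in raw_alleles:
        contributing = [s for s in support if per_sample_count.get(s, 0) < 2]
        if not contributing:
            log.info("dropping excess allele at %s:%d (sample diploid cap)", contig, span[0])
            continue
        for s in contributing:
            per_sample_count[s] = per_sample_count.get(s, 0) + 1
        idx = len(alleles) + 1
        alleles.append(LocusAllele(idx, seq, hap, recs, support))
    return SvLocus(0, contig, span, alleles)


# ---------------------------------------------------------------------------
# read scoring


def _allele_probe_windows(seq: str, centers: list[int], f: int) -> list[str]:
    out = []
    for c in centers:
        lo, hi = max(0, c - f), min(len(seq), c + f)
        if hi - lo >= f:
            out.append(seq[lo:hi])
    return out


def _junction_probes(locus: SvLocus, win_seq: str) -> tuple[list[str], dict[int, list[str]]]:
    """Breakpoint-local probe sequences for the reference and each allele.

    Reference probes span each record's junction coordinates in the
    reference window. Allele probes are derived from the allele's *records*:
    each is centred on a novel adjacency of the alternate haplotype — a
    deletion junction, the two ends of an inserted sequence, the
    copy1-end/copy2-start junction of a tandem duplication, or the two
    strand-switch junctions of an inversion — so every allele probe
    contains sequence from both sides of a breakpoint and cannot be matched
    by a read that lacks the event.
    """
    span0 = locus.span[0]
    f = JUNCTION_PROBE_FLANK
    ref_probes: list[str] = []
    alt_probes: dict[int, list[str]] = {}
    for allele in locus.alleles:
        for rec in allele.records:
            for off in {rec.pos - span0, rec.end - span0}:
                lo, hi = max(0, off - f), min(len(win_seq), off + f)
                if hi - lo >= f:
                    ref_probes.append(win_seq[lo:hi])
        if all(r.sv_type == "BND" for r in allele.records):
            # fused-junction allele: centred on the junction by construction
            mid = len(allele.seq) // 2
            alt_probes[allele.index] = _allele_probe_windows(allele.seq, [mid], f)
            continue
        centers: list[int] = []
        delta = 0  # allele-coordinate offset accumulated left of the cursor
        recs = sorted(
            (r for r in allele.records if r.sv_type != "BND"),
            key=lambda r: r.pos,
        )
        for rec in recs:
            off = rec.pos - span0 + delta
            size = abs(rec.svlen)
            if rec.sv_type == "DEL":
                centers.append(off)
                delta -= size
            elif rec.sv_type == "INS":
                centers.extend([off, off + size])
                if size > 4 * f:  # novel interior sequence is informative too
                    centers.append(off + size // 2)
                delta += size
            elif rec.sv_type == "DUP":
                # only the copy1-end/copy2-start adjacency is novel; the
                # interior and outer boundaries also exist on the reference
                # haplotype
                centers.append(rec.end - span0 + delta)
                delta += size
            elif rec.sv_type == "INV":
                centers.extend([off, rec.end - span0 + delta])
        if not centers:
            centers = [len(allele.seq) // 2]
        probes = _allele_probe_windows(allele.seq, centers, f)
        if not probes:
            mid = len(allele.seq) // 2
            probes = [allele.seq[max(0, mid - f) : mid + f]]
        alt_probes[allele.index] = probes
    if not ref_probes:
        mid = len(win_seq) // 2
        ref_probes.append(win_seq[max(0, mid - f) : mid + f])
    return ref_probes, alt_probes


def _probe_score(probes: list[str], read_seq: str) -> int:
    """Best (lowest) infix edit distance of any probe against the read.

    Both read strands are tried: a split read's primary record may store
    the sequence in either orientation relative to the junction probe.
    """
    rc = revcomp(read_seq)
    best = None
    for p in probes:
        for target in (read_seq, rc):
            d = edlib.align(p, target, mode="HW", task="distance")["editDistance"]
            if best is None or d < best:
                best = d
    return best if best is not None else 10**9


def score_read_vs_alleles(
    read_records: list[ReadAlignment],
    locus: SvLocus,
    win_seq: str,
    params: GenotypeModelParams,
    probes: Optional[tuple] = None,
) -> Optional[int]:
    """Assign one read to the allele it supports, or None when ambiguous.

    Small loci: the read subsequence spanning the locus window is globally
    aligned against the reference window and every allele sequence. Large
    loci (window > WINDOW_SCORE_CAP): breakpoint-junction probes are matched
    as infixes of the read. Assignment requires a margin of at least
    ``min_score_margin`` edit-distance units over the runner-up.
    """
    span = locus.span
    if not _use_probe_scoring(locus):
        seg = read_window_sequence(read_records, span[0], span[1])
        if seg is None:
            return None
        cands = [(0, win_seq)] + [(a.index, a.seq) for a in locus.alleles]
        dists = []
        for idx, seq in cands:
            d = edlib.align(seg, seq, mode="NW", task="distance")["editDistance"]
            dists.append((d, idx))
        dists.sort()
        if len(dists) > 1 and dists[1][0] - dists[0][0] < params.min_score_margin:
            return None
        return dists[0][1]
    if probes is None:
        probes = _junction_probes(locus, win_seq)
    ref_probes, alt_probes = probes
    primary = next((r for r in read_records if not r.is_supplementary), None)
    if primary is None or not primary.seq:
        return None
    d_ref = _probe_score(ref_probes, primary.seq)
    alt_dists = sorted(
        (_probe_score(alt_probes[a.index], primary.seq), a.index)
        for a in locus.alleles
    )
    d_alt, best_alt = alt_dists[0]
    # A hit on a novel-adjacency probe is decisive even when the read also
    # matches reference probes: events like tandem duplications destroy no
    # reference adjacency, so carrier reads legitimately match both.
    if d_alt <= PROBE_HIT_MAX and (
        len(alt_dists) == 1 or alt_dists[1][0] - d_alt >= params.min_score_margin
    ):
        return best_alt
    if d_ref <= PROBE_HIT_MAX and d_alt - d_ref >= params.min_score_margin:
        # a reference vote is only informative from a read whose alignment
        # fully spans a junction interval; e.g. a read starting inside the
        # second copy of a tandem duplication matches reference probes but
        # is genuinely uninformative about the extra copy
        f = JUNCTION_PROBE_FLANK
        lo = min(r.start for r in read_records if r.contig == locus.contig)
        hi = max(r.end for r in read_records if r.contig == locus.contig)
        for a in locus.alleles:
            for rec in a.records:
                for j in (rec.pos, rec.end):
                    if lo <= j - f and j + f <= hi:
                        return 0
        return None
    return None


# ---------------------------------------------------------------------------
# genotype model


def genotype_likelihoods(
    ad: list[int], n_alleles: int, epsilon: float
) -> dict[tuple, float]:
    """Log-likelihood of each diploid genotype given per-allele read counts.

    Per read assigned to allele ``a``: P(a | gt=(x,y)) = 0.5 f(a|x) +
    0.5 f(a|y) with f(a|c) = 1-eps if a == c else eps. For the biallelic
    case this reduces to the standard binomial mixture with per-read alt
    support probability eps / 0.5 / 1-eps for hom-ref / het / hom-alt.
    """
    gts = [
        (i, j) for i in range(n_alleles + 1) for j in range(i, n_alleles + 1)
    ]
    out = {}
    for gt in gts:
        x, y = gt
        ll = 0.0
        for a, count in enumerate(ad):
            if count == 0:
                continue
            fa = (1 - epsilon) if a == x else epsilon
            fb = (1 - epsilon) if a == y else epsilon
            ll += count * math.log(0.5 * fa + 0.5 * fb)
        out[gt] = ll
    return out


def genotype_locus(
    ad: list[int], params: GenotypeModelParams, n_alleles: Optional[int] = None
) -> tuple[Optional[tuple], int, dict]:
    """Call a genotype from per-allele supporting read counts.

    Returns ``(gt, gq, posteriors)``; ``gt`` is None (./.) with gq 0 when no
    reads were assigned. The prior over genotypes is uniform;
    ``gq = floor(-10 log10(1 - posterior))`` capped at 999.
    """
    if n_alleles is None:
        n_alleles = len(ad) - 1
    total = sum(ad)
    if total == 0:
        return None, 0, {}
    lls = genotype_likelihoods(ad, n_alleles, params.epsilon)
    gts = list(lls)
    arr = np.array([lls[g] for g in gts])
    norm = logsumexp(arr)
    log_post = arr - norm
    best = int(np.argmax(log_post))
    posteriors = {g: float(np.exp(lp)) for g, lp in zip(gts, log_post)}
    p = posteriors[gts[best]]
    err = 1.0 - p
    if err <= 0:
        gq = GQ_CAP
    else:
        gq = min(GQ_CAP, int(math.floor(-10.0 * math.log10(err))))
    return gts[best], max(gq, 0), posteriors


def genotype_sample_at_locus(
    locus: SvLocus,
    sample_id: str,
    reads_by_id: dict[str, list[ReadAlignment]],
    win_seq: str,
    params: GenotypeModelParams,
) -> GenotypeCall:
    """Score every local read against the alleles and call the genotype."""
    k = len(locus.alleles)
    ad = [0] * (k + 1)
    allele_reads: dict[int, set] = {i: set() for i in range(k + 1)}
    probes = None
    if _use_probe_scoring(locus):
        probes = _junction_probes(locus, win_seq)
    for rid in sorted(reads_by_id):
        assign = score_read_vs_alleles(reads_by_id[rid], locus, win_seq, params, probes)
        if assign is None:
            continue
        ad[assign] += 1
        allele_reads[assign].add(rid)
    gt, gq, _post = genotype_locus(ad, params)
    return GenotypeCall(sample_id, gt, ad, gq, allele_reads=allele_reads)


# ---------------------------------------------------------------------------
# phasing


def phase_overlapping(loci: list[SvLocus], sample_id: str, min_shared: int = 2) -> None:
    """Phase pairs of het loci in one sample that share supporting reads.

    Reads supporting the alt allele at one locus and the ref (or alt) allele
    at a neighbouring locus determine trans (or cis) configuration. Phase
    sets are identified by the leftmost locus position of the block.
    Conflicting evidence (both cis and trans supported) leaves the pair
    unphased.
    """
    hets = []
    for locus in loci:
        call = locus.genotypes.get(sample_id)
        if call is None or call.gt is None:
            continue
        alts = [a for a in call.gt if a != 0]
        if len(set(call.gt)) == 2:  # heterozygous (0/x or x/y)
            hets.append((locus, call))
    hets.sort(key=lambda t: t[0].span[0])

    block: list = []
    block_hap: dict = {}

    def flush():
        if len(block) > 1:
            ps = block[0][0].span[0]
            for locus, call in block:
                call.ps = ps
                call.phased = True
        block.clear()
        block_hap.clear()

    for locus, call in hets:
        if not block:
            block.append((locus, call))
            a, b = call.gt
            # orient: first haplotype carries the higher allele
            call.gt = (max(a, b), min(a, b))
            block_hap["hapA"] = call.allele_reads.get(max(a, b), set())
            block_hap["hapB"] = call.allele_reads.get(min(a, b), set())
            continue
        prev_a, prev_b = block_hap["hapA"], block_hap["hapB"]
        a, b = sorted(call.gt, reverse=True)  # a = alt-most allele
        reads_a = call.allele_reads.get(a, set())
        reads_b = call.allele_reads.get(b, set())
        cis = len(reads_a & prev_a) + len(reads_b & prev_b)
        trans = len(reads_a & prev_b) + len(reads_b & prev_a)
        if cis + trans < min_shared or (cis > 0 and trans > 0 and min(cis, trans) / (cis + trans) > 0.1):
            flush()
            block.append((locus, call))
            call.gt = (a, b)
            block_hap["hapA"] = reads_a
            block_hap["hapB"] = reads_b
            continue
        if cis >= trans:
            call.gt = (a, b)
            block_hap["hapA"] = block_hap["hapA"] | reads_a
            block_hap["hapB"] = block_hap["hapB"] | reads_b
        else:
            call.gt = (b, a)
            block_hap["hapA"] = block_hap["hapA"] | reads_b
            block_hap["hapB"] = block_hap["hapB"] | reads_a
        block.append((locus, call))
    flush()
    # restore unordered representation for unphased single het calls
    for locus in loci:
        call = locus.genotypes.get(sample_id)
        if call is not None and call.gt is not None and not call.phased:
            call.gt = tuple(sorted(call.gt))
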