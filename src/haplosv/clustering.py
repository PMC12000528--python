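"""Single-linkage clustering of SV signatures into candidate loci.

Two indel signatures link when they are the same kind, within ``max_dist``
on the reference, and their sizes agree to within ``size_ratio``. Split
junctions link when both breakends are within ``max_dist`` and orientations
match. Soft-clips never seed clusters on their own (weak evidence) but may
join a cluster seeded by other kinds. Single-linkage can chain distinct
nearby SVs; the assembly step separates haplotypes downstream, so
over-merging here is recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .signatures import Orient, SigKind, SvSignature

DEFAULT_MAX_DIST = 500
DEFAULT_SIZE_RATIO = 0.5
DEFAULT_MIN_CLUSTER_SUPPORT = 2


@dataclass
class SignatureCluster:
    cluster_id: int
    contig: str
    span: tuple[int, int]  # 0-based half-open envelope of member intervals
    members: list[SvSignature]
    sample_id: str

    @property
    def kind_profile(self) -> dict:
        prof: dict = {}
        for m in self.members:
            prof[m.kind] = prof.get(m.kind, 0) + 1
        return prof

    @property
    def support_reads(self) -> set[str]:
        return {m.read_id for m in self.members}

    @property
    def seed_kind(self) -> SigKind:
        """Dominant non-clip kind."""
        prof = {k: v for k, v in self.kind_profile.items() if k != SigKind.SOFTCLIP}
        return max(prof, key=lambda k: prof[k])


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, i: int) -> int:
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, a: int, b: int):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[rb] = ra


def signatures_link(a: SvSignature, b: SvSignature, max_dist: int, size_ratio: float) -> bool:
    """Pairwise link predicate (exposed for the brute-force oracle in tests)."""
    if a.kind != b.kind or a.contig != b.contig:
        return False
    if a.kind in (SigKind.INDEL_DEL, SigKind.INDEL_INS):
        if abs(a.pos - b.pos) > max_dist:
            return False
        lo, hi = sorted((a.size, b.size))
        return hi > 0 and lo / hi >= size_ratio
    if a.kind == SigKind.SPLIT_JUNCTION:
        return (
            abs(a.pos - b.pos) <= max_dist
            and a.mate.contig == b.mate.contig
            and abs(a.mate.pos - b.mate.pos) <= max_dist
            and a.orient == b.orient
            and a.mate.orient == b.mate.orient
        )
    return False  # SOFTCLIP: handled by attachment, never links


def _member_interval(sig: SvSignature, max_dist: int) -> tuple[int, int]:
    """Reference interval a member contributes to the cluster span."""
    if sig.kind == SigKind.INDEL_DEL:
        return sig.pos, sig.pos + sig.size
    if sig.kind == SigKind.SPLIT_JUNCTION and sig.mate.contig == sig.contig:
        lo, hi = sorted((sig.pos, sig.mate.pos))
        return lo, hi + 1
    return sig.pos, sig.pos + 1


def cluster_signatures(
    sigs: list[SvSignature],
    max_dist: int = DEFAULT_MAX_DIST,
    size_ratio: float = DEFAULT_SIZE_RATIO,
    min_cluster_support: int = DEFAULT_MIN_CLUSTER_SUPPORT,
) -> list[SignatureCluster]:
    """Single-linkage clustering; clusters below read support are dropped.

    Output is position-sorted with dense cluster ids from 0 and is invariant
    to input order.
    """
    seeds = [s for s in sigs if s.kind != SigKind.SOFTCLIP]
    clips = [s for s in sigs if s.kind == SigKind.SOFTCLIP]
    # canonical order makes the result independent of input permutation
    seeds.sort(key=lambda s: (s.contig, s.pos, s.size, s.kind.value, s.read_id))
    uf = _UnionFind(len(seeds))
    for i, a in enumerate(seeds):
        for j in range(i + 1, len(seeds)):
            b = seeds[j]
            if b.contig != a.contig or b.pos - a.pos > max_dist:
                break
            if signatures_link(a, b, max_dist, size_ratio):
                uf.union(i, j)
    groups: dict[int, list[SvSignature]] = {}
    for i, s in enumerate(seeds):
        groups.setdefault(uf.find(i), []).append(s)

    clusters = []
    for members in groups.values():
        lo = min(_member_interval(m, max_dist)[0] for m in members)
        hi = max(_member_interval(m, max_dist)[1] for m in members)
        clusters.append((members[0].contig, (lo, hi), members))
    # attach clips to the nearest cluster within max_dist of its span
    for clip in sorted(clips, key=lambda s: (s.contig, s.pos, s.read_id)):
        best, best_d = None, max_dist + 1
        for c in clusters:
            if c[0] != clip.contig:
                continue
            lo, hi = c[1]
            d = max(lo - clip.pos, clip.pos - hi, 0)
            if d < best_d:
                best, best_d = c, d
        if best is not None:
            best[2].append(clip)

    kept = [
        c for c in clusters
        if len({m.read_id for m in c[2]}) >= min_cluster_support
    ]
    kept.sort(key=lambda c: (c[0], c[1]))
    out = []
    for cid, (contig, span, members) in enumerate(kept):
        sample_id = members[0].sample_id
        out.append(SignatureCluster(cid, contig, span, members, sample_id))
    return out
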