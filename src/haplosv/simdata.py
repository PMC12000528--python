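"""Deterministic synthetic data: reference, diploid SV genotypes, long reads.

The generator emulates the data regime the caller targets: a reference
contig of i.i.d. uniform DNA (optionally with planted tandem-repeat arrays
so that breakpoint microhomology is exercised), diploid samples carrying
DEL/INS/DUP/INV/BND events of at least 50 bp with chosen genotypes,
high-accuracy long reads (10-30 kb, ~1% random errors as substitutions and
1-3 bp indels), and their alignments back to the reference. Alignments are
constructed analytically by lifting each read through the known
haplotype-to-reference block structure rather than by running a mapper, so
every CIGAR, split segment, and SA tag is exact by construction and the
whole pipeline can be tested hermetically.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pysam

from .alignio import ReadAlignment, revcomp
from .refine import canonical_inversion, canonicalize_insertion, compute_homology

BASES = np.array(list("ACGT"))

#: Planted SVs are non-overlapping per haplotype with at least this spacing.
MIN_SPACING = 2000
EDGE_MARGIN = 3000

#: Default 20-event plan spanning the three size strata (50-499, 500-4999,
#: >=5000 bp) across DEL/INS/DUP/INV.
DEFAULT_SV_PLAN = [
    ("DEL", 60), ("DEL", 120), ("DEL", 300), ("DEL", 800), ("DEL", 2500),
    ("DEL", 5200), ("DEL", 8000),
    ("INS", 75), ("INS", 160), ("INS", 200), ("INS", 450), ("INS", 1200),
    ("INS", 3000), ("INS", 5500),
    ("DUP", 90), ("DUP", 600), ("DUP", 5000),
    ("INV", 150), ("INV", 900), ("INV", 6000),
]


@dataclass
class PedigreeSpec:
    """Founder couple plus children; children inherit one haplotype per
    parent chosen by a seeded coin flip (one recombination-free block)."""

    n_children: int = 5
    father: str = "father"
    mother: str = "mother"

    @property
    def children(self) -> list[str]:
        return [f"child{i + 1}" for i in range(self.n_children)]

    @property
    def samples(self) -> list[str]:
        return [self.father, self.mother] + self.children


@dataclass
class SimConfig:
    seed: int = 0
    contig_len: int = 1_000_000
    contig_name: str = "chr1"
    sv_plan: list = field(default_factory=lambda: list(DEFAULT_SV_PLAN))
    n_bnd: int = 0  # inter-contig fusion junctions (adds a second contig)
    repeat_fraction: float = 0.15  # fraction of small DEL/INS placed in repeats
    hom_fraction: float = 1 / 3  # remainder het (single sample) or absent
    het_fraction: float = 2 / 3
    read_length_mean: int = 15_000
    read_length_sd: int = 3_000
    depth: float = 30.0
    error_rate: float = 0.01
    n_samples: int = 1
    pedigree: Optional[PedigreeSpec] = None
    allele_freq: float = 0.4  # founder haplotype carrier probability (pedigree)
    #: keep-out distance from contig ends for planted events; on short test
    #: contigs raise it above the read length so events sit outside the
    #: coverage ramp at the edges (an artifact real chromosomes do not have)
    edge_margin: Optional[int] = None

    @property
    def sample_names(self) -> list[str]:
        if self.pedigree:
            return self.pedigree.samples
        return [f"sample{i + 1}" for i in range(self.n_samples)]


@dataclass
class SvEvent:
    sv_type: str
    contig: str
    pos: int
    end: int  # pos for INS/BND
    size: int
    ins_seq: str = ""
    mate_contig: str = ""
    mate_pos: int = 0
    in_repeat: bool = False


@dataclass
class TruthRecord:
    sv_type: str
    contig: str
    pos: int  # canonical (leftmost-equivalent) start
    end: int
    svlen: int
    genotypes: dict  # sample_id -> (a, b) over {0, 1}
    hom_len: int = 0
    in_repeat: bool = False
    planted_pos: int = 0  # as-planted coordinates, before canonicalization


@dataclass
class Block:
    """One haplotype-to-reference liftover block."""

    hap_start: int
    hap_end: int
    contig: Optional[str]  # None: novel insertion
    ref_start: int
    ref_end: int
    strand: str  # '+', '-', or '.' for insertions


@dataclass
class SimSegment:
    contig: str
    strand: str
    ref_start: int
    ref_end: int
    q0: int  # query interval in as-sequenced read coordinates
    q1: int
    cigar: list  # (op, len) in query direction over [q0, q1)


@dataclass
class SimulatedRead:
    read_id: str
    seq: str  # as sequenced (haplotype-forward)
    segments: list


# ---------------------------------------------------------------------------
# reference and haplotypes


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, n)]


def make_reference(cfg: SimConfig) -> tuple[dict, list]:
    """Reference contigs plus repeat annotation; SVs are planted later.

    Returns ``(contigs, repeat_regions)`` where repeat planting is performed
    by :func:`simulate` at chosen SV sites (the annotation here is empty
    until then); exposed separately so the reference alone is reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    contigs = {cfg.contig_name: _random_dna(rng, cfg.contig_len)}
    if cfg.n_bnd > 0:
        contigs["chr2"] = _random_dna(rng, max(100_000, cfg.contig_len // 4))
    return contigs, []


def _place_events(cfg: SimConfig, rng: np.random.Generator) -> list[SvEvent]:
    margin = cfg.edge_margin if cfg.edge_margin is not None else EDGE_MARGIN
    plan = list(cfg.sv_plan)
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]
    spans = [size if t in ("DEL", "DUP", "INV") else 0 for t, size in plan]
    n = len(plan)
    total = sum(spans) + (n - 1) * MIN_SPACING + 2 * margin
    slack = cfg.contig_len - total
    if slack < 0:
        raise ValueError("contig too short for the requested SV plan")
    w = rng.random(n + 1)
    gaps = np.floor(w / w.sum() * slack).astype(int)
    events = []
    cur = margin + int(gaps[0])
    for i, ((t, size), span) in enumerate(zip(plan, spans)):
        ev = SvEvent(t, cfg.contig_name, cur, cur + span, size)
        events.append(ev)
        cur += span + MIN_SPACING + int(gaps[i + 1])
    events.sort(key=lambda e: e.pos)
    return events


def _plant_repeats(
    cfg: SimConfig, rng: np.random.Generator, contigs: dict, events: list
) -> list:
    """Overwrite the reference with tandem arrays at a fraction of small
    DEL/INS sites so those events carry breakpoint microhomology."""
    eligible = [e for e in events if e.sv_type in ("DEL", "INS") and e.size <= 500]
    n_rep = int(round(cfg.repeat_fraction * len(events)))
    chosen = eligible[:n_rep]
    regions = []
    seq = contigs[cfg.contig_name]
    for ev in chosen:
        unit_len = int(rng.integers(2, 9))
        unit = _random_dna(rng, unit_len)
        size = max(50, unit_len * max(1, round(ev.size / unit_len)))
        extra = int(rng.integers(3, 9))  # homology-bearing residual copies
        copies = size // unit_len + extra
        arr = np.tile(unit, copies)
        start = ev.pos - unit_len * (extra // 2)
        seq[start : start + len(arr)] = arr
        ev.size = size
        ev.in_repeat = True
        if ev.sv_type == "DEL":
            ev.end = ev.pos + size
        else:
            ev.ins_seq = "".join(np.tile(unit, size // unit_len))
        regions.append((cfg.contig_name, start, start + len(arr), "".join(unit)))
    return regions


def _finalize_events(cfg: SimConfig, rng: np.random.Generator, contigs: dict, events: list):
    ref = contigs[cfg.contig_name]
    for ev in events:
        if ev.sv_type == "INS" and not ev.ins_seq:
            ev.ins_seq = "".join(_random_dna(rng, ev.size))
    for i in range(cfg.n_bnd):
        # fusion junctions sit beyond every other event: a haplotype leaves
        # the host contig at the junction, so downstream events would vanish
        host = cfg.contig_name
        mate_len = len(contigs["chr2"])
        last_end = max([e.end for e in events], default=EDGE_MARGIN)
        pos = int(rng.integers(last_end + MIN_SPACING, cfg.contig_len - EDGE_MARGIN))
        mpos = int(rng.integers(EDGE_MARGIN, mate_len - EDGE_MARGIN - 8000))
        events.append(
            SvEvent("BND", host, pos, pos, 0, mate_contig="chr2", mate_pos=mpos)
        )
    events.sort(key=lambda e: e.pos)


def apply_events(ref: dict, contig: str, events: list) -> tuple[str, list]:
    """Build one haplotype sequence and its liftover blocks from events."""
    seq = ref[contig]
    out = []
    blocks = []
    cur = 0
    hpos = 0

    def emit_aln(a: int, b: int, strand: str = "+", src_contig: str = None, piece=None):
        nonlocal hpos
        if b <= a:
            return
        s = piece if piece is not None else "".join(seq[a:b])
        if strand == "-":
            s = revcomp(s)
        out.append(s)
        blocks.append(Block(hpos, hpos + len(s), src_contig or contig, a, b, strand))
        hpos += len(s)

    def emit_ins(s: str):
        nonlocal hpos
        if not s:
            return
        out.append(s)
        blocks.append(Block(hpos, hpos + len(s), None, 0, 0, "."))
        hpos += len(s)

    for ev in events:
        emit_aln(cur, ev.pos)
        if ev.sv_type == "DEL":
            cur = ev.end
        elif ev.sv_type == "INS":
            emit_ins(ev.ins_seq)
            cur = ev.pos
        elif ev.sv_type == "DUP":
            emit_aln(ev.pos, ev.end)
            emit_ins("".join(seq[ev.pos : ev.end]))  # second tandem copy
            cur = ev.end
        elif ev.sv_type == "INV":
            emit_aln(ev.pos, ev.end, strand="-")
            cur = ev.end
        elif ev.sv_type == "BND":
            # terminal fusion: the haplotype leaves the host contig here and
            # continues on the mate contig (single junction per haplotype)
            mate = ref[ev.mate_contig]
            mseq = "".join(mate[ev.mate_pos :])
            emit_aln(ev.mate_pos, len(mate), src_contig=ev.mate_contig, piece=mseq)
            return "".join(out), blocks
        else:
            raise ValueError(ev.sv_type)
    emit_aln(cur, len(seq))
    return "".join(out), blocks


# ---------------------------------------------------------------------------
# genotypes and truth


def _sample_genotypes(cfg: SimConfig, rng: np.random.Generator, events: list) -> dict:
    """Per-sample (hap1_carries, hap2_carries) for each event."""
    geno: dict[str, list] = {}
    if cfg.pedigree:
        ped = cfg.pedigree
        founders = {}
        for parent in (ped.father, ped.mother):
            founders[parent] = [
                tuple(rng.random(2) < cfg.allele_freq) for _ in events
            ]
        transmissions = {
            child: (int(rng.integers(0, 2)), int(rng.integers(0, 2)))
            for child in ped.children
        }
        geno[ped.father] = founders[ped.father]
        geno[ped.mother] = founders[ped.mother]
        for child in ped.children:
            tf, tm = transmissions[child]
            geno[child] = [
                (founders[ped.father][i][tf], founders[ped.mother][i][tm])
                for i in range(len(events))
            ]
        geno["_transmissions"] = transmissions
        return geno
    p_hom, p_het = cfg.hom_fraction, cfg.het_fraction
    for sample in cfg.sample_names:
        gts = []
        for _ in events:
            u = rng.random()
            if u < p_hom:
                gts.append((True, True))
            elif u < p_hom + p_het:
                gts.append((True, False) if rng.random() < 0.5 else (False, True))
            else:
                gts.append((False, False))
        geno[sample] = gts
    return geno


def _canonical_truth(ref_str: str, ev: SvEvent) -> tuple[int, int, int]:
    """(canonical_pos, canonical_end, hom_len) for one planted event."""
    if ev.sv_type == "DEL":
        hom_len, _seq, canon = compute_homology(ref_str, ev.pos, ev.end)
        return canon, canon + ev.size, hom_len
    if ev.sv_type == "INS":
        pos, _ins, shift = canonicalize_insertion(ref_str, ev.pos, ev.ins_seq)
        return pos, pos, shift
    if ev.sv_type == "DUP":
        # the caller sees the second copy as an insertion at ev.end
        pos, _ins, _ = canonicalize_insertion(ref_str, ev.end, ref_str[ev.pos : ev.end])
        return pos, pos + ev.size, 0
    if ev.sv_type == "INV":
        a, b = canonical_inversion(ref_str, ev.pos, ev.end)
        return a, b, 0
    return ev.pos, ev.end, 0


def _truth_records(cfg: SimConfig, contigs: dict, events: list, geno: dict) -> list:
    ref_str = "".join(contigs[cfg.contig_name])
    out = []
    samples = cfg.sample_names
    for i, ev in enumerate(events):
        gts = {}
        for s in samples:
            a, b = geno[s][i]
            gts[s] = tuple(sorted((int(a), int(b))))
        pos, end, hom_len = _canonical_truth(ref_str, ev)
        svlen = {"DEL": -ev.size, "INS": ev.size, "DUP": ev.size}.get(ev.sv_type, ev.end - ev.pos)
        if ev.sv_type == "BND":
            svlen = 0
        out.append(
            TruthRecord(ev.sv_type, ev.contig, pos, end, svlen, gts, hom_len,
                        ev.in_repeat, planted_pos=ev.pos)
        )
    return out


# ---------------------------------------------------------------------------
# read simulation


def _read_segments(blocks: list, s: int, e: int) -> list:
    """Alignment segments for a read covering haplotype interval [s, e)."""
    segs: list[SimSegment] = []
    cur: Optional[SimSegment] = None
    pending_ins = 0

    def close():
        nonlocal cur, pending_ins
        if cur is not None:
            segs.append(cur)
        cur = None
        pending_ins = 0

    for blk in blocks:
        if blk.hap_end <= s or blk.hap_start >= e:
            continue
        bs, be = max(blk.hap_start, s), min(blk.hap_end, e)
        q0, q1 = bs - s, be - s
        if blk.contig is None:
            if cur is not None:
                pending_ins += be - bs
            continue
        if blk.strand == "+":
            off0, off1 = bs - blk.hap_start, be - blk.hap_start
            rs, re_ = blk.ref_start + off0, blk.ref_start + off1
            if (
                cur is not None
                and cur.strand == "+"
                and cur.contig == blk.contig
                and rs >= cur.ref_end
            ):
                gap = rs - cur.ref_end
                if pending_ins:
                    cur.cigar.append(("I", pending_ins))
                    pending_ins = 0
                if gap:
                    cur.cigar.append(("D", gap))
                cur.cigar.append(("M", q1 - q0))
                cur.ref_end = re_
                cur.q1 = q1
            else:
                close()
                cur = SimSegment(blk.contig, "+", rs, re_, q0, q1, [("M", q1 - q0)])
        else:  # '-' block: one segment on its own
            off0, off1 = bs - blk.hap_start, be - blk.hap_start
            rs = blk.ref_start + (blk.hap_end - be)
            re_ = blk.ref_start + (blk.hap_end - bs)
            close()
            segs.append(SimSegment(blk.contig, "-", rs, re_, q0, q1, [("M", q1 - q0)]))
    close()
    # merge runs of equal ops
    for seg in segs:
        merged = []
        for op, n in seg.cigar:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + n)
            else:
                merged.append((op, n))
        seg.cigar = merged
    return segs


def _locate_m_run(segs: list, q: int, k: int = 1):
    """(segment, run index, offset) if [q, q+k) lies strictly inside an M run."""
    for seg in segs:
        if not (seg.q0 <= q and q + k <= seg.q1):
            continue
        qq = seg.q0
        for i, (op, n) in enumerate(seg.cigar):
            if op in ("M",):
                if qq + 1 <= q and q + k <= qq + n - 1:
                    return seg, i, q - qq
                qq += n
            elif op == "I":
                qq += n
        return None
    return None


def _inject_errors(read: SimulatedRead, rng: np.random.Generator, rate: float):
    seq = list(read.seq)
    L = len(seq)
    n_err = rng.binomial(L, rate)
    if n_err == 0:
        return
    qpos = np.sort(rng.choice(L, size=min(n_err, L), replace=False))[::-1]
    kinds = rng.random(len(qpos))
    sizes = rng.integers(1, 4, len(qpos))
    for q, u, k in zip(qpos.tolist(), kinds.tolist(), sizes.tolist()):
        if u < 0.7:  # substitution: M absorbs the mismatch
            cur = seq[q]
            alts = [b for b in "ACGT" if b != cur]
            seq[q] = alts[int(rng.integers(0, 3))]
            continue
        loc = _locate_m_run(read.segments, q, k if u >= 0.85 else 1)
        if loc is None:
            continue
        seg, run_i, off = loc
        op, n = seg.cigar[run_i]
        if u < 0.85:  # insertion error of k bases at q
            ins = "".join(BASES[rng.integers(0, 4, k)])
            seq[q:q] = list(ins)
            seg.cigar[run_i : run_i + 1] = [("M", off), ("I", k), ("M", n - off)]
            seg.q1 += k
            for other in read.segments:
                if other.q0 > q:
                    other.q0 += k
                    other.q1 += k
        else:  # deletion error: read skips k haplotype bases
            del seq[q : q + k]
            seg.cigar[run_i : run_i + 1] = [("M", off), ("D", k), ("M", n - off - k)]
            seg.q1 -= k
            for other in read.segments:
                if other.q0 > q:
                    other.q0 -= k
                    other.q1 -= k
    read.seq = "".join(seq)


def simulate_sample_reads(
    cfg: SimConfig,
    sample_id: str,
    haps: list[tuple[str, list]],
    rng: np.random.Generator,
) -> list[SimulatedRead]:
    reads = []
    per_hap_target = cfg.depth / 2
    lo, hi = 1000, 2 * cfg.read_length_mean
    for h_idx, (hseq, blocks) in enumerate(haps):
        target = per_hap_target * len(hseq)
        total = 0
        i = 0
        while total < target:
            L = int(np.clip(rng.normal(cfg.read_length_mean, cfg.read_length_sd), lo, hi))
            L = min(L, len(hseq))
            start = int(rng.integers(0, len(hseq) - L + 1))
            segs = _read_segments(blocks, start, start + L)
            read = SimulatedRead(
                f"{sample_id}.h{h_idx + 1}.{i:05d}", hseq[start : start + L], segs
            )
            if cfg.error_rate > 0:
                _inject_errors(read, rng, cfg.error_rate)
            reads.append(read)
            total += L
            i += 1
    return reads


# ---------------------------------------------------------------------------
# output


def _stored_record(read: SimulatedRead, seg: SimSegment) -> tuple[str, list, int, bool]:
    """(stored_seq, stored_cigar, pos, is_reverse) for one segment."""
    qlen = len(read.seq)
    if seg.strand == "+":
        cig = [("S", seg.q0)] + seg.cigar + [("S", qlen - seg.q1)]
        stored = read.seq
    else:
        cig = [("S", qlen - seg.q1)] + list(reversed(seg.cigar)) + [("S", seg.q0)]
        stored = revcomp(read.seq)
    cig = [(op, n) for op, n in cig if n > 0]
    return stored, cig, seg.ref_start, seg.strand == "-"


def _cigar_str(cig: list) -> str:
    return "".join(f"{n}{op}" for op, n in cig)


def read_to_alignments(read: SimulatedRead, sample_id: str) -> list[ReadAlignment]:
    if not read.segments:
        return []
    primary = max(read.segments, key=lambda s: s.q1 - s.q0)
    out = []
    for seg in read.segments:
        stored, cig, pos, rev = _stored_record(read, seg)
        out.append(
            ReadAlignment(
                read_id=read.read_id,
                sample_id=sample_id,
                contig=seg.contig,
                start=pos,
                cigar=cig,
                seq=stored,
                mapq=60,
                is_reverse=rev,
                supplementary_of=None if seg is primary else read.read_id,
            )
        )
    return out


_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}


def write_bam(
    reads: list[SimulatedRead], contigs: dict, path: str, sample_id: str
) -> None:
    """Write simulated reads as a coordinate-sorted, indexed BAM with SA
    tags linking split segments."""
    names = list(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(contigs[n])} for n in names],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    tmp = str(path) + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for read in reads:
            if not read.segments:
                continue
            primary = max(read.segments, key=lambda s: s.q1 - s.q0)
            stored_all = [_stored_record(read, s) for s in read.segments]
            sa_parts = [
                f"{s.contig},{pos + 1},{'-' if rev else '+'},{_cigar_str(cig)},60,0;"
                for s, (stored, cig, pos, rev) in zip(read.segments, stored_all)
            ]
            for seg, (stored, cig, pos, rev) in zip(read.segments, stored_all):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = read.read_id
                a.flag = (16 if rev else 0) | (0 if seg is primary else 2048)
                a.reference_id = names.index(seg.contig)
                a.reference_start = pos
                a.mapping_quality = 60
                a.cigartuples = [(_CODE[op], n) for op, n in cig]
                a.query_sequence = stored
                tags = [("RG", sample_id)]
                if len(read.segments) > 1:
                    others = [
                        p for s2, p in zip(read.segments, sa_parts) if s2 is not seg
                    ]
                    tags.append(("SA", "".join(others)))
                a.set_tags(tags)
                bam.write(a)
    pysam.sort("-o", str(path), tmp)
    pysam.index(str(path))
    import os

    os.remove(tmp)


def write_reference(contigs: dict, path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            s = "".join(seq)
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")
    pysam.faidx(str(path))


# ---------------------------------------------------------------------------
# top-level


@dataclass
class SimResult:
    config: SimConfig
    contigs: dict  # name -> numpy char array
    repeat_regions: list
    events: list
    truth: list
    haplotypes: dict  # sample -> [(seq, blocks), (seq, blocks)]
    reads: dict  # sample -> list[SimulatedRead]
    transmissions: dict = field(default_factory=dict)

    def reference_str(self, contig: str) -> str:
        return "".join(self.contigs[contig])

    def read_alignments(self, sample: str) -> list[ReadAlignment]:
        out = []
        for read in self.reads[sample]:
            out.extend(read_to_alignments(read, sample))
        out.sort(key=lambda a: (a.contig, a.start))
        return out

    def write_reference(self, path: str) -> None:
        write_reference(self.contigs, path)

    def write_bam(self, sample: str, path: str) -> None:
        write_bam(self.reads[sample], self.contigs, path, sample)

    def write_truth(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(t) for t in self.truth], fh, indent=1)

    def write_ped(self, path: str) -> None:
        ped = self.config.pedigree
        if ped is None:
            raise ValueError("not a pedigree simulation")
        with open(path, "w") as fh:
            fh.write(f"FAM\t{ped.father}\t0\t0\t1\t-9\n")
            fh.write(f"FAM\t{ped.mother}\t0\t0\t2\t-9\n")
            for child in ped.children:
                fh.write(f"FAM\t{child}\t{ped.father}\t{ped.mother}\t0\t-9\n")


def simulate(cfg: SimConfig) -> SimResult:
    """Run the full generator: reference, repeats, events, genotypes, reads."""
    rng = np.random.default_rng(cfg.seed)
    contigs = {cfg.contig_name: _random_dna(rng, cfg.contig_len)}
    if cfg.n_bnd > 0:
        contigs["chr2"] = _random_dna(rng, max(100_000, cfg.contig_len // 4))
    events = _place_events(cfg, rng)
    repeats = _plant_repeats(cfg, rng, contigs, events)
    _finalize_events(cfg, rng, contigs, events)
    geno = _sample_genotypes(cfg, rng, events)
    transmissions = geno.pop("_transmissions", {})
    truth = _truth_records(cfg, contigs, events, geno)

    ref = {name: contigs[name] for name in contigs}
    haplotypes = {}
    reads = {}
    for s_idx, sample in enumerate(cfg.sample_names):
        haps = []
        for h in range(2):
            evs = [ev for i, ev in enumerate(events) if geno[sample][i][h]]
            haps.append(apply_events(ref, cfg.contig_name, evs))
        haplotypes[sample] = haps
        sample_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, s_idx]))
        reads[sample] = simulate_sample_reads(cfg, sample, haps, sample_rng)
    return SimResult(cfg, contigs, repeats, events, truth, haplotypes, reads, transmissions)
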