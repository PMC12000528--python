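"""Two-phase calling driver: per-sample discovery, multi-sample joint call.

Discovery scans one sample's alignments for signatures, clusters them,
assembles consensus haplotypes, refines breakpoints, and records a binned
depth track. Its result is a plain, human-inspectable archive (JSON +
FASTA) containing everything joint calling needs except genotyping-time
read re-scoring, which re-reads the BAMs. Joint calling merges haplotypes
across samples, genotypes every locus in every sample, phases overlapping
het calls, applies depth-based DEL/DUP refinement, and writes one
multi-sample VCF.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import statistics
from dataclasses import dataclass, field, asdict

from . import assembly, clustering, depthref, jointgeno, refine, signatures, vcfout
from .alignio import ReadAlignment, ReferenceGenome, load_alignments
from .assembly import ConsensusHaplotype
from .refine import Breakpoint, SvRecord
from .signatures import Breakend, Orient, SigKind

log = logging.getLogger(__name__)

CONFIG_VERSION = 1


@dataclass
class RunConfig:
    """All tunable thresholds, named identically in flags and archives."""

    min_mapq: int = 10
    min_signature_size: int = signatures.DEFAULT_MIN_SIGNATURE_SIZE
    min_clip_size: int = signatures.DEFAULT_MIN_CLIP_SIZE
    max_gap: int = signatures.DEFAULT_MAX_GAP
    max_dist: int = clustering.DEFAULT_MAX_DIST
    size_ratio: float = clustering.DEFAULT_SIZE_RATIO
    min_cluster_support: int = clustering.DEFAULT_MIN_CLUSTER_SUPPORT
    flank: int = assembly.DEFAULT_FLANK
    split_threshold: float = assembly.DEFAULT_SPLIT_THRESHOLD
    max_haplotypes: int = assembly.DEFAULT_MAX_HAPLOTYPES
    min_sv_size: int = refine.MIN_SV_SIZE
    dup_min_identity: float = refine.DEFAULT_DUP_MIN_IDENTITY
    inv_max_span: int = refine.DEFAULT_INV_MAX_SPAN
    max_merge_dist: int = jointgeno.DEFAULT_MAX_MERGE_DIST
    merge_similarity: float = jointgeno.DEFAULT_MERGE_SIMILARITY
    epsilon: float = 0.05
    min_score_margin: int = 10
    bin_size: int = depthref.DEFAULT_BIN_SIZE
    min_depth_event_size: int = depthref.DEFAULT_MIN_DEPTH_EVENT_SIZE
    depth_tol: float = depthref.DEFAULT_TOL
    symbolic_threshold: int = vcfout.DEFAULT_SYMBOLIC_THRESHOLD
    seed: int = 0
    version: int = CONFIG_VERSION


@dataclass
class Discovery:
    sample_id: str
    haplotypes: list  # (ConsensusHaplotype, [SvRecord])
    depth: dict  # contig -> DepthTrack
    config: RunConfig


def _group_by_read(alns: list) -> dict:
    by_read: dict[str, list] = {}
    for a in alns:
        by_read.setdefault(a.read_id, []).append(a)
    return by_read


def _cluster_is_remote_bnd(cluster) -> bool:
    for m in cluster.members:
        if m.kind == SigKind.SPLIT_JUNCTION and m.mate.contig != m.contig:
            return True
    return False


def _cluster_inverted_junction(cluster):
    """(p1, p2, orient) medians for an inversion-orientation split cluster."""
    members = [
        m for m in cluster.members
        if m.kind == SigKind.SPLIT_JUNCTION
        and m.mate.contig == m.contig
        and m.orient == m.mate.orient
    ]
    if len(members) < len([m for m in cluster.members if m.kind == SigKind.SPLIT_JUNCTION]) / 2 or not members:
        return None
    p1 = int(statistics.median(m.pos for m in members))
    p2 = int(statistics.median(m.mate.pos for m in members))
    return p1, p2, members[0].orient


def _bnd_haplotype(cluster, ref: ReferenceGenome, sample_id: str, flank: int):
    """Junction-level BND call from a cross-contig split cluster.

    The fused allele sequence is constructed directly from the two
    reference sides of the median junction, no assembly needed.
    """
    members = [m for m in cluster.members if m.kind == SigKind.SPLIT_JUNCTION]
    p1 = int(statistics.median(m.pos for m in members))
    p2 = int(statistics.median(m.mate.pos for m in members))
    orient1 = members[0].orient
    mate = members[0].mate
    be1 = Breakend(cluster.contig, p1, orient1)
    be2 = Breakend(mate.contig, p2, mate.orient)
    host_len = ref.contig_length(cluster.contig)
    span = (max(0, p1 - flank), min(host_len, p1 + flank))
    if orient1 == Orient.LEFT_ANCHOR:
        left = ref.window(cluster.contig, span[0], p1).seq
    else:  # junction retains the right side of the host
        left = ref.window(cluster.contig, p1, span[1]).seq
    if be2.orient == Orient.RIGHT_ANCHOR:
        right = ref.window(be2.contig, p2, p2 + flank).seq
    else:
        from .alignio import revcomp

        right = revcomp(ref.window(be2.contig, max(0, p2 - flank), p2).seq)
    hap = ConsensusHaplotype(
        hap_id=f"{sample_id}:{cluster.cluster_id}:bnd",
        seq=left + right,
        support_reads=sorted(cluster.support_reads),
        cluster_ref=cluster.cluster_id,
        anchor=(cluster.contig, span[0], span[1]),
        sample_id=sample_id,
    )
    bp = Breakpoint(be1, be2, "", 0, "", hap.hap_id)
    rec = SvRecord("BND", cluster.contig, p1, p1, 0, [bp], hap.hap_id)
    return hap, [rec]


def _pair_sample_inversions(haplotypes: list, cfg: RunConfig) -> None:
    """Join inversion-orientation BND components across a sample's
    haplotypes into INV events; every contributing haplotype carries the
    full record set (both components plus the INV summary) so any merge
    representative reports the whole event."""
    intra = [
        r for _, recs in haplotypes for r in recs
        if r.sv_type == "BND" and r.breakpoints[0].be1.contig == r.breakpoints[0].be2.contig
    ]
    paired = refine.pair_inversion(intra, cfg.inv_max_span)
    invs = [r for r in paired if r.sv_type == "INV"]
    for inv in invs:
        comps = [
            r for r in paired
            if r.sv_type == "BND" and r.event_id == inv.event_id
        ]
        full = comps + [inv]
        for _, recs in haplotypes:
            if any(r in comps for r in recs):
                for extra in full:
                    if extra not in recs:
                        recs.append(extra)


def discover_sample(
    bam_path: str, ref: ReferenceGenome, sample_id: str, cfg: RunConfig
) -> Discovery:
    """Per-sample discovery: signatures -> clusters -> haplotypes -> records."""
    alns = list(load_alignments(bam_path, sample_id, min_mapq=0))
    by_read = _group_by_read(alns)

    all_sigs = []
    for rid in sorted(by_read):
        recs = [a for a in by_read[rid] if a.mapq >= cfg.min_mapq]
        if not recs:
            continue
        for a in recs:
            sigs = signatures.extract_signatures(
                a, cfg.min_signature_size, cfg.min_clip_size
            )
            all_sigs.extend(signatures.merge_adjacent_indels(sigs, cfg.max_gap))
        all_sigs.extend(signatures.extract_split_junctions(recs))
    all_sigs.sort(key=lambda s: (s.contig, s.pos))

    clusters = clustering.cluster_signatures(
        all_sigs, cfg.max_dist, cfg.size_ratio, cfg.min_cluster_support
    )
    log.info("%s: %d signatures, %d clusters", sample_id, len(all_sigs), len(clusters))

    haplotypes = []
    for cluster in clusters:
        if _cluster_is_remote_bnd(cluster):
            haplotypes.append(_bnd_haplotype(cluster, ref, sample_id, cfg.flank))
            continue
        contig_len = ref.contig_length(cluster.contig)
        win, segments = assembly.extract_read_segments(
            cluster, by_read, contig_len, cfg.flank
        )
        if len(segments) < cfg.min_cluster_support:
            continue
        haps = assembly.build_consensus(
            segments, cluster.cluster_id, sample_id,
            (cluster.contig, win[0], win[1]),
            cfg.max_haplotypes, cfg.split_threshold, cfg.min_cluster_support,
            seed=cfg.seed,
        )
        inv_junction = _cluster_inverted_junction(cluster)
        for hap in haps:
            window = ref.window(cluster.contig, win[0], win[1])
            if inv_junction is not None:
                rec = refine.refine_inversion(
                    hap, window, inv_junction[0], inv_junction[1],
                    inv_junction[2], cfg.min_sv_size,
                )
                if rec is not None:
                    haplotypes.append((hap, [rec]))
                    continue
            aln = refine.align_haplotype(hap, window)
            if aln is None:
                continue
            recs = refine.extract_breakpoints(
                aln, hap, window, cfg.min_sv_size, cfg.dup_min_identity
            )
            out_recs = []
            for rec in recs:
                if rec.sv_type == "INS":
                    # the anchor window can truncate left-normalization of a
                    # long tandem copy; redo it over a window wide enough to
                    # hold the whole slide, then test for duplication
                    pad = len(rec.ins_seq) + 600
                    dup_win = ref.window(
                        rec.contig, max(0, rec.pos - pad), rec.pos + pad
                    )
                    off = rec.pos - dup_win.start
                    new_off, new_ins, _ = refine.canonicalize_insertion(
                        dup_win.seq, off, rec.ins_seq
                    )
                    rec.pos = rec.end = dup_win.start + new_off
                    rec.ins_seq = new_ins
                    bp = rec.breakpoints[0]
                    rec.breakpoints = [
                        refine.Breakpoint(
                            dataclasses.replace(bp.be1, pos=rec.pos),
                            dataclasses.replace(bp.be2, pos=rec.pos),
                            new_ins, 0, "", bp.hap_ref,
                        )
                    ]
                    rec = refine.classify_duplication(rec, dup_win, cfg.dup_min_identity)
                out_recs.append(rec)
            if out_recs:
                haplotypes.append((hap, out_recs))

    _pair_sample_inversions(haplotypes, cfg)

    depth = {}
    for contig in ref.contigs:
        contig_alns = [a for a in alns if a.contig == contig]
        depth[contig] = depthref.build_depth_track(
            contig_alns, contig, ref.contig_length(contig), cfg.bin_size
        )
    return Discovery(sample_id, haplotypes, depth, cfg)


def _fetch_locus_reads(bam_path: str, sample_id: str, locus) -> dict:
    pad = 100
    alns = list(
        load_alignments(
            bam_path, sample_id,
            region=(locus.contig, max(0, locus.span[0] - pad), locus.span[1] + pad),
            min_mapq=0,
        )
    )
    return _group_by_read(alns)


def _alt_dosage(call, allele_index: int) -> int:
    if call is None or call.gt is None:
        return 0
    return sum(1 for a in call.gt if a == allele_index)


def _apply_depth_refinement(loci: list, discoveries: dict, cfg: RunConfig) -> None:
    for locus in loci:
        for allele in locus.alleles:
            for rec in allele.records:
                if rec.sv_type not in ("DEL", "DUP"):
                    continue
                if rec.end - rec.pos < cfg.min_depth_event_size:
                    continue
                votes = []
                for sample, disc in discoveries.items():
                    call = locus.genotypes.get(sample)
                    dosage = _alt_dosage(call, allele.index)
                    if dosage == 0:
                        continue
                    track = disc.depth.get(rec.contig)
                    if track is None:
                        continue
                    ratio = depthref.depth_ratio(track, (rec.pos, rec.end))
                    if ratio is None:
                        continue
                    own = depthref.expected_ratio(rec.sv_type, dosage)
                    other = depthref.expected_ratio(
                        "DUP" if rec.sv_type == "DEL" else "DEL", dosage
                    )
                    if abs(ratio - own) <= cfg.depth_tol:
                        votes.append("support")
                    elif abs(ratio - other) <= cfg.depth_tol:
                        votes.append("flip")
                    else:
                        votes.append("fail")
                if not votes:
                    continue
                if all(v == "flip" for v in votes):
                    size = abs(rec.svlen)
                    rec.sv_type = "DUP" if rec.sv_type == "DEL" else "DEL"
                    rec.svlen = size if rec.sv_type == "DUP" else -size
                    rec.depth_support = True
                else:
                    rec.depth_support = votes.count("support") >= len(votes) / 2


def joint_call(
    discoveries: list,
    bam_paths: dict,
    ref: ReferenceGenome,
    cfg: RunConfig,
) -> list:
    """Merge discoveries, genotype every sample at every locus, phase,
    depth-refine. Returns the genotyped loci (VCF writing is separate)."""
    for d in discoveries:
        if d.config.version != CONFIG_VERSION:
            raise ValueError("discovery archives were produced by a different config version")
    haps_all = [hr for d in discoveries for hr in d.haplotypes]
    loci = jointgeno.merge_haplotypes(haps_all, ref, cfg.max_merge_dist, cfg.merge_similarity)
    params = jointgeno.GenotypeModelParams(cfg.epsilon, cfg.min_score_margin)
    samples = [d.sample_id for d in discoveries]
    for locus in loci:
        win = ref.window(locus.contig, locus.span[0], locus.span[1])
        for sample in samples:
            reads = _fetch_locus_reads(bam_paths[sample], sample, locus)
            locus.genotypes[sample] = jointgeno.genotype_sample_at_locus(
                locus, sample, reads, win.seq, params
            )
    for sample in samples:
        jointgeno.phase_overlapping(loci, sample)
    _apply_depth_refinement(loci, {d.sample_id: d for d in discoveries}, cfg)
    return loci


def run_joint_call(
    discoveries: list,
    bam_paths: dict,
    ref: ReferenceGenome,
    out_vcf: str,
    cfg: RunConfig,
) -> list:
    loci = joint_call(discoveries, bam_paths, ref, cfg)
    samples = [d.sample_id for d in discoveries]
    vcfout.write_vcf(loci, ref, out_vcf, samples, cfg.symbolic_threshold)
    n_rec = sum(len(a.records) for l in loci for a in l.alleles)
    log.info("joint call: %d loci, %d records, %d samples", len(loci), n_rec, len(samples))
    return loci


# ---------------------------------------------------------------------------
# discovery archives (plain-directory artifacts)


def _bp_to_dict(bp: Breakpoint) -> dict:
    return {
        "be1": [bp.be1.contig, bp.be1.pos, bp.be1.orient.value],
        "be2": [bp.be2.contig, bp.be2.pos, bp.be2.orient.value],
        "ins_seq": bp.ins_seq,
        "hom_len": bp.hom_len,
        "hom_seq": bp.hom_seq,
        "hap_ref": bp.hap_ref,
    }


def _bp_from_dict(d: dict) -> Breakpoint:
    return Breakpoint(
        Breakend(d["be1"][0], d["be1"][1], Orient(d["be1"][2])),
        Breakend(d["be2"][0], d["be2"][1], Orient(d["be2"][2])),
        d["ins_seq"], d["hom_len"], d["hom_seq"], d["hap_ref"],
    )


def _rec_to_dict(rec: SvRecord) -> dict:
    d = dataclasses.asdict(rec)
    d["breakpoints"] = [_bp_to_dict(bp) for bp in rec.breakpoints]
    return d


def _rec_from_dict(d: dict) -> SvRecord:
    d = dict(d)
    d["breakpoints"] = [_bp_from_dict(b) for b in d["breakpoints"]]
    return SvRecord(**d)


def save_discovery(disc: Discovery, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(asdict(disc.config), fh, indent=1)
    haps = []
    for hap, recs in disc.haplotypes:
        haps.append({"hap": dataclasses.asdict(hap), "records": [_rec_to_dict(r) for r in recs]})
    with open(os.path.join(out_dir, "haplotypes.json"), "w") as fh:
        json.dump({"sample_id": disc.sample_id, "haplotypes": haps}, fh, indent=1)
    with open(os.path.join(out_dir, "haplotypes.fasta"), "w") as fh:
        for hap, _ in disc.haplotypes:
            fh.write(f">{hap.hap_id}\n{hap.seq}\n")
    depth = {
        contig: {"bin_size": t.bin_size, "bins": [round(float(b), 4) for b in t.bins]}
        for contig, t in disc.depth.items()
    }
    with open(os.path.join(out_dir, "depth.json"), "w") as fh:
        json.dump(depth, fh)


def load_discovery(out_dir: str) -> Discovery:
    import numpy as np

    with open(os.path.join(out_dir, "config.json")) as fh:
        cfg = RunConfig(**json.load(fh))
    with open(os.path.join(out_dir, "haplotypes.json")) as fh:
        data = json.load(fh)
    haps = []
    for entry in data["haplotypes"]:
        h = dict(entry["hap"])
        h["anchor"] = tuple(h["anchor"])
        haps.append((ConsensusHaplotype(**h), [_rec_from_dict(r) for r in entry["records"]]))
    with open(os.path.join(out_dir, "depth.json")) as fh:
        depth_raw = json.load(fh)
    depth = {
        contig: depthref.DepthTrack(contig, d["bin_size"], np.array(d["bins"]))
        for contig, d in depth_raw.items()
    }
    return Discovery(data["sample_id"], haps, depth, cfg)
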