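"""Multi-sample VCF serialization.

Records are allele-centric: one row per alternate allele (plus component
BND rows for multi-breakpoint events such as inversions). Sequence-resolved
REF/ALT are emitted for DEL/INS below ``symbolic_threshold``; larger
deletions and all DUP/INV use symbolic alleles with END. Inversions are
reported both as a symbolic INV row and as their two component breakend
rows sharing an EVENT id. Internal 0-based coordinates convert to 1-based
here and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from .alignio import ReferenceGenome
from .jointgeno import SvLocus
from .refine import SvRecord
from .signatures import Orient

log = logging.getLogger(__name__)

DEFAULT_SYMBOLIC_THRESHOLD = 10_000

_HEADER_META = """\
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant (negative for deletions)">
##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Length of breakpoint microhomology">
##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="Microhomology sequence at the canonical placement">
##INFO=<ID=INSLEN,Number=1,Type=Integer,Description="Length of inserted sequence">
##INFO=<ID=EVENT,Number=1,Type=String,Description="Multi-breakpoint event identifier">
##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend record id">
##INFO=<ID=DEPTHSUPPORT,Number=1,Type=String,Description="Read-depth signature consistent with the call (TRUE/FALSE)">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INV,Description="Inversion">
##ALT=<ID=INS,Description="Insertion">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (phred-scaled)">
##FORMAT=<ID=AD,Number=.,Type=Integer,Description="Read support per allele (ref first)">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
"""


def _format_sample(call, allele_index: int) -> str:
    """GT:GQ:AD:PS column for one sample on the row of one allele.

    Chromosomes carrying a different alternate allele at a multi-allelic
    locus are projected to 0 on this row (allele-centric representation).
    """
    if call is None or call.gt is None:
        return "./.:0:.:."
    mapped = tuple(1 if a == allele_index else 0 for a in call.gt)
    sep = "|" if call.phased else "/"
    gt = sep.join(str(a) for a in mapped)
    ref_n = call.ad[0] if call.ad else 0
    alt_n = call.ad[allele_index] if len(call.ad) > allele_index else 0
    ps = str(call.ps) if call.ps is not None else "."
    return f"{gt}:{call.gq}:{ref_n},{alt_n}:{ps}"


def _bnd_alt(ref_base: str, orient: Orient, mate_contig: str, mate_pos1: int, mate_orient: Orient) -> str:
    if orient == Orient.LEFT_ANCHOR:
        if mate_orient == Orient.RIGHT_ANCHOR:
            return f"{ref_base}[{mate_contig}:{mate_pos1}["
        return f"{ref_base}]{mate_contig}:{mate_pos1}]"
    if mate_orient == Orient.RIGHT_ANCHOR:
        return f"[{mate_contig}:{mate_pos1}[{ref_base}"
    return f"]{mate_contig}:{mate_pos1}]{ref_base}"


def _breakend_pos_ref(be, ref: ReferenceGenome) -> tuple[int, str]:
    """1-based POS and REF base for a breakend record."""
    if be.orient == Orient.LEFT_ANCHOR:
        pos0 = be.pos - 1  # last retained base
    else:
        pos0 = be.pos
    pos0 = max(0, pos0)
    base = ref.window(be.contig, pos0, pos0 + 1).seq or "N"
    return pos0 + 1, base


def _bnd_rows(rec: SvRecord, rid: str, ref: ReferenceGenome, info_extra: str, sample_cols: list) -> list:
    bp = rec.breakpoints[0]
    rows = []
    ids = (f"{rid}.1", f"{rid}.2")
    for i, (be, mate) in enumerate(((bp.be1, bp.be2), (bp.be2, bp.be1))):
        pos1, base = _breakend_pos_ref(be, ref)
        mate_pos1, _mb = _breakend_pos_ref(mate, ref)
        alt = _bnd_alt(base, be.orient, mate.contig, mate_pos1, mate.orient)
        info = f"SVTYPE=BND;MATEID={ids[1 - i]}"
        if info_extra:
            info += ";" + info_extra
        rows.append((be.contig, pos1, ids[i], base, alt, info, sample_cols))
    return rows


def write_vcf(
    loci: list[SvLocus],
    ref: ReferenceGenome,
    out_path: str,
    sample_order: list[str],
    symbolic_threshold: int = DEFAULT_SYMBOLIC_THRESHOLD,
) -> None:
    """Serialize genotyped loci to a VCF 4.2 file."""
    rows = []
    counter = 0
    for locus in loci:
        for allele in locus.alleles:
            calls = [locus.genotypes.get(s) for s in sample_order]
            sample_cols = [_format_sample(c, allele.index) for c in calls]
            for rec in allele.records:
                counter += 1
                rid = f"hsv{counter}"
                bp = rec.breakpoints[0] if rec.breakpoints else None
                extra = []
                if rec.event_id:
                    extra.append(f"EVENT={rec.event_id}")
                if rec.depth_support is not None:
                    extra.append(f"DEPTHSUPPORT={'TRUE' if rec.depth_support else 'FALSE'}")
                if rec.sv_type == "BND":
                    rows.extend(_bnd_rows(rec, rid, ref, ";".join(extra), sample_cols))
                    continue
                pos0 = rec.pos - 1  # anchor base before the variant
                anchor = ref.window(rec.contig, max(0, pos0), max(0, pos0) + 1).seq or "N"
                size = abs(rec.svlen)
                info = [f"SVTYPE={rec.sv_type}", f"SVLEN={rec.svlen}"]
                if rec.sv_type != "INS":
                    info.append(f"END={rec.end}")
                if bp is not None and bp.hom_len > 0:
                    info += [f"HOMLEN={bp.hom_len}", f"HOMSEQ={bp.hom_seq}"]
                if rec.sv_type == "INS":
                    info.append(f"INSLEN={size}")
                info += extra
                if rec.sv_type == "DEL" and size < symbolic_threshold:
                    ref_allele = anchor + ref.window(rec.contig, rec.pos, rec.end).seq
                    alt_allele = anchor
                elif rec.sv_type == "INS" and size < symbolic_threshold:
                    ref_allele = anchor
                    alt_allele = anchor + rec.ins_seq
                else:
                    ref_allele = anchor
                    alt_allele = f"<{rec.sv_type}>"
                rows.append(
                    (rec.contig, max(0, pos0) + 1, rid, ref_allele, alt_allele,
                     ";".join(info), sample_cols)
                )
    contig_order = {c: i for i, c in enumerate(ref.contigs)}
    rows.sort(key=lambda r: (contig_order.get(r[0], 10**9), r[1], r[2]))
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplosv\n")
        for c in ref.contigs:
            fh.write(f"##contig=<ID={c},length={ref.contig_length(c)}>\n")
        fh.write(_HEADER_META)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_order) + "\n")
        for contig, pos1, rid, ra, aa, info, cols in rows:
            fh.write(
                f"{contig}\t{pos1}\t{rid}\t{ra}\t{aa}\t.\tPASS\t{info}\tGT:GQ:AD:PS\t"
                + "\t".join(cols) + "\n"
            )


@dataclass
class VcfSv:
    """Lossy per-record view sufficient for evaluation and concordance."""

    sv_type: str
    contig: str
    pos: int  # 0-based
    end: int
    svlen: int
    genotypes: dict  # sample -> tuple | None
    gq: dict  # sample -> int
    phased: dict = field(default_factory=dict)
    record_id: str = ""
    hom_len: int = 0
    event_id: str = ""
    raw: str = ""  # original record line, for filter-and-rewrite workflows


def read_vcf(path: str) -> list[VcfSv]:
    """Parse a VCF (ours or any with SVTYPE/GT) back into evaluable records.

    This is a lossy inverse of :func:`write_vcf` sufficient for evaluation
    and concordance; each record also keeps its raw line so a filtered
    subset can be rewritten byte-identically via :func:`write_records`.
    """
    out = []
    skipped = 0
    with open(path) as fh:
        body_lines = [l.rstrip("\n") for l in fh if not l.startswith("#")]
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    for line_no, rec in enumerate(vf):
        svtype = rec.info.get("SVTYPE")
        if svtype is None:
            skipped += 1
            continue
        svlen = rec.info.get("SVLEN", 0)
        if isinstance(svlen, tuple):
            svlen = svlen[0] if svlen else 0
        end = rec.stop
        gts, gqs, phased = {}, {}, {}
        for s in samples:
            sd = rec.samples[s]
            gt = sd.get("GT")
            if gt is None or any(a is None for a in gt):
                gts[s] = None
            else:
                gts[s] = tuple(gt)
            gqs[s] = sd.get("GQ", 0) or 0
            phased[s] = bool(sd.phased)
        out.append(
            VcfSv(
                svtype, rec.contig, rec.start,
                end, int(svlen) if svlen is not None else 0, gts, gqs, phased,
                rec.id or "", int(rec.info.get("HOMLEN", 0) or 0),
                str(rec.info.get("EVENT", "") or ""),
                raw=body_lines[line_no],
            )
        )
    if skipped:
        log.info("read_vcf: skipped %d records without SVTYPE", skipped)
    return out


def write_records(svs: list[VcfSv], header_from: str, out_path: str) -> None:
    """Rewrite parsed records (e.g. a filtered subset) under the header of
    an existing VCF; record bodies are preserved byte-identically."""
    with open(header_from) as fh:
        header = [l for l in fh if l.startswith("#")]
    with open(out_path, "w") as fh:
        fh.writelines(header)
        for sv in svs:
            fh.write(sv.raw + "\n")
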