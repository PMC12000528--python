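"""Pedigree genotype-concordance evaluation.

For a founder couple plus children, a locus is concordant when some
assignment of each parent's two alleles to haplotypes, together with a
transmission choice per child, reproduces every child's genotype:

* MODE A (no inheritance map): transmissions are free per child, so the
  check reduces to Mendelian satisfiability, decided by exhaustive search.
* MODE B (inheritance map given): each child's transmitted parental
  haplotype is fixed per genomic region; only the parental phasings are
  searched, and the same phasing must explain all children jointly.

The evaluator never edits genotypes; it only scores them. Alleles are
treated as distinct labels, so multi-allelic loci work unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional


@dataclass
class Pedigree:
    father: str
    mother: str
    children: list

    @property
    def samples(self) -> list:
        return [self.father, self.mother] + list(self.children)

    @classmethod
    def from_ped(cls, path: str) -> "Pedigree":
        """Parse a PED file describing one founder couple plus children."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.strip() and not line.startswith("#"):
                    rows.append(line.split())
        children = [r[1] for r in rows if r[2] != "0" and r[3] != "0"]
        parents = {(r[2], r[3]) for r in rows if r[2] != "0"}
        if len(parents) != 1:
            raise ValueError("expected a single founder couple in the PED file")
        father, mother = next(iter(parents))
        return cls(father, mother, children)


@dataclass
class ConcordanceResult:
    verdicts: list  # per-locus 'concordant' | 'discordant' | 'unevaluated'
    concordant: int
    evaluated: int
    min_gq: int

    @property
    def proportion(self) -> Optional[float]:
        return self.concordant / self.evaluated if self.evaluated else None


#: inheritance map: child -> list of (contig, start, end, father_hap, mother_hap)
InheritanceMap = dict


def load_inheritance_map(path: str) -> InheritanceMap:
    """BED-like map: contig, start, end, child, father_hap, mother_hap."""
    out: InheritanceMap = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, start, end, child, fh_hap, mh_hap = line.split()[:6]
            out.setdefault(child, []).append(
                (contig, int(start), int(end), int(fh_hap), int(mh_hap))
            )
    return out


def _map_lookup(imap: InheritanceMap, child: str, contig: str, region: tuple):
    """Transmitted (father_hap, mother_hap) for a region, or 'straddle'/None."""
    hits = [
        (s, e, fh, mh)
        for (c, s, e, fh, mh) in imap.get(child, [])
        if c == contig and s < region[1] and e > region[0]
    ]
    if not hits:
        return None
    full = [(fh, mh) for s, e, fh, mh in hits if s <= region[0] and e >= region[1]]
    if not full:
        return "straddle"
    return full[0]


def check_locus(
    genotypes: dict,
    ped: Pedigree,
    contig: str = "",
    region: tuple = (0, 0),
    inheritance_map: Optional[InheritanceMap] = None,
) -> str:
    """Concordance verdict for one locus given all-sample genotypes.

    ``genotypes`` maps sample -> unordered allele pair (tuple) or None;
    any missing genotype makes the locus unevaluated.
    """
    samples = ped.samples
    if any(genotypes.get(s) is None for s in samples):
        return "unevaluated"
    f_gt = tuple(genotypes[ped.father])
    m_gt = tuple(genotypes[ped.mother])
    if inheritance_map is None:
        # MODE A: free transmission per child == Mendelian satisfiability
        for child in ped.children:
            c = tuple(sorted(genotypes[child]))
            ok = any(
                tuple(sorted((fa, ma))) == c for fa in f_gt for ma in m_gt
            )
            if not ok:
                return "discordant"
        return "concordant"
    # MODE B: transmissions fixed by the map; search parental phasings only
    trans = {}
    for child in ped.children:
        t = _map_lookup(inheritance_map, child, contig, region)
        if t == "straddle":
            return "unevaluated"
        if t is None:
            return "unevaluated"
        trans[child] = t
    for f_phase in {f_gt, f_gt[::-1]}:
        for m_phase in {m_gt, m_gt[::-1]}:
            ok = True
            for child in ped.children:
                fh_hap, mh_hap = trans[child]
                expect = tuple(
                    sorted((f_phase[fh_hap - 1], m_phase[mh_hap - 1]))
                )
                if expect != tuple(sorted(genotypes[child])):
                    ok = False
                    break
            if ok:
                return "concordant"
    return "discordant"


def summarize(
    verdicts: list,
    gq_per_locus: list,
    min_gq: int = 0,
) -> ConcordanceResult:
    """Totals under a GQ filter applied across all samples per locus.

    ``gq_per_locus[i]`` is a dict sample -> GQ for locus i. Loci where any
    sample falls below ``min_gq`` are excluded from the evaluated set;
    ``min_gq = 0`` reproduces the unfiltered totals.
    """
    filt = []
    for verdict, gqs in zip(verdicts, gq_per_locus):
        if gqs and min(gqs.values()) < min_gq:
            filt.append("unevaluated")
        else:
            filt.append(verdict)
    evaluated = sum(v in ("concordant", "discordant") for v in filt)
    concordant = sum(v == "concordant" for v in filt)
    return ConcordanceResult(filt, concordant, evaluated, min_gq)
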