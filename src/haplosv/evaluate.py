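"""Truth-set evaluation of called loci on simulated data.

Matching is type-aware: deletions match deletions, inversions match
inversion summary records, and the insertion class {INS, DUP} is matched
jointly — an insertion of extra units into a tandem array is a tandem
duplication of those units, so either label is a correct call for a
planted insertion-class event. Breakpoint exactness compares canonical
(leftmost-equivalent) coordinates on both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

_INS_CLASS = {"INS", "DUP"}


def _type_compatible(truth_type: str, call_type: str) -> bool:
    if truth_type in _INS_CLASS:
        return call_type in _INS_CLASS
    return truth_type == call_type


def _flatten_calls(loci: list) -> list:
    """(record, locus, allele) triples, keeping INV summaries over components."""
    out = []
    for locus in loci:
        for allele in locus.alleles:
            for rec in allele.records:
                if rec.sv_type == "BND" and rec.event_id:
                    continue  # represented by the INV summary
                out.append((rec, locus, allele))
    return out


@dataclass
class EvalResult:
    n_truth: int
    n_called: int
    n_exact: int  # among called non-repeat placements
    n_nonrepeat_called: int
    gt_checked: int
    gt_correct: int

    @property
    def recall(self) -> float:
        return self.n_called / self.n_truth if self.n_truth else 0.0

    @property
    def exact_fraction(self) -> float:
        return self.n_exact / self.n_nonrepeat_called if self.n_nonrepeat_called else 0.0

    @property
    def genotype_accuracy(self) -> float:
        return self.gt_correct / self.gt_checked if self.gt_checked else 0.0


def _gt_as_binary(gt) -> tuple:
    if gt is None:
        return None
    return tuple(sorted(1 if a else 0 for a in gt))


def evaluate_calls(
    loci: list,
    truth: list,
    samples: list,
    match_window: int = 1000,
    size_ratio: float = 0.5,
) -> EvalResult:
    """Match called loci against planted truth records.

    A truth event counts as called when a type-compatible record lies
    within ``match_window`` of its canonical position with size agreement
    of at least ``size_ratio``; as exact when canonical pos/end (and svlen
    for the insertion class) agree to the basepair. Genotypes are compared
    per sample as unordered ref/alt pairs on matched events.
    """
    calls = _flatten_calls(loci)
    present = [
        t for t in truth
        if any(any(a for a in t.genotypes.get(s, (0, 0))) for s in samples)
    ]
    n_called = n_exact = n_nonrep_called = 0
    gt_checked = gt_correct = 0
    for t in present:
        t_size = abs(t.svlen) if t.svlen else max(t.end - t.pos, 1)
        best = None
        for rec, locus, allele in calls:
            if rec.contig != t.contig or not _type_compatible(t.sv_type, rec.sv_type):
                continue
            if abs(rec.pos - t.pos) > match_window:
                continue
            c_size = abs(rec.svlen) if rec.svlen else max(rec.end - rec.pos, 1)
            lo, hi = sorted((t_size, c_size))
            if t.sv_type != "BND" and hi and lo / hi < size_ratio:
                continue
            d = abs(rec.pos - t.pos)
            if best is None or d < best[0]:
                best = (d, rec, locus, allele)
        if best is None:
            continue
        n_called += 1
        _, rec, locus, allele = best
        if not t.in_repeat:
            n_nonrep_called += 1
            exact = rec.pos == t.pos
            if t.sv_type == "DEL":
                exact = exact and rec.end == t.end and rec.svlen == t.svlen
            elif t.sv_type == "INV":
                exact = exact and rec.end == t.end
            elif t.sv_type in _INS_CLASS:
                exact = exact and abs(rec.svlen) == abs(t.svlen)
            if exact:
                n_exact += 1
        for s in samples:
            t_gt = _gt_as_binary(t.genotypes.get(s))
            call = locus.genotypes.get(s)
            if call is None:
                continue
            c_gt = (
                _gt_as_binary(tuple(1 if a == allele.index else 0 for a in call.gt))
                if call.gt is not None
                else None
            )
            gt_checked += 1
            if c_gt == t_gt:
                gt_correct += 1
    return EvalResult(len(present), n_called, n_exact, n_nonrep_called, gt_checked, gt_correct)
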