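"""Breakpoint refinement: realignment, microhomology, type classification."""

import numpy as np
import pytest

from haplosv.alignio import ReferenceWindow, revcomp
from haplosv.assembly import ConsensusHaplotype
from haplosv.refine import (
    SvRecord,
    align_haplotype,
    canonicalize_insertion,
    classify_duplication,
    compute_homology,
    extract_breakpoints,
    pair_inversion,
    refine_inversion,
)
from haplosv.signatures import Breakend, Orient

RNG = np.random.default_rng(99)
BASES = np.array(list("ACGT"))


def random_seq(n, rng=RNG):
    return "".join(BASES[rng.integers(0, 4, n)])


def hap_of(seq, anchor=("c", 0, 0)):
    return ConsensusHaplotype("s:0:0", seq, ["r1", "r2"], 0, anchor, "s")


def window(seq, start=0, contig="c"):
    return ReferenceWindow(contig, start, start + len(seq), seq)


# ---------------------------------------------------------------------------
# microhomology


def homology_oracle(ref_seq, del_start, del_end):
    """Slide the deletion window over every placement; collect placements
    whose alternate sequence equals the original one."""
    size = del_end - del_start
    alt = ref_seq[:del_start] + ref_seq[del_end:]
    starts = [
        s for s in range(0, len(ref_seq) - size + 1)
        if ref_seq[:s] + ref_seq[s + size:] == alt
    ]
    canonical = min(starts)
    hom_len = max(starts) - canonical
    return hom_len, ref_seq[canonical : canonical + hom_len], canonical


class TestComputeHomology:
    def test_tandem_repeat_deletion_worked_example(self):
        ref = "ACGTTATATATAGGCC"
        assert compute_homology(ref, 5, 9) == (4, "TATA", 4)
        assert homology_oracle(ref, 5, 9) == (4, "TATA", 4)

    def test_no_flanking_identity_gives_zero(self):
        ref = "AACCGGTTACGT"
        hom_len, hom_seq, canon = compute_homology(ref, 2, 4)
        assert compute_homology(ref, 2, 4) == homology_oracle(ref, 2, 4)

    def test_matches_sliding_oracle_on_repeat_seeded_references(self):
        """Exact equality with the exhaustive placement oracle on 200 random
        instances including repeat-seeded references."""
        rng = np.random.default_rng(17)
        for trial in range(200):
            n = int(rng.integers(30, 120))
            seq = list(random_seq(n, rng))
            if trial % 2 == 0:  # seed a tandem repeat array
                unit = random_seq(int(rng.integers(1, 6)), rng)
                arr = unit * int(rng.integers(3, 8))
                at = int(rng.integers(0, max(1, n - len(arr))))
                seq[at : at + len(arr)] = list(arr)
            seq = "".join(seq)[:n]
            size = int(rng.integers(1, min(12, n - 2)))
            start = int(rng.integers(1, n - size))
            assert compute_homology(seq, start, start + size) == homology_oracle(
                seq, start, start + size
            )

    def test_canonicalization_idempotent(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            seq = random_seq(80, rng)
            start = int(rng.integers(1, 60))
            size = int(rng.integers(1, 10))
            _, _, canon = compute_homology(seq, start, start + size)
            _, _, canon2 = compute_homology(seq, canon, canon + size)
            assert canon2 == canon


class TestCanonicalizeInsertion:
    def test_slides_left_through_repeat(self):
        ref = "AAAATATATACCCC"
        pos, ins, shift = canonicalize_insertion(ref, 8, "TA")
        assert pos == 3 and shift > 0  # leftmost equivalent placement
        # the alternate sequence is preserved by canonicalization
        assert ref[:8] + "TA" + ref[8:] == ref[:pos] + ins + ref[pos:]

    def test_unique_context_does_not_move(self):
        assert canonicalize_insertion("ACGTACGT", 4, "GGG") == (4, "GGG", 0)


# ---------------------------------------------------------------------------
# realignment and record extraction


def affine_score_oracle(a, b, match=1, mismatch=-5, open_=-6, extend=-0.5):
    """Small dense affine-gap DP (Gotoh), used only on tiny cases."""
    import numpy as np

    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = open_ + extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = open_ + extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + extend)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + extend)
    return max(M[n, m], X[n, m], Y[n, m])


class TestAlignHaplotype:
    def test_identity_alignment(self):
        seq = random_seq(800)
        aln = align_haplotype(hap_of(seq), window(seq))
        assert aln is not None
        assert aln.cigar == [("M", 800)]
        assert aln.score == 800

    @pytest.mark.parametrize("kind", ["D", "I"])
    def test_single_60bp_event_aligns_as_one_run(self, kind):
        rng = np.random.default_rng(12)
        ref = random_seq(700, rng)
        if kind == "D":
            hseq = ref[:300] + ref[360:]
        else:
            hseq = ref[:300] + random_seq(60, rng) + ref[300:]
        aln = align_haplotype(hap_of(hseq), window(ref))
        runs = [(op, n) for op, n in aln.cigar if op != "M"]
        assert runs == [(kind, 60)]

    def test_score_matches_dense_dp_oracle_on_small_cases(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            ref = random_seq(60, rng)
            h = random_seq(55, rng)
            aln = align_haplotype(hap_of(h), window(ref))
            if aln is None:  # low flank identity on random pairs is expected
                continue
            assert aln.score == pytest.approx(affine_score_oracle(ref, h))

    def test_low_flank_identity_dropped(self):
        ref = random_seq(900)
        h = random_seq(300) + ref[300:]  # scrambled left flank
        assert align_haplotype(hap_of(h), window(ref)) is None


class TestExtractBreakpoints:
    def test_deletion_offset_arithmetic(self):
        rng = np.random.default_rng(14)
        ref = random_seq(1000, rng)
        hseq = ref[:400] + ref[460:]
        aln = align_haplotype(hap_of(hseq), window(ref, start=5000))
        recs = extract_breakpoints(aln, hap_of(hseq), window(ref, start=5000))
        assert len(recs) == 1
        r = recs[0]
        assert (r.sv_type, r.svlen) == ("DEL", -60)
        hom, _, canon = compute_homology(ref, 400, 460)
        assert r.pos == 5000 + canon and r.end == r.pos + 60

    def test_insertion_offset_arithmetic(self):
        rng = np.random.default_rng(15)
        ref = random_seq(1000, rng)
        ins = random_seq(60, rng)
        hseq = ref[:400] + ins + ref[400:]
        aln = align_haplotype(hap_of(hseq), window(ref, start=5000))
        recs = extract_breakpoints(aln, hap_of(hseq), window(ref, start=5000))
        assert len(recs) == 1
        r = recs[0]
        assert (r.sv_type, r.svlen) == ("INS", 60)
        pos, canon_ins, _ = canonicalize_insertion(ref, 400, ins)
        assert r.pos == 5000 + pos and r.ins_seq == canon_ins

    def test_runs_below_threshold_yield_no_record(self):
        rng = np.random.default_rng(16)
        ref = random_seq(600, rng)
        hseq = ref[:250] + ref[290:300] + ref[340:]  # two 40 bp deletions
        aln = align_haplotype(hap_of(hseq), window(ref))
        recs = extract_breakpoints(aln, hap_of(hseq), window(ref), min_size=50)
        assert recs == []

    def test_refined_records_are_canonical_fixed_points(self):
        """Re-extracting from already-canonical coordinates changes nothing."""
        rng = np.random.default_rng(18)
        ref = random_seq(800, rng)
        hseq = ref[:250] + ref[330:]
        w = window(ref, start=100)
        aln = align_haplotype(hap_of(hseq), w)
        recs = extract_breakpoints(aln, hap_of(hseq), w)
        r = recs[0]
        hom, homseq, canon = compute_homology(ref, r.pos - 100, r.end - 100)
        assert canon == r.pos - 100
        assert r.breakpoints[0].hom_len == hom


class TestClassifyDuplication:
    def _ins_record(self, pos, ins):
        bp = None
        return SvRecord("INS", "c", pos, pos, len(ins), [], "h", ins_seq=ins)

    def test_perfect_tandem_copy_becomes_dup(self):
        rng = np.random.default_rng(20)
        ref = random_seq(1000, rng)
        ins = ref[300:400]  # copy of the segment left of pos 400
        rec = classify_duplication(self._ins_record(400, ins), window(ref), 0.9)
        assert rec.sv_type == "DUP"
        assert (rec.pos, rec.end) == (300, 400)

    def test_random_insertion_stays_ins(self):
        rng = np.random.default_rng(21)
        ref = random_seq(1000, rng)
        rec = classify_duplication(self._ins_record(400, random_seq(100, rng)), window(ref), 0.9)
        assert rec.sv_type == "INS"

    def test_noisy_tandem_copy_with_five_percent_substitutions(self):
        rng = np.random.default_rng(22)
        ref = random_seq(1000, rng)
        ins = list(ref[300:400])
        for q in rng.choice(100, size=5, replace=False):
            ins[q] = {"A": "C", "C": "G", "G": "T", "T": "A"}[ins[q]]
        rec = classify_duplication(self._ins_record(400, "".join(ins)), window(ref), 0.9)
        assert rec.sv_type == "DUP"

    def test_dispersed_copy_stays_ins(self):
        rng = np.random.default_rng(23)
        ref = random_seq(2000, rng)
        ins = ref[100:200]  # far from the insertion point
        rec = classify_duplication(self._ins_record(1500, ins), window(ref), 0.9)
        assert rec.sv_type == "INS"


class TestInversions:
    def _inv_setup(self, size=300, seed=24):
        rng = np.random.default_rng(seed)
        ref = random_seq(size + 800, rng)
        a, b = 400, 400 + size
        hseq = ref[:a] + revcomp(ref[a:b]) + ref[b:]
        return ref, hseq, a, b

    def test_refine_inversion_recovers_exact_boundaries(self):
        ref, hseq, a, b = self._inv_setup()
        from haplosv.refine import canonical_inversion

        ca, cb = canonical_inversion(ref, a, b)
        rec = refine_inversion(hap_of(hseq), window(ref, start=1000), 1000 + a, 1000 + b,
                               Orient.LEFT_ANCHOR)
        assert rec is not None and rec.sv_type == "BND"
        assert (rec.pos, rec.end) == (1000 + ca, 1000 + cb)

    def test_refine_inversion_polishes_jittered_junctions(self):
        ref, hseq, a, b = self._inv_setup()
        from haplosv.refine import canonical_inversion

        ca, cb = canonical_inversion(ref, a, b)
        rec = refine_inversion(hap_of(hseq), window(ref, start=0), a - 7, b + 5,
                               Orient.RIGHT_ANCHOR)
        assert rec is not None
        assert (rec.pos, rec.end) == (ca, cb)

    def test_non_inverted_haplotype_rejected(self):
        ref, _, a, b = self._inv_setup()
        rec = refine_inversion(hap_of(ref), window(ref, start=0), a, b, Orient.LEFT_ANCHOR)
        assert rec is None

    def test_pair_inversion_joins_matching_orientations(self):
        def bnd(p1, p2, orient):
            bp_ = None
            from haplosv.refine import Breakpoint

            bp_ = Breakpoint(Breakend("c", p1, orient), Breakend("c", p2, orient), "", 0, "", "h")
            return SvRecord("BND", "c", p1, p2, 0, [bp_], "h")

        ll = bnd(5000, 10_000, Orient.LEFT_ANCHOR)
        rr = bnd(5000, 10_000, Orient.RIGHT_ANCHOR)
        out = pair_inversion([ll, rr])
        invs = [r for r in out if r.sv_type == "INV"]
        assert len(invs) == 1
        assert (invs[0].pos, invs[0].end) == (5000, 10_000)
        assert ll.event_id == rr.event_id == invs[0].event_id

    def test_deletion_orientation_pair_not_joined(self):
        from haplosv.refine import Breakpoint

        bp = Breakpoint(Breakend("c", 5000, Orient.LEFT_ANCHOR),
                        Breakend("c", 10_000, Orient.RIGHT_ANCHOR), "", 0, "", "h")
        rec = SvRecord("BND", "c", 5000, 10_000, 0, [bp], "h")
        out = pair_inversion([rec, rec])
        assert all(r.sv_type == "BND" for r in out)

    def test_span_guard(self):
        from haplosv.refine import Breakpoint

        def bnd(orient):
            bp = Breakpoint(Breakend("c", 0, orient), Breakend("c", 10_000_000, orient), "", 0, "", "h")
            return SvRecord("BND", "c", 0, 10_000_000, 0, [bp], "h")

        out = pair_inversion([bnd(Orient.LEFT_ANCHOR), bnd(Orient.RIGHT_ANCHOR)], max_span=1_000_000)
        assert all(r.sv_type == "BND" for r in out)
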