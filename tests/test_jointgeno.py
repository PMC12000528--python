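"""Cross-sample merging, genotype model, phasing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplosv.assembly import ConsensusHaplotype
from haplosv.jointgeno import (
    GenotypeModelParams,
    genotype_likelihoods,
    genotype_locus,
    merge_haplotypes,
    phase_overlapping,
)

PARAMS = GenotypeModelParams()


def direct_biallelic_posteriors(r, a, eps):
    """Independent direct evaluation of the binomial-mixture formula."""
    lik = {
        (0, 0): (1 - eps) ** r * eps**a,
        (0, 1): 0.5 ** (r + a),
        (1, 1): eps**r * (1 - eps) ** a,
    }
    z = sum(lik.values())
    return {g: v / z for g, v in lik.items()}


class TestGenotypeModel:
    def test_hom_ref_worked_example(self):
        """10 ref reads, 0 alt, eps 0.05: hom-ref at GQ 27."""
        gt, gq, post = genotype_locus([10, 0], PARAMS)
        assert gt == (0, 0)
        oracle = direct_biallelic_posteriors(10, 0, 0.05)
        assert gq == math.floor(-10 * math.log10(1 - oracle[(0, 0)]))
        assert gq == 27

    def test_balanced_het_worked_example(self):
        """6 ref / 6 alt reads: het at GQ 40."""
        gt, gq, post = genotype_locus([6, 6], PARAMS)
        assert gt == (0, 1)
        assert gq == 40

    def test_no_evidence_is_missing(self):
        gt, gq, post = genotype_locus([0, 0], PARAMS)
        assert gt is None and gq == 0

    @given(
        r=st.integers(0, 80), a=st.integers(0, 80),
        eps=st.floats(0.01, 0.3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_posteriors_match_direct_formula(self, r, a, eps):
        if r + a == 0:
            return
        _, _, post = genotype_locus([r, a], GenotypeModelParams(epsilon=eps))
        oracle = direct_biallelic_posteriors(r, a, eps)
        for g, p in oracle.items():
            assert post[g] == pytest.approx(p, abs=1e-9)

    @given(r=st.integers(0, 40), a=st.integers(0, 40), eps=st.floats(0.01, 0.3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_posterior_normalizes(self, r, a, eps):
        if r + a == 0:
            return
        _, _, post = genotype_locus([r, a], GenotypeModelParams(epsilon=eps))
        assert sum(post.values()) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("ratio", ["hom", "het"])
    def test_gq_monotone_in_depth(self, ratio):
        prev = -1
        for n in range(2, 61):
            ad = [n, 0] if ratio == "hom" else [n, n]
            _, gq, _ = genotype_locus(ad, PARAMS)
            assert gq >= prev
            prev = gq

    def test_multiallelic_enumeration(self):
        gt, gq, post = genotype_locus([0, 8, 9], PARAMS)
        assert gt == (1, 2)
        assert set(post) == {(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)}


class _FakeRef:
    """Reference accessor backed by one in-memory contig."""

    def __init__(self, seq, contig="c"):
        self.seq, self.contig_name = seq, contig

    @property
    def contigs(self):
        return [self.contig_name]

    def contig_length(self, contig):
        return len(self.seq)

    def window(self, contig, start, end):
        from haplosv.alignio import ReferenceWindow

        end = min(end, len(self.seq))
        return ReferenceWindow(contig, start, end, self.seq[start:end])


def _hap(seq, sample, anchor, support=3, hid=None):
    return ConsensusHaplotype(
        hid or f"{sample}:0:0", seq, [f"{sample}r{i}" for i in range(support)],
        0, anchor, sample,
    )


RNG = np.random.default_rng(55)


def _random_seq(n):
    return "".join(np.array(list("ACGT"))[RNG.integers(0, 4, n)])


class TestMergeHaplotypes:
    def setup_method(self):
        self.ref_seq = _random_seq(8000)
        self.ref = _FakeRef(self.ref_seq)

    def test_identical_alleles_across_samples_merge(self):
        alt = self.ref_seq[1000:2000] + "A" * 60 + self.ref_seq[2000:3000]
        h1 = _hap(alt, "s1", ("c", 1000, 3000))
        h2 = _hap(alt, "s2", ("c", 1000, 3000))
        loci = merge_haplotypes([(h1, []), (h2, [])], self.ref)
        assert len(loci) == 1
        assert len(loci[0].alleles) == 1
        assert set(loci[0].alleles[0].sample_support) == {"s1", "s2"}

    def test_distinct_expansion_alleles_stay_separate(self):
        base = self.ref_seq[1000:2000] + "AT" * 30 + self.ref_seq[2000:3000]
        longer = self.ref_seq[1000:2000] + "AT" * 45 + self.ref_seq[2000:3000]
        h1 = _hap(base, "s1", ("c", 1000, 3000))
        h2 = _hap(longer, "s2", ("c", 1000, 3000))
        loci = merge_haplotypes([(h1, []), (h2, [])], self.ref, merge_similarity=0.99)
        assert len(loci) == 1
        assert len(loci[0].alleles) == 2

    def test_singleton_locus_preserved(self):
        h1 = _hap(self.ref_seq[1000:3000], "s1", ("c", 1000, 3000))
        loci = merge_haplotypes([(h1, [])], self.ref)
        assert len(loci) == 1 and len(loci[0].alleles) == 1

    def test_allele_indices_by_support_then_sequence(self):
        a = self.ref_seq[1000:2000] + "A" * 60 + self.ref_seq[2000:3000]
        b = self.ref_seq[1000:2000] + "C" * 60 + self.ref_seq[2000:3000]
        h1 = _hap(a, "s1", ("c", 1000, 3000), support=2)
        h2 = _hap(b, "s2", ("c", 1000, 3000), support=5)
        loci = merge_haplotypes([(h1, []), (h2, [])], self.ref)
        assert loci[0].alleles[0].hap.sample_id == "s2"  # more support -> allele 1

    def test_self_merge_idempotent(self):
        """Merging two copies of the same sample's haplotype set yields
        allele-identical loci."""
        alt = self.ref_seq[1000:2000] + "G" * 80 + self.ref_seq[2000:3000]
        h1 = _hap(alt, "s1", ("c", 1000, 3000))
        h1b = _hap(alt, "s1", ("c", 1000, 3000), hid="s1:0:1")
        once = merge_haplotypes([(h1, [])], self.ref)
        twice = merge_haplotypes([(h1, []), (h1b, [])], self.ref)
        assert len(once) == len(twice) == 1
        assert [a.seq for a in once[0].alleles] == [a.seq for a in twice[0].alleles]


class TestPhasing:
    def _locus(self, span, gt, allele_reads, sample="s1"):
        from haplosv.jointgeno import GenotypeCall, LocusAllele, SvLocus

        allele = LocusAllele(1, "A" * 100, _hap("A" * 100, sample, ("c",) + span), [], {})
        call = GenotypeCall(sample, gt, [len(allele_reads.get(0, [])), len(allele_reads.get(1, []))],
                            60, allele_reads={k: set(v) for k, v in allele_reads.items()})
        locus = SvLocus(0, "c", span, [allele], {sample: call})
        return locus

    def test_cis_pair_shares_phase_set(self):
        l1 = self._locus((100, 200), (0, 1), {0: ["a", "b"], 1: ["c", "d"]})
        l2 = self._locus((300, 400), (0, 1), {0: ["a", "b"], 1: ["c", "d"]})
        phase_overlapping([l1, l2], "s1")
        c1, c2 = l1.genotypes["s1"], l2.genotypes["s1"]
        assert c1.phased and c2.phased
        assert c1.ps == c2.ps == 100
        assert c1.gt == c2.gt  # cis: same ordering at both loci

    def test_trans_pair_orders_opposite(self):
        l1 = self._locus((100, 200), (0, 1), {0: ["a", "b"], 1: ["c", "d"]})
        l2 = self._locus((300, 400), (0, 1), {0: ["c", "d"], 1: ["a", "b"]})
        phase_overlapping([l1, l2], "s1")
        c1, c2 = l1.genotypes["s1"], l2.genotypes["s1"]
        assert c1.phased and c2.phased and c1.ps == c2.ps
        assert c1.gt == tuple(reversed(c2.gt))

    def test_isolated_het_unphased(self):
        l1 = self._locus((100, 200), (0, 1), {0: ["a"], 1: ["b"]})
        l2 = self._locus((9000, 9100), (0, 1), {0: ["x"], 1: ["y"]})  # no shared reads
        phase_overlapping([l1, l2], "s1")
        assert not l1.genotypes["s1"].phased
        assert l1.genotypes["s1"].ps is None
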