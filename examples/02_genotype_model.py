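"""The relative-read-support genotype model in isolation.

Each read spanning a locus is assigned to the reference or an alternate
allele; the per-allele counts feed a binomial-mixture likelihood with a
uniform diploid prior. GQ is the phred-scaled probability that the called
genotype is wrong: floor(-10 log10(1 - posterior)).
"""

from haplosv.jointgeno import GenotypeModelParams, genotype_locus

params = GenotypeModelParams(epsilon=0.05)

print("ref,alt reads -> genotype, GQ (eps = 0.05, uniform prior)")
for ad in ([10, 0], [6, 6], [0, 12], [15, 3], [2, 2], [0, 0]):
    gt, gq, post = genotype_locus(ad, params)
    label = "./." if gt is None else "/".join(map(str, gt))
    top = max(post.values()) if post else float("nan")
    print(f"  AD={ad!s:>9}  GT={label:>4}  GQ={gq:>3}  posterior={top:.6f}" if post
          else f"  AD={ad!s:>9}  GT={label:>4}  GQ={gq:>3}  (no evidence)")

print()
print("GQ grows with depth at a fixed allele balance (het 1:1):")
for n in (3, 6, 12, 24, 48):
    _, gq, _ = genotype_locus([n, n], params)
    print(f"  {n:>3} + {n:<3} reads -> GQ {gq}")
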