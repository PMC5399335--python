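"""SNP and duplicate-sample quality control on a panel with planted faults.

Filters run in a fixed order (chromosome, call rate, quality score,
heterozygosity deviation, MAF, Hardy-Weinberg) and each removed SNP is
attributed to the first rule it violated.
"""

import numpy as np

import ovinepred as op
from ovinepred.containers import MISSING, GenotypeMatrix
from ovinepred.qc import filter_duplicate_samples, filter_snps

rng = np.random.default_rng(0)
n, m = 200, 300
p = rng.uniform(0.03, 0.5, m)  # include rarer variants so the het rule has honest spread
calls = rng.binomial(2, p[None, :], (n, m)).astype(np.int8)
calls[: int(0.15 * n), 1] = MISSING          # SNP 1: call rate 85% < 90%
calls[:, 2] = 0                              # SNP 2: monomorphic (MAF 0)
calls[:, 3] = np.where(np.arange(n) < n // 2, 2, 0)  # SNP 3: no heterozygotes, HWE blown
calls[:, 4] = 1                              # SNP 4: every sample heterozygous
chrom = np.array(["1"] * m, dtype=object)
chrom[5] = "X"                               # SNP 5: excluded chromosome
calls[-1] = calls[0]                         # last sample duplicates the first

geno = GenotypeMatrix(
    ids=np.array([f"an{i}" for i in range(n)], dtype=object),
    snp_ids=np.array([f"snp{j}" for j in range(m)], dtype=object),
    chrom=chrom,
    pos=np.arange(1, m + 1) * 1000,
    calls=calls,
)

snp_report = filter_snps(geno, op.QCThresholds())
print(f"kept {len(snp_report.kept_snps)}/{m} SNPs; removals:")
for snp, rule, stat in snp_report.removal_log:
    print(f"  {snp}: {rule} (statistic {stat:.3g})")

dup_report = filter_duplicate_samples(geno, op.QCThresholds())
print(f"kept {len(dup_report.kept_samples)}/{n} samples; "
      f"duplicates removed: {[i for i, _, _ in dup_report.removal_log]} "
      f"(genotype correlation >= 0.98)")
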