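"""SNP and sample quality control.

SNP filters are applied in a fixed, documented order — chromosome exclusion,
call rate, per-genotype quality score, heterozygosity deviation, minor
allele frequency, Hardy-Weinberg equilibrium — and each removed SNP is
attributed to the first rule that triggered.  The heterozygosity rule
(observed heterozygote fraction outside the panel mean +/- k SD) is iterated
to a fixed point so that re-running QC on its own output removes nothing.

Sample QC removes near-duplicate samples: pairs whose 0/1/2 genotype
correlation over jointly non-missing SNPs reaches the threshold keep only
the earlier-listed member, transitively.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ovinepred.containers import MISSING, GenotypeMatrix

__all__ = ["QCThresholds", "QCReport", "filter_snps", "filter_duplicate_samples", "hwe_pvalue"]


@dataclass
class QCThresholds:
    """Filter thresholds (defaults are the standard array-QC settings)."""

    min_call_rate: float = 0.90
    min_quality_score: float = 0.6
    het_sd_limit: float = 3.0
    min_maf: float = 0.01
    hwe_p_floor: float = 1e-15
    duplicate_r: float = 0.98
    excluded_chroms: frozenset = frozenset({"X", "Y"})

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_quality_score", "min_maf", "hwe_p_floor", "duplicate_r"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.het_sd_limit <= 0:
            raise ValueError("het_sd_limit must be positive")
        self.excluded_chroms = frozenset(str(c) for c in self.excluded_chroms)


@dataclass
class QCReport:
    """Survivors plus a removal log attributing each item to one rule."""

    kept_snps: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    kept_samples: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    removal_log: list = field(default_factory=list)  # (id, rule, statistic)
    warnings: list = field(default_factory=list)

    def removed_by(self, rule: str) -> list:
        return [item for item, r, _ in self.removal_log if r == rule]

    def n_removed(self) -> int:
        return len(self.removal_log)


def hwe_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Hardy-Weinberg test p-value for one SNP's genotype counts.

    Chi-squared with 1 df against HWE expectations; switches to the exact
    conditional test (Wigginton-style enumeration of heterozygote counts
    given allele counts) whenever any expected count is below 5.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab
    p = n_a / (2 * n)
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) * (1 - p)])
    if p in (0.0, 1.0):
        return 1.0
    if exp.min() < 5:
        return _hwe_exact(n_aa, n_ab, n_bb)
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_exact(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE test: sum probabilities of heterozygote counts no more
    likely than the observed one, conditional on allele counts."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    rare = min(n_a, 2 * n - n_a)
    # heterozygote count shares parity with the rare allele count
    het_values = range(rare % 2, rare + 1, 2)
    logs = []
    for h in het_values:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        lp = (
            math.lgamma(n + 1)
            - math.lgamma(hom_r + 1)
            - math.lgamma(hom_c + 1)
            - math.lgamma(h + 1)
            + h * math.log(2)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )
        logs.append(lp)
    logs = np.array(logs)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs_het = n_ab
    p_obs = probs[list(het_values).index(obs_het)]
    return float(min(1.0, probs[probs <= p_obs + 1e-12].sum()))


def filter_snps(geno: GenotypeMatrix, t: QCThresholds | None = None) -> QCReport:
    """Apply the SNP filters in order and report survivors and removals."""
    if t is None:
        t = QCThresholds()
    if geno.n_snps == 0 or geno.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    n, m = geno.calls.shape
    alive = np.ones(m, dtype=bool)
    log: list = []

    def remove(mask: np.ndarray, rule: str, stat: np.ndarray) -> None:
        for j in np.flatnonzero(mask & alive):
            log.append((geno.snp_ids[j], rule, float(stat[j])))
        alive[mask & alive] = False

    # 1. chromosome exclusion
    on_bad_chrom = np.array([str(c) in t.excluded_chroms for c in geno.chrom])
    remove(on_bad_chrom, "chromosome", np.zeros(m))

    # 2. call rate
    n_called = (geno.calls != MISSING).sum(axis=0)
    call_rate = n_called / n
    remove(call_rate < t.min_call_rate, "call_rate", call_rate)

    # 3. quality score (skipped when no quality channel supplied): a SNP is
    # removed when its mean per-genotype score over called genotypes is low
    if geno.call_quality is not None:
        q = np.where(geno.calls != MISSING, geno.call_quality, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_q = np.nanmean(q, axis=0)
        mean_q = np.where(np.isnan(mean_q), 1.0, mean_q)
        remove(mean_q < t.min_quality_score, "quality_score", mean_q)

    # 4. heterozygosity deviation, iterated to a fixed point for idempotence
    with np.errstate(invalid="ignore"):
        het = np.where(n_called > 0, (geno.calls == 1).sum(axis=0) / np.maximum(n_called, 1), 0.0)
    while True:
        cur = np.flatnonzero(alive)
        if cur.size == 0:
            break
        mu, sd = het[cur].mean(), het[cur].std()
        if sd == 0:
            break
        dev = np.abs(het - mu)
        mask = alive & (dev > t.het_sd_limit * sd)
        if not mask.any():
            break
        remove(mask, "heterozygosity", dev / sd)

    # 5. minor allele frequency
    freqs = geno.allele_frequencies()
    freqs = np.where(np.isnan(freqs), 0.0, freqs)
    maf = np.minimum(freqs, 1.0 - freqs)
    remove(maf < t.min_maf, "maf", maf)

    # 6. Hardy-Weinberg equilibrium
    hwe_p = np.ones(m)
    for j in np.flatnonzero(alive):
        col = geno.calls[:, j]
        n_bb = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_aa = int((col == 2).sum())
        hwe_p[j] = hwe_pvalue(n_aa, n_ab, n_bb)
    remove(hwe_p < t.hwe_p_floor, "hwe", hwe_p)

    if not alive.any():
        raise ValueError("all SNPs removed by QC")
    return QCReport(
        kept_snps=geno.snp_ids[alive],
        kept_samples=geno.ids.copy(),
        removal_log=log,
    )


def filter_duplicate_samples(
    geno: GenotypeMatrix, t: QCThresholds | None = None, min_overlap: int = 100
) -> QCReport:
    """Remove near-duplicate samples (genotype correlation >= threshold).

    For each correlated pair the later-listed sample is removed, so
    transitive duplicate groups keep exactly their first member.  Pairs with
    fewer than ``min_overlap`` jointly non-missing SNPs are skipped with a
    warning recorded in the report.
    """
    if t is None:
        t = QCThresholds()
    n = geno.n_individuals
    if n < 2:
        raise ValueError("need at least 2 samples")
    d = geno.dosage()
    obs = ~np.isnan(d)
    log: list = []
    warn: list = []
    alive = np.ones(n, dtype=bool)

    if obs.all():
        with np.errstate(invalid="ignore"):
            sd = d.std(axis=1)
            c = np.corrcoef(d)
        for i in range(n):
            if not alive[i]:
                continue
            for j in range(i + 1, n):
                if not alive[j]:
                    continue
                r = c[i, j] if sd[i] > 0 and sd[j] > 0 else np.nan
                if np.isfinite(r) and r >= t.duplicate_r:
                    log.append((geno.ids[j], "duplicate", float(r)))
                    alive[j] = False
    else:
        for i in range(n):
            if not alive[i]:
                continue
            for j in range(i + 1, n):
                if not alive[j]:
                    continue
                both = obs[i] & obs[j]
                k = int(both.sum())
                if k < min_overlap:
                    msg = f"pair ({geno.ids[i]}, {geno.ids[j]}): only {k} overlapping SNPs, skipped"
                    warn.append(msg)
                    warnings.warn(msg, stacklevel=2)
                    continue
                xi, xj = d[i, both], d[j, both]
                if xi.std() == 0 or xj.std() == 0:
                    continue
                r = float(np.corrcoef(xi, xj)[0, 1])
                if r >= t.duplicate_r:
                    log.append((geno.ids[j], "duplicate", r))
                    alive[j] = False

    return QCReport(
        kept_snps=geno.snp_ids.copy(),
        kept_samples=geno.ids[alive],
        removal_log=log,
        warnings=warn,
    )


def apply_snp_report(geno: GenotypeMatrix, report: QCReport) -> GenotypeMatrix:
    keep = set(report.kept_snps)
    idx = np.flatnonzero(np.array([s in keep for s in geno.snp_ids]))
    return geno.subset_snps(idx)


def apply_sample_report(geno: GenotypeMatrix, report: QCReport) -> GenotypeMatrix:
    keep = set(report.kept_samples)
    idx = np.flatnonzero(np.array([s in keep for s in geno.ids]))
    return geno.subset_individuals(idx)
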