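"""SNP-array quality control: call-rate, MAF, HWE and placement filters.

Filters are applied in a fixed, audited order — sample call rate first, then
per-SNP call rate, MAF, the Hardy–Weinberg exact test, and finally removal of
unplaced / sex-chromosome SNPs.  Each removed SNP is attributed to the FIRST
filter it fails, so the per-filter counts in :class:`QCReport` are disjoint
and satisfy ``before - sum(removed) = after`` exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .panel import MISSING, NON_AUTOSOME_LABELS, GenotypePanel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow standard array-QC practice.

    ``max_missing_per_snp``/``max_missing_per_sample`` are the complements of
    the SNP/individual call-rate floors (a 95% call-rate requirement is a 5%
    missingness ceiling).  A variant or sample is removed when its missing
    fraction strictly exceeds the threshold.
    """

    max_missing_per_snp: float = 0.05
    max_missing_per_sample: float = 0.05
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6
    drop_unplaced: bool = True
    drop_sex_chroms: bool = True
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        for name in ("max_missing_per_snp", "max_missing_per_sample", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.hwe_alpha <= 1.0:
            raise ValueError(f"hwe_alpha must be in (0, 1], got {self.hwe_alpha}")


@dataclass
class QCReport:
    """Removal accounting for one QC run; counts are disjoint by filter."""

    n_samples_before: int = 0
    n_snps_before: int = 0
    removed_by_sample_callrate: int = 0
    removed_by_snp_callrate: int = 0
    removed_by_maf: int = 0
    removed_by_hwe: int = 0
    removed_unplaced_or_sex: int = 0
    removed_monomorphic: int = 0
    n_samples_after: int = 0
    n_snps_after: int = 0
    filter_order: list[str] = field(default_factory=list)

    def snp_removals(self) -> int:
        return (self.removed_by_snp_callrate + self.removed_by_maf
                + self.removed_by_hwe + self.removed_unplaced_or_sex
                + self.removed_monomorphic)

    def validate(self) -> None:
        if self.n_snps_before - self.snp_removals() != self.n_snps_after:
            raise AssertionError("QC accounting identity violated")
        if self.n_samples_before - self.removed_by_sample_callrate != self.n_samples_after:
            raise AssertionError("QC sample accounting identity violated")

    def to_tsv(self, path) -> None:
        """Write a two-row TSV with removal-accounting column names."""
        cols = [
            ("Number of animal before QC", self.n_samples_before),
            ("Number of animal after QC", self.n_samples_after),
            ("SNP number before QC", self.n_snps_before),
            ("MAF < 5%", self.removed_by_maf),
            ("SNP call rate <0.05", self.removed_by_snp_callrate),
            ("MIND < 0.05", self.removed_by_sample_callrate),
            ("HWE < 10^-6", self.removed_by_hwe),
            ("Monomorphic", self.removed_monomorphic),
            ("Unplaced or sex chromosome", self.removed_unplaced_or_sex),
            ("SNP number after QC", self.n_snps_after),
            ("Filter order", ";".join(self.filter_order)),
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(name for name, _ in cols) + "\n")
            fh.write("\t".join(str(val) for _, val in cols) + "\n")


# ---------------------------------------------------------------------------
# per-variant statistics
# ---------------------------------------------------------------------------

def minor_allele_frequency(dosages: np.ndarray) -> float:
    """MAF of one variant from allele2 dosages over {0, 1, 2, MISSING}.

    ``maf = min(p, 1 - p)`` with ``p = (2 n2 + n1) / (2 n_called)``.

    Raises
    ------
    ValueError
        If every call is missing (frequency undefined; such variants are the
        call-rate filter's responsibility, not MAF's).
    """
    dosages = np.asarray(dosages)
    called = dosages[dosages != MISSING]
    if called.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    p = float(called.sum()) / (2.0 * called.size)
    return min(p, 1.0 - p)


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value from genotype counts.

    Conditional on the observed allele counts, heterozygote counts are
    distributed over {h : h <= min(nA, nB), h = nA mod 2}; the p-value sums
    the probabilities of every configuration no more probable than the
    observed one.  Monomorphic input returns 1.0 by convention.

    Probabilities are computed in log space (gammaln) and renormalised, which
    is exact to ~1e-15 for the count ranges seen in array data.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("need at least one called genotype")
    n_a = 2 * n_hom1 + n_het
    n_b = 2 * n_hom2 + n_het
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: cannot deviate

    n_rare = min(n_a, n_b)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(h) ∝ h·log2 - log(homr! · h! · homc!)  (shared terms cancel)
    logp = hets * np.log(2.0) - (
        gammaln(hom_rare + 1) + gammaln(hets + 1) + gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    # sum all configurations with probability <= observed (tiny fp slack)
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def _genotype_counts(genotypes: np.ndarray) -> np.ndarray:
    """Per-variant (n0, n1, n2) counts, ignoring MISSING; shape (m, 3)."""
    return np.stack([(genotypes == d).sum(axis=0) for d in (0, 1, 2)], axis=1)


# ---------------------------------------------------------------------------
# the filter pipeline
# ---------------------------------------------------------------------------

def apply_qc(panel: GenotypePanel,
             thresholds: QCThresholds | None = None) -> tuple[GenotypePanel, QCReport]:
    """Filter a panel and return ``(filtered_panel, report)``.

    Sample missingness is computed on the full SNP set (before any SNP
    removal); SNP statistics are computed on the surviving samples.
    Idempotent: re-running on its own output removes nothing.
    """
    thr = thresholds or QCThresholds()
    report = QCReport(
        n_samples_before=panel.n_samples,
        n_snps_before=panel.n_variants,
        filter_order=["sample_callrate", "snp_callrate", "maf", "hwe",
                      "unplaced_or_sex"],
    )

    # 1. sample call rate, on the pristine SNP set
    miss = panel.missing_mask()
    if panel.n_variants > 0:
        sample_missing = miss.mean(axis=1)
    else:
        sample_missing = np.zeros(panel.n_samples)
    keep_samples = sample_missing <= thr.max_missing_per_sample
    report.removed_by_sample_callrate = int((~keep_samples).sum())
    working = panel.subset_samples(np.flatnonzero(keep_samples))
    report.n_samples_after = working.n_samples

    m = working.n_variants
    removed_reason = np.zeros(m, dtype=np.int8)  # 0 = keep
    REASON_CALLRATE, REASON_MAF, REASON_HWE, REASON_PLACE, REASON_MONO = 1, 2, 3, 4, 5

    if working.n_samples == 0:
        removed_reason[:] = REASON_CALLRATE  # nothing callable
    elif m > 0:
        G = working.genotypes
        miss_frac = (G == MISSING).mean(axis=0)

        # 2. SNP call rate (also catches all-missing variants)
        fail_cr = miss_frac > thr.max_missing_per_snp
        removed_reason[fail_cr] = REASON_CALLRATE

        counts = _genotype_counts(G)
        n_called = counts.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p2 = (2 * counts[:, 2] + counts[:, 1]) / (2 * n_called)
        maf = np.minimum(p2, 1.0 - p2)
        all_missing = n_called == 0
        removed_reason[all_missing & (removed_reason == 0)] = REASON_CALLRATE

        # 3. MAF (maf == 0 means monomorphic: folded in here when enabled)
        candidate = removed_reason == 0
        if thr.min_maf > 0:
            fail_maf = candidate & ~all_missing & (maf < thr.min_maf)
            removed_reason[fail_maf] = REASON_MAF
        elif thr.drop_monomorphic:
            fail_mono = candidate & ~all_missing & (maf == 0.0)
            removed_reason[fail_mono] = REASON_MONO

        # 4. HWE exact test
        for j in np.flatnonzero(removed_reason == 0):
            p = hwe_exact_p(int(counts[j, 0]), int(counts[j, 1]), int(counts[j, 2]))
            if p < thr.hwe_alpha:
                removed_reason[j] = REASON_HWE

        # 5. unplaced / sex-chromosome SNPs
        for j in np.flatnonzero(removed_reason == 0):
            v = working.variants[j]
            unplaced = thr.drop_unplaced and v.bp == 0
            non_auto = thr.drop_sex_chroms and (
                v.chrom in NON_AUTOSOME_LABELS or v.chrom not in working.autosomes
            )
            if unplaced or non_auto:
                removed_reason[j] = REASON_PLACE

    report.removed_by_snp_callrate = int((removed_reason == REASON_CALLRATE).sum())
    report.removed_by_maf = int((removed_reason == REASON_MAF).sum())
    report.removed_by_hwe = int((removed_reason == REASON_HWE).sum())
    report.removed_unplaced_or_sex = int((removed_reason == REASON_PLACE).sum())
    report.removed_monomorphic = int((removed_reason == REASON_MONO).sum())

    filtered = working.subset_variants(np.flatnonzero(removed_reason == 0))
    report.n_snps_after = filtered.n_variants
    report.validate()
    if filtered.n_variants == 0 or filtered.n_samples == 0:
        warnings.warn("QC removed every SNP and/or sample; result is empty",
                      stacklevel=2)
    log.info("QC: %d/%d SNPs and %d/%d samples retained",
             report.n_snps_after, report.n_snps_before,
             report.n_samples_after, report.n_samples_before)
    return filtered, report


__all__ = ["QCThresholds", "QCReport", "minor_allele_frequency",
           "hwe_exact_p", "apply_qc"]
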