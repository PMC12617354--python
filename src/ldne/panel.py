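"""In-memory genotype panel: samples, variants, and a dosage matrix.

Genotypes are stored as an ``n_samples x n_variants`` ``int8`` matrix of
allele2 dosages (0, 1, 2) with :data:`MISSING` (-1) for no-calls.  Allele2 is
the dosage-counted allele throughout the package — the same convention as the
binary PLINK dialect — so the minor allele frequency reported by QC refers to
``min(p2, 1 - p2)`` where ``p2`` is the allele2 frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: Default autosome label set (cattle, BTA1-29).
CATTLE_AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 30))

#: Chromosome labels treated as sex/mitochondrial by default.
NON_AUTOSOME_LABELS: frozenset[str] = frozenset({"X", "Y", "MT", "XY", "30", "31", "33"})


class PanelFormatError(ValueError):
    """Raised when an on-disk genotype file violates its dialect contract."""


class PanelValidationError(ValueError):
    """Raised when panel metadata and genotype matrix are inconsistent."""


@dataclass(frozen=True)
class VariantRecord:
    """One SNP: chromosome label, identifier, map positions, and alleles.

    ``bp == 0`` encodes an unknown physical position; such variants are kept
    at read time and removed (if configured) by quality control.
    """

    chrom: str
    vid: str
    cm: float
    bp: int
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.bp < 0:
            raise PanelValidationError(f"variant {self.vid}: bp must be >= 0, got {self.bp}")


@dataclass(frozen=True)
class SampleRecord:
    """One genotyped individual identified by (family id, individual id)."""

    fid: str
    iid: str
    sex: str = "unknown"  # {male, female, unknown}

    @property
    def key(self) -> tuple[str, str]:
        return (self.fid, self.iid)


@dataclass
class GenotypePanel:
    """A validated diploid unphased SNP panel.

    Parameters
    ----------
    samples
        Ordered sample metadata; ``(fid, iid)`` must be unique.
    variants
        Ordered variant metadata; ``vid`` must be unique.
    genotypes
        ``len(samples) x len(variants)`` int8 matrix over {0, 1, 2, MISSING},
        counting copies of each variant's ``allele2``.
    """

    samples: list[SampleRecord]
    variants: list[VariantRecord]
    genotypes: np.ndarray
    autosomes: frozenset[str] = field(default=CATTLE_AUTOSOMES)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise PanelValidationError("genotype matrix must be 2-D")
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.variants):
            raise PanelValidationError(
                f"matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelValidationError(
                f"invalid dosage {self.genotypes[i, j]} at sample {i}, variant {j}"
            )
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            dup = _first_duplicate(keys)
            raise PanelValidationError(f"duplicate sample id {dup!r}")
        vids = [v.vid for v in self.variants]
        if len(set(vids)) != len(vids):
            dup = _first_duplicate(vids)
            raise PanelValidationError(f"duplicate variant id {dup!r}")

    # -- shape ------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    # -- derived vectors ---------------------------------------------------
    def variant_bp(self) -> np.ndarray:
        return np.array([v.bp for v in self.variants], dtype=np.int64)

    def variant_chrom(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing calls, same shape as ``genotypes``."""
        return self.genotypes == MISSING

    # -- subsetting --------------------------------------------------------
    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "GenotypePanel":
        index = np.asarray(index, dtype=np.intp)
        return GenotypePanel(
            samples=list(self.samples),
            variants=[self.variants[i] for i in index],
            genotypes=self.genotypes[:, index].copy(),
            autosomes=self.autosomes,
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypePanel":
        index = np.asarray(index, dtype=np.intp)
        return GenotypePanel(
            samples=[self.samples[i] for i in index],
            variants=list(self.variants),
            genotypes=self.genotypes[index, :].copy(),
            autosomes=self.autosomes,
        )

    def equals(self, other: "GenotypePanel") -> bool:
        """Cell-for-cell equality of genotypes plus ordered metadata."""
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.genotypes, other.genotypes)
        )


def _first_duplicate(items: Iterable) -> object:
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


__all__ = [
    "MISSING",
    "CATTLE_AUTOSOMES",
    "NON_AUTOSOME_LABELS",
    "VariantRecord",
    "SampleRecord",
    "GenotypePanel",
    "PanelFormatError",
    "PanelValidationError",
    "replace",
]
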