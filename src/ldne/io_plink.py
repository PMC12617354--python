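"""Readers and writers for the PLINK text (.ped/.map) and binary
(.bed/.bim/.fam) genotype dialects.

The binary dialect is the SNP-major layout: 3 header bytes ``6C 1B 01``
followed by ``ceil(n_samples / 4)`` bytes per variant, two bits per sample,
low-order bits first.  The 2-bit codes map to allele2 dosage as::

    0b00 -> 0 (homozygous allele1)     0b10 -> 1 (heterozygous)
    0b01 -> MISSING                    0b11 -> 2 (homozygous allele2)

In the text dialect a ``0`` allele marks a no-call; a half-missing pair such
as ``A 0`` is conservatively treated as fully missing.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .panel import (
    MISSING,
    GenotypePanel,
    PanelFormatError,
    PanelValidationError,
    SampleRecord,
    VariantRecord,
)

_BED_MAGIC = bytes((0x6C, 0x1B))
_BED_SNP_MAJOR = 0x01

# 2-bit code -> dosage, indexed by code value.
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
# dosage (0,1,2) -> 2-bit code; MISSING handled separately.
_DOSAGE_TO_CODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}

_SEX_FROM_PED = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}


# ---------------------------------------------------------------------------
# text dialect
# ---------------------------------------------------------------------------

def read_map(map_path: str | Path) -> list[VariantRecord]:
    """Parse a 4-column .map file (chrom, vid, cM, bp)."""
    variants: list[VariantRecord] = []
    for lineno, line in enumerate(_read_lines(map_path), start=1):
        fields = line.split()
        if len(fields) != 4:
            raise PanelFormatError(
                f"{map_path}:{lineno}: expected 4 columns in .map, got {len(fields)}"
            )
        chrom, vid, cm, bp = fields
        try:
            variants.append(
                VariantRecord(chrom=chrom, vid=vid, cm=float(cm), bp=int(bp),
                              allele1="0", allele2="0")
            )
        except ValueError as exc:
            raise PanelFormatError(f"{map_path}:{lineno}: {exc}") from exc
    return variants


def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypePanel:
    """Read a PLINK text fileset into a :class:`GenotypePanel`.

    The text dialect does not state which allele is dosage-counted, so the
    reader orients deterministically: the observed alleles of each variant
    are sorted and the lexicographically larger becomes allele2 (the counted
    one).  A round trip through the text dialect is therefore exact for
    panels in this canonical orientation (allele1 < allele2), which covers
    every panel this package itself produces; a panel read from a .bim with
    reversed allele order is canonicalised, not corrupted.
    """
    variants = read_map(map_path)
    m = len(variants)
    samples: list[SampleRecord] = []
    allele_pairs: list[list[str]] = []  # per sample, flat list of 2m alleles

    for lineno, line in enumerate(_read_lines(ped_path), start=1):
        fields = line.split()
        if len(fields) != 6 + 2 * m:
            raise PanelFormatError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} columns "
                f"(6 + 2 x {m} variants from {map_path}), got {len(fields)}"
            )
        fid, iid, _pat, _mat, sex, _pheno = fields[:6]
        samples.append(SampleRecord(fid=fid, iid=iid, sex=_SEX_FROM_PED.get(sex, "unknown")))
        allele_pairs.append(fields[6:])

    keys = [(s.fid, s.iid) for s in samples]
    if len(set(keys)) != len(keys):
        raise PanelValidationError(f"{ped_path}: duplicate (fid, iid) pair")

    n = len(samples)
    genotypes = np.full((n, m), MISSING, dtype=np.int8)
    resolved: list[VariantRecord] = []
    for j, var in enumerate(variants):
        a1, a2 = var.allele1, var.allele2  # "0", "0" from .map
        col = [(allele_pairs[i][2 * j], allele_pairs[i][2 * j + 1]) for i in range(n)]
        alleles_seen = sorted({a for pair in col for a in pair if a != "0"})
        if len(alleles_seen) > 2:
            raise PanelFormatError(
                f"{ped_path}: variant {var.vid} has >2 alleles: {alleles_seen}"
            )
        a1 = alleles_seen[0] if alleles_seen else "0"
        a2 = alleles_seen[1] if len(alleles_seen) > 1 else "0"
        for i, (x, y) in enumerate(col):
            if x == "0" or y == "0":
                genotypes[i, j] = MISSING
            else:
                genotypes[i, j] = (x == a2) + (y == a2)
        resolved.append(
            VariantRecord(chrom=var.chrom, vid=var.vid, cm=var.cm, bp=var.bp,
                          allele1=a1, allele2=a2)
        )
    return GenotypePanel(samples=samples, variants=resolved, genotypes=genotypes)


def write_plink_text(panel: GenotypePanel, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; missing calls become ``0 0``."""
    prefix = Path(prefix)
    ped_path, map_path = prefix.with_suffix(".ped"), prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for v in panel.variants:
            cm = f"{v.cm:g}"
            fh.write(f"{v.chrom}\t{v.vid}\t{cm}\t{v.bp}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(panel.samples):
            fields = [s.fid, s.iid, "0", "0", _SEX_TO_PED[s.sex], "-9"]
            row = panel.genotypes[i]
            for j, v in enumerate(panel.variants):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [v.allele1, v.allele1]
                elif d == 1:
                    fields += [v.allele1, v.allele2]
                else:
                    fields += [v.allele2, v.allele2]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# binary dialect
# ---------------------------------------------------------------------------

def read_plink_binary(bed_path: str | Path, bim_path: str | Path,
                      fam_path: str | Path) -> GenotypePanel:
    """Read a SNP-major PLINK binary fileset into a :class:`GenotypePanel`."""
    samples: list[SampleRecord] = []
    for lineno, line in enumerate(_read_lines(fam_path), start=1):
        fields = line.split()
        if len(fields) != 6:
            raise PanelFormatError(
                f"{fam_path}:{lineno}: expected 6 columns in .fam, got {len(fields)}"
            )
        samples.append(SampleRecord(fid=fields[0], iid=fields[1],
                                    sex=_SEX_FROM_PED.get(fields[4], "unknown")))

    variants: list[VariantRecord] = []
    for lineno, line in enumerate(_read_lines(bim_path), start=1):
        fields = line.split()
        if len(fields) != 6:
            raise PanelFormatError(
                f"{bim_path}:{lineno}: expected 6 columns in .bim, got {len(fields)}"
            )
        chrom, vid, cm, bp, a1, a2 = fields
        variants.append(VariantRecord(chrom=chrom, vid=vid, cm=float(cm),
                                      bp=int(bp), allele1=a1, allele2=a2))

    n, m = len(samples), len(variants)
    payload = Path(bed_path).read_bytes()
    if len(payload) < 3 or payload[:2] != _BED_MAGIC:
        raise PanelFormatError(f"{bed_path}: bad magic bytes (not a PLINK .bed file)")
    if payload[2] != _BED_SNP_MAJOR:
        raise PanelFormatError(
            f"{bed_path}: mode byte {payload[2]:#04x} is not SNP-major (0x01)"
        )
    bytes_per_variant = math.ceil(n / 4) if n else 0
    expected = 3 + bytes_per_variant * m
    if len(payload) != expected:
        raise PanelFormatError(
            f"{bed_path}: payload is {len(payload)} bytes, expected {expected} "
            f"(3 + ceil({n}/4) x {m}); file truncated or metadata mismatch"
        )

    if m == 0 or n == 0:
        genotypes = np.zeros((n, m), dtype=np.int8)
    else:
        raw = np.frombuffer(payload, dtype=np.uint8, offset=3)
        raw = raw.reshape(m, bytes_per_variant)
        # unpack 2-bit codes, low bits first
        codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
        for k in range(4):
            codes[:, k::4] = (raw >> (2 * k)) & 0b11
        genotypes = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    return GenotypePanel(samples=samples, variants=variants, genotypes=genotypes)


def write_plink_binary(panel: GenotypePanel, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.bed/.bim/.fam`` in SNP-major order."""
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    with open(fam_path, "w") as fh:
        for s in panel.samples:
            fh.write(f"{s.fid} {s.iid} 0 0 {_SEX_TO_PED[s.sex]} -9\n")
    with open(bim_path, "w") as fh:
        for v in panel.variants:
            fh.write(f"{v.chrom}\t{v.vid}\t{v.cm:g}\t{v.bp}\t{v.allele1}\t{v.allele2}\n")

    n, m = panel.n_samples, panel.n_variants
    bytes_per_variant = math.ceil(n / 4) if n else 0
    codes = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)  # pad code 0b00
    if n and m:
        G = panel.genotypes.T  # SNP-major
        codes[:, :n] = np.select(
            [G == 0, G == 1, G == 2, G == MISSING],
            [0b00, 0b10, 0b11, 0b01],
        ).astype(np.uint8)
    packed = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())
    return bed_path, bim_path, fam_path


def write_genotype_panel(panel: GenotypePanel, prefix: str | Path,
                         dialect: str = "binary"):
    """Write a panel as PLINK text or binary files; returns the paths written."""
    if dialect == "text":
        return write_plink_text(panel, prefix)
    if dialect == "binary":
        return write_plink_binary(panel, prefix)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'text' or 'binary'")


def read_genotype_panel(prefix: str | Path, dialect: str = "binary") -> GenotypePanel:
    """Read a panel previously written by :func:`write_genotype_panel`."""
    prefix = Path(prefix)
    if dialect == "text":
        return read_plink_text(prefix.with_suffix(".ped"), prefix.with_suffix(".map"))
    if dialect == "binary":
        return read_plink_binary(prefix.with_suffix(".bed"), prefix.with_suffix(".bim"),
                                 prefix.with_suffix(".fam"))
    raise ValueError(f"unknown dialect {dialect!r}; expected 'text' or 'binary'")


def _read_lines(path: str | Path):
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip():
                yield line


__all__ = [
    "read_plink_text",
    "read_plink_binary",
    "read_map",
    "write_plink_text",
    "write_plink_binary",
    "write_genotype_panel",
    "read_genotype_panel",
]
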