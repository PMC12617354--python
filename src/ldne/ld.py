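"""Pairwise r² and binned LD-decay profiles.

LD between two SNPs is measured as the squared Pearson correlation of their
0/1/2 genotype dosages over pairwise-complete samples (the phase-free
"composite" estimator — the standard choice for unphased array data).
Intra-chromosomal pairs with physical distance in ``[mindist, maxdist)`` are
aggregated into equal-width distance bins; each bin reports the mean pair
distance, mean r² and contributing pair count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDParams:
    """Pairing and binning parameters for the LD-decay profile.

    Defaults mirror common SNP-array practice for livestock demography scans:
    pairs from 10 kb to 40 Mb, 40 distance bins, at most 100k SNPs per
    chromosome (uniformly thinned with ``seed`` beyond that), and bins
    supported by fewer than ``min_pairs_per_bin`` pairs flagged
    low-confidence.  When ``num_bins`` is set it takes precedence and bins
    are ``num_bins`` equal-width intervals over ``[mindist, maxdist)``;
    ``binwidth_bp`` is honoured only when ``num_bins`` is None.
    """

    mindist_bp: int = 10_000
    maxdist_bp: int = 40_000_000
    binwidth_bp: int = 50_000
    num_bins: int | None = 40
    max_snps_per_chrom: int = 100_000
    min_pairs_per_bin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mindist_bp < self.maxdist_bp:
            raise ValueError("require 0 <= mindist < maxdist")
        if self.num_bins is not None and self.num_bins < 1:
            raise ValueError("num_bins must be >= 1")
        if self.binwidth_bp <= 0:
            raise ValueError("binwidth_bp must be > 0")

    def bin_edges(self) -> np.ndarray:
        """Distance-bin edges (left-closed, right-open intervals)."""
        if self.num_bins is not None:
            return np.linspace(self.mindist_bp, self.maxdist_bp,
                               self.num_bins + 1)
        edges = np.arange(self.mindist_bp, self.maxdist_bp, self.binwidth_bp,
                          dtype=float)
        return np.append(edges, self.maxdist_bp)


@dataclass
class LDBin:
    """One distance bin of the LD-decay profile."""

    lo_bp: float
    hi_bp: float
    mean_dist_bp: float  # NaN when n_pairs == 0
    mean_r2: float       # NaN when n_pairs == 0
    n_pairs: int
    low_confidence: bool = False


class EmptyProfileError(ValueError):
    """No eligible SNP pair anywhere in the panel."""


# ---------------------------------------------------------------------------
# pairwise r2
# ---------------------------------------------------------------------------

def pairwise_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Uses pairwise-complete samples (both calls non-missing).  Requires at
    least 3 complete pairs and both loci polymorphic on the complete subset;
    otherwise the statistic is undefined and a ``ValueError`` is raised
    (profile building skips and counts such pairs instead).
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("fewer than 3 pairwise-complete genotypes")
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        raise ValueError("locus monomorphic on the pairwise-complete subset")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    r2 = (cov * cov) / (va * vb)
    return float(min(r2, 1.0))  # clip fp overshoot at exactly-collinear input


def _masked_r2_block(Z: np.ndarray, M: np.ndarray, rows: np.ndarray,
                     cols: np.ndarray) -> np.ndarray:
    """r² between variant sets ``rows`` x ``cols`` under missing mask.

    ``Z`` is the dosage matrix with missing entries zeroed (n x m), ``M`` the
    0/1 presence mask.  Returns a (len(rows), len(cols)) matrix with NaN for
    undefined pairs (<3 complete samples or monomorphic subset).
    """
    Zr, Mr = Z[:, rows], M[:, rows]
    Zc, Mc = Z[:, cols], M[:, cols]
    n = Mr.T @ Mc
    sx = Zr.T @ Mc
    sy = Mr.T @ Zc
    sxy = Zr.T @ Zc
    sxx = (Zr * Zr).T @ Mc
    syy = Mr.T @ (Zc * Zc)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sxy - sx * sy
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        r2 = (cov * cov) / (vx * vy)
    r2[(n < 3) | (vx <= 0) | (vy <= 0)] = np.nan
    return np.minimum(r2, 1.0, out=r2, where=~np.isnan(r2))


# ---------------------------------------------------------------------------
# profile construction
# ---------------------------------------------------------------------------

def build_ld_profile(panel: GenotypePanel, params: LDParams | None = None,
                     _block: int = 512) -> list[LDBin]:
    """Bin all eligible intra-chromosomal SNP pairs into an LD-decay profile.

    Every same-chromosome pair with ``mindist <= |bp_i - bp_j| < maxdist``
    and a defined r² contributes to exactly one bin.  Chromosomes with more
    than ``max_snps_per_chrom`` SNPs are uniformly thinned first (seeded).
    Bins are returned in increasing distance order, including empty ones
    (``n_pairs = 0``, NaN means), so the bin grid is stable across panels.
    """
    params = params or LDParams()
    edges = params.bin_edges()
    nbins = len(edges) - 1
    sum_d = np.zeros(nbins)
    sum_r2 = np.zeros(nbins)
    n_pairs = np.zeros(nbins, dtype=np.int64)
    n_undefined = 0

    chroms = panel.variant_chrom()
    bp = panel.variant_bp()
    rng = np.random.default_rng(params.seed)

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if idx.size > params.max_snps_per_chrom:
            keep = rng.choice(idx.size, size=params.max_snps_per_chrom,
                              replace=False)
            idx = idx[np.sort(keep)]
        if idx.size < 2:
            continue
        order = np.argsort(bp[idx], kind="stable")
        idx = idx[order]
        pos = bp[idx].astype(float)

        Z = panel.genotypes[:, idx].astype(float)
        M = (panel.genotypes[:, idx] != MISSING).astype(float)
        Z = Z * M  # zero out missing entries

        m = idx.size
        local = np.arange(m)
        for start in range(0, m, _block):
            rows = local[start:start + _block]
            # only partners to the right, within maxdist of the block's span
            lo = start + 1
            hi = int(np.searchsorted(pos, pos[rows].max() + params.maxdist_bp,
                                     side="left"))
            cols = local[lo:hi]
            if cols.size == 0:
                continue
            dist = np.abs(pos[cols][None, :] - pos[rows][:, None])
            upper = cols[None, :] > rows[:, None]  # each unordered pair once
            eligible = upper & (dist >= params.mindist_bp) & (dist < params.maxdist_bp)
            if not eligible.any():
                continue
            r2 = _masked_r2_block(Z, M, rows, cols)
            defined = eligible & ~np.isnan(r2)
            n_undefined += int((eligible & np.isnan(r2)).sum())
            if not defined.any():
                continue
            d = dist[defined]
            v = r2[defined]
            which = np.clip(np.searchsorted(edges, d, side="right") - 1,
                            0, nbins - 1)
            np.add.at(sum_d, which, d)
            np.add.at(sum_r2, which, v)
            np.add.at(n_pairs, which, 1)

    if n_pairs.sum() == 0:
        raise EmptyProfileError(
            "no eligible SNP pair in any chromosome within the distance window"
        )
    if n_undefined:
        log.info("LD profile: skipped %d pairs with undefined r2", n_undefined)

    bins: list[LDBin] = []
    for k in range(nbins):
        if n_pairs[k] > 0:
            bins.append(LDBin(
                lo_bp=float(edges[k]), hi_bp=float(edges[k + 1]),
                mean_dist_bp=float(sum_d[k] / n_pairs[k]),
                mean_r2=float(sum_r2[k] / n_pairs[k]),
                n_pairs=int(n_pairs[k]),
                low_confidence=bool(n_pairs[k] < params.min_pairs_per_bin),
            ))
        else:
            bins.append(LDBin(
                lo_bp=float(edges[k]), hi_bp=float(edges[k + 1]),
                mean_dist_bp=float("nan"), mean_r2=float("nan"),
                n_pairs=0, low_confidence=True,
            ))
    return bins


def downsample_panel(panel: GenotypePanel,
                     target_variant_ids: list[str] | None = None,
                     target_count: int | None = None,
                     seed: int = 0) -> GenotypePanel:
    """Thin a panel to a variant subset, preserving genomic order.

    Either an explicit id list or a target count (uniform random, seeded).
    Emulates the density check of re-profiling a high-density panel after
    thinning it to a lower-density array's size.
    """
    if (target_variant_ids is None) == (target_count is None):
        raise ValueError("give exactly one of target_variant_ids / target_count")
    if target_variant_ids is not None:
        vid_to_idx = {v.vid: j for j, v in enumerate(panel.variants)}
        missing = [v for v in target_variant_ids if v not in vid_to_idx]
        if missing:
            raise KeyError(f"variant ids not in panel: {missing[:5]}...")
        index = sorted(vid_to_idx[v] for v in target_variant_ids)
    else:
        if target_count > panel.n_variants:
            raise ValueError(
                f"requested {target_count} variants but panel has {panel.n_variants}"
            )
        rng = np.random.default_rng(seed)
        index = np.sort(rng.choice(panel.n_variants, size=target_count,
                                   replace=False))
    return panel.subset_variants(np.asarray(index))


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

_PROFILE_COLS = ["lo_bp", "hi_bp", "mean_dist_bp", "mean_r2", "n_pairs"]


def profile_to_frame(bins: list[LDBin]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(b, c) for c in _PROFILE_COLS} for b in bins])


def write_ld_profile(bins: list[LDBin], path: str | Path) -> None:
    profile_to_frame(bins).to_csv(path, sep="\t", index=False)


def read_ld_profile(path: str | Path) -> list[LDBin]:
    df = pd.read_csv(path, sep="\t")
    return [
        LDBin(lo_bp=row.lo_bp, hi_bp=row.hi_bp, mean_dist_bp=row.mean_dist_bp,
              mean_r2=row.mean_r2, n_pairs=int(row.n_pairs))
        for row in df.itertuples()
    ]


__all__ = ["LDParams", "LDBin", "EmptyProfileError", "pairwise_r2",
           "build_ld_profile", "downsample_panel", "profile_to_frame",
           "write_ld_profile", "read_ld_profile", "replace"]
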