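"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: the HWE oracle uses
exact rational arithmetic over the full conditional distribution, the r²
oracle uses numpy's corrcoef, and the LD-profile oracle enumerates every
SNP pair one at a time.
"""

from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np

MISSING = -1


@lru_cache(maxsize=None)
def _hwe_distribution(n: int, n_a: int) -> dict[int, Fraction]:
    """Exact conditional distribution of heterozygote counts.

    Given ``n`` diploids carrying ``n_a`` copies of allele A (and 2n - n_a
    of B), P(h) = [n! / (nAA! h! nBB!)] 2^h / C(2n, n_a) over the parity-
    compatible support.
    """
    n_b = 2 * n - n_a
    denom = comb(2 * n, n_a)
    dist: dict[int, Fraction] = {}
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        n_aa = (n_a - h) // 2
        n_bb = (n_b - h) // 2
        ways = Fraction(_fact(n), _fact(n_aa) * _fact(h) * _fact(n_bb)) * 2**h
        dist[h] = ways / denom
    assert sum(dist.values()) == 1
    return dist


@lru_cache(maxsize=None)
def _fact(k: int) -> int:
    out = 1
    for i in range(2, k + 1):
        out *= i
    return out


def hwe_exact_p_oracle(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact HWE p-value by exhaustive rational enumeration."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    dist = _hwe_distribution(n, n_a)
    p_obs = dist[n_het]
    return float(sum(p for p in dist.values() if p <= p_obs))


def r2_oracle(a, b) -> float:
    """Squared Pearson correlation over pairwise-complete entries."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = (a != MISSING) & (b != MISSING)
    r = np.corrcoef(a[ok], b[ok])[0, 1]
    return float(r * r)


def ld_profile_oracle(panel, params):
    """All-pairs enumeration of (bin index, distance, r²) tuples.

    Returns per-bin (sum_dist, sum_r2, n_pairs) arrays on the same bin grid
    as the implementation's params, computed one pair at a time.
    """
    edges = params.bin_edges()
    nbins = len(edges) - 1
    sum_d = np.zeros(nbins)
    sum_r2 = np.zeros(nbins)
    n_pairs = np.zeros(nbins, dtype=int)
    chroms = [v.chrom for v in panel.variants]
    bps = [v.bp for v in panel.variants]
    m = panel.n_variants
    for i in range(m):
        for j in range(i + 1, m):
            if chroms[i] != chroms[j]:
                continue
            d = abs(bps[i] - bps[j])
            if not (params.mindist_bp <= d < params.maxdist_bp):
                continue
            a = panel.genotypes[:, i]
            b = panel.genotypes[:, j]
            ok = (a != MISSING) & (b != MISSING)
            if ok.sum() < 3:
                continue
            aa, bb = a[ok].astype(float), b[ok].astype(float)
            if aa.var() == 0 or bb.var() == 0:
                continue
            r2 = r2_oracle(a, b)
            k = min(int(np.searchsorted(edges, d, side="right")) - 1, nbins - 1)
            sum_d[k] += d
            sum_r2[k] += r2
            n_pairs[k] += 1
    return sum_d, sum_r2, n_pairs


def weighted_median(values, weights) -> float:
    """Smallest value at which cumulative weight reaches half the total."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values)
    cum = np.cumsum(weights[order]) / weights.sum()
    return float(values[order][np.searchsorted(cum, 0.5)])
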