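"""Forward Wright–Fisher simulation of diploid SNP panels with recombination.

The simulator provides genotype panels with *known* demographic ground truth
so the QC → LD → Ne pipeline can be validated end to end: a randomly mating
diploid population of piecewise-constant size N evolves for a burn-in plus
the scheduled epochs, gametes recombine between adjacent sites with
probability equal to the interval's map length in Morgans (at most one
crossover per interval per meiosis; chromosomes assort freely), and at the
end ``sample_size_n`` individuals are drawn without replacement and emitted
as an unphased dosage panel on a uniform physical grid.

There is no mutation or selection: allele frequencies start segregating
(drawn uniformly from ``[maf_floor_init, 1 - maf_floor_init]``) and then
drift, which is exactly the regime where Sved's E[r²] ≈ 1/(1 + 4 Ne c)
relation applies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from .panel import MISSING, GenotypePanel, SampleRecord, VariantRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DemographyModel:
    """Piecewise-constant diploid population-size history.

    ``epochs`` is an ordered list of ``(duration_generations, diploid_N)``
    pairs, most ancient first; the simulator runs them in order after the
    burn-in, so the last epoch is the present.
    """

    epochs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("demography needs at least one epoch")
        for dur, n in self.epochs:
            if dur < 1:
                raise ValueError(f"epoch duration must be >= 1, got {dur}")
            if n < 2:
                raise ValueError(f"diploid N must be >= 2, got {n}")

    @classmethod
    def constant(cls, n: int, duration: int = 1) -> "DemographyModel":
        return cls(epochs=((duration, n),))

    @property
    def ancient_n(self) -> int:
        return self.epochs[0][1]

    @property
    def final_n(self) -> int:
        return self.epochs[-1][1]


@dataclass(frozen=True)
class SimConfig:
    """Panel-shape and sampling parameters for one simulation run.

    Defaults produce a small two-chromosome panel shaped like a thinned
    livestock array: 50 Mb chromosomes, uniformly spaced sites, 1 cM/Mb.
    ``burn_in_generations=None`` means 4 x the most ancient epoch's N.
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000_000
    n_sites_per_chrom: int = 500
    cm_per_mb: float = 1.0
    sample_size_n: int = 50
    missing_rate: float = 0.0
    maf_floor_init: float = 0.05
    burn_in_generations: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.maf_floor_init < 0.5:
            raise ValueError("maf_floor_init must be in [0, 0.5)")
        if min(self.n_chromosomes, self.n_sites_per_chrom,
               self.chrom_length_bp, self.sample_size_n) < 1:
            raise ValueError("panel shape parameters must be positive")


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated panel (for validation only)."""

    demography: DemographyModel
    config: SimConfig
    generations_run: int
    n_fixed_sites: int

    def write(self, path: str | Path) -> None:
        payload = {
            "demography_epochs": [list(e) for e in self.demography.epochs],
            "config": asdict(self.config),
            "generations_run": self.generations_run,
            "n_fixed_sites": self.n_fixed_sites,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _recombine(haps: np.ndarray, parents: np.ndarray, xover_p: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Form one gamete per parent by recombining that parent's two haplotypes.

    ``haps``: (N, 2, S) haplotype array for one chromosome.
    ``parents``: (G,) parent individual indices, one gamete each.
    ``xover_p``: (S-1,) per-interval crossover probabilities (Morgans).
    Returns (G, S) gametes.
    """
    G = parents.size
    S = haps.shape[2]
    start = rng.integers(0, 2, size=(G, 1))
    if S > 1:
        xo = rng.random((G, S - 1)) < xover_p
        which = (start + np.concatenate(
            [np.zeros((G, 1), dtype=np.int64), np.cumsum(xo, axis=1)], axis=1
        )) % 2
    else:
        which = start
    pat = haps[parents, 0, :]
    mat = haps[parents, 1, :]
    return np.where(which == 0, pat, mat)


def simulate_panel(demography: DemographyModel,
                   config: SimConfig) -> tuple[GenotypePanel, TruthRecord]:
    """Run the forward simulation and return ``(panel, truth_record)``.

    Deterministic for a fixed ``(demography, config)`` pair: the same inputs
    produce a byte-identical panel.
    """
    cfg = config
    if cfg.sample_size_n > demography.final_n:
        raise ValueError(
            f"sample_size_n={cfg.sample_size_n} exceeds final epoch N="
            f"{demography.final_n}"
        )
    rng = np.random.default_rng(cfg.seed)
    S = cfg.n_sites_per_chrom
    spacing = cfg.chrom_length_bp // S
    if spacing < 1:
        raise ValueError("chrom_length_bp must be >= n_sites_per_chrom")
    positions = spacing * np.arange(1, S + 1, dtype=np.int64)
    xover_p = np.diff(positions).astype(float) * cfg.cm_per_mb * 1e-8

    burn_in = (cfg.burn_in_generations if cfg.burn_in_generations is not None
               else 4 * demography.ancient_n)
    schedule: list[int] = []
    if burn_in:
        schedule += [demography.ancient_n] * burn_in
    for dur, n in demography.epochs:
        schedule += [n] * dur

    n0 = schedule[0]
    # init: independent biallelic sites, frequency U[floor, 1-floor]
    freqs = rng.uniform(cfg.maf_floor_init, 1.0 - cfg.maf_floor_init,
                        size=(cfg.n_chromosomes, S))
    haps = [
        (rng.random((n0, 2, S)) < freqs[c]).astype(np.uint8)
        for c in range(cfg.n_chromosomes)
    ]

    n_prev = n0
    for n_next in schedule:
        # 2*n_next gametes; consecutive pairs form the n_next offspring
        parents = rng.integers(0, n_prev, size=2 * n_next)
        for c in range(cfg.n_chromosomes):
            gametes = _recombine(haps[c], parents, xover_p, rng)
            haps[c] = gametes.reshape(n_next, 2, S)
        n_prev = n_next

    chosen = rng.choice(n_prev, size=cfg.sample_size_n, replace=False)
    chosen.sort()
    dosage_blocks = [haps[c][chosen].sum(axis=1).astype(np.int8)
                     for c in range(cfg.n_chromosomes)]
    genotypes = np.concatenate(dosage_blocks, axis=1)

    variants = [
        VariantRecord(chrom=str(c + 1), vid=f"chr{c + 1}_snp{k + 1}",
                      cm=positions[k] * cfg.cm_per_mb / 1e6,
                      bp=int(positions[k]), allele1="A", allele2="B")
        for c in range(cfg.n_chromosomes) for k in range(S)
    ]
    samples = [SampleRecord(fid="sim", iid=f"ind{i + 1:04d}")
               for i in range(cfg.sample_size_n)]
    panel = GenotypePanel(samples=samples, variants=variants,
                          genotypes=genotypes)

    if cfg.missing_rate > 0:
        panel = inject_missingness(panel, cfg.missing_rate,
                                   seed=int(rng.integers(0, 2**31 - 1)))

    pop_freq = np.concatenate([h.mean(axis=(0, 1)) for h in haps])
    n_fixed = int(((pop_freq == 0.0) | (pop_freq == 1.0)).sum())
    if n_fixed == cfg.n_chromosomes * S:
        warnings.warn(
            f"all sites fixed by drift (seed={cfg.seed}); rerun with a "
            "different seed, shorter history or larger N", stacklevel=2)
    truth = TruthRecord(demography=demography, config=cfg,
                        generations_run=len(schedule), n_fixed_sites=n_fixed)
    log.info("simulated %d generations, %d/%d sites fixed",
             len(schedule), n_fixed, cfg.n_chromosomes * S)
    return panel, truth


def inject_missingness(panel: GenotypePanel, rate: float,
                       seed: int = 0) -> GenotypePanel:
    """Set each call to MISSING independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return panel
    rng = np.random.default_rng(seed)
    g = panel.genotypes.copy()
    g[rng.random(g.shape) < rate] = MISSING
    return GenotypePanel(samples=list(panel.samples),
                         variants=list(panel.variants), genotypes=g,
                         autosomes=panel.autosomes)


# ---------------------------------------------------------------------------
# deterministic hand-built fixtures
# ---------------------------------------------------------------------------

def _fixture_ld_toy_3snp() -> GenotypePanel:
    """Three SNPs on one chromosome at bp 1, 100001, 200001; six samples.

    SNP1 and SNP2 carry the dosage vectors whose r² is 0.5625
    (cov 0.5, variances 2/3); SNP3 duplicates SNP1 so r²(1,3) = 1.
    """
    g = np.array([
        [0, 0, 0],
        [0, 1, 0],
        [1, 0, 1],
        [1, 1, 1],
        [2, 2, 2],
        [2, 2, 2],
    ], dtype=np.int8)
    variants = [
        VariantRecord("1", "toy_snp1", 0.0, 1, "A", "B"),
        VariantRecord("1", "toy_snp2", 0.1, 100_001, "A", "B"),
        VariantRecord("1", "toy_snp3", 0.2, 200_001, "A", "B"),
    ]
    samples = [SampleRecord("toy", f"s{i}") for i in range(1, 7)]
    return GenotypePanel(samples=samples, variants=variants, genotypes=g)


def _fixture_qc_edge_cases() -> GenotypePanel:
    """25 samples x 24 SNPs exercising each QC filter exactly once.

    Documented expectations under default thresholds:
      rare_maf         one het in 25 -> MAF 0.02 < 0.05, removed by MAF
      holey            missing in 3/25 (12% > 5%), removed by SNP call rate
      sexchrom         on X, removed as sex-chromosome
      unplaced         bp = 0, removed as unplaced
      clean01..clean20 balanced (6/13/6), complete, in HWE -> retained
    With 24 SNPs a sample carrying one of ``holey``'s three missing calls
    has 1/24 ≈ 4.2% missingness, below the 5% sample ceiling, so no sample
    is removed.  Expected report: 1 MAF, 1 call-rate, 2 unplaced/sex,
    0 samples; 24 -> 20 SNPs.
    """
    n = 25

    def balanced(shift: int) -> np.ndarray:
        # Hardy-Weinberg-compatible 6/13/6 layout at p = 0.5, rotated
        col = np.array([0] * 6 + [1] * 13 + [2] * 6, dtype=np.int8)
        return np.roll(col, shift)

    g = np.zeros((n, 24), dtype=np.int8)
    g[:, 0] = 0; g[0, 0] = 1                          # rare_maf: MAF = 1/50
    g[:, 1] = balanced(1); g[[2, 7, 11], 1] = MISSING  # holey: 3/25 missing
    g[:, 2] = balanced(2)                             # sexchrom (content clean)
    g[:, 3] = balanced(3)                             # unplaced (content clean)
    for k in range(4, 24):
        g[:, k] = balanced(k)
    variants = [
        VariantRecord("1", "rare_maf", 0.0, 10_000, "A", "B"),
        VariantRecord("1", "holey", 0.0, 20_000, "A", "B"),
        VariantRecord("X", "sexchrom", 0.0, 30_000, "A", "B"),
        VariantRecord("1", "unplaced", 0.0, 0, "A", "B"),
    ] + [
        VariantRecord(str(1 + k % 3), f"clean{k + 1:02d}", 0.0,
                      40_000 + 10_000 * k, "A", "B")
        for k in range(20)
    ]
    samples = [SampleRecord("qc", f"s{i:02d}") for i in range(1, n + 1)]
    return GenotypePanel(samples=samples, variants=variants, genotypes=g)


def _fixture_hwe_extremes() -> GenotypePanel:
    """25 samples x 3 SNPs probing the HWE exact test's extremes.

    ``all_het`` is heterozygous in all 25 samples — the maximal departure
    (exact p ≈ 2.7e-7 < 1e-6, removed); ``in_hwe`` sits at Hardy–Weinberg
    proportions; ``mono`` is monomorphic (p = 1 by convention, but removed
    as MAF 0 when the MAF filter is on).
    """
    n = 25
    g = np.zeros((n, 3), dtype=np.int8)
    g[:, 0] = 1                                   # all heterozygous
    g[:, 1] = np.array([0] * 6 + [1] * 13 + [2] * 6, dtype=np.int8)
    g[:, 2] = 0                                   # monomorphic
    variants = [
        VariantRecord("1", "all_het", 0.0, 10_000, "A", "B"),
        VariantRecord("1", "in_hwe", 0.0, 20_000, "A", "B"),
        VariantRecord("1", "mono", 0.0, 30_000, "A", "B"),
    ]
    samples = [SampleRecord("hwe", f"s{i:02d}") for i in range(1, n + 1)]
    return GenotypePanel(samples=samples, variants=variants, genotypes=g)


_FIXTURES = {
    "ld_toy_3snp": _fixture_ld_toy_3snp,
    "qc_edge_cases": _fixture_qc_edge_cases,
    "hwe_extremes": _fixture_hwe_extremes,
}


def make_fixture_panel(name: str) -> GenotypePanel:
    """Return a hand-built deterministic panel from the fixture registry."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return builder()


__all__ = ["DemographyModel", "SimConfig", "TruthRecord", "simulate_panel",
           "inject_missingness", "make_fixture_panel"]
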