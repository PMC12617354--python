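"""Canned simulation studies validating the QC -> LD -> Ne pipeline.

Two ground-truth experiments, reused by the test suite, the acceptance
script and the analysis drivers:

* :func:`constant_ne_recovery` — a constant-size Wright–Fisher population
  (default N = 100) is simulated repeatedly; the pipeline should recover N
  from the mid-range of the LD-decay curve.  The per-seed point estimate is
  the pair-count-weighted median Ne over bins with mean pair distance in
  [1, 15] Mb: closer bins sit where Sved's one-term approximation is
  weakest, while the longest bins carry almost no corrected signal at
  n = 50 samples.
* :func:`decline_detection` — a two-epoch history (large ancient N, small
  recent N) should yield recent Ne estimates below ancient ones.  "Recent"
  pools trajectory points with T at most the recent epoch's length
  (pair-weighted median); "ancient" pools points with T > 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .ld import LDParams, build_ld_profile
from .ne import ne_trajectory
from .qc import apply_qc
from .simulate import DemographyModel, SimConfig, simulate_panel

MID_RANGE_BP = (1_000_000, 15_000_000)


def weighted_median(values, weights) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_median of empty input")
    order = np.argsort(values)
    cum = np.cumsum(weights[order]) / weights.sum()
    return float(values[order][np.searchsorted(cum, 0.5)])


@dataclass
class ConstantNeResult:
    true_ne: int
    ne_estimates: list[float]      # per-seed weighted-median Ne, mid-range
    pooled_spearman: float         # bin index vs pooled mean r² rank corr.
    pooled_bin_means: np.ndarray
    seeds: list[int]

    def fraction_within(self, rel_tol: float) -> float:
        lo, hi = self.true_ne * (1 - rel_tol), self.true_ne * (1 + rel_tol)
        return float(np.mean([(lo <= x <= hi) for x in self.ne_estimates]))


@dataclass
class DeclineResult:
    recent_ne: list[float]         # per-seed pair-weighted median, T <= epoch
    ancient_ne: list[float]        # per-seed pair-weighted median, T > 100
    seeds: list[int]

    def detection_fraction(self) -> float:
        wins = [r < a for r, a in zip(self.recent_ne, self.ancient_ne)]
        return float(np.mean(wins))


def _run_pipeline_on_sim(demography: DemographyModel, cfg: SimConfig,
                         ld_params: LDParams):
    panel, _ = simulate_panel(demography, cfg)
    filtered, _ = apply_qc(panel)
    profile = build_ld_profile(filtered, ld_params)
    traj = ne_trajectory(profile, filtered.n_samples, "one_over_n",
                         cfg.cm_per_mb, max_generations=float("inf"))
    return profile, traj


def constant_ne_recovery(true_ne: int = 100, n_seeds: int = 10,
                         base_seed: int = 0) -> ConstantNeResult:
    """Recover a constant Ne from repeated forward simulations.

    Each replicate simulates 2 chromosomes x 500 sites x 50 Mb at 1 cM/Mb,
    burn-in 4N generations, sample n = 50, then runs QC -> LD -> Ne with
    the 1/n correction.  Also pools pairs across replicates per distance
    bin and reports the Spearman rank correlation between bin index and
    pooled mean r² (LD decay monotonicity).
    """
    seeds = [base_seed + i for i in range(n_seeds)]
    demo = DemographyModel.constant(true_ne, duration=30)
    params = LDParams()
    nbins = len(params.bin_edges()) - 1
    pooled_r2 = np.zeros(nbins)
    pooled_n = np.zeros(nbins)
    estimates: list[float] = []
    for seed in seeds:
        cfg = SimConfig(seed=seed, burn_in_generations=4 * true_ne)
        profile, traj = _run_pipeline_on_sim(demo, cfg, params)
        for k, b in enumerate(profile):
            if b.n_pairs:
                pooled_r2[k] += b.mean_r2 * b.n_pairs
                pooled_n[k] += b.n_pairs
        mid = [p for p in traj.points
               if MID_RANGE_BP[0] <= p.mean_dist_bp <= MID_RANGE_BP[1]]
        estimates.append(weighted_median([p.ne for p in mid],
                                         [p.n_pairs for p in mid]))
    populated = pooled_n > 0
    means = pooled_r2[populated] / pooled_n[populated]
    rho = float(spearmanr(np.flatnonzero(populated), means).statistic)
    return ConstantNeResult(true_ne=true_ne, ne_estimates=estimates,
                            pooled_spearman=rho, pooled_bin_means=means,
                            seeds=seeds)


def decline_detection(ancient_n: int = 500, ancient_gens: int = 300,
                      recent_n: int = 50, recent_gens: int = 30,
                      n_seeds: int = 10, base_seed: int = 0) -> DeclineResult:
    """Detect a population-size collapse from the Ne trajectory.

    Two-epoch demography (default N 500 for 300 generations, then N 50 for
    30).  Panels use 20 kb site spacing (2 chromosomes x 500 sites x 10 Mb)
    so the trajectory resolves both T > 100 (short-range LD, ancient epoch)
    and T within the recent epoch (long-range LD); burn-in is 2 x ancient N.
    """
    seeds = [base_seed + i for i in range(n_seeds)]
    demo = DemographyModel(epochs=((ancient_gens, ancient_n),
                                   (recent_gens, recent_n)))
    params = LDParams(maxdist_bp=10_000_000)
    recent_est: list[float] = []
    ancient_est: list[float] = []
    for seed in seeds:
        cfg = SimConfig(seed=seed, burn_in_generations=2 * ancient_n,
                        chrom_length_bp=10_000_000, n_sites_per_chrom=500)
        _, traj = _run_pipeline_on_sim(demo, cfg, params)
        rec = [p for p in traj.points if p.T <= recent_gens]
        anc = [p for p in traj.points if p.T > 100]
        recent_est.append(weighted_median([p.ne for p in rec],
                                          [p.n_pairs for p in rec]))
        ancient_est.append(weighted_median([p.ne for p in anc],
                                           [p.n_pairs for p in anc]))
    return DeclineResult(recent_ne=recent_est, ancient_ne=ancient_est,
                         seeds=seeds)


__all__ = ["MID_RANGE_BP", "weighted_median", "ConstantNeResult",
           "DeclineResult", "constant_ne_recovery", "decline_detection"]
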