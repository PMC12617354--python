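"""Effective population size from LD decay via Sved's relation.

Under drift–recombination balance the expected LD between loci at
recombination distance ``c`` Morgans satisfies ``E[r²] ≈ 1 / (1 + 4 Ne c)``
(Sved's equation), which inverts to ``Ne = (1/4c)(1/r² − 1)``.  LD at
distance ``c`` reflects drift roughly ``T = 1/(2c)`` generations ago, so a
binned LD-decay profile maps to an Ne-versus-generation trajectory:
long-range bins speak to recent generations, short-range bins to ancient
ones.  Physical distance is mapped to Morgans with a constant genome-average
rate (default 1 cM/Mb).

Observed r² is inflated by finite sample size; before inversion the bin mean
is reduced by 1/n (default) or 1/(2n), selectable per run and stamped into
the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ld import LDBin

log = logging.getLogger(__name__)

CORRECTION_MODES = ("none", "one_over_n", "one_over_2n")


@dataclass(frozen=True)
class NePoint:
    """One (generation, Ne) estimate derived from a single distance bin."""

    T: float            # generations before present, = 1/(2c)
    c: float            # recombination distance, Morgans
    r2_adj: float       # sample-size-corrected bin mean r²
    ne: float
    n_pairs: int
    low_confidence: bool = False
    mean_dist_bp: float = float("nan")  # the bin's mean pair distance


@dataclass
class NeTrajectory:
    """Ne estimates ordered from the most recent generation backwards."""

    points: list[NePoint]
    sample_size_n: int
    correction_mode: str
    stabilized_from_T: float | None = None
    dropped_bins: list[str] = field(default_factory=list)


class EmptyTrajectoryError(ValueError):
    """Every bin was dropped by the correction or validity checks."""


# ---------------------------------------------------------------------------
# elementary maps
# ---------------------------------------------------------------------------

def morgans_from_bp(distance_bp: float, cm_per_mb: float = 1.0) -> float:
    """Physical→genetic distance: ``c = bp × cm_per_mb × 1e-8`` Morgans.

    At the default 1 cM/Mb, 1 Mb maps to 0.01 Morgans.
    """
    if distance_bp <= 0:
        raise ValueError(f"distance must be > 0 bp, got {distance_bp}")
    return float(distance_bp) * cm_per_mb * 1e-8


def correct_r2(mean_r2: float, n_samples: int, mode: str = "one_over_n") -> float:
    """Remove the finite-sample inflation of a bin-mean r².

    ``one_over_n`` subtracts 1/n, ``one_over_2n`` subtracts 1/(2n), ``none``
    returns the input.  A non-positive result means the bin carries no
    usable LD signal at this sample size; callers drop such bins.
    """
    if mode not in CORRECTION_MODES:
        raise ValueError(f"mode must be one of {CORRECTION_MODES}, got {mode!r}")
    if not 0.0 <= mean_r2 <= 1.0:
        raise ValueError(f"mean_r2 must be in [0, 1], got {mean_r2}")
    if n_samples < 2:
        raise ValueError("need n_samples >= 2")
    if mode == "none":
        return float(mean_r2)
    denom = n_samples if mode == "one_over_n" else 2 * n_samples
    return float(mean_r2 - 1.0 / denom)


def sved_ne(r2_adj: float, c: float) -> float:
    """Invert Sved's relation: ``Ne = (1/4c) (1/r² − 1)``."""
    if c <= 0:
        raise ValueError(f"recombination distance must be > 0, got {c}")
    if not 0.0 < r2_adj <= 1.0:
        raise ValueError(f"r2_adj must be in (0, 1], got {r2_adj}")
    return (1.0 / (4.0 * c)) * (1.0 / r2_adj - 1.0)


def generation_for_c(c: float) -> float:
    """Generations before present probed by LD at distance ``c``: T = 1/(2c)."""
    if c <= 0:
        raise ValueError(f"recombination distance must be > 0, got {c}")
    return 1.0 / (2.0 * c)


def heterozygosity_loss(ne: float, t_generations: float) -> float:
    """Expected fractional loss of heterozygosity after ``t`` generations.

    Drift erodes diversity at rate 1/(2Ne) per generation:
    ``loss = 1 − (1 − 1/(2 Ne))^t``.
    """
    if ne <= 0.5:
        raise ValueError(f"ne must be > 0.5 for a defined loss rate, got {ne}")
    if t_generations < 0:
        raise ValueError("t_generations must be >= 0")
    return 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** t_generations


# ---------------------------------------------------------------------------
# trajectory assembly
# ---------------------------------------------------------------------------

def ne_trajectory(ld_profile: list[LDBin], n_samples: int,
                  correction_mode: str = "one_over_n",
                  cm_per_mb: float = 1.0,
                  stability_tol: float = 0.01,
                  max_generations: float = 2000.0) -> NeTrajectory:
    """Convert a binned LD profile into an Ne-versus-generation trajectory.

    Each bin with pairs and a positive corrected r² maps through its mean
    pair distance to ``c``, then to ``(T, Ne)``.  Points are sorted by T
    ascending (recent first).  ``stabilized_from_T`` is the smallest T from
    which the relative change in Ne between every subsequent adjacent pair
    of points stays below ``stability_tol`` — the "Ne values stabilize
    across adjacent bins" convergence notion.  Points with
    ``T > max_generations`` are kept but flagged low-confidence.
    """
    if not ld_profile:
        raise EmptyTrajectoryError("empty LD profile")
    points: list[NePoint] = []
    dropped: list[str] = []
    for b in ld_profile:
        if b.n_pairs == 0 or not np.isfinite(b.mean_r2):
            dropped.append(f"bin[{b.lo_bp:g},{b.hi_bp:g}): no pairs")
            continue
        r2_adj = correct_r2(b.mean_r2, n_samples, correction_mode)
        if r2_adj <= 0.0:
            dropped.append(
                f"bin[{b.lo_bp:g},{b.hi_bp:g}): corrected r2 {r2_adj:.4g} <= 0"
            )
            continue
        c = morgans_from_bp(b.mean_dist_bp, cm_per_mb)
        T = generation_for_c(c)
        r2a = min(r2_adj, 1.0)
        points.append(NePoint(
            T=T, c=c, r2_adj=r2a, ne=sved_ne(r2a, c), n_pairs=b.n_pairs,
            low_confidence=b.low_confidence or T > max_generations,
            mean_dist_bp=float(b.mean_dist_bp),
        ))
    if not points:
        raise EmptyTrajectoryError(
            f"all {len(ld_profile)} bins dropped: {dropped[:3]}..."
        )
    if dropped:
        log.info("trajectory: dropped %d bins (%s...)", len(dropped), dropped[0])
    points.sort(key=lambda p: p.T)

    stabilized: float | None = None
    ne = np.array([p.ne for p in points])
    if len(ne) >= 2:
        rel = np.abs(np.diff(ne)) / ne[:-1]
        ok = rel < stability_tol
        # smallest T (index) from which every later adjacent change is small
        suffix_ok = np.flip(np.logical_and.accumulate(np.flip(ok)))
        idx = np.flatnonzero(suffix_ok)
        if idx.size:
            stabilized = float(points[idx[0]].T)
    elif len(ne) == 1:
        stabilized = float(points[0].T)

    return NeTrajectory(points=points, sample_size_n=n_samples,
                        correction_mode=correction_mode,
                        stabilized_from_T=stabilized, dropped_bins=dropped)


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def trajectory_to_frame(traj: NeTrajectory) -> pd.DataFrame:
    return pd.DataFrame([
        {"T": p.T, "c_morgans": p.c, "mean_dist_bp": p.mean_dist_bp,
         "r2_adj": p.r2_adj, "ne": p.ne, "n_pairs": p.n_pairs,
         "low_confidence": p.low_confidence}
        for p in traj.points
    ])


def write_ne_trajectory(traj: NeTrajectory, path: str | Path) -> None:
    trajectory_to_frame(traj).to_csv(path, sep="\t", index=False)


__all__ = ["NePoint", "NeTrajectory", "EmptyTrajectoryError",
           "CORRECTION_MODES", "morgans_from_bp", "correct_r2", "sved_ne",
           "generation_for_c", "heterozygosity_loss", "ne_trajectory",
           "trajectory_to_frame", "write_ne_trajectory"]
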