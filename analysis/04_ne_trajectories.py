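#!/usr/bin/env python
"""Ne-versus-generation trajectories from the LD profiles.

Inverts Sved's relation per distance bin after the 1/n sample-size
correction.  For the constant-N=100 panel the trajectory should hover near
100 through the mid-range generations; for the collapse panel the recent
(large-distance, small-T) points should sit far below the ancient ones.
"""

from pathlib import Path

from ldne import ne_trajectory, read_genotype_panel, read_ld_profile, write_ne_trajectory
from ldne.experiments import weighted_median
from ldne.pipeline import summarize_headline

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "ne"
OUT.mkdir(parents=True, exist_ok=True)

for name in ("constant_ne100", "collapse_500_to_50"):
    panel = read_genotype_panel(ROOT / "qc" / f"{name}.clean", "binary")
    profile = read_ld_profile(ROOT / "ld" / f"{name}.ld_profile.tsv")
    traj = ne_trajectory(profile, panel.n_samples, "one_over_n",
                         max_generations=float("inf"))
    write_ne_trajectory(traj, OUT / f"{name}.ne_trajectory.tsv")
    summary = summarize_headline(profile, traj)
    with open(OUT / f"{name}.summary.tsv", "w") as fh:
        fh.write("\t".join(summary) + "\n")
        fh.write("\t".join("NA" if v is None else f"{v:.6g}"
                           for v in summary.values()) + "\n")
    rec = [p for p in traj.points if p.T <= 30]
    anc = [p for p in traj.points if p.T > 100]
    msg = (f"{name}: {len(traj.points)} points, "
           f"T {traj.points[0].T:.1f}..{traj.points[-1].T:.0f}; "
           f"recent-epoch weighted-median Ne "
           f"{weighted_median([p.ne for p in rec], [p.n_pairs for p in rec]):.0f}")
    if anc:
        msg += (f", ancient (T>100) "
                f"{weighted_median([p.ne for p in anc], [p.n_pairs for p in anc]):.0f}")
    print(msg)
    print(f"  summary: {summary}")
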