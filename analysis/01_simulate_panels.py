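#!/usr/bin/env python
"""Simulate the two study panels used throughout the analysis.

Panel A: constant-size population (N = 100), the calibration scenario —
Sved's relation should recover N from its LD decay.  Panel B: a two-epoch
collapse (N 500 for 300 generations, then N 50 for 30), the detection
scenario.  Both are written as PLINK binary filesets with a ground-truth
YAML next to them.
"""

from pathlib import Path

from ldne import DemographyModel, SimConfig, simulate_panel, write_genotype_panel

OUT = Path(__file__).resolve().parent.parent / "results" / "panels"
OUT.mkdir(parents=True, exist_ok=True)

scenarios = {
    "constant_ne100": (
        DemographyModel.constant(100, duration=30),
        SimConfig(seed=1, burn_in_generations=400),
    ),
    "collapse_500_to_50": (
        DemographyModel(epochs=((300, 500), (30, 50))),
        SimConfig(seed=1, burn_in_generations=1000,
                  chrom_length_bp=10_000_000, n_sites_per_chrom=500),
    ),
}

for name, (demo, cfg) in scenarios.items():
    panel, truth = simulate_panel(demo, cfg)
    prefix = OUT / name
    write_genotype_panel(panel, prefix, "binary")
    truth.write(prefix.with_suffix(".truth.yaml"))
    seg = panel.n_variants - truth.n_fixed_sites
    print(f"{name}: {panel.n_samples} samples x {panel.n_variants} sites "
          f"({seg} still segregating after {truth.generations_run} generations)"
          f" -> {prefix}.bed/.bim/.fam")
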