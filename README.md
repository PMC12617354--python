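# ldne

Linkage-disequilibrium decay profiling and LD-based effective population
size (Ne) estimation for diploid SNP-array genotypes, with a Wright–Fisher
forward simulator that provides ground-truth panels for validation.

The package is aimed at population and livestock geneticists who have an
unphased SNP panel (PLINK text or binary files) and want the classic
LD-based demographic readout: how fast r² decays with physical distance,
and what that decay implies about the population's size history.

## The method

For two loci at recombination distance *c* (Morgans), drift–recombination
balance gives Sved's approximation for expected LD,

    E[r²] ≈ 1 / (1 + 4 Ne c),

which inverts to

    Ne = (1 / 4c) · (1 / r² − 1).

LD at distance *c* reflects drift about **T = 1/(2c)** generations ago, so
short-range LD speaks to ancient Ne and long-range LD to recent Ne.  The
pipeline is:

1. **QC** — remove samples and SNPs with >5% missing calls, SNPs with
   MAF < 5%, SNPs failing the Hardy–Weinberg exact test at p < 10⁻⁶, and
   unplaced or sex-chromosome SNPs, with disjoint per-filter accounting.
2. **LD decay** — all intra-chromosomal pairs with separation in
   [10 kb, 40 Mb) are scored with the phase-free composite r² (squared
   Pearson correlation of 0/1/2 dosages, pairwise-complete) and aggregated
   into 40 equal-width distance bins.
3. **Ne trajectory** — each bin's mean r², reduced by 1/n for sample-size
   inflation, is mapped through its mean pair distance (1 cM ≈ 1 Mb by
   default) to a (T, Ne) point.
4. **Diversity loss** — the drift helper 1 − (1 − 1/(2Ne))^t converts an
   Ne into expected heterozygosity loss over t generations.

Because real array datasets are large and external, the package ships a
diploid Wright–Fisher forward simulator (recombination, piecewise-constant
N, no mutation/selection) so every stage can be validated against known
demographic truth.

## Worked example

```python
from ldne import (DemographyModel, SimConfig, simulate_panel, apply_qc,
                  build_ld_profile, ne_trajectory)

demo = DemographyModel.constant(100, duration=30)          # true Ne = 100
cfg = SimConfig(seed=1, burn_in_generations=400)           # 2 x 500 sites x 50 Mb, n = 50
panel, truth = simulate_panel(demo, cfg)
clean, report = apply_qc(panel)
profile = build_ld_profile(clean)
traj = ne_trajectory(profile, clean.n_samples, "one_over_n")
```

Running the equivalent numbered drivers in `analysis/` prints:

```
constant_ne100: 1000 -> 158 SNPs (MAF 842, call-rate 0, HWE 0); samples 50 -> 50
constant_ne100: 6212 pairs in 40 bins; r² 0.428 at 496 kb -> 0.016 at 39.5 Mb
constant_ne100: 31 points, T 1.4..101; recent-epoch weighted-median Ne 122, ancient (T>100) 73
```

Read: drift fixed most of the 1000 simulated sites (the MAF filter removes
them, as it would monomorphic probes on a real array); the surviving panel
shows the expected nonlinear decay from r² ≈ 0.43 at half a megabase to
≈ 0.02 at 40 Mb; and the trajectory's pair-weighted median over the
mid-range bins lands near the true Ne of 100 (individual bins are noisy at
n = 50 — pool before you interpret).  For the two-epoch collapse scenario
(N 500 → 50) the same drivers print a recent-epoch median Ne of 75 against
an ancient (T > 100) median of 203: the collapse is visible as recent
estimates sitting far below ancient ones.

The same stages are available as shell subcommands:

```bash
ldne simulate --epochs 300:500,30:50 --out-prefix panel
ldne qc --in-prefix panel --out-prefix clean
ldne ld --in-prefix clean --out ld_profile.tsv
ldne ne --profile ld_profile.tsv --n-samples 50 --out trajectory.tsv
ldne run --simulate-epochs 30:100 --out-dir run1   # one-shot pipeline
```

## Layout

- `src/ldne/` — library: `panel`, `io_plink`, `qc`, `ld`, `ne`,
  `simulate`, `experiments`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers writing tables under `results/`
- `tests/` — pytest suite with brute-force oracles in `tests/_oracles.py`
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
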