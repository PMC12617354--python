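#!/usr/bin/env python
"""Expected heterozygosity loss under drift for conservation-relevant Ne.

Tabulates 1 - (1 - 1/(2Ne))^t for the Ne values usually quoted in
conservation guidance, over 5 and 10 generations.  At Ne = 25 a population
loses nearly a fifth of its diversity in 10 generations; above Ne = 100 the
10-generation loss stays under 5%.
"""

from pathlib import Path

from ldne import heterozygosity_loss

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for ne in (25, 50, 100, 125, 250, 500):
    rows.append((ne,
                 heterozygosity_loss(ne, 5) * 100,
                 heterozygosity_loss(ne, 10) * 100))

with open(OUT / "diversity_loss.tsv", "w") as fh:
    fh.write("ne\tloss_pct_5gen\tloss_pct_10gen\n")
    for ne, l5, l10 in rows:
        fh.write(f"{ne}\t{l5:.2f}\t{l10:.2f}\n")

print("Ne    loss in 5 gen   loss in 10 gen")
for ne, l5, l10 in rows:
    print(f"{ne:<5d} {l5:>9.2f}%      {l10:>9.2f}%")
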