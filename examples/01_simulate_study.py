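"""Generate a synthetic coastal SNP survey and look at its structure.

Builds the default study — 232 diploids at ~1,137 unlinked SNPs along a
~1,900 km coastline, four correlated environmental gradients, and ten
loci with an allele-frequency cline in bottom temperature — and prints
its basic shape.
"""

import numpy as np

from flounderscape.study import SimStudyConfig, simulate_study

data = simulate_study(SimStudyConfig(seed=1))
m = data.matrix

print(f"individuals: {m.n_individuals} "
      f"({(m.samples['deme'] == 'north').sum()} north / "
      f"{(m.samples['deme'] == 'south').sum()} south)")
print(f"loci: {m.n_loci} ({data.clinal_mask.sum()} clinal)")
print(f"missing genotypes: {100 * m.missing_mask.mean():.2f}%")
maf = m.minor_allele_freq()
print(f"minor allele frequency range: {np.nanmin(maf):.3f}-"
      f"{np.nanmax(maf):.3f}")
print(data.env.describe().loc[["mean", "std"]].round(2))

# The deme split and the temperature gradient are the two features the
# downstream analyses interrogate: the demes should look panmictic at
# neutral loci while the clinal loci track bottom temperature.
paths = data.write("scratch/example_study")
print("wrote:", ", ".join(paths.values()))
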