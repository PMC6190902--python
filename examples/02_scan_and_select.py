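"""Single-marker Mantel scan and forward selection of a marker set.

Plants a 6-locus architecture at heritability 0.5 in 300 animals, scans 800
markers, gates at the per-marker permutation p < 0.01, and grows the
cumulative-correlation curve.  The printed peak is the selected marker set.
"""

import numpy as np
import pandas as pd

from mantelqtl import (ArchitectureSpec, filter_markers_by_maf,
                       marker_set_analysis, phenotype_distance,
                       simulate_founder_panel, simulate_hs_genomes,
                       simulate_phenotypes)

ss = np.random.SeedSequence(7).spawn(4)
panel = simulate_founder_panel(8, 800, seed=ss[0])
g = simulate_hs_genomes(panel, 300, mean_block_markers=20, seed=ss[1])
cond = pd.DataFrame({"cohort": ["c1"] * 300, "condition": ["sham"] * 300},
                    index=pd.Index(g.samples, name="sample"))
rng = np.random.default_rng(ss[2])
causal = list(rng.choice(g.markers, 6, replace=False))
spec = ArchitectureSpec(effects={"sham": [(m, 1.0) for m in causal]},
                        heritability=0.5, seed=0)
pheno, _ = simulate_phenotypes(g, spec, cond)

g = filter_markers_by_maf(g, 0.05)
d = phenotype_distance(pheno, "context_avgmot")
res = marker_set_analysis(g, d, B=199, seed=ss[3])

print("top of the ranked scan (r = per-marker Mantel correlation):")
print(res.scan.table.head(8).to_string(index=False))
print(f"\nmarkers passing the p < 0.01 gate: {len(res.eligible)}")
print(f"peak of the cumulative curve: k* = {res.k_star}, "
      f"cumulative r = {res.peak_value:.3f}")
print(f"planted loci inside the peak set: "
      f"{len(set(causal) & set(res.peak_markers))} of {len(causal)}")
print("\nThe cumulative r at k* exceeds any single-marker r: combining "
      "individually gated markers raises the genotype-phenotype correlation.")
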