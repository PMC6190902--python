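"""Genes near reproducibly detected markers, tested against gene sets.

Builds a synthetic gene annotation tiled along the simulated chromosomes and
a synthetic GMT collection, collects genes within 1 Mb of markers detected
in both of two strata, and tests each set for hypergeometric
overrepresentation with Benjamini-Hochberg adjustment.
"""

import numpy as np
import pandas as pd

from mantelqtl.enrichment import enrich, genes_near_markers
from mantelqtl.io import GeneAnnotation, GeneSetCollection
from mantelqtl.simulate import simulate_founder_panel

panel = simulate_founder_panel(8, 400, seed=3)
mp = panel.marker_map

# synthetic annotation: one gene every 400 kb along each chromosome
rows, gid = [], 0
for chrom, grp in mp.groupby("chrom", sort=False):
    for start in range(1, int(grp["bp"].max()) + 500_000, 400_000):
        rows.append((f"gene{gid:04d}", chrom, start, start + 200_000))
        gid += 1
ann = GeneAnnotation(pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))

# markers "detected in both strata": a clump on one chromosome
common = list(mp.index[:6])
genes = genes_near_markers(common, mp, ann, window_bp=1_000_000)
universe = set(ann.table.loc[ann.table["chrom"].isin(
    set(mp.loc[common, "chrom"])), "gene"])
print(f"{len(common)} common markers -> {len(genes)} genes within 1 Mb "
      f"(universe: {len(universe)} genes on the touched chromosomes)")

# synthetic collection: one set enriched near the markers, others random
rng = np.random.default_rng(0)
near = sorted(genes)
sets = {"near_markers": set(near[: max(5, len(near) // 2)])}
all_genes = ann.table["gene"].to_numpy()
for i in range(6):
    sets[f"random_{i}"] = set(rng.choice(all_genes, 15, replace=False))
coll = GeneSetCollection({k: v & universe or v for k, v in sets.items()})

df = enrich(genes, coll, universe)
print(df.to_string(index=False))
print("\np is the hypergeometric upper tail of the query/set overlap; "
      "q is its Benjamini-Hochberg adjustment across the collection.")
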