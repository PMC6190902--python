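"""Generate a heterogeneous-stock-like dataset and write it to disk.

Simulates 8 founder strains, 400 mosaic-genome animals genotyped at 2,000
markers, six correlated behavioral categories, two cohorts with mean/variance
shifts, and four irradiation arms sharing one causal architecture.  The
ground-truth manifest records which markers are causal in which condition.
"""

from mantelqtl.pipeline import simulate_command

paths = simulate_command("example_output/dataset", seed=1,
                         n_samples=400, n_markers=2000, n_causal=10,
                         heritability=0.4)
for name, path in paths.items():
    print(f"{name:>14}: {path}")
print("\nThe genotype TSV holds 0/1/2 dosages; phenotypes are z-scale "
      "measures in six categories; ground_truth.yaml lists the planted "
      "causal markers so downstream recovery can be checked.")
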