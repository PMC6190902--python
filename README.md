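# mantelqtl

Distance-based multi-locus genotype–phenotype association for genetically
heterogeneous populations: Mantel-correlation QTL scanning, forward-selected
marker sets with label-shuffled Z-score calibration, Fisher-exact overlap of
marker sets detected under different environmental conditions, and
gene-window set enrichment — plus a synthetic heterogeneous-stock (HS)
mouse data generator with known ground truth.

## Who this is for

Behavioral and quantitative geneticists working with dense SNP genotypes
and many correlated phenotype measures per animal (the P ≫ N regime), who
want *set-level* evidence of genetic control — and want to ask whether an
environmental challenge (a stressor, irradiation) changes *which* loci
matter, rather than only whether group means move.

## The method

Genotypes over a marker set S and phenotype measures within a category are
each reduced to N × N Manhattan distance matrices over samples
(d_G(i,j) = Σ_m |g_i(m) − g_j(m)| on 0/1/2 dosages, equal weight per
marker). The Mantel statistic r correlates their N(N−1)/2 off-diagonal
entries; permutation of sample labels gives p = (b+1)/(B+1). The pipeline:

1. scan every marker (MAF > 5%) against a phenotype category;
2. forward-select markers in decreasing significance, gated at individual
   permutation p < 0.01, tracking the cumulative correlation c_k and
   taking the earliest entry into its plateau;
3. repeat the whole procedure on R phenotype-label shuffles and report
   Z_k = (c_k − μ_k)/σ_k — Z > 3 (normal tail 0.00135) marks marker sets
   unlikely to arise from the scan's own selection bias;
4. compare peak sets across strata (cohorts; sham vs. irradiated) with the
   Fisher exact odds ratio over the shared marker universe, and test genes
   within 1 Mb of reproducibly detected markers for gene-set enrichment.

See `docs/methods.md` for the model, parameter meanings and limitations.

## Worked example

`examples/02_scan_and_select.py` plants a 6-locus architecture
(heritability 0.5) in 300 simulated HS animals over 800 markers, scans,
gates and selects:

```
top of the ranked scan (r = per-marker Mantel correlation):
 marker chrom      bp        r     p  exceed  n_perm
 m00778 chr19  687847 0.137541 0.005       0     199
 m00313  chr8 2121593 0.132671 0.005       0     199
 ...

markers passing the p < 0.01 gate: 12
peak of the cumulative curve: k* = 6, cumulative r = 0.290
planted loci inside the peak set: 4 of 6
```

The cumulative correlation at the peak (0.290) exceeds every single-marker
r (max 0.138): combining individually gated markers raises the
genotype–phenotype correlation, and most of the selected set is causal or
linked to a causal locus. `examples/03_null_calibration.py` calibrates such
a curve against 20 label shuffles and prints the per-k Z-scores (max Z =
4.43 on its planted data — far outside the null ensemble), and
`examples/04_condition_overlap.py` contrasts identical vs. fully shifted
architectures across sham/irradiated strata (odds ratio 98.6 with CI
[19.1, 508.8] vs. a CI spanning 1).

A thin CLI mirrors the library (`mantelqtl simulate | scan | select |
calibrate | compare | enrich | run-all`); `run-all` takes a YAML config and
writes a report bundle whose manifest embeds the config hash and seed, so
identical configs reproduce identical bytes.

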