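"""Does irradiation shift which loci correlate with behavior?

Simulates sham and irradiated strata twice: once sharing one causal
architecture, once with fully disjoint causal loci.  The Fisher-exact odds
ratio of the two independently detected marker sets separates the cases: a
confidence interval above 1 means the architectures agree; an odds ratio at
or below 1 (or a CI spanning 1) means the loci shifted.
"""

from mantelqtl.validation import overlap_replicate

for overlap, label in ((1.0, "identical architectures"),
                       (0.0, "fully shifted architectures")):
    res = overlap_replicate(5, architecture_overlap=overlap,
                            n_per_stratum=400, n_markers=1000)
    print(f"{label}:")
    print(f"  2x2 table (both, A only, B only, neither) = "
          f"({res.a}, {res.b}, {res.c}, {res.d})")
    if res.degenerate:
        print("  odds ratio undefined (an empty marker set)")
    else:
        print(f"  odds ratio = {res.odds_ratio:.2f} "
              f"[95% CI {res.ci_low:.2f} - {res.ci_high:.2f}], "
              f"Fisher p = {res.p:.2g}")
    print()
print("Shared loci are re-detected in both strata (CI above 1); disjoint "
      "loci leave only chance-level overlap.")
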