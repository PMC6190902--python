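import numpy as np
import pandas as pd
import pytest

from mantelqtl.io import GenotypeMatrix, PhenotypeTable
from mantelqtl.simulate import (ArchitectureSpec, simulate_founder_panel,
                                simulate_hs_genomes, simulate_phenotypes)


def make_genotypes(dosages, chrom=None, bp=None) -> GenotypeMatrix:
    """Hand-built genotype matrix with an auto-generated marker map."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    markers = [f"m{j}" for j in range(m)]
    mp = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * m,
        "bp": bp if bp is not None else np.arange(1, m + 1) * 1000,
        "ref": ["A"] * m,
        "alt": ["G"] * m,
    }, index=pd.Index(markers, name="marker"))
    return GenotypeMatrix([f"s{i}" for i in range(n)], markers, dosages, mp)


def make_phenotypes(values: np.ndarray, category: str = "context_avgmot",
                    samples=None) -> PhenotypeTable:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    n, m = values.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    cols = [f"y{j}" for j in range(m)]
    df = pd.DataFrame(values, index=pd.Index(samples, name="sample"), columns=cols)
    return PhenotypeTable(df, {c: category for c in cols})


def planted(seed, n_samples=150, n_markers=300, n_causal=3, heritability=0.6,
            mean_block=20, measures_per_category=4):
    """Small single-condition planted dataset for signal-recovery tests."""
    ss = np.random.SeedSequence(seed).spawn(4)
    panel = simulate_founder_panel(8, n_markers, seed=ss[0])
    g = simulate_hs_genomes(panel, n_samples, mean_block, seed=ss[1])
    cond = pd.DataFrame({"cohort": ["c1"] * n_samples,
                         "condition": ["sham"] * n_samples},
                        index=pd.Index(g.samples, name="sample"))
    rng = np.random.default_rng(ss[2])
    causal = list(rng.choice(g.markers, n_causal, replace=False))
    eff = rng.uniform(0.5, 1.5, n_causal) * rng.choice((-1.0, 1.0), n_causal)
    spec = ArchitectureSpec(effects={"sham": list(zip(causal, eff))},
                            heritability=heritability,
                            seed=int(ss[3].generate_state(1)[0] % 2**31))
    pheno, truth = simulate_phenotypes(g, spec, cond,
                                       measures_per_category=measures_per_category)
    return g, pheno, cond, truth


@pytest.fixture(scope="session")
def small_planted():
    return planted(seed=42)
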