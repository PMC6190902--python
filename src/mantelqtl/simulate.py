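"""Synthetic heterogeneous-stock-like genotypes and correlated,
condition-dependent phenotypes with known ground truth.

The generator emulates the structure of an 8-founder heterogeneous stock:
founder haplotypes carry biallelic markers at controlled minor allele
frequencies; each simulated animal is a pair of chromosome-wise founder
mosaics whose founder-of-origin switches as a Markov chain along ordered
markers (geometric block lengths), giving realistic local linkage without a
pedigree simulation.  Phenotype measures are built from a per-condition
additive genetic score (standardized within condition so heritability is a
variance fraction), a latent factor shared within each of six behavioral
categories, and independent noise; per-cohort mean offsets and variance
multipliers are applied last.  Which markers are causal in which condition
is a configuration knob, so shifted and shared architectures across
conditions can both be generated with known truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._seeds import as_seedseq
from .io import DEFAULT_CATEGORIES, GenotypeMatrix, PhenotypeTable

FOUNDER_STRAINS = ("A/J", "AKR/J", "BALB/cJ", "C3H/HeJ", "C57BL/6J", "CBA/J",
                   "DBA/2J", "LP/J")


@dataclass
class FounderPanel:
    """Founder haplotypes (founders x markers, alleles {0,1}) with a marker
    map and the minor-allele frequency each marker attains under equal
    founder mixing."""

    haplotypes: np.ndarray
    marker_map: pd.DataFrame  # index marker id; chrom, bp, ref, alt
    target_maf: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("founder alleles must be binary")
        if self.haplotypes.shape[1] != len(self.marker_map):
            raise ValueError("haplotypes and marker map disagree on marker count")
        for _, grp in self.marker_map.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if (np.diff(bp) <= 0).any():
                raise ValueError("positions must be strictly increasing within a chromosome")
        if (self.marker_map["bp"] < 1).any():
            raise ValueError("positions must be positive")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def markers(self) -> np.ndarray:
        return self.marker_map.index.to_numpy(dtype=object)


@dataclass
class ArchitectureSpec:
    """Phenotype architecture: per-condition causal effects, heritability,
    category structure and cohort shifts.

    ``effects`` maps condition label -> list of (marker id, additive effect).
    ``heritability`` is a fraction in [0, 1], either one value for all
    categories or a mapping category -> value.  ``within_correlation`` is the
    target total within-category Pearson correlation (the latent-factor share
    is solved internally so the realized correlation matches).
    ``cohort_shift`` maps cohort label -> (additive offset, variance
    multiplier).
    """

    effects: dict
    heritability: object = 0.3
    categories: dict = field(default_factory=dict)  # measure -> category
    within_correlation: object = 0.7
    cohort_shift: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        for h in self._heritabilities().values():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"heritability {h} outside [0, 1]")
        for cohort, (_, mult) in self.cohort_shift.items():
            if mult <= 0:
                raise ValueError(f"variance multiplier for {cohort!r} must be > 0")

    def _heritabilities(self) -> dict:
        cats = sorted(set(self.categories.values())) or list(DEFAULT_CATEGORIES)
        if isinstance(self.heritability, dict):
            return {c: float(self.heritability[c]) for c in cats}
        return {c: float(self.heritability) for c in cats}

    def _within_corr(self, category: str) -> float:
        if isinstance(self.within_correlation, dict):
            return float(self.within_correlation[category])
        return float(self.within_correlation)


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream evaluation."""

    causal: dict  # condition -> list of marker ids
    realized_heritability: dict  # measure -> realized genetic variance share
    cohorts: pd.Series
    conditions: pd.Series

    def to_yaml(self, path) -> None:
        doc = {
            "causal_markers": {k: list(map(str, v)) for k, v in self.causal.items()},
            "realized_heritability": {k: float(v) for k, v in
                                      self.realized_heritability.items()},
            "n_samples": int(len(self.conditions)),
            "condition_counts": {k: int(v) for k, v in
                                 self.conditions.value_counts().items()},
            "cohort_counts": {k: int(v) for k, v in
                              self.cohorts.value_counts().items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# founders


def simulate_founder_panel(
    n_founders: int = 8,
    n_markers: int = 2000,
    chrom_layout: dict | None = None,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed=None,
) -> FounderPanel:
    """Founder haplotypes whose equal-mixing population MAF lies in
    [maf_low, maf_high].

    With ``n_founders`` founders the attainable frequencies are multiples of
    1/n_founders; each marker draws a target in the requested band and uses
    the nearest attainable carrier count (so ``target_maf`` records the
    realized, not the drawn, value).  ``chrom_layout`` maps chromosome label
    -> marker count; by default markers are spread over 19 autosomes.
    """
    if n_founders < 1 or n_markers < 1:
        raise ValueError("n_founders and n_markers must be >= 1")
    if not 0.0 < maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    if chrom_layout is None:
        n_chrom = min(19, n_markers)
        base, extra = divmod(n_markers, n_chrom)
        chrom_layout = {f"chr{i + 1}": base + (i < extra) for i in range(n_chrom)}
    if sum(chrom_layout.values()) != n_markers:
        raise ValueError("chrom_layout marker counts must sum to n_markers")

    rows = []
    for chrom, count in chrom_layout.items():
        gaps = rng.integers(20_000, 200_000, size=count)
        pos = np.cumsum(gaps)
        for p in pos:
            rows.append((chrom, int(p)))
    markers = [f"m{i:05d}" for i in range(n_markers)]
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_markers)
    alt = rng.choice(bases, size=n_markers)
    alt[alt == ref] = np.where(ref[alt == ref] == "A", "G", "A")
    marker_map = pd.DataFrame(rows, columns=["chrom", "bp"])
    marker_map["ref"] = ref
    marker_map["alt"] = alt
    marker_map.index = pd.Index(markers, name="marker")

    k_max = n_founders // 2
    lo_k = max(1, math.ceil(n_founders * maf_low))
    hi_k = min(k_max, math.floor(n_founders * maf_high))
    haplotypes = np.zeros((n_founders, n_markers), dtype=np.int8)
    target = np.zeros(n_markers)
    for j in range(n_markers):
        if k_max < 1:
            k = 0  # a single founder cannot segregate
        elif lo_k <= hi_k:
            want = rng.uniform(maf_low, maf_high)
            k = int(np.clip(round(n_founders * want), lo_k, hi_k))
        else:
            k = max(1, min(k_max, round(n_founders * maf_low)))
        if k > 0:
            carriers = rng.choice(n_founders, size=k, replace=False)
            haplotypes[carriers, j] = 1
        target[j] = k / n_founders
    return FounderPanel(haplotypes, marker_map, target)


# ---------------------------------------------------------------------------
# mosaic genomes


def simulate_hs_genomes(
    panel: FounderPanel,
    n_samples: int,
    mean_block_markers: float = 20,
    seed=None,
) -> GenotypeMatrix:
    """Diploid founder mosaics: each sample carries two haplotypes per
    chromosome whose founder-of-origin switches with probability
    1/mean_block_markers at each marker step (geometric block lengths);
    dosage = sum of the two haplotype alleles, no missing values."""
    if panel.n_markers == 0:
        raise ValueError("empty founder panel")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mean_block_markers < 1:
        raise ValueError("mean_block_markers must be >= 1")
    rng = np.random.default_rng(seed)
    p_switch = 1.0 / mean_block_markers
    n_hap = 2 * n_samples
    dosages = np.empty((n_samples, panel.n_markers), dtype=np.int8)
    col = 0
    chrom_order = panel.marker_map["chrom"].to_numpy()
    for chrom in pd.unique(chrom_order):
        cols = np.flatnonzero(chrom_order == chrom)
        mc = len(cols)
        switch = rng.random((n_hap, mc)) < p_switch
        switch[:, 0] = True
        draws = rng.integers(0, panel.n_founders, size=(n_hap, mc))
        step = np.where(switch, np.arange(mc), -1)
        last = np.maximum.accumulate(step, axis=1)
        founder = np.take_along_axis(draws, last, axis=1)
        alleles = panel.haplotypes[founder, cols[None, :]]
        dosages[:, cols] = alleles[0::2] + alleles[1::2]
        col += mc
    samples = np.array([f"s{i:04d}" for i in range(n_samples)], dtype=object)
    return GenotypeMatrix(samples, panel.markers, dosages, panel.marker_map)


# ---------------------------------------------------------------------------
# architectures


def condition_architectures(
    markers,
    conditions,
    n_causal: int = 10,
    effect_scale: float = 1.0,
    overlap: float = 1.0,
    seed=None,
) -> dict:
    """Per-condition causal-marker lists with a configurable shared fraction.

    ``overlap`` = 1 gives every condition the same loci; 0 gives fully
    disjoint loci; intermediate values share round(overlap * n_causal) loci.
    Effects are drawn uniform in [0.5, 1.5] * effect_scale with random sign.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    markers = list(markers)
    conditions = list(conditions)
    n_shared = round(overlap * n_causal)
    n_own = n_causal - n_shared
    need = n_shared + n_own * len(conditions)
    if need > len(markers):
        raise ValueError(f"need {need} distinct causal markers, only {len(markers)} available")
    pool = list(rng.choice(len(markers), size=need, replace=False))
    shared = [markers[i] for i in pool[:n_shared]]
    # shared loci keep one effect across conditions: the architecture knob
    # shifts which loci act, not how the common ones act
    shared_eff = rng.uniform(0.5, 1.5, size=n_shared) * effect_scale
    shared_eff *= rng.choice((-1.0, 1.0), size=n_shared)
    out = {}
    at = n_shared
    for cond in conditions:
        own = [markers[i] for i in pool[at:at + n_own]]
        at += n_own
        own_eff = rng.uniform(0.5, 1.5, size=n_own) * effect_scale
        own_eff *= rng.choice((-1.0, 1.0), size=n_own)
        out[cond] = list(zip(shared + own, np.concatenate([shared_eff, own_eff])))
    return out


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    spec: ArchitectureSpec,
    conditions: pd.DataFrame,
    measures_per_category: int = 4,
) -> tuple[PhenotypeTable, GroundTruth]:
    """Condition-dependent phenotypes over six correlated categories.

    For sample i with condition label c(i), measure j in category C:

        y_ij = sqrt(h2_C) * Gtilde_i + sqrt(1 - h2_C) *
               (sqrt(lam_C) * L_iC + sqrt(1 - lam_C) * eps_ij)

    where Gtilde is the per-condition additive genetic score standardized
    within condition, L_iC a standard-normal latent factor shared by the
    category's measures and lam_C is solved so the total within-category
    correlation matches the target (h2 + (1 - h2) * lam = target).  Cohort
    offsets and variance multipliers are applied last.
    """
    samples = list(genotypes.samples)
    missing = set(samples) - set(conditions.index)
    if missing:
        raise ValueError(f"samples without condition labels: {sorted(missing)[:5]}")
    cond = conditions.loc[samples]
    labels = cond["condition"].to_numpy()
    unknown = set(labels) - set(spec.effects)
    if unknown:
        raise ValueError(f"condition labels without an architecture: {sorted(unknown)}")
    for c, eff in spec.effects.items():
        bad = [m for m, _ in eff if m not in set(genotypes.markers)]
        if bad:
            raise ValueError(f"architecture for {c!r} references unknown markers {bad[:5]}")

    rng = np.random.default_rng(spec.seed)
    n = len(samples)
    marker_pos = {m: i for i, m in enumerate(genotypes.markers)}

    # per-condition genetic score, standardized within condition
    score = np.zeros(n)
    for c, eff in spec.effects.items():
        mask = labels == c
        if not mask.any():
            continue
        s = np.zeros(mask.sum())
        for m, e in eff:
            s += e * genotypes.dosages[mask, marker_pos[m]]
        sd = s.std()
        score[mask] = (s - s.mean()) / sd if sd > 0 else 0.0

    categories = spec.categories
    if not categories:
        categories = {
            f"{cat}_{i + 1}": cat
            for cat in DEFAULT_CATEGORIES
            for i in range(measures_per_category)
        }
    h2 = spec._heritabilities()
    cats = sorted(set(categories.values()))
    latent = {c: rng.standard_normal(n) for c in cats}

    values = {}
    realized = {}
    for measure, cat in categories.items():
        h = h2[cat]
        rho = spec._within_corr(cat)
        lam = 0.0 if h >= 1.0 else float(np.clip((rho - h) / (1.0 - h), 0.0, 1.0))
        env = math.sqrt(lam) * latent[cat] + math.sqrt(1.0 - lam) * rng.standard_normal(n)
        y = math.sqrt(h) * score + math.sqrt(1.0 - h) * env
        tot = y.var()
        realized[measure] = float(h * score.var() / tot) if tot > 0 else 0.0
        values[measure] = y

    df = pd.DataFrame(values, index=pd.Index(samples, name="sample"))
    for cohort, (offset, mult) in spec.cohort_shift.items():
        mask = (cond["cohort"] == cohort).to_numpy()
        if mask.any():
            df.loc[mask] = df.loc[mask] * math.sqrt(mult) + offset

    truth = GroundTruth(
        causal={c: [m for m, _ in eff] for c, eff in spec.effects.items()},
        realized_heritability=realized,
        cohorts=cond["cohort"],
        conditions=cond["condition"],
    )
    return PhenotypeTable(df, dict(categories)), truth


# ---------------------------------------------------------------------------
# whole datasets


def default_conditions(
    n_samples: int,
    cohort_fractions: dict | None = None,
    condition_fractions: dict | None = None,
    seed=None,
) -> pd.DataFrame:
    """Random cohort and irradiation-arm labels in study-like proportions:
    two cohorts (1:2) and four arms (sham, fe, si, gamma, equal sizes)."""
    rng = np.random.default_rng(seed)
    cohort_fractions = cohort_fractions or {"cohort1": 1 / 3, "cohort2": 2 / 3}
    condition_fractions = condition_fractions or {
        "sham": 0.25, "fe": 0.25, "si": 0.25, "gamma": 0.25}
    samples = [f"s{i:04d}" for i in range(n_samples)]
    cohorts = rng.choice(list(cohort_fractions), size=n_samples,
                         p=np.array(list(cohort_fractions.values()))
                         / sum(cohort_fractions.values()))
    conds = rng.choice(list(condition_fractions), size=n_samples,
                       p=np.array(list(condition_fractions.values()))
                       / sum(condition_fractions.values()))
    return pd.DataFrame({"cohort": cohorts, "condition": conds},
                        index=pd.Index(samples, name="sample"))


def simulate_dataset(
    n_samples: int = 400,
    n_markers: int = 2000,
    n_founders: int = 8,
    mean_block_markers: float = 20,
    n_causal: int = 10,
    heritability: object = 0.3,
    within_correlation: object = 0.7,
    architecture_overlap: float = 1.0,
    cohort_shift: dict | None = None,
    conditions: pd.DataFrame | None = None,
    seed=None,
):
    """One self-consistent dataset: panel, genomes, labels, phenotypes, truth.

    Returns (GenotypeMatrix, PhenotypeTable, conditions, GroundTruth).
    """
    ss = as_seedseq(seed).spawn(5)
    panel = simulate_founder_panel(n_founders, n_markers, seed=ss[0])
    g = simulate_hs_genomes(panel, n_samples, mean_block_markers, seed=ss[1])
    if conditions is None:
        conditions = default_conditions(n_samples, seed=ss[2])
    else:
        conditions = conditions.loc[list(g.samples)]
    if cohort_shift is None:
        cohort_shift = {"cohort1": (0.0, 1.0), "cohort2": (0.5, 1.5)}
    effects = condition_architectures(
        list(g.markers), sorted(set(conditions["condition"])),
        n_causal=n_causal, overlap=architecture_overlap, seed=ss[3])
    spec = ArchitectureSpec(
        effects=effects, heritability=heritability,
        within_correlation=within_correlation, cohort_shift=cohort_shift,
        seed=int(ss[4].generate_state(1)[0] % (2 ** 31)))
    pheno, truth = simulate_phenotypes(g, spec, conditions)
    return g, pheno, conditions, truth


__all__ = [
    "FounderPanel", "ArchitectureSpec", "GroundTruth", "FOUNDER_STRAINS",
    "simulate_founder_panel", "simulate_hs_genomes", "simulate_phenotypes",
    "condition_architectures", "default_conditions", "simulate_dataset",
]
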