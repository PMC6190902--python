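"""Overlap of significant marker sets detected under different conditions.

Two marker sets detected independently (in two cohorts, or in sham versus
irradiated animals) are cross-tabulated over a shared marker universe and
tested with the two-sided Fisher exact test.  The odds ratio carries the
directional claim: a confidence interval above 1 means the two conditions
recover overlapping genetic architectures; an odds ratio at or below 1 means
the overlap is no better than chance (the architecture shifted).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import as_seedseq
from .distance import DistanceMatrix, phenotype_distance
from .io import GenotypeMatrix, PhenotypeTable
from .selection import marker_set_analysis

logger = logging.getLogger(__name__)

DEFAULT_STRATUM_FLOOR = 30


@dataclass
class OverlapResult:
    """2x2 marker-membership table with OR, Woolf CI95 and Fisher exact p.

    a = in both sets, b = set A only, c = set B only, d = in neither.
    ``odds_ratio`` is the plain cross-product ratio (a*d)/(b*c); when any cell
    is zero the Haldane-Anscombe +0.5 correction is used for both the point
    estimate and the CI, and ``corrected`` is set.  ``degenerate`` flags an
    empty margin (an empty marker set), where the OR is undefined.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    universe_size: int
    corrected: bool = False
    degenerate: bool = False

    @property
    def table(self):
        return np.array([[self.a, self.b], [self.c, self.d]])


def overlap_table(set_a, set_b, universe) -> np.ndarray:
    """Exact membership cross-tabulation [[a, b], [c, d]] over the universe."""
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    if not set_a <= universe:
        raise ValueError(f"set A members outside universe: {sorted(set_a - universe)[:5]}")
    if not set_b <= universe:
        raise ValueError(f"set B members outside universe: {sorted(set_b - universe)[:5]}")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    return np.array([[a, b], [c, d]])


def fisher_overlap(table) -> OverlapResult:
    """Fisher exact test and Woolf log-OR CI95 for a 2x2 membership table."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    a, b, c, d = (int(x) for x in table.ravel())
    n = a + b + c + d
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if degenerate:
        # an empty set (or set = universe) leaves the OR undefined
        return OverlapResult(a, b, c, d, math.nan, math.nan, math.nan,
                             float(p), n, degenerate=True)
    corrected = min(a, b, c, d) == 0
    if corrected:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = math.exp(math.log(or_) - 1.959963984540054 * se)
    hi = math.exp(math.log(or_) + 1.959963984540054 * se)
    return OverlapResult(a, b, c, d, or_, lo, hi, float(p), n,
                         corrected=corrected)


def compare_two_strata(
    g_a: GenotypeMatrix,
    d_a: DistanceMatrix,
    g_b: GenotypeMatrix,
    d_b: DistanceMatrix,
    universe,
    set_definition: str = "peak",
    seed=None,
    **params,
) -> tuple[OverlapResult, dict]:
    """Run the full scan -> gate -> forward-selection pipeline independently
    in two strata and Fisher-test the overlap of the detected marker sets.

    ``set_definition`` picks which set enters the overlap: the forward-
    selected ``"peak"`` set (default) or all ``"gate"``-passing markers.
    Both definitions are reported in the returned detail dict.
    """
    if set_definition not in ("peak", "gate"):
        raise ValueError("set_definition must be 'peak' or 'gate'")
    ss = as_seedseq(seed).spawn(2)
    res_a = marker_set_analysis(g_a, d_a, seed=ss[0], **params)
    res_b = marker_set_analysis(g_b, d_b, seed=ss[1], **params)
    sets = {
        "peak": (res_a.peak_markers, res_b.peak_markers),
        "gate": (res_a.eligible, res_b.eligible),
    }
    sa, sb = sets[set_definition]
    result = fisher_overlap(overlap_table(sa, sb, universe))
    detail = {
        "peak_sizes": (len(res_a.peak_markers), len(res_b.peak_markers)),
        "gate_sizes": (len(res_a.eligible), len(res_b.eligible)),
        "peak_values": (res_a.peak_value, res_b.peak_value),
        "analyses": (res_a, res_b),
    }
    logger.info("overlap (%s sets): a=%d b=%d c=%d d=%d OR=%.3g p=%.3g",
                set_definition, result.a, result.b, result.c, result.d,
                result.odds_ratio, result.p)
    return result, detail


def compare_conditions(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    conditions: pd.DataFrame,
    split: str = "cohort",
    categories=None,
    stratum_floor: int = DEFAULT_STRATUM_FLOOR,
    standardize: bool = True,
    set_definition: str = "peak",
    seed=None,
    **params,
) -> dict:
    """Per-category overlap of marker sets between two sample strata.

    ``split`` is ``"cohort"`` (the two cohort labels) or
    ``"sham_vs_irradiated"`` (condition == 'sham' versus everything else,
    all radiation types combined).  Strata are analyzed fully independently
    over the shared post-MAF marker universe of ``g``; each stratum must have
    at least ``stratum_floor`` samples.
    """
    if not np.array_equal(g.samples, np.asarray(pheno.samples, dtype=object)):
        raise ValueError("genotype and phenotype samples are not aligned")
    cond = conditions.loc[list(g.samples)]
    if split == "cohort":
        labels = cond["cohort"].to_numpy()
        values = sorted(set(labels))
        if len(values) != 2:
            raise ValueError(f"cohort split needs exactly 2 cohorts, found {values}")
        mask_a = labels == values[0]
    elif split == "sham_vs_irradiated":
        labels = cond["condition"].to_numpy()
        if "sham" not in labels:
            raise ValueError("no 'sham' condition labels found")
        mask_a = labels == "sham"
        values = ["sham", "irradiated"]
    else:
        raise ValueError(f"unknown split {split!r}")
    mask_b = ~mask_a
    for name, mask in zip(values, (mask_a, mask_b)):
        if mask.sum() < stratum_floor:
            raise ValueError(
                f"stratum {name!r} has {int(mask.sum())} samples, below the "
                f"floor of {stratum_floor}")
    ids_a = list(g.samples[mask_a])
    ids_b = list(g.samples[mask_b])
    g_a, g_b = g.subset_samples(ids_a), g.subset_samples(ids_b)
    p_a, p_b = pheno.subset_samples(ids_a), pheno.subset_samples(ids_b)
    universe = list(g.markers)
    if categories is None:
        categories = pheno.category_names
    out = {}
    ss = as_seedseq(seed).spawn(len(categories))
    for cat, child in zip(categories, ss):
        d_a = phenotype_distance(p_a, cat, standardize=standardize)
        d_b = phenotype_distance(p_b, cat, standardize=standardize)
        result, detail = compare_two_strata(
            g_a, d_a, g_b, d_b, universe, set_definition=set_definition,
            seed=child, **params)
        out[cat] = (result, detail)
    return out


def overlap_report(results: dict, path) -> None:
    """Per-category TSV (a, b, c, d, OR, CI, p) mirroring the figure tables."""
    with open(path, "w") as fh:
        fh.write("category\ta\tb\tc\td\todds_ratio\tci_low\tci_high\tp\tuniverse\n")
        for cat, (res, _) in results.items():
            fh.write(
                f"{cat}\t{res.a}\t{res.b}\t{res.c}\t{res.d}\t"
                f"{res.odds_ratio:.6g}\t{res.ci_low:.6g}\t{res.ci_high:.6g}\t"
                f"{res.p:.6g}\t{res.universe_size}\n")


__all__ = [
    "OverlapResult", "overlap_table", "fisher_overlap",
    "compare_two_strata", "compare_conditions", "overlap_report",
    "DEFAULT_STRATUM_FLOOR",
]
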