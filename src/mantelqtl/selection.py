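"""Forward selection of marker sets along the scan ranking, the cumulative
Mantel correlation curve, and peak/plateau detection.

Markers enter in decreasing order of their single-marker association (the
scan ranking), gated at an individual permutation p-value below ``p_gate``
(default 0.01).  Because the Manhattan genotype distance over a marker set is
the sum of single-marker distances, the cumulative correlation at set size k
is updated incrementally; the result equals recomputing the full distance
matrix at every k.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix
from .io import GenotypeMatrix
from .mantel import (ScanResult, _condensed_moments, _xp_cross_sums_percol,
                     marker_pair_moments, pearson_from_moments,
                     single_marker_scan)

logger = logging.getLogger(__name__)

DEFAULT_P_GATE = 0.01
DEFAULT_PLATEAU_TOL = 0.02
DEFAULT_MAX_K = 1000


@dataclass
class SelectionCurve:
    """Ordered included markers m_1..m_K with the cumulative correlation c_k."""

    markers: np.ndarray
    c: np.ndarray
    p_gate: float
    metric: str = "manhattan_dosage"

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers, dtype=object)
        self.c = np.asarray(self.c, dtype=np.float64)
        if len(self.markers) != len(self.c):
            raise ValueError("markers and c have different lengths")

    def __len__(self) -> int:
        return len(self.c)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("k\tmarker\tc_k\n")
            for k, (m, ck) in enumerate(zip(self.markers, self.c), start=1):
                fh.write(f"{k}\t{m}\t{ck:.10g}\n")


@dataclass
class MarkerSetAnalysis:
    """One stratum/category run: scan -> gate -> curve -> peak."""

    scan: ScanResult
    eligible: list
    curve: SelectionCurve | None
    k_star: int | None
    peak_markers: list
    peak_value: float | None

    def peak_summary(self) -> dict:
        return {
            "n_eligible": len(self.eligible),
            "k_star": self.k_star,
            "peak_value": self.peak_value,
            "peak_markers": list(self.peak_markers),
        }


def eligible_markers(scan: ScanResult, p_gate: float = DEFAULT_P_GATE) -> list:
    """Markers with permutation p strictly below the gate, in scan rank order."""
    t = scan.table
    out = list(t.loc[t["p"] < p_gate, "marker"])
    if not out:
        logger.info("no markers pass the p < %g gate", p_gate)
    return out


def cumulative_curve(
    g: GenotypeMatrix,
    pheno_d: DistanceMatrix,
    ordered_markers,
    max_k: int | None = None,
    metric: str = "manhattan_dosage",
) -> SelectionCurve:
    """c_k = Mantel correlation of the first-k-marker genotype distance with
    the phenotype distance, for k = 1..max_k.

    Uses Manhattan additivity to accumulate pair distances marker by marker;
    the cross and marginal moments are tracked exactly (integer-valued
    floats), so the result matches a from-scratch recomputation at every k.
    """
    ordered_markers = list(ordered_markers)
    if not ordered_markers:
        raise ValueError("ordered_markers must be nonempty")
    if not np.array_equal(g.samples, pheno_d.ids):
        raise ValueError("genotype and phenotype samples are not aligned")
    if max_k is None:
        max_k = min(len(ordered_markers), DEFAULT_MAX_K)
    ordered_markers = ordered_markers[:max_k]

    sub = g.subset_markers(ordered_markers)
    D = sub.dosages
    n = g.n_samples
    P = pheno_d.values
    row = P.sum(axis=0)
    n_pairs, sum_p, sum_p2 = _condensed_moments(P)

    H0 = (D == 0).astype(np.float64)
    H2 = (D == 2).astype(np.float64)
    s_single = _xp_cross_sums_percol(P, row, H0, H2, metric)
    n0 = H0.sum(axis=0)
    n2 = H2.sum(axis=0)
    sx_single, _ = marker_pair_moments(n0, n - n0 - n2, n2, metric)

    iu, jv = np.triu_indices(n, 1)
    gv = D.astype(np.float64)
    cum = np.zeros(n_pairs)
    s_xp = 0.0
    sum_x = 0.0
    sum_x2 = 0.0
    c = np.empty(len(ordered_markers))
    for k in range(len(ordered_markers)):
        if metric == "manhattan_dosage":
            xk = np.abs(gv[iu, k] - gv[jv, k])
        else:
            xk = (gv[iu, k] != gv[jv, k]).astype(np.float64)
        s_xp += s_single[k]
        sum_x += sx_single[k]
        sum_x2 += 2.0 * (cum @ xk) + (xk @ xk)
        cum += xk
        c[k] = pearson_from_moments(s_xp, sum_x, sum_x2, sum_p, sum_p2, n_pairs)
    return SelectionCurve(np.array(ordered_markers, dtype=object), c,
                          p_gate=np.nan, metric=metric)


def select_peak(curve: SelectionCurve, plateau_tol: float = DEFAULT_PLATEAU_TOL):
    """Earliest entry into the plateau of the cumulative correlation.

    Returns (k_star, markers m_1..m_{k_star}) where k_star is the smallest k
    with c_k >= (1 - plateau_tol) * max_k c_k.
    """
    if len(curve) == 0:
        raise ValueError("empty selection curve")
    if plateau_tol < 0:
        raise ValueError("plateau_tol must be >= 0")
    cmax = curve.c.max()
    k_star = int(np.argmax(curve.c >= (1.0 - plateau_tol) * cmax)) + 1
    return k_star, list(curve.markers[:k_star])


def marker_set_analysis(
    g: GenotypeMatrix,
    pheno_d: DistanceMatrix,
    B: int = 999,
    seed=None,
    p_gate: float = DEFAULT_P_GATE,
    max_k: int | None = None,
    plateau_tol: float = DEFAULT_PLATEAU_TOL,
    metric: str = "manhattan_dosage",
    scan_mode: str = "gate",
) -> MarkerSetAnalysis:
    """The full per-stratum procedure: scan, gate, forward-select, find peak."""
    scan = single_marker_scan(g, pheno_d, B=B, seed=seed, mode=scan_mode,
                              p_gate=p_gate, metric=metric)
    elig = eligible_markers(scan, p_gate)
    if not elig:
        return MarkerSetAnalysis(scan, [], None, None, [], None)
    curve = cumulative_curve(g, pheno_d, elig, max_k=max_k, metric=metric)
    curve.p_gate = p_gate
    k_star, peak = select_peak(curve, plateau_tol)
    return MarkerSetAnalysis(scan, elig, curve, k_star, peak,
                             float(curve.c[k_star - 1]))


def write_peak_summary(analysis: MarkerSetAnalysis, path) -> None:
    with open(path, "w") as fh:
        json.dump(analysis.peak_summary(), fh, indent=2)


__all__ = [
    "SelectionCurve", "MarkerSetAnalysis", "eligible_markers",
    "cumulative_curve", "select_peak", "marker_set_analysis",
    "write_peak_summary", "DEFAULT_P_GATE", "DEFAULT_PLATEAU_TOL",
    "DEFAULT_MAX_K",
]
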