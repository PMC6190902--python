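"""Mantel correlation between distance matrices, permutation testing, and the
single-marker genome scan.

The Mantel statistic is the Pearson correlation over the N(N-1)/2 upper
off-diagonal entries of two pairwise distance matrices; its p-value comes from
jointly permuting the rows and columns of one matrix (relabelling samples) and
uses the add-one estimator p = (b + 1)/(B + 1), so p is never zero and the
smallest attainable value with B = 1000 is 1/1001.

The genome scan exploits the fact that a single biallelic marker partitions
samples into at most three dosage classes, so the only permutation-dependent
part of the statistic is a cross-sum between phenotype-distance blocks and the
class-indicator vectors.  That cross-sum is computed for all markers at once
with two matrix products per permutation, which is what makes whole-scan
randomization ensembles affordable.  Each marker draws its permutations from
its own seed stream (spawned from the scan seed by marker position), so
results do not depend on execution order or on which other markers are
scanned.

When only the gate decision ``p < p_gate`` is needed (``mode="gate"``, used by
the null-curve ensembles), a marker's permutation stream is truncated as soon
as its exceedance count can no longer pass the gate.  The eligible set is
provably identical to the full-B scan; truncated markers report the add-one p
over the permutations actually drawn, which is always on the ineligible side
of the gate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import as_seedseq
from .distance import DistanceMatrix
from .io import GenotypeMatrix

logger = logging.getLogger(__name__)


class DegenerateDistanceError(ValueError):
    """A distance matrix has constant off-diagonal entries; r is undefined."""


class EmptyScanError(ValueError):
    """No polymorphic markers to scan."""


@dataclass
class MantelResult:
    r: float
    B: int
    exceed: int
    p: float
    seed: object
    alternative: str = "greater"


@dataclass
class ScanResult:
    """Ranked per-marker Mantel correlations and permutation p-values.

    ``table`` is ordered by the ranking keys (r descending, p ascending, then
    marker-map order) and has columns marker, chrom, bp, r, p, exceed, n_perm.
    """

    table: pd.DataFrame
    B: int
    seed: object
    mode: str
    p_gate: float | None
    skipped: list

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pairwise Mantel


def _check_aligned(d1: DistanceMatrix, d2: DistanceMatrix) -> None:
    if d1.n != d2.n or not np.array_equal(d1.ids, d2.ids):
        raise ValueError("distance matrices have different sample ids or ordering")
    if d1.n < 3:
        raise ValueError("Mantel statistic needs at least 3 samples")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(xc @ xc)
    sy = math.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateDistanceError("constant off-diagonal distances; Mantel r undefined")
    return float((xc @ yc) / (sx * sy))


def mantel_statistic(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Pearson correlation over the upper off-diagonal entries of d1 and d2."""
    _check_aligned(d1, d2)
    return _pearson(d1.condensed(), d2.condensed())


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    B: int = 999,
    seed=None,
    alternative: str = "greater",
) -> MantelResult:
    """Permutation Mantel test; permutes sample labels of ``d2``.

    One-sided by default (large positive r = genotype similarity predicts
    phenotype similarity); ``alternative="two-sided"`` compares |r|.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    _check_aligned(d1, d2)
    x = d1.condensed()
    y2 = d2.values
    r_obs = _pearson(x, d2.condensed())
    rng = np.random.default_rng(seed)
    n = d1.n
    iu = np.triu_indices(n, 1)
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(n)
        yp = y2[np.ix_(perm, perm)]
        r_p = _pearson(x, yp[iu])
        if alternative == "greater":
            exceed += r_p >= r_obs
        else:
            exceed += abs(r_p) >= abs(r_obs)
    p = (exceed + 1) / (B + 1)
    return MantelResult(r=r_obs, B=B, exceed=int(exceed), p=p, seed=seed,
                        alternative=alternative)


# ---------------------------------------------------------------------------
# scan engine internals


def _condensed_moments(values: np.ndarray):
    """(n_pairs, sum, sum of squares) over the upper off-diagonal of a
    symmetric matrix with zero diagonal."""
    n = values.shape[0]
    n_pairs = n * (n - 1) // 2
    s = float(values.sum()) / 2.0
    s2 = float((values * values).sum()) / 2.0
    return n_pairs, s, s2


def pearson_from_moments(s_xy, sum_x, sum_x2, sum_y, sum_y2, n_pairs):
    """Pearson r from raw cross/marginal moments over n_pairs entries.

    Shared by the scan and the cumulative-curve code so that a one-marker
    curve reproduces the scan statistic bit for bit.
    """
    mean_x = sum_x / n_pairs
    mean_y = sum_y / n_pairs
    var_x = sum_x2 / n_pairs - mean_x * mean_x
    var_y = sum_y2 / n_pairs - mean_y * mean_y
    if var_x <= 0 or var_y <= 0:
        raise DegenerateDistanceError("constant off-diagonal distances; Mantel r undefined")
    return (s_xy / n_pairs - mean_x * mean_y) / math.sqrt(var_x * var_y)


def marker_pair_moments(n0, n1, n2, metric: str):
    """Sum and sum of squares of the single-marker pair distances X_ij over
    all sample pairs, from the dosage class counts alone.

    manhattan_dosage: X in {0,1,2} (2 only for 0-vs-2 pairs);
    ibs_mismatch:     X in {0,1}.
    """
    cross01 = n0 * n1 + n1 * n2
    cross02 = n0 * n2
    if metric == "manhattan_dosage":
        return cross01 + 2 * cross02, cross01 + 4 * cross02
    s = cross01 + cross02
    return s, s


def _xp_cross_sums(P, row, H0, H2, metric: str):
    """sum_{i<j} X_ij P_ij for every marker column, where X is the
    single-marker distance implied by the dosage-class indicators.

    ``H0``/``H2`` are (N, M) indicator arrays for dosage 0 and 2 (float).
    Derivation collapses the class-block sums so that only two matrix
    products are needed:
      manhattan: S = row.H0 + row.H2 - H0'PH0 - H2'PH2
      ibs:       S = row.H0 + row.H2 - H0'PH0 - H2'PH2 - H0'PH2
    """
    PH0 = P @ H0
    a = np.einsum("nm,nm->m", H0, PH0)
    b = np.einsum("nm,nm->m", H2, P @ H2)
    s = row @ H0 + row @ H2 - a - b
    if metric == "ibs_mismatch":
        s = s - np.einsum("nm,nm->m", H2, PH0)
    return s


def _xp_cross_sums_percol(P, row, H0, H2, metric: str):
    """Column-at-a-time variant of :func:`_xp_cross_sums`.

    Used for the observed statistics (scan and cumulative curve) so the same
    marker always yields the bit-identical cross-sum regardless of how many
    markers are evaluated together; the batched variant's BLAS result can
    differ in the last ulp with the batch width.
    """
    m = H0.shape[1]
    out = np.empty(m)
    for j in range(m):
        h0 = H0[:, j]
        h2 = H2[:, j]
        ph0 = P @ h0
        s = row @ h0 + row @ h2 - h0 @ ph0 - h2 @ (P @ h2)
        if metric == "ibs_mismatch":
            s -= h2 @ ph0
        out[j] = s
    return out


def _batch_schedule(B: int, first: int = 16):
    out, nb, left = [], first, B
    while left > 0:
        take = min(nb, left)
        out.append(take)
        left -= take
        nb *= 2
    return out


def single_marker_scan(
    g: GenotypeMatrix,
    pheno_d: DistanceMatrix,
    B: int = 999,
    seed=None,
    mode: str = "exact",
    p_gate: float = 0.01,
    metric: str = "manhattan_dosage",
) -> ScanResult:
    """Mantel-correlate every marker's distance matrix with ``pheno_d``.

    Monomorphic markers are skipped with a log entry.  ``B = 0`` computes the
    correlations only (all p = 1), which is enough for rank-based uses.
    ``mode="gate"`` truncates permutation streams once a marker can no longer
    pass ``p < p_gate`` (see module docstring); ``mode="exact"`` runs all B
    permutations for every marker.
    """
    if mode not in ("exact", "gate"):
        raise ValueError(f"mode must be 'exact' or 'gate', got {mode!r}")
    if B < 0:
        raise ValueError("B must be >= 0")
    if not np.array_equal(g.samples, pheno_d.ids):
        raise ValueError("genotype and phenotype samples are not aligned")
    n = g.n_samples
    if n < 3:
        raise ValueError("scan needs at least 3 samples")

    D = g.dosages
    H0_all = D == 0
    H2_all = D == 2
    n0 = H0_all.sum(axis=0)
    n2 = H2_all.sum(axis=0)
    n1 = n - n0 - n2
    poly = ~((n0 == n) | (n1 == n) | (n2 == n))
    skipped = list(g.markers[~poly])
    if skipped:
        logger.info("skipping %d monomorphic markers", len(skipped))
    if not poly.any():
        raise EmptyScanError("no polymorphic markers to scan")

    markers = g.markers[poly]
    m = len(markers)
    H0 = H0_all[:, poly]
    H2 = H2_all[:, poly]
    sum_x, sum_x2 = marker_pair_moments(
        n0[poly].astype(np.float64), n1[poly].astype(np.float64),
        n2[poly].astype(np.float64), metric)

    P = pheno_d.values
    row = P.sum(axis=0)
    n_pairs, sum_p, sum_p2 = _condensed_moments(P)

    # observed statistics in float64
    s_obs = _xp_cross_sums_percol(P, row, H0.astype(np.float64),
                                  H2.astype(np.float64), metric)
    r = np.array([
        pearson_from_moments(s_obs[j], sum_x[j], sum_x2[j], sum_p, sum_p2, n_pairs)
        for j in range(m)
    ])

    exceed = np.zeros(m, dtype=np.int64)
    n_perm = np.zeros(m, dtype=np.int64)
    if B > 0:
        _permutation_pass(P, row, H0, H2, metric, s_obs, B, seed, mode, p_gate,
                          exceed, n_perm)
        p = (exceed + 1) / (n_perm + 1)
    else:
        p = np.ones(m)

    mp = g.marker_map.loc[markers]
    order = np.lexsort((np.arange(m), p, -r))
    table = pd.DataFrame({
        "marker": markers[order],
        "chrom": mp["chrom"].to_numpy()[order],
        "bp": mp["bp"].to_numpy()[order],
        "r": r[order],
        "p": p[order],
        "exceed": exceed[order],
        "n_perm": n_perm[order],
    })
    return ScanResult(table=table, B=B, seed=seed, mode=mode,
                      p_gate=p_gate if mode == "gate" else None, skipped=skipped)


def _permutation_pass(P, row, H0, H2, metric, s_obs, B, seed, mode, p_gate,
                      exceed, n_perm):
    """Fill ``exceed``/``n_perm`` in place for every marker column."""
    n, m = H0.shape
    P32 = P.astype(np.float32)
    row32 = row.astype(np.float32)
    H0_8 = H0.astype(np.int8)
    H2_8 = H2.astype(np.int8)
    # observed cross-sums through the same float32 path the permutations use,
    # so exceedance comparisons are internally consistent
    s_obs32 = _xp_cross_sums(P32, row32, H0_8.astype(np.float32),
                             H2_8.astype(np.float32), metric)
    if mode == "gate":
        # eligible iff (b+1)/(B+1) < p_gate  <=>  b <= ceil(p_gate*(B+1)) - 2
        b_max = math.ceil(p_gate * (B + 1)) - 2
        if b_max < 0:
            raise ValueError(
                f"p_gate={p_gate} unattainable with B={B}; smallest p is 1/{B + 1}")
    else:
        b_max = B  # never truncate
    rngs = [np.random.default_rng(s) for s in as_seedseq(seed).spawn(m)]
    active = np.arange(m)
    for nb in _batch_schedule(B):
        ma = len(active)
        idx = np.empty((nb, n, ma), dtype=np.int16)
        for t, j in enumerate(active):
            idx[:, :, t] = np.argsort(rngs[j].random((nb, n)), axis=1).astype(np.int16)
        h0a = H0_8[:, active]
        h2a = H2_8[:, active]
        sa_obs = s_obs32[active]
        b_batch = np.zeros(ma, dtype=np.int64)
        for s in range(nb):
            h0p = np.take_along_axis(h0a, idx[s], axis=0).astype(np.float32)
            h2p = np.take_along_axis(h2a, idx[s], axis=0).astype(np.float32)
            s_perm = _xp_cross_sums(P32, row32, h0p, h2p, metric)
            b_batch += s_perm >= sa_obs
        exceed[active] += b_batch
        n_perm[active] += nb
        if mode == "gate":
            active = active[exceed[active] <= b_max]
            if len(active) == 0:
                break


__all__ = [
    "MantelResult", "ScanResult", "DegenerateDistanceError", "EmptyScanError",
    "mantel_statistic", "mantel_test", "single_marker_scan",
    "pearson_from_moments", "marker_pair_moments",
]
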