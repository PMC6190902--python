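"""Label-shuffled empirical null for the whole selection procedure, and the
Z-scores that calibrate an observed cumulative-correlation curve against it.

Each of the R randomizations shuffles the phenotype sample labels (breaking
only the genotype-phenotype link) and repeats the *entire* procedure —
re-scan, re-gate, re-select — with the same parameters as the observed
analysis.  The observed curve is then expressed per set size k as
Z_k = (c_k - mu_k) / sigma_k against the null mean and (R-1)-divisor standard
deviation.  Under the null the one-sided normal tail at Z = 3 is 0.00135, so
sustained Z > 3 marks marker sets unlikely to arise by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._seeds import as_seedseq
from .distance import DistanceMatrix
from .io import GenotypeMatrix
from .selection import (DEFAULT_MAX_K, DEFAULT_P_GATE, SelectionCurve,
                        marker_set_analysis)

logger = logging.getLogger(__name__)


@dataclass
class NullCurveEnsemble:
    """R null selection curves, right-padded by carrying each curve's last
    value, with per-k mean and standard deviation."""

    curves: np.ndarray  # (R, L) padded
    lengths: np.ndarray  # (R,) original curve lengths (0 = no eligible markers)
    mu: np.ndarray
    sigma: np.ndarray  # ddof=1
    seed: object
    params: dict

    @property
    def R(self) -> int:
        return self.curves.shape[0]

    def padded_to(self, length: int) -> "NullCurveEnsemble":
        """Extend (or view) the ensemble at a given curve length."""
        R, L = self.curves.shape
        if length <= L:
            cur = self.curves[:, :length]
        else:
            cur = np.concatenate(
                [self.curves, np.repeat(self.curves[:, -1:], length - L, axis=1)],
                axis=1)
        return NullCurveEnsemble(cur, self.lengths, cur.mean(axis=0),
                                 cur.std(axis=0, ddof=1), self.seed, self.params)

    def to_tsv(self, path, observed: "SelectionCurve | None" = None) -> None:
        z = z_curve(observed, self).z if observed is not None else None
        with open(path, "w") as fh:
            fh.write("k\tmu_k\tsigma_k" + ("\tZ_k" if z is not None else "") + "\n")
            L = len(self.mu) if z is None else len(z)
            ens = self.padded_to(L)
            for k in range(L):
                line = f"{k + 1}\t{ens.mu[k]:.10g}\t{ens.sigma[k]:.10g}"
                if z is not None:
                    line += f"\t{z[k]:.10g}"
                fh.write(line + "\n")


@dataclass
class ZCurve:
    """Per-k Z-scores; NaN (flagged in ``undefined``) where sigma_k = 0."""

    z: np.ndarray
    undefined: np.ndarray  # bool mask where sigma_k == 0

    def max(self) -> float:
        if np.all(self.undefined):
            return float("nan")
        return float(np.nanmax(self.z))


def null_ensemble(
    g: GenotypeMatrix,
    pheno_d: DistanceMatrix,
    R: int = 25,
    seed=None,
    B: int = 999,
    p_gate: float = DEFAULT_P_GATE,
    max_k: int | None = None,
    plateau_tol: float = 0.02,
    metric: str = "manhattan_dosage",
) -> NullCurveEnsemble:
    """Build the empirical null by R phenotype-label shuffles.

    The identity permutation is excluded.  A shuffle yielding zero eligible
    markers contributes a flat zero curve (logged).  The scans inside the
    ensemble run in gate mode: only the p < p_gate decision and the ranking
    matter for the null curves, so permutation streams are truncated once a
    marker is out of contention (the eligible sets are identical to a full-B
    scan).
    """
    if R < 2:
        raise ValueError("R must be >= 2 to estimate sigma")
    master = as_seedseq(seed)
    children = master.spawn(R)
    n = pheno_d.n
    curves: list[np.ndarray] = []
    for i, child in enumerate(children):
        perm_seed, scan_seed = child.spawn(2)
        rng = np.random.default_rng(perm_seed)
        perm = rng.permutation(n)
        while np.array_equal(perm, np.arange(n)):
            perm = rng.permutation(n)
        shuffled = DistanceMatrix(pheno_d.ids,
                                  pheno_d.values[np.ix_(perm, perm)],
                                  pheno_d.source, pheno_d.label + "|shuffled")
        res = marker_set_analysis(g, shuffled, B=B, seed=scan_seed,
                                  p_gate=p_gate, max_k=max_k,
                                  plateau_tol=plateau_tol, metric=metric,
                                  scan_mode="gate")
        if res.curve is None:
            logger.info("null shuffle %d: no eligible markers, flat zero curve", i)
            curves.append(np.zeros(1))
        else:
            curves.append(res.curve.c)
    L = max(len(c) for c in curves)
    padded = np.stack([
        np.concatenate([c, np.full(L - len(c), c[-1])]) for c in curves
    ])
    lengths = np.array([len(c) for c in curves])
    if (lengths < L).any():
        logger.info("right-padded %d of %d null curves to length %d",
                    int((lengths < L).sum()), R, L)
    return NullCurveEnsemble(
        curves=padded, lengths=lengths,
        mu=padded.mean(axis=0), sigma=padded.std(axis=0, ddof=1),
        seed=seed,
        params={"R": R, "B": B, "p_gate": p_gate, "max_k": max_k,
                "metric": metric},
    )


def z_curve(observed: SelectionCurve, ensemble: NullCurveEnsemble) -> ZCurve:
    """Z_k = (c_k - mu_k) / sigma_k for each k of the observed curve.

    Null curves shorter than the observed one carry their last value; where
    sigma_k = 0 the Z-score is undefined and flagged, never fabricated.
    """
    K = len(observed)
    ens = ensemble.padded_to(K)
    undefined = ens.sigma == 0.0
    z = np.full(K, np.nan)
    ok = ~undefined
    z[ok] = (observed.c[ok] - ens.mu[ok]) / ens.sigma[ok]
    if undefined.any():
        logger.info("sigma_k = 0 at %d of %d set sizes; Z flagged undefined",
                    int(undefined.sum()), K)
    return ZCurve(z=z, undefined=undefined)


def z_to_p(z) -> np.ndarray | float:
    """One-sided standard-normal upper-tail probability for a Z-score."""
    return stats.norm.sf(z)


__all__ = ["NullCurveEnsemble", "ZCurve", "null_ensemble", "z_curve", "z_to_p"]
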