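"""Pairwise sample dissimilarity matrices for genotype marker sets and
phenotype categories.

Both modalities use the Manhattan (city-block) distance with equal weight per
marker / per measure, so the genotype distance over a marker set is the
element-wise sum of the single-marker distances — the property the forward
selection step exploits to update distances incrementally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

GENOTYPE_METRICS = ("manhattan_dosage", "ibs_mismatch")


@dataclass
class DistanceMatrix:
    """N x N symmetric nonnegative dissimilarities with sample ids.

    ``source`` records the data modality ("genotype" or "phenotype") and
    ``label`` the marker subset or category it was built from.
    """

    ids: np.ndarray
    values: np.ndarray
    source: str = "unknown"
    label: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Upper-off-diagonal entries in scipy condensed order."""
        return squareform(self.values, checks=False)

    def permuted(self, perm: np.ndarray) -> "DistanceMatrix":
        """Joint row+column reordering (relabels samples by ``perm``)."""
        perm = np.asarray(perm)
        return DistanceMatrix(self.ids[perm], self.values[np.ix_(perm, perm)],
                              self.source, self.label)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def genotype_distance(
    g: GenotypeMatrix,
    markers=None,
    metric: str = "manhattan_dosage",
) -> DistanceMatrix:
    """Distance between samples over a marker set, equal weight per marker.

    ``manhattan_dosage``: d(i,j) = sum_m |dosage_i(m) - dosage_j(m)|.
    ``ibs_mismatch``:     d(i,j) = sum_m [dosage_i(m) != dosage_j(m)].
    Dosages are used raw (no standardization).
    """
    if metric not in GENOTYPE_METRICS:
        raise ValueError(f"metric must be one of {GENOTYPE_METRICS}, got {metric!r}")
    if markers is None:
        sub = g
        label = "all_markers"
    else:
        markers = list(markers)
        if not markers:
            raise ValueError("empty marker list")
        sub = g.subset_markers(markers)
        label = f"{len(markers)}_markers"
    x = sub.dosages.astype(np.float64)
    if metric == "manhattan_dosage":
        d = pdist(x, metric="cityblock")
    else:
        d = pdist(x, metric="hamming") * x.shape[1]
    return DistanceMatrix(g.samples, squareform(d), "genotype", label)


def phenotype_distance(
    p: PhenotypeTable,
    category: str,
    standardize: bool = True,
) -> DistanceMatrix:
    """Manhattan distance over one category's measure vector.

    With ``standardize`` (default) each measure is centered and scaled to unit
    variance first, so measures on different scales carry equal weight; a
    zero-variance measure cannot be standardized and is dropped with a
    warning.
    """
    measures = p.measures_in(category)
    x = p.values[measures].to_numpy(dtype=np.float64)
    if np.isnan(x).any():
        raise ValueError(f"missing phenotype values in category {category!r}")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [m for m, k in zip(measures, keep) if not k]
            warnings.warn(
                f"dropping zero-variance measures {dropped} from category {category!r}",
                UserWarning, stacklevel=2,
            )
            x, sd = x[:, keep], sd[keep]
            if x.shape[1] == 0:
                raise ValueError(f"all measures in category {category!r} have zero variance")
        x = (x - x.mean(axis=0)) / sd
    d = pdist(x, metric="cityblock")
    return DistanceMatrix(p.samples, squareform(d), "phenotype", category)


__all__ = ["DistanceMatrix", "genotype_distance", "phenotype_distance", "GENOTYPE_METRICS"]
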