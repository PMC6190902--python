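"""Readers, writers and validated in-memory containers for every on-disk format.

Conventions
-----------
* Genotype matrix: TSV, one row per sample, one column per marker, dosage codes
  0/1/2 counting copies of the minor allele.  A companion marker map (TSV:
  marker, chrom, bp, ref, alt) covers every marker; positions are 1-based.
* Phenotype table: CSV, one row per sample, one column per measure, plus a
  measure -> category map (CSV: measure, category).
* Gene annotation: BED-like TSV (gene, chrom, start, end) with 1-based
  inclusive coordinates, stated in the header comment.
* Gene sets: standard GMT (name TAB description TAB member...).

Readers validate and reject rather than silently coerce; all round-trips are
lossless for valid data.  Sample alignment across files is by id, never by
row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES = (
    "context_pctfrze",
    "context_avgmot",
    "cued_pctfrze",
    "train_pctfrze",
    "shock_avgmot",
    "train_avgmo",
)

#: strings accepted as a missing dosage on read
MISSING_TOKENS = {"", "NA", "NaN", "nan", "."}


class FormatError(ValueError):
    """A file violates the documented on-disk contract."""


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with a marker map.

    ``dosages`` is an (N, M) int8 array of minor-allele counts in {0, 1, 2};
    ``marker_map`` is indexed by marker id with columns chrom, bp, ref, alt.
    """

    samples: np.ndarray  # (N,) str
    markers: np.ndarray  # (M,) str
    dosages: np.ndarray  # (N, M) int8
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample ids")
        if len(set(self.markers)) != len(self.markers):
            raise FormatError("duplicate marker ids")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"dosage {self.dosages[i, j]} outside {{0,1,2}} at "
                f"sample {self.samples[i]!r}, marker {self.markers[j]!r}"
            )
        missing = set(self.markers) - set(self.marker_map.index)
        if missing:
            raise FormatError(f"markers absent from map: {sorted(missing)[:5]}")
        # keep the map aligned to matrix column order
        self.marker_map = self.marker_map.loc[self.markers]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_frequency(self) -> np.ndarray:
        """Per-marker frequency of the counted allele, (allele count) / 2N."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, marker_ids) -> "GenotypeMatrix":
        idx = self._marker_indices(marker_ids)
        return GenotypeMatrix(
            samples=self.samples,
            markers=self.markers[idx],
            dosages=self.dosages[:, idx],
            marker_map=self.marker_map.iloc[idx],
        )

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            idx = np.array([pos[s] for s in sample_ids])
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None
        return GenotypeMatrix(
            samples=self.samples[idx],
            markers=self.markers,
            dosages=self.dosages[idx],
            marker_map=self.marker_map,
        )

    def _marker_indices(self, marker_ids) -> np.ndarray:
        pos = {m: i for i, m in enumerate(self.markers)}
        try:
            return np.array([pos[m] for m in marker_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown marker id {e.args[0]!r}") from None


@dataclass
class PhenotypeTable:
    """Samples x measures numeric table plus a measure -> category map."""

    values: pd.DataFrame  # index sample id, columns measure names
    categories: dict = field(default_factory=dict)  # measure -> category

    def __post_init__(self) -> None:
        unmapped = set(self.values.columns) - set(self.categories)
        if unmapped:
            raise FormatError(f"measures without a category: {sorted(unmapped)[:5]}")
        if self.values.index.has_duplicates:
            raise FormatError("duplicate sample ids in phenotype table")
        if not all(np.issubdtype(d, np.number) for d in self.values.dtypes):
            raise FormatError("non-numeric phenotype column")

    @property
    def samples(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def category_names(self) -> list:
        return sorted(set(self.categories.values()))

    def measures_in(self, category: str) -> list:
        out = [m for m in self.values.columns if self.categories[m] == category]
        if not out:
            raise KeyError(f"category {category!r} has no measures")
        return out

    def subset_samples(self, sample_ids) -> "PhenotypeTable":
        return PhenotypeTable(self.values.loc[list(sample_ids)], dict(self.categories))


@dataclass
class GeneAnnotation:
    """Gene intervals: columns gene, chrom, start, end (1-based inclusive)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene", "chrom", "start", "end"}
        if not need <= set(self.table.columns):
            raise FormatError(f"annotation needs columns {sorted(need)}")
        if self.table["gene"].duplicated().any():
            dup = self.table.loc[self.table["gene"].duplicated(), "gene"].iloc[0]
            raise FormatError(f"duplicate gene id {dup!r}")
        bad = self.table["start"] > self.table["end"]
        if bad.any():
            g = self.table.loc[bad, "gene"].iloc[0]
            raise FormatError(f"gene {g!r} has start > end")

    @property
    def genes(self) -> np.ndarray:
        return self.table["gene"].to_numpy()


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict  # name -> frozenset of gene ids
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(str(m) for m in members)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(path, map_path, missing_policy: str = "reject") -> GenotypeMatrix:
    """Read a dosage TSV plus marker map.

    ``missing_policy`` is ``"reject"`` (default) or ``"impute_mean"``
    (per-marker mean, rounded to the nearest legal dosage, with a logged count).
    """
    if missing_policy not in ("reject", "impute_mean"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    mp = read_marker_map(map_path)
    samples = df.index.to_numpy(dtype=object)
    markers = df.columns.to_numpy(dtype=object)
    raw = df.fillna("NA").to_numpy(dtype=str)
    raw = np.char.strip(raw)
    miss = np.isin(raw, list(MISSING_TOKENS))
    valid = np.isin(raw, ("0", "1", "2"))
    bad = ~(miss | valid)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"dosage {raw[i, j]!r} outside {{0,1,2}} at sample "
            f"{samples[i]!r}, marker {markers[j]!r}"
        )
    dosages = np.where(valid, raw, "0").astype(np.float64)
    if miss.any():
        if missing_policy == "reject":
            i, j = np.argwhere(miss)[0]
            raise FormatError(
                f"missing dosage at sample {samples[i]!r}, marker {markers[j]!r} "
                "(missing_policy='reject')"
            )
        n = int(miss.sum())
        for j in np.unique(np.argwhere(miss)[:, 1]):
            col = dosages[:, j]
            m = miss[:, j]
            fill = col[~m].mean() if (~m).any() else 0.0
            col[m] = int(round(fill))
        logger.info("imputed %d missing dosages (per-marker rounded mean)", n)
    return GenotypeMatrix(samples, markers, dosages.astype(np.int8), mp)


def read_marker_map(path) -> pd.DataFrame:
    mp = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str}, comment="#")
    need = {"marker", "chrom", "bp"}
    if not need <= set(mp.columns):
        raise FormatError(f"marker map needs columns {sorted(need)}")
    if mp["marker"].duplicated().any():
        raise FormatError("duplicate marker in map")
    if (mp["bp"] < 1).any():
        raise FormatError("marker bp positions must be >= 1")
    for col in ("ref", "alt"):
        if col not in mp.columns:
            mp[col] = "N"
    return mp.set_index("marker")


def write_genotypes(g: GenotypeMatrix, path, map_path) -> None:
    df = pd.DataFrame(g.dosages, index=pd.Index(g.samples, name="sample"), columns=g.markers)
    df.to_csv(path, sep="\t")
    mp = g.marker_map.reset_index()
    if "marker" not in mp.columns:  # index name may differ
        mp = mp.rename(columns={mp.columns[0]: "marker"})
    mp.to_csv(map_path, sep="\t", index=False)


def filter_markers_by_maf(g: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep markers with minor allele frequency strictly above ``threshold``."""
    if not 0 <= threshold < 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5), got {threshold}")
    keep = g.maf() > threshold
    logger.info("MAF filter > %.3f: kept %d of %d markers", threshold, keep.sum(), g.n_markers)
    return GenotypeMatrix(g.samples, g.markers[keep], g.dosages[:, keep], g.marker_map)


# ---------------------------------------------------------------------------
# phenotype / condition I/O


def read_phenotypes(path, category_map_path) -> PhenotypeTable:
    values = pd.read_csv(path, index_col=0)
    values.index = values.index.astype(str)
    cm = pd.read_csv(category_map_path, dtype=str)
    if not {"measure", "category"} <= set(cm.columns):
        raise FormatError("category map needs columns measure, category")
    if cm["measure"].duplicated().any():
        raise FormatError("measure mapped to more than one category")
    cats = dict(zip(cm["measure"], cm["category"]))
    try:
        return PhenotypeTable(values, {m: cats[m] for m in values.columns})
    except KeyError as e:
        raise FormatError(f"measure {e.args[0]!r} missing from category map") from None


def write_phenotypes(p: PhenotypeTable, path, category_map_path) -> None:
    out = p.values.copy()
    out.index.name = "sample"
    out.to_csv(path)
    pd.DataFrame(
        {"measure": list(p.categories), "category": list(p.categories.values())}
    ).to_csv(category_map_path, index=False)


def read_conditions(path) -> pd.DataFrame:
    """Per-sample labels CSV with columns sample, cohort, condition."""
    df = pd.read_csv(path, dtype=str)
    need = {"sample", "cohort", "condition"}
    if not need <= set(df.columns):
        raise FormatError(f"condition table needs columns {sorted(need)}")
    if df["sample"].duplicated().any():
        raise FormatError("duplicate sample in condition table")
    return df.set_index("sample")


def write_conditions(conditions: pd.DataFrame, path) -> None:
    out = conditions.copy()
    out.index.name = "sample"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# annotation I/O


def read_gene_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str},
    )
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except ValueError as e:
        raise FormatError(f"non-integer gene coordinate: {e}") from None
    return GeneAnnotation(df[["gene", "chrom", "start", "end"]])


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tgene (1-based inclusive coordinates)\n")
        ann.table[["chrom", "start", "end", "gene"]].to_csv(
            fh, sep="\t", header=False, index=False
        )


def read_gmt(path) -> GeneSetCollection:
    sets, desc = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            members = [p for p in parts[2:] if p]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = frozenset(members)
            desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# alignment


def align_samples(g: GenotypeMatrix, p: PhenotypeTable, conditions: pd.DataFrame | None = None):
    """Inner-join genotype, phenotype (and optionally condition) tables by id.

    Returns the aligned objects in genotype-file sample order and logs any
    dropped samples.
    """
    keep = set(g.samples) & set(p.samples)
    if conditions is not None:
        keep &= set(conditions.index)
    order = [s for s in g.samples if s in keep]
    dropped = (set(g.samples) | set(p.samples)) - keep
    if dropped:
        logger.info("dropped %d samples absent from some input: %s",
                    len(dropped), sorted(dropped)[:5])
    if len(order) < 2:
        raise ValueError("fewer than 2 samples shared across inputs")
    g2 = g.subset_samples(order)
    p2 = p.subset_samples(order)
    if conditions is None:
        return g2, p2
    return g2, p2, conditions.loc[order]


__all__ = [
    "FormatError", "GenotypeMatrix", "PhenotypeTable", "GeneAnnotation",
    "GeneSetCollection", "DEFAULT_CATEGORIES",
    "read_genotypes", "read_marker_map", "write_genotypes",
    "filter_markers_by_maf", "read_phenotypes", "write_phenotypes",
    "read_conditions", "write_conditions", "read_gene_annotation",
    "write_gene_annotation", "read_gmt", "write_gmt", "align_samples",
]
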