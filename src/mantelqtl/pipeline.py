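"""End-to-end orchestration: configuration, staged execution, provenance.

A single :class:`PipelineConfig` carries every tunable (MAF threshold, gate
p-value, permutation and randomization counts, plateau tolerance, gene
window, metric, strata) plus the master seed; its hash and the seed are
embedded in the output manifest so a run can be reproduced byte for byte.
Strata are analyzed fully independently — no information flows between them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .calibration import null_ensemble, z_curve
from .distance import GENOTYPE_METRICS, phenotype_distance
from .enrichment import enrich, genes_near_markers, intersect_condition_markers
from .overlap import compare_conditions, overlap_report
from .selection import marker_set_analysis, write_peak_summary
from .simulate import simulate_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    maf_threshold: float = 0.05
    p_gate: float = 0.01
    B: int = 999
    R: int = 25
    plateau_tol: float = 0.02
    window_bp: int = 1_000_000
    metric: str = "manhattan_dosage"
    standardize: bool = True
    max_k: int = 1000
    stratify_by: str | None = None  # None | "cohort" | "sham_vs_irradiated"
    stratum_floor: int = 30
    set_definition: str = "peak"
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5)")
        if not 0 < self.p_gate < 1:
            raise ValueError("p_gate must be in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.R < 2:
            raise ValueError("R must be >= 2")
        if self.plateau_tol < 0:
            raise ValueError("plateau_tol must be >= 0")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.metric not in GENOTYPE_METRICS:
            raise ValueError(f"metric must be one of {GENOTYPE_METRICS}")
        if self.max_k < 1:
            raise ValueError("max_k must be >= 1")
        if self.stratify_by not in (None, "cohort", "sham_vs_irradiated"):
            raise ValueError("stratify_by must be None, 'cohort' or 'sham_vs_irradiated'")
        if self.set_definition not in ("peak", "gate"):
            raise ValueError("set_definition must be 'peak' or 'gate'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise PipelineError(f"stage {name!r} failed: {e}") from e
    return wrap


def run_full_analysis(
    config: PipelineConfig,
    genotype_path,
    map_path,
    phenotype_path,
    category_map_path,
    condition_path,
    out_dir,
    annotation_path=None,
    gmt_path=None,
) -> dict:
    """Scan, select, calibrate, compare and (optionally) enrich; write the
    report bundle to ``out_dir`` and return the manifest dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    g = _stage("read_genotypes")(mio.read_genotypes, genotype_path, map_path)
    pheno = _stage("read_phenotypes")(mio.read_phenotypes, phenotype_path,
                                      category_map_path)
    conditions = _stage("read_conditions")(mio.read_conditions, condition_path)
    g, pheno, conditions = _stage("align")(mio.align_samples, g, pheno, conditions)
    g = _stage("maf_filter")(mio.filter_markers_by_maf, g, config.maf_threshold)
    logger.info("aligned %d samples, %d post-MAF markers", g.n_samples, g.n_markers)

    strata = _split_strata(g, conditions, config)
    categories = pheno.category_names
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(strata) * len(categories) + 1)
    manifest = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "n_samples": int(g.n_samples),
        "n_markers_post_maf": int(g.n_markers),
        "strata": {k: int(len(v)) for k, v in strata.items()},
        "files": [],
        "peaks": {},
    }

    peak_sets: dict = {}
    ci = 0
    for sname, ids in strata.items():
        gs = g.subset_samples(ids)
        ps = pheno.subset_samples(ids)
        peak_sets[sname] = {}
        for cat in categories:
            child = children[ci]
            ci += 1
            tag = f"{sname}.{cat}"
            d = _stage(f"phenotype_distance[{tag}]")(
                phenotype_distance, ps, cat, config.standardize)
            seeds = child.spawn(2)
            res = _stage(f"marker_set_analysis[{tag}]")(
                marker_set_analysis, gs, d, B=config.B, seed=seeds[0],
                p_gate=config.p_gate, max_k=config.max_k,
                plateau_tol=config.plateau_tol, metric=config.metric,
                scan_mode="exact")
            res.scan.to_tsv(out / f"scan.{tag}.tsv")
            manifest["files"].append(f"scan.{tag}.tsv")
            if res.curve is not None:
                res.curve.to_tsv(out / f"curve.{tag}.tsv")
                write_peak_summary(res, out / f"peak.{tag}.json")
                manifest["files"] += [f"curve.{tag}.tsv", f"peak.{tag}.json"]
                ens = _stage(f"null_ensemble[{tag}]")(
                    null_ensemble, gs, d, R=config.R, seed=seeds[1],
                    B=config.B, p_gate=config.p_gate, max_k=config.max_k,
                    plateau_tol=config.plateau_tol, metric=config.metric)
                ens.to_tsv(out / f"zcurve.{tag}.tsv", observed=res.curve)
                manifest["files"].append(f"zcurve.{tag}.tsv")
                z = z_curve(res.curve, ens)
                manifest["peaks"][tag] = {
                    "k_star": res.k_star, "peak_value": res.peak_value,
                    "max_z": None if np.isnan(z.max()) else float(z.max()),
                }
            else:
                manifest["peaks"][tag] = {"k_star": None, "peak_value": None,
                                          "max_z": None}
            sets = res.peak_markers if config.set_definition == "peak" else res.eligible
            peak_sets[sname][cat] = sets

    if config.stratify_by is not None and len(strata) == 2:
        child = children[ci]
        results = _stage("compare_conditions")(
            compare_conditions, g, pheno, conditions,
            split=config.stratify_by, stratum_floor=config.stratum_floor,
            standardize=config.standardize,
            set_definition=config.set_definition, seed=child,
            B=config.B, p_gate=config.p_gate, max_k=config.max_k,
            plateau_tol=config.plateau_tol, metric=config.metric)
        overlap_report(results, out / "overlap.tsv")
        manifest["files"].append("overlap.tsv")
        manifest["overlap"] = {
            cat: {"odds_ratio": res.odds_ratio, "ci": [res.ci_low, res.ci_high],
                  "p": res.p}
            for cat, (res, _) in results.items()
        }
        if annotation_path is not None and gmt_path is not None:
            ann = _stage("read_annotation")(mio.read_gene_annotation, annotation_path)
            coll = _stage("read_gmt")(mio.read_gmt, gmt_path)
            s1, s2 = strata.keys()
            for cat in categories:
                common = intersect_condition_markers(
                    peak_sets[s1][cat], peak_sets[s2][cat])
                if not common:
                    logger.info("no common markers for %s; enrichment skipped", cat)
                    continue
                genes = _stage(f"genes_near_markers[{cat}]")(
                    genes_near_markers, common, g.marker_map, ann,
                    config.window_bp)
                chroms = set(g.marker_map.loc[list(common), "chrom"])
                universe = set(ann.table.loc[
                    ann.table["chrom"].isin(chroms), "gene"])
                if not genes:
                    continue
                df = _stage(f"enrich[{cat}]")(enrich, genes, coll, universe)
                df.to_csv(out / f"enrichment.{cat}.tsv", sep="\t", index=False)
                manifest["files"].append(f"enrichment.{cat}.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _split_strata(g, conditions, config: PipelineConfig) -> dict:
    cond = conditions.loc[list(g.samples)]
    if config.stratify_by is None:
        return {"all": list(g.samples)}
    if config.stratify_by == "cohort":
        labels = cond["cohort"]
        names = sorted(labels.unique())
    else:
        labels = cond["condition"].map(lambda c: "sham" if c == "sham" else "irradiated")
        names = ["sham", "irradiated"]
    strata = {n: list(labels.index[labels == n]) for n in names}
    for n, ids in strata.items():
        if len(ids) < config.stratum_floor:
            raise PipelineError(
                f"stage 'stratify' failed: stratum {n!r} has {len(ids)} samples, "
                f"below floor {config.stratum_floor}")
    return strata


def simulate_command(out_dir, seed: int = 0, **sim_kwargs) -> dict:
    """Generate a synthetic dataset on disk plus its ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, pheno, conditions, truth = simulate_dataset(seed=seed, **sim_kwargs)
    mio.write_genotypes(g, out / "genotypes.tsv", out / "marker_map.tsv")
    mio.write_phenotypes(pheno, out / "phenotypes.csv", out / "categories.csv")
    mio.write_conditions(conditions, out / "conditions.csv")
    truth.to_yaml(out / "ground_truth.yaml")
    return {
        "genotypes": str(out / "genotypes.tsv"),
        "marker_map": str(out / "marker_map.tsv"),
        "phenotypes": str(out / "phenotypes.csv"),
        "categories": str(out / "categories.csv"),
        "conditions": str(out / "conditions.csv"),
        "ground_truth": str(out / "ground_truth.yaml"),
    }


__all__ = ["PipelineConfig", "PipelineError", "run_full_analysis",
           "simulate_command"]
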