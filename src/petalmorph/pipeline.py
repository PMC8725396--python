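"""Orchestration of the two analysis arms plus input validation.

The morphometric arm chains measurement of cell outlines, the quadratic
triple-interaction fits for CL, log(CA) and CLWR, and the heterochrony
verdict.  The expression arm chains hit filtering, isoform collapsing, the
cross-species inner join, TMM/cpm normalization and filtering, sample QC,
the four NB Wald contrasts and the four signature GSEAs.  Every run writes
a manifest (config hash + per-output checksums) so deterministic stages can
be audited for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from petalmorph import io as pio
from petalmorph import merge as pmerge
from petalmorph.dge import NBWaldModel, estimate_dispersion, standard_contrasts
from petalmorph.geometry import Polygon, clwr, lobeyness, polygon_area
from petalmorph.gsea import DEFAULT_KEYWORDS, Signature, build_signature, gsea_report, rank_genes
from petalmorph.morphometrics import fit_quadratic_interaction_model

logger = logging.getLogger(__name__)

__all__ = ["Config", "measure_polygons", "run_morphometric_arm",
           "run_expression_arm", "validate_inputs", "write_manifest"]

_DEFAULTS = {
    "evalue": 1e-3,
    "min_cpm": 1.0,
    "min_samples": 3,
    "fdr": 0.05,
    "alpha": 0.05,
    "n_perm": 1000,
    "cells_per_image": 10,
    "basal_stage": "bud",
    "basal_species": None,  # lexicographically first when unset
    "orientation": "basal_first",
    "seed": 0,
}


@dataclass
class Config:
    """Thresholds, factor levels and seeds for one pipeline run."""

    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(_DEFAULTS)
        merged.update(self.params)
        self.params = merged
        p = self.params
        if p["evalue"] <= 0:
            raise ValueError("evalue threshold must be positive")
        if not (0 < p["fdr"] < 1) or not (0 < p["alpha"] < 1):
            raise ValueError("fdr and alpha must lie in (0, 1)")
        if p["min_samples"] < 1 or p["min_cpm"] < 0:
            raise ValueError("invalid cpm filter settings")
        if p["n_perm"] < 100:
            raise ValueError("n_perm must be >= 100")
        if p["orientation"] not in ("basal_first", "apical_first"):
            raise ValueError("orientation must be basal_first or apical_first")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(paths=raw.get("paths", {}), params=raw.get("params", {}))

    def hash(self) -> str:
        blob = json.dumps({"paths": {k: str(v) for k, v in self.paths.items()},
                           "params": self.params}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(config: Config, outputs: dict[str, Path], out_path) -> dict:
    manifest = {
        "tool": "petalmorph 0.1.0",
        "config_hash": config.hash(),
        "seed": config.params.get("seed"),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in outputs.items() if Path(p).exists()},
    }
    pio.write_json(manifest, out_path)
    return manifest


def measure_polygons(polygons: dict[str, np.ndarray], covariates: pd.DataFrame,
                     longitudinal_axis: str = "y") -> pd.DataFrame:
    """Compute cl / ca_um2 / clwr for each outline and join the covariates.

    ``covariates`` is a cell table (may lack the metric columns) keyed by
    ``cell_id``.  Outlines are validated (self-intersections rejected).
    """
    cov = covariates.set_index("cell_id")
    rows = []
    for cid, verts in polygons.items():
        if cid not in cov.index:
            raise ValueError(f"polygon {cid!r} missing from the cell table")
        poly = Polygon(verts, longitudinal_axis=longitudinal_axis)
        poly.validate_simple()
        _, cl = lobeyness(poly)
        rows.append({
            "cell_id": cid, "cl": cl, "ca_um2": polygon_area(poly),
            "clwr": clwr(poly),
        })
    metrics = pd.DataFrame(rows).set_index("cell_id")
    out = cov.drop(columns=[c for c in ("cl", "ca_um2", "clwr") if c in cov.columns])
    out = out.join(metrics, how="inner").reset_index()
    return out


def run_morphometric_arm(config: Config, cell_table: pd.DataFrame | None = None,
                         polygons: dict[str, np.ndarray] | None = None,
                         out_dir=None) -> dict:
    """measure (if outlines given) -> fit CL / log(CA) / CLWR -> classify.

    Either a ready metric table or outlines + covariates must be supplied
    (paths in the config are read when arguments are omitted).
    """
    try:
        if cell_table is None:
            cell_table = pio.read_cell_table(config.paths["cell_table"])
        if polygons is None and "polygons" in config.paths:
            polygons = pio.read_polygons(config.paths["polygons"])
        if polygons is not None:
            axis = "y" if config.params["orientation"] in ("basal_first", "apical_first") else "y"
            cell_table = measure_polygons(polygons, cell_table, longitudinal_axis=axis)
    except Exception as exc:
        raise RuntimeError(f"[measure] {exc}") from exc

    basal_species = config.params["basal_species"]
    fits = {}
    try:
        for response in ("cl", "log_ca", "clwr"):
            fits[response] = fit_quadratic_interaction_model(
                cell_table, response=response,
                basal_stage=config.params["basal_stage"],
                basal_species=basal_species,
            )
    except Exception as exc:
        raise RuntimeError(f"[fit-morphometrics] {exc}") from exc

    call = fits["cl"].classify_heterochrony(alpha=config.params["alpha"])
    result = {"metrics": cell_table, "fits": fits, "call": call}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs = {}
        pio.write_cell_table(cell_table, out_dir / "metrics.tsv")
        outputs["metrics"] = out_dir / "metrics.tsv"
        for response, fit in fits.items():
            p = out_dir / f"fit_{response}.tsv"
            fit.coefficient_table().to_csv(p, sep="\t", index=False)
            outputs[f"fit_{response}"] = p
        pio.write_json({"verdict": call.verdict, "alpha": call.alpha,
                        "tests": call.tests}, out_dir / "heterochrony_call.json")
        outputs["call"] = out_dir / "heterochrony_call.json"
        write_manifest(config, outputs, out_dir / "manifest.json")
    return result


def run_expression_arm(config: Config, *, isoform_counts: dict | None = None,
                       hits: pd.DataFrame | None = None,
                       annotation: pd.DataFrame | None = None,
                       sample_sheet: pd.DataFrame | None = None,
                       out_dir=None) -> dict:
    """filter_hits -> collapse -> join -> TMM -> cpm/filter -> QC -> DE -> GSEA."""
    stage = "inputs"
    try:
        if hits is None:
            hits = pio.read_blast_hits(config.paths["hits"])
        if annotation is None:
            annotation = pio.read_annotation(config.paths["annotation"])
        if sample_sheet is None:
            sample_sheet = pio.read_sample_sheet(config.paths["sample_sheet"])
        if isoform_counts is None:
            isoform_counts = {
                sp: pio.read_counts(path)
                for sp, path in config.paths["isoform_counts"].items()
            }

        stage = "merge-counts"
        mapping = pmerge.filter_hits(hits, e_threshold=config.params["evalue"])
        species = sorted(isoform_counts)
        if len(species) != 2:
            raise ValueError("need isoform tables for exactly two species")
        per_species = {
            sp: pmerge.collapse_isoforms(isoform_counts[sp], mapping)
            for sp in species
        }
        merged, join_report = pmerge.inner_join_species(
            per_species[species[0]], per_species[species[1]])

        stage = "normalize"
        norm = pmerge.tmm_normalize(merged)
        filtered_cpm, kept = pmerge.cpm_and_filter(
            norm, min_cpm=config.params["min_cpm"],
            min_samples=config.params["min_samples"])

        stage = "qc"
        qc = pmerge.qc_sample_similarity(filtered_cpm)

        stage = "de"
        counts_f = merged.loc[kept]
        model = NBWaldModel(counts_f, sample_sheet,
                            effective_lib_sizes=norm.effective_library_sizes)
        basal = config.params["basal_species"] or species[0]
        derived = next(s for s in species if s != basal)
        contrasts = standard_contrasts(basal, derived)
        de = {c.name: model.fit(c) for c in contrasts}

        stage = "gsea"
        signatures = [build_signature(annotation, name) for name in DEFAULT_KEYWORDS]
        ranked = {name: rank_genes(res.table) for name, res in de.items()}
        seed = config.params["seed"]
        report = gsea_report(ranked, signatures, n_perm=config.params["n_perm"],
                             seed=seed)
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"[{stage}] {exc}") from exc

    result = {"merged_counts": merged, "join_report": join_report, "norm": norm,
              "filtered_cpm": filtered_cpm, "qc": qc, "de": de,
              "signatures": signatures, "gsea": report}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        outputs = {}
        pio.write_counts(merged, out_dir / "merged_counts.tsv")
        outputs["merged_counts"] = out_dir / "merged_counts.tsv"
        norm.factors.to_csv(out_dir / "tmm_factors.tsv", sep="\t")
        outputs["tmm_factors"] = out_dir / "tmm_factors.tsv"
        filtered_cpm.to_csv(out_dir / "filtered_cpm.tsv", sep="\t")
        outputs["filtered_cpm"] = out_dir / "filtered_cpm.tsv"
        pio.write_json({
            "join": {k: (v if isinstance(v, int) else len(v))
                     for k, v in join_report.items()},
            "n_kept_genes": len(kept),
            "pc1_variance": float(qc["variance_explained"][0]),
        }, out_dir / "qc.json")
        outputs["qc"] = out_dir / "qc.json"
        for name, res in de.items():
            p = out_dir / f"de_{name}.tsv"
            res.table.to_csv(p, sep="\t", index_label="gene_id")
            outputs[f"de_{name}"] = p
        pio.write_gmt({s.name: s.genes for s in signatures}, out_dir / "signatures.gmt")
        outputs["signatures"] = out_dir / "signatures.gmt"
        report.to_csv(out_dir / "gsea.tsv", sep="\t", index=False)
        outputs["gsea"] = out_dir / "gsea.tsv"
        write_manifest(config, outputs, out_dir / "manifest.json")
    return result


def validate_inputs(config: Config) -> dict:
    """Schema-check every declared input; returns {'fatal': [...],
    'warnings': [...]} without raising."""
    fatal, warn = [], []
    paths = config.paths

    def _try(name, fn, *args):
        try:
            return fn(*args)
        except FileNotFoundError:
            fatal.append(f"{name}: file not found")
        except Exception as exc:
            fatal.append(f"{name}: {exc}")
        return None

    cell_table = None
    if "cell_table" in paths:
        cell_table = _try("cell_table", pio.read_cell_table, paths["cell_table"])
    if "polygons" in paths:
        polys = _try("polygons", pio.read_polygons, paths["polygons"])
        if polys is not None and cell_table is not None:
            missing = set(polys) - set(cell_table["cell_id"].astype(str))
            if missing:
                fatal.append(f"polygons: {len(missing)} cell ids absent from the cell table")
    sheet = None
    if "sample_sheet" in paths:
        sheet = _try("sample_sheet", pio.read_sample_sheet, paths["sample_sheet"])
    if "isoform_counts" in paths:
        for sp, p in paths["isoform_counts"].items():
            tbl = _try(f"isoform_counts[{sp}]", pio.read_counts, p)
            if tbl is not None and sheet is not None:
                absent = [s for s in tbl.columns if s not in sheet.index]
                if absent:
                    fatal.append(
                        f"isoform_counts[{sp}]: samples {absent} absent from the sample sheet")
    if "hits" in paths:
        _try("hits", pio.read_blast_hits, paths["hits"])
    if "annotation" in paths:
        ann = _try("annotation", pio.read_annotation, paths["annotation"])
        if ann is not None and ann["description"].isna().any():
            warn.append("annotation: empty descriptions present")
    return {"fatal": fatal, "warnings": warn, "ok": not fatal}
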