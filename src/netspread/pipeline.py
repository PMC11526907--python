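"""End-to-end pipeline: fit, validate, vulnerability, association, enrichment.

A :class:`PipelineConfig` names the input files and analysis settings; the
pipeline executes the stages in order, writes every intermediate as plain
text, and emits a manifest (input hashes, configuration, package version,
seeds, stage record) that makes reruns byte-reproducible: identical config
and seeds produce identical output bytes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as nio
from .diffusion import FitConfig, fit_model, summarize_pathology
from .expression import gene_vulnerability_correlation, kinase_filter
from .gsea import preranked_gsea
from .validation import alternate_seed_test, crossval_compare
from .vulnerability import (
    DEFAULT_VULN_MPI,
    composite_vulnerability,
    peak_timepoint,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

STAGES = ("fit", "seed_null", "crossval", "vulnerability", "association", "enrichment")


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name. Partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    connectome: str
    pathology: str
    seed_region: str
    expression: str | None = None
    region_metadata: str | None = None
    kinase_list: str | None = None
    de_gene_list: str | None = None
    gene_sets: str | None = None
    measure: str = "total"
    mode: str = "bidirectional"
    floor: float = 1e-12
    grid_size: int = 10
    c_bounds: tuple[float, float] = (1e-3, 1e2)
    refine: bool = True
    n_alt: int = 100
    n_iter: int = 100
    n_perm: int = 1000
    vuln_mpi: tuple[float, ...] = DEFAULT_VULN_MPI
    fdr_threshold: float = 0.05
    rng_seed: int = 0
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.measure not in {"total", "cell_body", "neurite"}:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.n_alt < 1 or self.n_iter < 1 or self.n_perm < 1:
            raise ValueError("n_alt, n_iter and n_perm must be >= 1")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        needs_expr = {"association", "enrichment"} & set(self.stages)
        if needs_expr and self.expression is None:
            raise ValueError(
                "association/enrichment stages enabled but no expression path given"
            )
        if "enrichment" in self.stages and self.gene_sets is None:
            raise ValueError("enrichment stage enabled but no gene_sets path given")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("c_bounds", "vuln_mpi", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def fit_config(self) -> FitConfig:
        return FitConfig(
            grid_size=self.grid_size,
            c_bounds=tuple(self.c_bounds),
            refine=self.refine,
            floor=self.floor,
        )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the configured stages, writing artifacts into ``outdir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Any stage failure raises :class:`PipelineError` naming the stage;
    artifacts from completed stages remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        k: getattr(config, k)
        for k in (
            "connectome", "pathology", "expression", "region_metadata",
            "kinase_list", "de_gene_list", "gene_sets",
        )
        if getattr(config, k) is not None
    }
    manifest: dict = {
        "version": __version__,
        "config": _jsonable(asdict(config)),
        "input_hashes": {k: _sha256(v) for k, v in inputs.items()},
        "rng_seed": config.rng_seed,
        "stages": [],
    }
    ss = np.random.SeedSequence(config.rng_seed)
    sub = {
        name: int(s.generate_state(1)[0] % 2**31)
        for name, s in zip(("seed_null", "crossval", "enrichment"), ss.spawn(3))
    }

    conn = nio.read_connectome(config.connectome, metadata=config.region_metadata)
    pathology = nio.read_pathology(config.pathology)
    summary = summarize_pathology(pathology, conn, measure=config.measure)
    fc = config.fit_config()
    fitted = None
    vuln = None
    assoc = None

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "fit":
                fitted = fit_model(summary, conn, config.seed_region, config.mode, fc)
                nio.write_fitted_model(fitted, outdir / "fit.json")
                peaks = peak_timepoint(summary)
                peaks.rename_axis("region_id").to_frame().assign(
                    measure=config.measure
                )[["measure", "peak_mpi"]].to_csv(outdir / "peaks.tsv", sep="\t")
                manifest["stages"].append(
                    {"name": stage, "n_timepoints": len(fitted.timepoints)}
                )
            elif stage == "seed_null":
                res = alternate_seed_test(
                    summary, conn, config.seed_region, config.mode,
                    n_alt=config.n_alt, rng_seed=sub["seed_null"], config=fc,
                    replace=config.n_alt >= conn.n,
                )
                _write_json(
                    {
                        "actual_seed": res.actual_seed,
                        "n_alt": res.n_alt,
                        "r_actual": {f"{t:g}": res.r_actual[t] for t in res.timepoints},
                        "p": {f"{t:g}": res.p[t] for t in res.timepoints},
                        "p_raw": {f"{t:g}": res.p_raw[t] for t in res.timepoints},
                        "r_alternate": {
                            f"{t:g}": _nanlist(res.r_alternate[t])
                            for t in res.timepoints
                        },
                    },
                    outdir / "seednull.json",
                )
                manifest["stages"].append({"name": stage, "n_alt": res.n_alt})
            elif stage == "crossval":
                cv = crossval_compare(
                    summary, conn, config.seed_region, n_iter=config.n_iter,
                    rng_seed=sub["crossval"], config=fc,
                )
                _write_json(
                    {
                        "modes": cv.modes,
                        "n_iter": cv.n_iter,
                        "unstable_modes": cv.unstable_modes,
                        "heldout_r": {
                            m: {f"{t:g}": _nanlist(cv.heldout_r[m][t])
                                for t in cv.timepoints}
                            for m in cv.modes
                        },
                        "comparisons": {
                            f"{m1}|{m2}": {
                                f"{t:g}": {
                                    "median_diff": _nan_none(d["median_diff"]),
                                    "p": d["p"],
                                }
                                for t, d in per_t.items()
                            }
                            for (m1, m2), per_t in cv.comparisons.items()
                        },
                    },
                    outdir / "crossval.json",
                )
                manifest["stages"].append({"name": stage, "n_iter": cv.n_iter})
            elif stage == "vulnerability":
                if fitted is None:
                    raise ValueError("vulnerability stage requires the fit stage")
                vuln = composite_vulnerability(fitted, include_mpi=config.vuln_mpi)
                nio.write_vulnerability(vuln, outdir / "vulnerability.tsv")
                manifest["stages"].append({"name": stage, "n_regions": len(vuln.region_ids)})
            elif stage == "association":
                if vuln is None:
                    raise ValueError("association stage requires the vulnerability stage")
                atlas = nio.read_expression(config.expression)
                assoc = gene_vulnerability_correlation(atlas, vuln.as_series())
                assoc.to_csv(outdir / "assoc.tsv", sep="\t", float_format="%.17g")
                n_sig = int((assoc["q"] < config.fdr_threshold).sum())
                manifest["stages"].append(
                    {"name": stage, "n_genes": len(assoc), "n_significant": n_sig}
                )
            elif stage == "enrichment":
                if assoc is None:
                    raise ValueError("enrichment stage requires the association stage")
                sets = nio.read_gmt(config.gene_sets)
                ranking = {
                    g: float(r)
                    for g, r in assoc["r"].items()
                    if np.isfinite(r)
                }
                results = preranked_gsea(
                    ranking, sets, n_perm=config.n_perm, rng_seed=sub["enrichment"]
                )
                pd.DataFrame(
                    [
                        {
                            "set": r.name, "size": r.size, "es": r.es,
                            "nes": r.nes, "p": r.p, "fdr": r.fdr,
                            "leading_edge": ",".join(r.leading_edge),
                        }
                        for r in results
                    ]
                ).to_csv(outdir / "gsea.tsv", sep="\t", index=False,
                         float_format="%.17g")
                entry = {"name": stage, "n_sets": len(results)}
                if config.kinase_list and config.de_gene_list:
                    kin = kinase_filter(
                        assoc,
                        nio.read_gene_list(config.kinase_list),
                        nio.read_gene_list(config.de_gene_list),
                        q_threshold=config.fdr_threshold,
                    )
                    nio.write_gene_list(kin, outdir / "kinase_hits.txt")
                    entry["n_kinase_hits"] = len(kin)
                manifest["stages"].append(entry)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            _write_json(manifest, outdir / "manifest.json")
            raise PipelineError(stage, exc) from exc

    _write_json(manifest, outdir / "manifest.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _nan_none(v):
    return None if v is None or not np.isfinite(v) else float(v)


def _nanlist(arr) -> list:
    return [_nan_none(v) for v in np.asarray(arr, dtype=float)]
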