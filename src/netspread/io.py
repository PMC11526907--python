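"""File formats: connectome matrices, pathology tables, expression, results.

All readers validate on load; all writers produce plain text (TSV/CSV/JSON)
that round-trips exactly through the matching reader.  Region and gene
identifiers are opaque strings matched exactly and case-sensitively.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome
from .diffusion import DiffusionParams, FittedModel
from .vulnerability import VulnerabilityMap

__all__ = [
    "read_connectome",
    "write_connectome",
    "read_region_metadata",
    "write_region_metadata",
    "read_pathology",
    "write_pathology",
    "read_expression",
    "write_expression",
    "read_gene_list",
    "write_gene_list",
    "read_gmt",
    "write_gmt",
    "read_vulnerability",
    "write_vulnerability",
    "fitted_model_to_dict",
    "write_fitted_model",
    "read_fitted_model_params",
]

PATHOLOGY_COLUMNS = ["mouse_id", "mpi", "region_id", "hemisphere", "measure", "pct_area"]
MEASURES = {"total", "cell_body", "neurite"}


def read_connectome(
    path: str | Path,
    orientation: str = "row_to_col",
    metadata: str | Path | None = None,
) -> Connectome:
    """Square weighted matrix with header row and label column.

    ``orientation`` declares whether the file stores source regions as rows
    (``row_to_col``, the in-memory convention) or as columns
    (``col_to_row``, transposed on load).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    W = df.to_numpy(dtype=float)
    if orientation == "col_to_row":
        W = W.T
    elif orientation != "row_to_col":
        raise ValueError(f"unknown orientation {orientation!r}")
    hemisphere = coords = base_ids = None
    if metadata is not None:
        meta = read_region_metadata(metadata)
        meta = meta.reindex([str(r) for r in df.index])
        if meta.isna().any().any():
            missing = meta[meta.isna().any(axis=1)].index.tolist()
            raise ValueError(f"metadata missing regions: {missing[:5]}")
        if "hemisphere" in meta:
            hemisphere = list(meta["hemisphere"])
        if {"x", "y", "z"} <= set(meta.columns):
            coords = meta[["x", "y", "z"]].to_numpy(dtype=float)
        if "base_id" in meta:
            base_ids = list(meta["base_id"])
    return Connectome(
        region_ids=[str(r) for r in df.index],
        W=W,
        hemisphere=hemisphere,
        coords=coords,
        base_ids=base_ids,
    )


def write_connectome(conn: Connectome, path: str | Path) -> None:
    df = pd.DataFrame(conn.W, index=conn.region_ids, columns=conn.region_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_region_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "region_id" not in meta.columns:
        raise ValueError(f"{path}: missing region_id column")
    return meta.set_index("region_id")


def write_region_metadata(conn: Connectome, path: str | Path) -> None:
    d: dict = {"region_id": conn.region_ids}
    if conn.hemisphere is not None:
        d["hemisphere"] = conn.hemisphere
    if conn.coords is not None:
        d["x"], d["y"], d["z"] = conn.coords.T
    if conn.base_ids is not None:
        d["base_id"] = conn.base_ids
    pd.DataFrame(d).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pathology(path: str | Path, derive_neurite: bool = True) -> pd.DataFrame:
    """Long-format regional pathology quantification.

    Validates required columns, nonnegative percent area, known measures
    and uniqueness of (mouse, mpi, region, hemisphere, measure); offending
    row numbers (1-based, excluding header) are named in errors.  When
    ``total`` and ``cell_body`` are present for a site but ``neurite`` is
    absent, the neurite measure is derived as their difference.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PATHOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[df["pct_area"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative pct_area at rows {[i + 1 for i in bad[:5]]}")
    unk = df.index[~df["measure"].isin(MEASURES)]
    if len(unk):
        raise ValueError(
            f"{path}: unknown measure at rows {[i + 1 for i in unk[:5]]} "
            f"(expected one of {sorted(MEASURES)})"
        )
    key = ["mouse_id", "mpi", "region_id", "hemisphere", "measure"]
    dup = df.index[df.duplicated(subset=key)]
    if len(dup):
        raise ValueError(f"{path}: duplicate rows at {[i + 1 for i in dup[:5]]}")
    if derive_neurite:
        df = _derive_neurite(df)
    return df[PATHOLOGY_COLUMNS]


def _derive_neurite(df: pd.DataFrame) -> pd.DataFrame:
    site = ["mouse_id", "mpi", "region_id", "hemisphere"]
    wide = df.pivot_table(
        index=site, columns="measure", values="pct_area", aggfunc="first"
    )
    if "total" in wide and "cell_body" in wide:
        need = wide["total"].notna() & wide["cell_body"].notna()
        if "neurite" in wide:
            need &= wide["neurite"].isna()
        if need.any():
            new = wide.loc[need, ["total", "cell_body"]]
            derived = (new["total"] - new["cell_body"]).clip(lower=0).reset_index()
            derived.columns = site + ["pct_area"]
            derived["measure"] = "neurite"
            df = pd.concat([df, derived[PATHOLOGY_COLUMNS]], ignore_index=True)
    return df


def write_pathology(df: pd.DataFrame, path: str | Path) -> None:
    df[PATHOLOGY_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x region TSV (genes as rows)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate region ids")
    return df


def write_expression(atlas: pd.DataFrame, path: str | Path) -> None:
    atlas.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_list(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in genes))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs name, description, >=1 gene")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    lines = []
    for name, members in sets.items():
        lines.append("\t".join([name, ""] + sorted(members)))
    Path(path).write_text("".join(ln + "\n" for ln in lines))


def read_vulnerability(path: str | Path) -> VulnerabilityMap:
    df = pd.read_csv(path, sep="\t")
    return VulnerabilityMap(
        region_ids=list(df["region_id"].astype(str)),
        score=df["score"].to_numpy(dtype=float),
        count=df["n_contributing"].to_numpy(dtype=int),
    )


def write_vulnerability(vmap: VulnerabilityMap, path: str | Path) -> None:
    vmap.frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def fitted_model_to_dict(fitted: FittedModel) -> dict:
    return {
        "mode": fitted.mode,
        "seed_region": fitted.seed_region,
        "c_a": fitted.params.c_a,
        "c_r": fitted.params.c_r,
        "sse": fitted.sse,
        "region_ids": fitted.region_ids,
        "timepoints": fitted.timepoints,
        "coefficients": {
            f"{t:g}": list(fitted.params.coeffs[t]) for t in fitted.timepoints
        },
        "pearson_r": {f"{t:g}": _nan_none(fitted.fits[t].r) for t in fitted.timepoints},
        "residuals": {
            f"{t:g}": [_nan_none(v) for v in fitted.fits[t].residuals]
            for t in fitted.timepoints
        },
    }


def _nan_none(v: float):
    return None if not np.isfinite(v) else float(v)


def write_fitted_model(fitted: FittedModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(fitted_model_to_dict(fitted), sort_keys=True, indent=1) + "\n"
    )


def read_fitted_model_params(path: str | Path) -> DiffusionParams:
    d = json.loads(Path(path).read_text())
    return DiffusionParams(
        c_a=d["c_a"],
        c_r=d["c_r"],
        coeffs={float(t): tuple(v) for t, v in d["coefficients"].items()},
    )
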