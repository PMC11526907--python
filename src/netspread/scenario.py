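"""The shipped synthetic scenario and its simulator.

One versioned configuration — 40 regions, the study's 8 timepoints, 5 mice
per timepoint, planted vulnerability offsets and 50 planted genes among
1,000 nulls — shared by the documentation, tests and acceptance runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import io as nio
from .synthetic import (
    DEFAULT_TIMEPOINTS,
    default_truth,
    synth_connectome,
    synth_expression,
    synth_pathology,
)

__all__ = ["DEFAULT_SCENARIO", "simulate_scenario"]

DEFAULT_SCENARIO = {
    "n_regions": 40,
    "density": 0.25,
    "hemispheres": False,
    "timepoints": list(DEFAULT_TIMEPOINTS),
    "n_mice": 5,
    "noise_sd": 0.1,
    "delta_sd": 0.15,
    "c_a": 0.5,
    "c_r": 2.0,
    "n_genes": 1050,
    "n_planted": 50,
    "true_r": 0.6,
    "n_kinases": 60,
}


def simulate_scenario(
    outdir: str | Path, rng_seed: int = 0, config: dict | None = None
) -> dict:
    """Generate a full synthetic study into ``outdir``.

    Writes ``connectome.tsv``, ``regions.tsv``, ``pathology.csv``,
    ``expression.tsv``, ``kinases.txt``, ``de_genes.txt``, ``sets.gmt`` and
    ``truth.json``; returns the paths plus the in-memory objects.  Derived
    sub-seeds keep each component's stream independent but reproducible.
    """
    cfg = {**DEFAULT_SCENARIO, **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(rng_seed)
    s_conn, s_truth, s_path, s_expr, s_lists = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)
    )

    conn = synth_connectome(
        cfg["n_regions"], cfg["density"], hemispheres=cfg["hemispheres"],
        rng_seed=s_conn,
    )
    truth = default_truth(
        conn, c_a=cfg["c_a"], c_r=cfg["c_r"], timepoints=cfg["timepoints"],
        delta_sd=cfg["delta_sd"], rng_seed=s_truth,
    )
    truth.rng_seed = rng_seed
    pathology = synth_pathology(
        conn, truth, cfg["timepoints"], n_mice=cfg["n_mice"],
        noise_sd=cfg["noise_sd"], rng_seed=s_path,
    )

    # expression planted against the true vulnerability offsets
    vuln_true = np.array([truth.delta.get(r, 0.0) for r in conn.region_ids])
    atlas, planted = synth_expression(
        conn.region_ids, vuln_true, n_genes=cfg["n_genes"],
        n_planted=cfg["n_planted"], true_r=cfg["true_r"], rng_seed=s_expr,
    )
    truth.planted_genes = planted
    truth.true_r = cfg["true_r"]

    # gene lists: kinases = half planted, half null; DE list overlaps planted
    rng = np.random.default_rng(s_lists)
    nulls = [g for g in atlas.index if g not in set(planted)]
    n_kin = cfg["n_kinases"]
    kinases = sorted(
        planted[: n_kin // 2] + list(rng.choice(nulls, n_kin - n_kin // 2, replace=False))
    )
    de_genes = sorted(
        planted[: n_kin // 4] + list(rng.choice(nulls, 40, replace=False))
    )
    gene_sets = {
        "PLANTED_SET": set(planted),
        "RANDOM_SET_A": set(rng.choice(nulls, 30, replace=False)),
        "RANDOM_SET_B": set(rng.choice(nulls, 30, replace=False)),
    }

    paths = {
        "connectome": outdir / "connectome.tsv",
        "regions": outdir / "regions.tsv",
        "pathology": outdir / "pathology.csv",
        "expression": outdir / "expression.tsv",
        "kinases": outdir / "kinases.txt",
        "de_genes": outdir / "de_genes.txt",
        "gene_sets": outdir / "sets.gmt",
        "truth": outdir / "truth.json",
    }
    nio.write_connectome(conn, paths["connectome"])
    nio.write_region_metadata(conn, paths["regions"])
    nio.write_pathology(pathology, paths["pathology"])
    nio.write_expression(atlas, paths["expression"])
    nio.write_gene_list(kinases, paths["kinases"])
    nio.write_gene_list(de_genes, paths["de_genes"])
    nio.write_gmt(gene_sets, paths["gene_sets"])
    paths["truth"].write_text(truth.to_json() + "\n")

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "conn": conn,
        "truth": truth,
        "pathology": pathology,
        "atlas": atlas,
        "config": cfg,
    }
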