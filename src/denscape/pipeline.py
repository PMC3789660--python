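"""End-to-end orchestration of the two-scale den-site selection analysis.

``run_homerange`` chains distance ratios → MANOVA → bootstrap CIs → t-tests
→ ranking; ``run_denarea`` chains standardization → VIF → separation
screening → model-set fitting → Akaike weights → model averaging → k-fold CV
→ substrate summaries.  Each run writes plain-CSV tables plus a JSON
manifest (config echo, per-stage seeds and row counts, warnings) sufficient
to reproduce it bit-for-bit.

A single master seed is expanded deterministically into per-stage seeds via
``numpy.random.SeedSequence(master).spawn`` in a fixed, documented stage
order: (0) landscape/simulation, (1) den placement, (2) random points,
(3) bootstrap, (4) choice data, (5) cross-validation.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import denarea, geospatial, homerange, landscape
from .geospatial import FEATURES, LandscapeMap

__version__ = "0.1.0"

log = logging.getLogger("denscape")

_STAGES = ("simulate_landscape", "place_dens", "random_points", "bootstrap", "choice_data", "kfold")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Expand the master seed into one integer seed per pipeline stage."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class RunConfig:
    """Analysis parameters for a pipeline run (defaults follow the study
    design: 800 m buffers, 200 random points per buffer, 1000 bootstrap
    reps, ΔAICc ≤ 4 confidence set)."""

    radius_m: float = 800.0
    n_random: int = 200
    boot_reps: int = 1000
    delta_threshold: float = 4.0
    kfold: int = 10
    alpha: float = 0.05
    k_offset: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("radius_m", "n_random", "boot_reps", "delta_threshold", "kfold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def _manifest(config: RunConfig, stage: str, **extra) -> dict:
    return {
        "software": f"denscape {__version__}",
        "stage": stage,
        "config": asdict(config),
        "stage_seeds": stage_seeds(config.seed),
        **extra,
    }


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_homerange(
    config: RunConfig,
    dens: pd.DataFrame,
    landscape_map: LandscapeMap,
    out_dir: str | None = None,
) -> dict:
    """Home-range-scale analysis; returns a dict of result tables and the
    manifest, optionally writing CSV/JSON files to ``out_dir``."""
    seeds = stage_seeds(config.seed)
    log.info("homerange: computing distance ratios for %d dens", len(dens))
    matrix = homerange.compute_distance_ratios(
        dens, landscape_map, n_random=config.n_random, radius_m=config.radius_m,
        seed=seeds["random_points"],
    )
    manova = homerange.manova_vs_ones(matrix)
    table = homerange.selection_table(
        matrix, reps=config.boot_reps, seed=seeds["bootstrap"], alpha=config.alpha
    )
    fig2 = table[["feature", "ratio", "lo", "hi"]].rename(columns={"ratio": "mean"})
    manifest = _manifest(
        config,
        "homerange",
        n_dens=len(dens),
        n_features=len(FEATURES),
        manova={
            "pillai_trace": manova.pillai_trace,
            "f_stat": manova.f_stat,
            "df1": manova.df1,
            "df2": manova.df2,
            "p_value": manova.p_value,
        },
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        _write_csv(table, os.path.join(out_dir, "selection_table.csv"))
        _write_csv(fig2, os.path.join(out_dir, "ratio_cis.csv"))
        _write_csv(
            matrix.reset_index(drop=True), os.path.join(out_dir, "distance_ratios.csv")
        )
        with open(os.path.join(out_dir, "homerange_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"matrix": matrix, "manova": manova, "table": table, "cis": fig2, "manifest": manifest}


def run_denarea(
    config: RunConfig,
    choice_df: pd.DataFrame,
    out_dir: str | None = None,
    specs: list | None = None,
) -> dict:
    """Den-area-scale analysis; returns model/averaging/CV tables and the
    manifest, optionally writing CSV/JSON files to ``out_dir``."""
    seeds = stage_seeds(config.seed)
    denarea.split_choice_sets(choice_df)  # validate structure early
    std_df, scale = denarea.standardize_covariates(choice_df)
    vif = denarea.compute_vif(std_df[list(denarea.CONTINUOUS_COVARIATES)])

    warnings_list = []
    substrate_report = denarea.detect_separation(choice_df, "substrate")
    if substrate_report.separated:
        warnings_list.append(
            f"substrate shows {substrate_report.flag} separation "
            f"({substrate_report.rule}); summarized descriptively, not fitted"
        )
    specs = specs if specs is not None else denarea.candidate_models()
    for spec in specs:
        for term in spec.terms:
            if ":" in term:
                continue
            rep = denarea.detect_separation(std_df, term)
            if rep.flag == "complete":
                raise denarea.SeparationError(
                    f"modelled term {term!r} exhibits complete separation ({rep.rule}); "
                    "remove it from the candidate set"
                )

    fits = denarea.fit_model_set(specs, std_df, k_offset=config.k_offset)
    table2 = denarea.model_table(fits)
    table3 = denarea.average_models(fits, delta_threshold=config.delta_threshold)
    cv_delta = denarea.kfold_cv(
        fits[0].spec, std_df, k=min(int(config.kfold), choice_df["set_id"].nunique()),
        seed=seeds["kfold"],
    )
    fig3 = denarea.substrate_proportions(choice_df)
    manifest = _manifest(
        config,
        "denarea",
        n_rows=len(choice_df),
        n_sets=int(choice_df["set_id"].nunique()),
        standardization={c: {"mean": m, "sd": s} for c, (m, s) in scale.items()},
        vif=vif.to_dict(),
        separation={
            "term": substrate_report.term,
            "flag": substrate_report.flag,
            "sensitivity": substrate_report.sensitivity,
            "specificity": substrate_report.specificity,
        },
        cv={"k": min(int(config.kfold), choice_df["set_id"].nunique()), "delta": cv_delta},
        warnings=warnings_list,
    )
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        _write_csv(table2, os.path.join(out_dir, "model_ranking.csv"))
        _write_csv(table3, os.path.join(out_dir, "averaged_estimates.csv"))
        _write_csv(fig3, os.path.join(out_dir, "substrate_proportions.csv"))
        with open(os.path.join(out_dir, "denarea_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "model_table": table2,
        "averaged": table3,
        "cv_delta": cv_delta,
        "substrate": fig3,
        "fits": fits,
        "vif": vif,
        "manifest": manifest,
    }


def simulate_inputs(
    config: RunConfig,
    n_dens: int = 26,
    n_sets: int = 26,
    m_available: int = 4,
    truth: landscape.SelectionTruth | None = None,
    landscape_config: landscape.LandscapeConfig | None = None,
):
    """Generate a landscape, dens and choice sets under a known truth.

    Dens are placed in the extent inset by the buffer radius so every buffer
    stays inside the mapped area.
    """
    seeds = stage_seeds(config.seed)
    truth = truth if truth is not None else landscape.default_truth()
    lc = landscape_config if landscape_config is not None else landscape.LandscapeConfig(
        seed=seeds["simulate_landscape"]
    )
    lmap = landscape.generate_landscape(lc)
    dens = landscape.place_dens(
        lmap, truth, n_dens, seed=seeds["place_dens"], margin_m=config.radius_m
    )
    choice = landscape.generate_choice_data(
        n_sets, m_available, truth, seed=seeds["choice_data"]
    )
    return lmap, dens, choice


def make_fixtures(seed: int, out_dir: str) -> dict[str, str]:
    """Write a small fixture dataset emulating the study design: a mosaic
    landscape, 26 dens placed under grassland selection, and 26 choice sets
    of 1 used + 4 available rows.  Same seed, same bytes."""
    os.makedirs(out_dir, exist_ok=True)
    config = RunConfig(seed=seed)
    lc = landscape.LandscapeConfig(
        extent_m=(4000.0, 4000.0), n_patches=60, n_roads=5,
        seed=stage_seeds(seed)["simulate_landscape"],
    )
    lmap, dens, choice = simulate_inputs(config, landscape_config=lc)
    paths = {
        "landscape": os.path.join(out_dir, "landscape.geojson"),
        "dens": os.path.join(out_dir, "dens.csv"),
        "choice_sets": os.path.join(out_dir, "choice_sets.csv"),
    }
    geospatial.write_landscape(lmap, paths["landscape"])
    _write_csv(dens, paths["dens"])
    _write_csv(choice, paths["choice_sets"])
    return paths
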