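"""End-to-end orchestration: preprocess -> cluster -> mixed models -> PLS.

Every stage writes its intermediate artifact as CSV (plus JSON sidecars),
so any number in the final report can be traced to an on-disk file, and a
run manifest records the seed, thresholds, counts and timings.  All
randomness flows through the single seed recorded in the manifest; a rerun
with the same seed reproduces the numeric outputs byte for byte.
"""

from __future__ import annotations

import json
import sys
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    build_habituation_space,
    cityblock_to_centroids,
    kmeans_curves,
    label_centroids,
    silhouette_profile,
)
from .curves import CurveSet
from .datasets import load_table1, synthesize_oav, assign_sessions
from .design import assemble_X, assemble_Y, autoscale, sensory_means
from .mixed import fit_odorant_lmm, pairwise_fdr
from .pls import fit_pls, interpret, loo_rmsep, select_components, explained_variance
from .preprocess import ExclusionRules, apply_exclusions, normalize_intensity, parse_recordings
from .simulate import default_config, default_truth, generate_cohort, write_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run; defaults follow the study."""

    recordings: str | None = None     # None -> simulate a default cohort
    ratings: str | None = None
    descriptors: str | None = None    # None -> packaged descriptor table
    out_dir: str = "odorhab_run"
    seed: int = 1
    # exclusion stage
    delay_max_s: float = 17.0
    chaos_rate_threshold: float = 0.5
    # clustering stage
    k: int = 3
    k_range: tuple[int, ...] = ()     # e.g. (2, 3, 4, 5) to profile silhouettes
    n_restarts: int = 50
    # regression stage
    a_max: int = 10
    lw_threshold: float = 0.3
    loading_threshold: float = 0.2
    vip_threshold: float = 1.0
    # mixed models
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if min(self.delay_max_s, self.chaos_rate_threshold, self.a_max, self.alpha) <= 0:
            raise ValueError("thresholds must be positive")


def _log(msg: str) -> None:
    print(f"[odorhab] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write all artifacts under out_dir.

    Returns the run manifest (also written as ``manifest.json``).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": {k: v for k, v in asdict(config).items()},
                      "stages": {}}

    for name in ("recordings", "ratings", "descriptors"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"{name} file not found: {path}")

    # ---- inputs -----------------------------------------------------------
    if config.descriptors is not None:
        descriptors = pd.read_csv(config.descriptors, index_col=0)
    else:
        descriptors = load_table1()
    if "oav" not in descriptors.columns:
        descriptors["oav"] = synthesize_oav(descriptors, seed=config.seed)
    if "pres_order" not in descriptors.columns:
        descriptors["pres_order"] = assign_sessions(descriptors)

    if config.recordings is None:
        _log("no recordings given: simulating the default cohort")
        truth = default_truth(seed=config.seed)
        cohort = default_config(odorants=descriptors)
        curves, ratings, cohort_truth = generate_cohort(cohort, truth)
        write_cohort(out / "simulated", curves, ratings, cohort_truth)
        manifest["stages"]["simulate"] = cohort_truth.counts()
    else:
        curves = parse_recordings(config.recordings)
        ratings = pd.read_csv(config.ratings) if config.ratings else None

    # ---- preprocess -------------------------------------------------------
    t = time.time()
    rules = ExclusionRules(
        delay_max_s=config.delay_max_s, chaos_rate_threshold=config.chaos_rate_threshold
    )
    retained, report = apply_exclusions(curves, rules, session_of=descriptors["pres_order"])
    normalized = normalize_intensity(retained)
    (out / "exclusion_report.json").write_text(report.to_json())
    normalized.write_csv(out / "retained_curves.csv")
    manifest["stages"]["preprocess"] = {
        "n_input": report.n_input_curves,
        "n_retained": report.n_retained,
        "seconds": round(time.time() - t, 2),
    }
    _log(f"preprocess: retained {report.n_retained}/{report.n_input_curves} curves")

    # ---- clustering -------------------------------------------------------
    t = time.time()
    if config.k_range:
        prof = silhouette_profile(
            normalized, config.k_range, n_restarts=config.n_restarts, seed=config.seed
        )
        pd.Series(prof, name="mean_silhouette").rename_axis("k").to_csv(
            out / "silhouette_profile.csv"
        )
        manifest["stages"]["silhouette"] = {str(k): v for k, v in prof.items()}
    cs = label_centroids(
        kmeans_curves(normalized, config.k, n_restarts=config.n_restarts, seed=config.seed)
    )
    centroid_frame = pd.DataFrame(
        cs.centroids.T, index=pd.Index(cs.times, name="time_s"),
        columns=[cs.labels[i] for i in range(cs.k)],
    )
    centroid_frame.to_csv(out / "centroids.csv")
    distances = cityblock_to_centroids(normalized, cs)
    distances.to_csv(out / "curve_distances.csv", index=False)
    space = build_habituation_space(distances)
    n_odorants_in = distances["odorant_id"].nunique()
    if len(space) < n_odorants_in:
        warnings.warn("some odorants lost all curves and were dropped from the space")
    space.to_csv(out / "habituation_space.csv")
    manifest["stages"]["cluster"] = {
        "k": cs.k,
        "inertia": float(cs.inertia),
        "n_odorants": int(len(space)),
        "seconds": round(time.time() - t, 2),
    }
    _log(f"clustering: k={cs.k}, {len(space)} odorants in the habituation space")

    # ---- mixed models -----------------------------------------------------
    t = time.time()
    mm_summary = {}
    omnibus_rows = []
    for coord, col in (("lowhab", "d_low"), ("midhab", "d_mid"), ("highhab", "d_high")):
        fit = fit_odorant_lmm(distances, col)
        rep = pairwise_fdr(fit, alpha=config.alpha)
        rep.pairwise.to_csv(out / f"pairwise_{coord}.csv", index=False)
        omnibus_rows.append(
            {"coordinate": coord, "F": rep.f_statistic, "df_num": rep.df_num,
             "df_den": rep.df_den, "p": rep.p_value, "n_significant": rep.n_significant}
        )
        mm_summary[coord] = {"F": rep.f_statistic, "n_significant": rep.n_significant}
    pd.DataFrame(omnibus_rows).to_csv(out / "omnibus.csv", index=False)
    manifest["stages"]["mixed_models"] = {
        **{k: v for k, v in mm_summary.items()}, "seconds": round(time.time() - t, 2)
    }
    _log("mixed models: omnibus + pairwise tables written")

    # ---- design matrices + PLS -------------------------------------------
    t = time.time()
    sens = sensory_means(ratings) if ratings is not None else None
    X_raw, meta = assemble_X(descriptors.loc[space.index], sensory=sens)
    Y_raw = assemble_Y(space, odorant_order=X_raw.index)
    Xs, x_means, x_scales = autoscale(X_raw)
    Ys, y_means, y_scales = autoscale(Y_raw)
    X_raw.to_csv(out / "X_matrix.csv")
    Y_raw.to_csv(out / "Y_matrix.csv")
    (out / "X_metadata.json").write_text(
        json.dumps([asdict(mt) for mt in meta], indent=2)
    )

    a_max = min(config.a_max, len(Xs) - 2, Xs.shape[1])
    rmsep = loo_rmsep(X_raw.to_numpy(), Y_raw, a_max, scale=True)
    rmsep.to_csv(out / "rmsep.csv")
    per_response, a_star = select_components(rmsep)
    fit = fit_pls(Xs.to_numpy(), Ys.to_numpy(), a_star)
    ev = explained_variance(fit)
    ev.columns = ["X", *Y_raw.columns]
    ev.to_csv(out / "explained_variance.csv")
    loadings = pd.DataFrame(
        fit.x_weights_, index=X_raw.columns,
        columns=[f"comp{a}" for a in range(1, fit.n_components_ + 1)],
    )
    loadings.to_csv(out / "loading_weights.csv")
    pd.DataFrame(
        fit.y_loadings_, index=Y_raw.columns, columns=loadings.columns
    ).to_csv(out / "y_loadings.csv")
    pd.Series(fit.vip_, index=X_raw.columns, name="vip").to_csv(out / "vip.csv")
    report_pls = interpret(
        fit, X_raw.columns, Y_raw.columns,
        lw_threshold=config.lw_threshold,
        loading_threshold=config.loading_threshold,
        vip_threshold=config.vip_threshold,
    )
    report_pls.summary.to_csv(out / "determinants.csv", index=False)
    manifest["stages"]["pls"] = {
        "a_per_response": per_response,
        "a_selected": a_star,
        "x_shape": list(X_raw.shape),
        "explained_x_cum": float(fit.explained_x_variance_.sum()),
        "n_vip_gt_1": int((fit.vip_ > config.vip_threshold).sum()),
        "seconds": round(time.time() - t, 2),
    }
    _log(f"pls: selected {a_star} components; X is {X_raw.shape[0]}x{X_raw.shape[1]}")

    manifest["total_seconds"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
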