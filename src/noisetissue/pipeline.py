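"""Pipeline stages: each runs one analysis end to end and writes CSV output.

Stages never mutate their inputs; warnings (excluded nuclei, skipped
images) go both to the log and to a machine-readable ``qc.json`` sidecar.
When no input table is configured, the data-requiring stages synthesize one
with the configured generator so that every stage is runnable standalone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import inheritance as inh
from . import io as ntio
from . import model, noise, spatial, synthetic
from .config import RunConfig, stage_seed
from .errors import EstimationError, ParameterError
from .measurements import average_duplicates, cell_matrix, ks_skew_filter, normalize_table

__all__ = ["STAGES", "run_pipeline"]

log = logging.getLogger("noisetissue")

STAGES = ("synth", "simulate", "kik-decay", "temporal", "noise", "spatial", "tiers", "inherit")


def _load_or_synthesize(config: RunConfig, stage: str, kik: bool):
    if config.input_table is not None:
        return ntio.read_nucleus_table(config.input_table), None
    seed = stage_seed(config.master_seed, stage)
    if kik:
        table, truth = synthetic.generate_kik_timecourse(
            config.params, config.extrinsic, n_cells=config.kik_n_cells,
            noise_sigma=config.kik_noise_sigma, seed=seed)
    else:
        table, truth = synthetic.generate_tissue(
            dataclasses.replace(config.tissue, seed=seed))
    log.info("synthesized %s table: %d rows, seed %d", "time-course" if kik else "tissue",
             len(table), seed)
    return table, truth


def _normalized_images(config: RunConfig, stage: str, qc: dict):
    """Per-image normalized tables that pass the channel-skew screen."""
    from .measurements import NucleusTable

    table, _ = _load_or_synthesize(config, stage, kik=False)
    table = normalize_table(average_duplicates(table))
    qc["excluded_rows"] = {f"{k[0]}/{k[1]}": v for k, v in table.excluded_counts.items()}
    kept = []
    for image_id, df in table.data.groupby("image_id", sort=False):
        img = NucleusTable(df.reset_index(drop=True), state=table.state)
        wide = cell_matrix(img, channels=config.tissue.channels)
        dec = ks_skew_filter(wide[config.tissue.channels[0]],
                             wide[config.tissue.channels[1]], alpha=config.ks_alpha)
        if dec.keep:
            kept.append((image_id, img))
        else:
            log.warning("image %s excluded by KS screen (p = %.4g)", image_id, dec.p_value)
            qc.setdefault("ks_excluded_images", []).append(
                {"image_id": str(image_id), "p": dec.p_value})
    if not kept:
        raise EstimationError("all images excluded by the KS screen")
    return kept


def run_pipeline(config: RunConfig, stage: str, out_dir) -> dict:
    """Execute one named stage, writing its CSV outputs under ``out_dir``.

    Returns a small dict of the stage's headline numbers (also logged).
    """
    if stage not in STAGES:
        raise ParameterError(f"unknown stage {stage!r}; choose from {', '.join(STAGES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc: dict = {"stage": stage, "master_seed": config.master_seed}
    result: dict = {}

    if stage == "synth":
        table, truth = _load_or_synthesize(config, stage, kik=False)
        ntio.write_nucleus_table(table, out / "tissue.csv")
        if truth is not None:
            truth.cells.to_csv(out / "ground_truth.csv", index=False)
            qc["analytic"] = {"eta2_int": truth.eta2_int_analytic,
                              "eta2_ext": truth.eta2_ext_analytic}
        result = {"rows": len(table), "cells": table.n_cells}

    elif stage == "simulate":
        rng = np.random.default_rng(stage_seed(config.master_seed, stage))
        frames = []
        for i in range(3):
            v1 = model.draw_translation_rate(config.extrinsic, rng)
            traj = model.ssa_two_stage(config.params, v1, t_conversion=0.0, t_end=6.0,
                                       seed=rng)
            traj.cell_id = f"cell_{i}"
            frames.append(traj.to_frame())
        pd.concat(frames, ignore_index=True).to_csv(out / "trajectories.csv", index=False)
        result = {"n_trajectories": 3}

    elif stage == "kik-decay":
        table, _ = _load_or_synthesize(config, stage, kik=True)
        table = average_duplicates(table)
        df = table.data
        red = df[df["channel"] == "KikR"]
        r1 = red[red["time_h"] == config.decay_t1_h].set_index("cell_id")["mean_grey"]
        r2 = red[red["time_h"] == config.decay_t2_h].set_index("cell_id")["mean_grey"]
        common = r1.index.intersection(r2.index)
        bg = red["background_mean_grey"].iloc[0]
        est = model.estimate_decay_rate(r1[common] - bg, r2[common] - bg,
                                        config.decay_t2_h - config.decay_t1_h)
        pd.DataFrame([est._asdict()]).to_csv(out / "decay_rate.csv", index=False)
        qc["excluded_nuclei"] = est.n_excluded
        result = {"decay_rate_per_h": est.rate, "se": est.se, "n": est.n_used}

    elif stage == "temporal":
        table, _ = _load_or_synthesize(config, stage, kik=True)
        table = normalize_table(average_duplicates(table))
        df = table.data
        green = df[df["channel"] == "KikG"]
        rows = []
        for image_id, img in green.groupby("image_id", sort=False):
            a = img[img["time_h"] == config.decay_t1_h].set_index("cell_id")["mean_grey"]
            b = img[img["time_h"] == config.decay_t2_h].set_index("cell_id")["mean_grey"]
            common = a.index.intersection(b.index)
            rows.append({
                "image_id": image_id, "n_cells": len(common),
                "pearson": stats.pearsonr(a[common], b[common]).statistic,
                "spearman": stats.spearmanr(a[common], b[common]).statistic,
            })
        res = pd.DataFrame(rows)
        res.to_csv(out / "temporal_correlation.csv", index=False)
        result = {"mean_pearson": float(res["pearson"].mean()),
                  "mean_spearman": float(res["spearman"].mean())}

    elif stage == "noise":
        kept = _normalized_images(config, stage, qc)
        results, summary = noise.aggregate_noise([img for _, img in kept],
                                                 channels=config.tissue.channels)
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            out / "noise_per_image.csv", index=False)
        summary.to_csv(out / "noise_summary.csv", index=False)
        result = {"n_images": len(results),
                  "median_eta2_int": float(np.median([r.eta2_int for r in results])),
                  "median_eta2_ext": float(np.median([r.eta2_ext for r in results]))}

    elif stage in ("spatial", "tiers"):
        kept = _normalized_images(config, stage, qc)
        cfg = dataclasses.replace(config.spatial,
                                  seed=stage_seed(config.master_seed, "spatial"),
                                  channels=config.tissue.channels)
        rows = []
        for image_id, img in kept:
            try:
                res = spatial.analyze_spatial(img, cfg)
            except EstimationError as exc:
                log.warning("image %s skipped: %s", image_id, exc)
                qc.setdefault("skipped_images", []).append(str(image_id))
                continue
            for tier in res.tier_profile:
                rows.append({"image_id": image_id, "r": res.r, "p": res.p,
                             "n_cells": res.n_cells,
                             "mean_nn_distance_um": res.mean_nn_distance,
                             "tier_index": tier.tier, "tier_mean": tier.mean,
                             "tier_sd": tier.sd})
        if not rows:
            raise EstimationError("no image yielded a defined spatial estimate")
        df = pd.DataFrame(rows)
        df.to_csv(out / "spatial_results.csv", index=False)
        result = {"r": float(df["r"].iloc[0]), "p": float(df["p"].iloc[0]),
                  "n_images": int(df["image_id"].nunique())}

    elif stage == "inherit":
        rows = []
        for mode in inh.MODES:
            cfg = config.inheritance_config(mode)
            ens = inh.simulate_division_pairs(cfg)
            r = inh.sibling_correlation(ens)
            se = (1 - r**2) / np.sqrt(cfg.n_pairs)
            rows.append({"mode": mode, "n_pairs": cfg.n_pairs,
                         "mean_division_age_h": ens.mean_age_used,
                         "r": r, "mc_se": se, "seed": cfg.seed})
            result[f"r_{mode}"] = r
        pd.DataFrame(rows).to_csv(out / "inheritance.csv", index=False)
        result["mean_division_age_h"] = rows[0]["mean_division_age_h"]

    (out / "qc.json").write_text(json.dumps(qc, indent=2, default=str))
    log.info("stage %s done: %s", stage, result)
    return result
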