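"""End-to-end orchestration: simulate -> preprocess -> connectivity -> stats.

``run_all`` executes the whole analysis for a configuration and writes all
result tables (CSV) plus a manifest with the seed and config hash, so that
an identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, truth_from_config
from .connectivity import granger_matrix, to_edge_list
from .preprocess import apply_montage, bandpass_resample, reject_artifacts, segment
from .session import build_session
from .signals import simulate_rest_recording
from .simulate import BehaviorParams, sample_cohort, simulate_behavior
from .stats import (
    ModelSpec,
    SmoothSpec,
    build_design,
    evaluate_smooth,
    fdr_correct,
    fit_behavior_models,
    fit_penalized,
    test_smooths,
)

__all__ = ["run_all", "analyze_edge_table", "compare_conditions"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def _seed(cfg_seed: int, *path: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(cfg_seed) % (2**31), *path])


def simulate_condition_edges(
    cfg: RunConfig, cohort: pd.DataFrame, condition: str, cond_index: int
) -> pd.DataFrame:
    """Simulate, preprocess and estimate GC for every participant."""
    truth = truth_from_config(cfg, condition)
    matrices = []
    identity_montage = {lab: [lab] for lab in truth.roi_labels}
    for i, (_, prof) in enumerate(cohort.iterrows()):
        rec = simulate_rest_recording(
            prof,
            truth,
            duration_s=cfg.duration_s,
            fs=cfg.fs,
            seed=_seed(cfg.seed, 1, cond_index, i),
        )
        rec = bandpass_resample(rec, low_hz=cfg.highpass_hz, high_hz=None, target_fs=cfg.fs)
        segs = segment(rec, seg_s=cfg.seg_s)
        kept, _ = reject_artifacts(segs)
        if not kept:
            raise RuntimeError(
                f"all segments of {prof['participant_id']}/{condition} rejected"
            )
        roi_segs = apply_montage(kept, identity_montage)
        matrices.append(
            granger_matrix(
                roi_segs,
                order_policy=cfg.order_policy,
                max_order=cfg.max_order,
                condition=condition,
                participant_id=prof["participant_id"],
            )
        )
    return to_edge_list(matrices, cohort)


def analyze_edge_table(edge_table: pd.DataFrame, cfg: RunConfig):
    """Fit the factor-smooth model to one condition's edge table.

    Returns (results table, fit).  The results table has one row per
    directed connection with the smooth edf, test statistic, raw and
    FDR-adjusted p-value and the significance flag at ``cfg.fdr_q``.
    """
    spec = ModelSpec(
        smooth=SmoothSpec(k=cfg.k, penalty=cfg.penalty),
        re_penalty=cfg.re_penalty,
    )
    design = build_design(edge_table, spec)
    fit = fit_penalized(design)
    res = test_smooths(
        fit, method=cfg.test_method, n_boot=cfg.n_boot, seed=_seed(cfg.seed, 2)
    )
    p_adj, rej = fdr_correct(res["p_value"], q=cfg.fdr_q)
    res = res.rename(columns={"p_value": "p_raw"})
    res["p_fdr"] = p_adj
    res["significant"] = rej
    return res, fit


def _smooth_values(fit, connections: list[str]) -> pd.DataFrame:
    frames = []
    for conn in connections:
        grid, vals = evaluate_smooth(fit, conn)
        frames.append(
            pd.DataFrame({"connection": conn, "lsbq": grid, "smooth": vals})
        )
    if not frames:
        return pd.DataFrame(columns=["connection", "lsbq", "smooth"])
    return pd.concat(frames, ignore_index=True)


def compare_conditions(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Shared/condition-specific significant connections across conditions.

    Expects per-condition result tables over an identical connection set.
    """
    conds = list(results)
    sets = {}
    base = None
    for cond, res in results.items():
        conns = set(res["connection"])
        if base is None:
            base = conns
        elif conns != base:
            raise ValueError("conditions cover different connection sets")
        sets[cond] = set(res.loc[res["significant"], "connection"])
    rows = []
    for conn in sorted(base):
        flags = {c: conn in sets[c] for c in conds}
        if any(flags.values()):
            rows.append(
                {
                    "connection": conn,
                    **{f"significant_{c}": flags[c] for c in conds},
                    "shared": all(flags.values()),
                }
            )
    return pd.DataFrame(
        rows, columns=["connection", *[f"significant_{c}" for c in conds], "shared"]
    )


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write result files to ``cfg.out_dir``.

    Returns a summary dict with the per-condition results tables, the
    comparison table and the output paths.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = sample_cohort(cfg.n_participants, seed=_seed(cfg.seed, 0))
    cohort.to_csv(out / "cohort.csv", index=False, float_format=_FLOAT_FMT)

    summary: dict = {"results": {}, "paths": {"cohort": str(out / "cohort.csv")}}

    if cfg.include_behavior:
        session = build_session(seed=int(_seed(cfg.seed, 3).generate_state(1)[0] % 2**31))
        behavior = simulate_behavior(
            cohort, session, BehaviorParams(), seed=_seed(cfg.seed, 4)
        )
        behavior.to_csv(out / "behavior_trials.csv", index=False, float_format=_FLOAT_FMT)
        beh_models = fit_behavior_models(behavior)
        beh_rows = []
        for level, table in beh_models.items():
            t = table.copy()
            t.insert(0, "ambiguity_level", level)
            beh_rows.append(t)
        beh_table = pd.concat(beh_rows, ignore_index=True)
        beh_table.to_csv(out / "behavior_models.csv", index=False, float_format=_FLOAT_FMT)
        summary["behavior_models"] = beh_models
        summary["paths"]["behavior_models"] = str(out / "behavior_models.csv")

    results = {}
    for ci, cond in enumerate(cfg.conditions):
        logger.info("condition %s: simulating %d participants", cond, cfg.n_participants)
        edges = simulate_condition_edges(cfg, cohort, cond, ci)
        edges.to_csv(out / f"edges_{cond}.csv", index=False, float_format=_FLOAT_FMT)
        res, fit = analyze_edge_table(edges, cfg)
        res.to_csv(out / f"results_{cond}.csv", index=False, float_format=_FLOAT_FMT)
        sig = list(res.loc[res["significant"], "connection"])
        _smooth_values(fit, sig).to_csv(
            out / f"smooths_{cond}.csv", index=False, float_format=_FLOAT_FMT
        )
        results[cond] = res
        summary["results"][cond] = res
        summary["paths"][f"results_{cond}"] = str(out / f"results_{cond}.csv")

    if len(results) > 1:
        comparison = compare_conditions(results)
        comparison.to_csv(out / "comparison.csv", index=False)
        summary["comparison"] = comparison
        summary["paths"]["comparison"] = str(out / "comparison.csv")

    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "package_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    summary["paths"]["manifest"] = str(out / "manifest.json")
    return summary
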