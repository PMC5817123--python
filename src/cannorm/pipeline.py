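"""End-to-end analysis pipeline.

Stages: (1) symmetrize + superimpose the dorsal head configurations and
superimpose the lateral body configurations; (2) integrate the two shape
blocks by two-block PLS and summarize the PLS1 plane by its dominant axis
(the shape score, oriented so cannibal-like specimens score low) and the
SVL-HeadCS plane by its dominant axis (the size score, oriented so larger
specimens score high); (3) per-population distribution statistics and the
census correlation suite; (4) planned-contrast ANOVA of noncannibal scores
and AIC model selection for cannibal responses.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import model_selection as ms
from .group_discrimination import cva
from .integration_stats import pca_scores, two_block_pls
from .population_norm import (
    anova_planned_contrasts,
    census_correlation_suite,
    population_distribution_stats,
    summaries_to_blocks,
)
from .procrustes_core import centroid_size, gpa, symmetrize_bilateral
from .sma_regression import sma_fit
from .synthetic_data import SyntheticStudy

__all__ = ["ScoreTable", "score_study", "population_stage", "model_stage", "run_pipeline"]


@dataclass
class ScoreTable:
    """Per-specimen score table with columns pls1_dorsal, pls1_lateral,
    pc1_shape, pc2_shape, svl, head_cs, pc1_size, pc2_size plus metadata."""

    frame: pd.DataFrame
    pls_pct_sq_cov: float
    pls_r1: float
    shape_pct_variance: np.ndarray
    size_pct_variance: np.ndarray


def score_study(study: SyntheticStudy) -> ScoreTable:
    """Alignment + integration: landmark configurations to score table."""
    halves, head_cs = [], []
    for cfg in study.dorsal:
        full, half = symmetrize_bilateral(cfg)
        head_cs.append(centroid_size(full))
        halves.append(half)
    aligned_d = gpa(halves)
    aligned_l = gpa(study.lateral)

    pls = two_block_pls(aligned_d.flat(), aligned_l.flat())
    meta = study.truth[["specimen_id", "tank_id", "category"]].reset_index(drop=True)
    cannibal_low = -(meta["category"] == "Cannibal").astype(float).to_numpy()

    shape_plane = np.column_stack([pls.scores_left, pls.scores_right])
    shape_pca = pca_scores(shape_plane, orient_by=cannibal_low)

    svl = np.array([m.SVL for m in study.measurements])
    size_plane = np.column_stack([svl, np.array(head_cs)])
    size_pca = pca_scores(size_plane, orient_by=svl)

    frame = meta.copy()
    frame["pls1_dorsal"] = pls.scores_left
    frame["pls1_lateral"] = pls.scores_right
    frame["pc1_shape"] = shape_pca.scores[:, 0]
    frame["pc2_shape"] = shape_pca.scores[:, 1]
    frame["svl"] = svl
    frame["head_cs"] = head_cs
    frame["pc1_size"] = size_pca.scores[:, 0]
    frame["pc2_size"] = size_pca.scores[:, 1]
    return ScoreTable(
        frame=frame,
        pls_pct_sq_cov=float(pls.pct_sq_cov[0]),
        pls_r1=pls.r_pls1,
        shape_pct_variance=shape_pca.pct_variance,
        size_pct_variance=size_pca.pct_variance,
    )


def population_stage(scores: ScoreTable, census, n_perm: int = 10_000, seed=None):
    """Population summaries plus the census correlation suite."""
    tbl = scores.frame.rename(columns={"pc1_size": "pc1_size", "pc1_shape": "pc1_shape"})
    summaries = population_distribution_stats(tbl, census=census)
    suite = census_correlation_suite(summaries, n_perm=n_perm, seed=seed)
    return summaries, suite


def model_stage(scores: ScoreTable, summaries):
    """Nonlinear curves for cannibal means and Models 1-6 for largest cannibals."""
    df = scores.frame
    by_tank = {s.tank_id: s for s in summaries}
    rows = []
    for tank, s in by_tank.items():
        if tank == "sol":
            sub = df[df["category"] == "Solitary"]
        else:
            sub = df[(df["tank_id"] == tank) & (df["category"] == "Cannibal")]
        if sub.empty:
            continue
        largest = sub.loc[sub["pc1_size"].idxmax()]
        rows.append(
            dict(
                tank_id=tank, x1=s.x1, x2=s.x2,
                mean_size=sub["pc1_size"].mean(), mean_shape=sub["pc1_shape"].mean(),
                largest_size=largest["pc1_size"], largest_shape=largest["pc1_shape"],
            )
        )
    tanks = pd.DataFrame(rows)
    out = {"tanks": tanks}
    # nonlinear curves on cannibal (plus zero-victim Solitary) means
    out["nonlinear_size"] = ms.compare_nonlinear(tanks["x2"], tanks["mean_size"])
    out["nonlinear_shape"] = ms.compare_nonlinear(tanks["x2"], tanks["mean_shape"])
    hd = tanks[tanks["tank_id"] != "sol"]
    if len(hd) >= 6:
        out["largest_size"] = ms.select_largest_cannibal_models(
            hd["x1"], hd["x2"], hd["largest_size"]
        )
        out["largest_shape"] = ms.select_largest_cannibal_models(
            hd["x1"], hd["x2"], hd["largest_shape"]
        )
    return out


def run_pipeline(
    study: SyntheticStudy,
    outdir: str | Path,
    n_perm: int = 999,
    seed: int = 0,
    stages=("align", "integrate", "discriminate", "populations", "models"),
) -> dict:
    """Run the requested stages on a study and write a CSV/JSON report bundle.

    Returns the JSON-serializable summary that is also written to
    ``summary.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"seed": seed, "n_permutations": n_perm, "stages": list(stages)}

    scores = score_study(study)
    if "integrate" in stages or "align" in stages:
        scores.frame.to_csv(out / "scores.csv", index=False)
        summary["integration"] = {
            "pls1_pct_sq_cov": scores.pls_pct_sq_cov,
            "r_pls1": scores.pls_r1,
            "pc1_shape_pct": float(scores.shape_pct_variance[0]),
            "pc1_size_pct": float(scores.size_pct_variance[0]),
        }

    if "discriminate" in stages:
        rng = np.random.default_rng(seed)
        labels = scores.frame["category"].to_numpy()
        flat = scores.frame[["pls1_dorsal", "pls1_lateral"]].to_numpy()
        cv = cva(flat, labels, n_pca_retain=2)
        pd.DataFrame(
            dict(specimen_id=scores.frame["specimen_id"], cv1=cv.scores[:, 0])
        ).to_csv(out / "cv_scores.csv", index=False)
        summary["discrimination"] = {"cva_eigenvalues": cv.eigenvalues.tolist()}

    if "populations" in stages:
        summaries, suite = population_stage(
            scores, study.census, n_perm=n_perm, seed=seed
        )
        df, X, Y = summaries_to_blocks(summaries)
        df.to_csv(out / "population_summary.csv", index=False)
        fit = sma_fit(df["x1"], df["x2"])
        summary["census_sma"] = {"slope": fit.slope, "intercept": fit.intercept}
        summary["census_suite"] = suite
        nc = scores.frame[scores.frame["category"].isin(["NonCannibal", "Solitary"])]
        vic_map = {s.tank_id: s.x2 for s in summaries}
        pops = np.where(nc["category"] == "Solitary", "sol", nc["tank_id"])
        vics = np.array([vic_map.get(p, 0) for p in pops], float)
        for score_col, mode in (("pc1_size", "regression"), ("pc1_shape", "nonzero")):
            tab = anova_planned_contrasts(
                nc[score_col].to_numpy(), pops, vics, decomposition=mode
            )
            tab.to_csv(out / f"anova_{score_col}.csv")

    if "models" in stages:
        summaries, _ = population_stage(scores, study.census, n_perm=0, seed=seed)
        models = model_stage(scores, summaries)
        for key in ("nonlinear_size", "nonlinear_shape", "largest_size", "largest_shape"):
            if key in models:
                models[key].to_frame().to_csv(out / f"models_{key}.csv", index=False)
                summary.setdefault("model_selection", {})[key] = {
                    "best": models[key].best.model,
                    "wAIC": models[key].best.w_aic,
                }

    summary["elapsed_s"] = round(time.time() - t0, 3)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
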