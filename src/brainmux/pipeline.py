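"""End-to-end pipeline: layers -> MSTs -> multiplex -> centrality -> stats.

Per subject, the eight connectivity matrices (six band-limited PLI layers,
one absolutized-correlation layer, one structural layer) are reduced to MST
backbones, stacked into a supra-adjacency multiplex, and summarized as the
FPN mean of multilayer eigenvector centrality and multilayer degree, plus
eight single-layer FPN eigenvector-centrality values (MST-based for the MEG
bands, weighted for the BOLD-like and structural layers, unless the all-MST
variant is requested). The statistics stage then runs the blockwise stepwise
regression of executive functioning on the single-layer values (block 1)
with the multilayer value forced in a second block, the hierarchical age +
age^2 model of multilayer FPN centrality, and the leave-one-out
cross-validated R^2 of the final model.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .atlas import AtlasMapping
from .backbone import mst_backbone
from .connectivity import (
    CANONICAL_BANDS,
    MEG_BAND_NAMES,
    ConnectivityMatrix,
    EpochedTimeSeries,
    correlation_matrix,
    pli_matrix,
    validate_structural,
)
from .io import config_hash, read_cohort_layers
from .multilayer import (
    build_supra_adjacency,
    multilayer_degree,
    multilayer_ec,
    single_layer_ec,
    subnetwork_mean,
)
from .stats import hierarchical_quadratic, loocv_r2, stepwise_blockwise
from .synthetic import LAYER_ORDER, SyntheticCohort

log = logging.getLogger("brainmux")

__all__ = ["PipelineSettings", "analyze_subject", "run_cohort", "run_pipeline"]


@dataclass(frozen=True)
class PipelineSettings:
    """Tunable pipeline choices (defaults follow the primary analysis)."""

    interlayer_weight: float = 1.0
    coupling: str = "categorical"          # interlayer topology
    all_mst_single_layer: bool = False     # MST-based EC for every layer
    epoch_average_pli: bool = True
    stepwise_direction: str = "backward"
    p_remove: float = 0.10
    p_enter: float = 0.05
    block2_entry: str = "before"
    subnetwork: str = "FPN"


def _subject_matrices(
    layers: Mapping[str, EpochedTimeSeries | ConnectivityMatrix],
    subject_id: str,
    settings: PipelineSettings,
) -> dict[str, ConnectivityMatrix]:
    mats: dict[str, ConnectivityMatrix] = {}
    for layer in LAYER_ORDER:
        if layer not in layers:
            raise KeyError(f"subject {subject_id!r} is missing layer {layer!r}")
        data = layers[layer]
        if layer in MEG_BAND_NAMES:
            mats[layer] = pli_matrix(
                data, CANONICAL_BANDS[layer],
                epoch_average=settings.epoch_average_pli, subject_id=subject_id,
            )
        elif layer == "rsfmri":
            mats[layer] = correlation_matrix(data, subject_id=subject_id)
        else:
            if isinstance(data, ConnectivityMatrix):
                w, labels = data.weights, data.region_labels
            else:
                w, labels = np.asarray(data, dtype=float), ()
            mats[layer] = validate_structural(w, region_labels=labels,
                                              subject_id=subject_id)
    return mats


def analyze_subject(
    layers: Mapping[str, EpochedTimeSeries | ConnectivityMatrix],
    atlas: AtlasMapping,
    subject_id: str = "",
    settings: PipelineSettings = PipelineSettings(),
) -> dict[str, float]:
    """All network summaries for one subject (one row of the result table)."""
    mats = _subject_matrices(layers, subject_id, settings)
    trees = {layer: mst_backbone(mats[layer]) for layer in LAYER_ORDER}
    supra = build_supra_adjacency(
        [trees[layer] for layer in LAYER_ORDER],
        interlayer_weight=settings.interlayer_weight,
        coupling=settings.coupling,
    )
    sub = settings.subnetwork
    row: dict[str, float] = {"subject_id": subject_id}
    mec = multilayer_ec(supra, atlas)
    row[f"mlec_{sub}"] = subnetwork_mean(mec, atlas, sub)
    mdeg = multilayer_degree(supra)
    row[f"mldeg_{sub}"] = subnetwork_mean(mdeg, atlas, sub)
    single_vals = []
    for layer in LAYER_ORDER:
        use_mst = settings.all_mst_single_layer or layer in MEG_BAND_NAMES
        cv = single_layer_ec(trees[layer] if use_mst else mats[layer])
        val = subnetwork_mean(cv, atlas, sub)
        row[f"ec_{layer}_{sub}"] = val
        single_vals.append(val)
    row[f"ec_single_mean_{sub}"] = float(np.mean(single_vals))
    return row


def run_cohort(
    cohort: SyntheticCohort,
    settings: PipelineSettings = PipelineSettings(),
    with_stats: bool = True,
) -> dict:
    """Run the pipeline on an in-memory cohort; returns the result bundle."""
    rows = []
    for subj in cohort.subjects:
        t0 = time.perf_counter()
        try:
            row = analyze_subject(subj.layers, cohort.atlas, subj.subject_id, settings)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for subject {subj.subject_id!r}: {exc}"
            ) from exc
        row["EF"] = subj.cognition.get("EF", np.nan)
        row["age"] = subj.age
        rows.append(row)
        log.debug("subject %s analyzed in %.2fs", subj.subject_id,
                  time.perf_counter() - t0)
    table = pd.DataFrame(rows).set_index("subject_id")
    bundle: dict = {"table": table, "settings": settings}
    if with_stats:
        bundle["stats"] = cohort_stats(table, settings)
    return bundle


def cohort_stats(table: pd.DataFrame, settings: PipelineSettings = PipelineSettings()) -> dict:
    """Statistics stage on a per-subject summary table."""
    sub = settings.subnetwork
    block1 = [f"ec_{layer}_{sub}" for layer in LAYER_ORDER]
    block2 = [f"mlec_{sub}"]
    steps = stepwise_blockwise(
        table["EF"], table, block1, block2,
        direction=settings.stepwise_direction,
        p_remove=settings.p_remove, p_enter=settings.p_enter,
        block2_entry=settings.block2_entry,
    )
    final = steps[-1].model
    age_steps = hierarchical_quadratic(table["age"].to_numpy(),
                                       table[f"mlec_{sub}"].to_numpy())
    cv = loocv_r2(table[list(final.predictors)], table["EF"])
    return {"stepwise": steps, "final": final, "age_model": age_steps,
            "loocv_r2": cv}


def run_pipeline(
    cohort_dir: str | Path,
    out_dir: str | Path,
    settings: PipelineSettings = PipelineSettings(),
) -> dict:
    """Disk-to-disk pipeline over a written cohort tree.

    Reads ``atlas.csv``, ``covariates.csv`` and the per-subject layer files,
    writes the per-subject summary table and a tidy stepwise-model table,
    both stamped with the configuration hash and layer order.
    """
    atlas, cov, layers = read_cohort_layers(cohort_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash({"settings": asdict(settings), "layers": LAYER_ORDER})
    rows = []
    for sid, subject_layers in layers.items():
        try:
            row = analyze_subject(subject_layers, atlas, str(sid), settings)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed for subject {sid!r}: {exc}") from exc
        row["EF"] = cov.loc[sid, "EF"] if "EF" in cov.columns else np.nan
        row["age"] = cov.loc[sid, "age"] if "age" in cov.columns else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject_id")
    stats = cohort_stats(table, settings) if table.shape[0] > len(LAYER_ORDER) + 2 else None

    header = f"# config_hash={chash} layer_order={','.join(LAYER_ORDER)}\n"
    with open(out / "subject_summary.csv", "w") as fh:
        fh.write(header)
        table.to_csv(fh)
    if stats is not None:
        tidy = []
        for k, step in enumerate(stats["stepwise"]):
            m = step.model
            for pred in m.predictors:
                tidy.append({
                    "model_step": k, "action": step.action, "predictor": pred,
                    "beta": m.std_betas[pred], "p": m.pvalues[pred],
                    "R2": m.r2, "adjR2": m.adj_r2, "F": m.f_stat,
                    "df1": m.df[0], "df2": m.df[1],
                })
        with open(out / "stepwise_models.csv", "w") as fh:
            fh.write(header)
            pd.DataFrame(tidy).to_csv(fh, index=False)
    return {"table": table, "stats": stats, "config_hash": chash}
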