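"""End-to-end orchestration: preprocess, segment, score, analyze.

``run_pipeline`` takes a cohort (generated in memory or read from
disk), preprocesses every trial to the uniform 100 Hz grid, segments
it, computes the per-trial metric vector on the insertion subtask,
scores the two consistency metrics on each stage's five insertion
profiles, and hands the stage table to the statistics layer.  Trials
that fail any stage are quarantined (logged, skipped) rather than
aborting the run; results are deterministic under the configured seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as M
from .preprocessing import preprocess_trial
from .segmentation import segment_trial
from .stats import ContrastTables, STAGES, build_stage_table, run_full_analysis
from .synthetic import CohortDataset
from .trial import SubtaskLabel

__all__ = ["PipelineConfig", "PipelineResult", "process_trial", "run_pipeline"]

logger = logging.getLogger("needledrive")


@dataclass
class PipelineConfig:
    """Validated knobs of the full analysis pipeline.

    Defaults match the study constants: 100 Hz target rate, 10 Hz
    2nd-order zero-phase Butterworth, 0.06 N force threshold, blocks of
    5 trials, 5 profiles per consistency score.
    """

    target_rate: float = 100.0
    cutoff: float = 10.0
    filter_order: int = 2
    force_threshold: float = 0.06
    gripper_threshold: float = 0.5
    segment: str = "insertion"
    circle_radius: float | None = None  # None -> fitted radius in Theta_arc
    plane_method: str = "auto"
    torsion_eps: float = 1e-6
    n_profiles: int = 5
    block_size: int = 5
    n_boot: int = 10000
    ci_level: float = 0.95
    seed: int = 0
    bounds_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target_rate <= 0 or self.cutoff <= 0 or self.filter_order < 1:
            raise ValueError("invalid preprocessing parameters")
        if self.force_threshold < 0:
            raise ValueError("force threshold must be >= 0")
        if self.block_size < 2 or self.n_profiles < 2:
            raise ValueError("block size and profile count must be >= 2")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class PipelineResult:
    metric_table: pd.DataFrame  # one row per (participant, trial, segment)
    stage_table: pd.DataFrame
    tables: ContrastTables
    log: pd.DataFrame  # per-trial status + timing


def process_trial(trial, geom, config: PipelineConfig):
    """Preprocess + segment + score one trial.

    Returns ``(segmented, metric_vector)``.
    """
    uniform = preprocess_trial(
        trial, config.target_rate, config.cutoff, config.filter_order
    )
    trial_id = f"{trial.meta.get('participant', '?')}:{trial.meta.get('trial', '?')}"
    seg = segment_trial(
        uniform,
        geom,
        threshold=config.force_threshold,
        gripper_threshold=config.gripper_threshold,
        bounds_override=config.bounds_overrides.get(trial_id),
    )
    mv = M.compute_metric_vector(
        seg,
        geom,
        segment=config.segment,
        circle_radius=config.circle_radius,
        plane_method=config.plane_method,
        torsion_eps=config.torsion_eps,
    )
    return seg, mv


def _stage_blocks(part_rows: pd.DataFrame, block_size: int):
    """Map stage name -> trial ids of that stage's block."""
    out = {}
    for stage, (phase, end) in STAGES.items():
        sel = part_rows[part_rows["phase"] == phase].sort_values("trial_in_phase")
        block = sel.head(block_size) if end == "first" else sel.tail(block_size)
        out[stage] = block["trial"].tolist()
    return out


def run_pipeline(config: PipelineConfig, cohort: CohortDataset) -> PipelineResult:
    """Run the full analysis over a signal-level cohort."""
    if len(cohort.trials) == 0:
        raise ValueError("empty cohort")

    metric_rows = []
    log_rows = []
    segments: dict[tuple[str, int], object] = {}
    for _, row in cohort.manifest.iterrows():
        key = (row["participant"], int(row["trial"]))
        trial, gt = cohort.trials[key]
        t0 = time.perf_counter()
        try:
            seg, mv = process_trial(trial, gt.geometry, config)
            segments[key] = seg
            rec = {
                "participant": row["participant"],
                "condition": row["condition"],
                "phase": row["phase"],
                "block": row["block"],
                "trial": int(row["trial"]),
                "trial_in_phase": int(row["trial_in_phase"]),
                "setup": row["setup"],
                "segment": config.segment,
            }
            rec.update(mv.as_dict())
            metric_rows.append(rec)
            status, detail = "ok", ""
        except Exception as err:  # quarantine, keep going
            status, detail = "quarantined", f"{type(err).__name__}: {err}"
            logger.warning("trial %s quarantined: %s", key, detail)
        log_rows.append(
            {
                "participant": row["participant"],
                "trial": int(row["trial"]),
                "status": status,
                "detail": detail,
                "seconds": time.perf_counter() - t0,
            }
        )
    if not metric_rows:
        raise ValueError("all trials quarantined; nothing to analyze")
    metric_table = pd.DataFrame(metric_rows)

    scalar_cols = [m for m in M.SCALAR_METRICS if m in metric_table.columns]
    stage_table = build_stage_table(metric_table, scalar_cols, config.block_size)

    # consistency metrics: DTW over each stage's insertion profiles
    for col in M.CONSISTENCY_METRICS:
        stage_table[col] = np.nan
    seg_label = SubtaskLabel[config.segment.upper()]
    for (participant, _), part in metric_table.groupby(["participant", "condition"]):
        blocks = _stage_blocks(part, config.block_size)
        for stage, trial_ids in blocks.items():
            force_profiles, pos_profiles = [], []
            for tid in trial_ids[-config.n_profiles :]:
                seg = segments.get((participant, tid))
                if seg is None:
                    continue
                sel = seg.segment_slice(seg_label)
                if np.sum(sel) < 2:
                    continue
                force_profiles.append(seg.trial.force[sel])
                pos_profiles.append(seg.trial.position[sel])
            idx = (stage_table["participant"] == participant) & (
                stage_table["stage"] == stage
            )
            if len(force_profiles) >= 2:
                stage_table.loc[idx, "force_consistency"] = M.dtw_consistency(
                    force_profiles
                )
                stage_table.loc[idx, "trajectory_consistency"] = M.dtw_consistency(
                    pos_profiles
                )

    tables = run_full_analysis(
        stage_table=stage_table,
        block_size=config.block_size,
        n_boot=config.n_boot,
        seed=config.seed,
    )
    return PipelineResult(
        metric_table=metric_table,
        stage_table=stage_table,
        tables=tables,
        log=pd.DataFrame(log_rows),
    )
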