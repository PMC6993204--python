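"""Trial-bound detection and subtask classification.

A trial spans the first to the last sample where the needle interacts
with the tissue: force magnitude above the sensor noise threshold
(0.06 N) *and* the tooltip's surface-plane projection inside the tissue
contour — both conditions simultaneously, so accidental contacts with
the fixture outside the contour are ignored.

Within the bounds, samples with the gripper closed and force above the
threshold belong to needle-driving segments.  Maximal runs of such
samples are ordered in time: the first run is the insertion, the last
run the extraction; intermediate runs are corrections when their mean
tooltip position (projected to the surface plane) is closer to the
entrance point than to the exit point, extraction-class otherwise.
Gaps between runs are repositioning.  A single continuous run is
labeled insertion (insertion always exists; extraction may be merged
into it).  Automatic bounds can be overridden with manually validated
ones via ``apply_bounds_override``.
"""

from __future__ import annotations

import numpy as np

from .trial import SegmentedTrial, SubtaskLabel, TissueGeometry, UniformTrial

__all__ = [
    "NoTrialDetectedError",
    "detect_trial_bounds",
    "label_driving_samples",
    "classify_segments",
    "segment_trial",
    "relative_durations",
    "apply_bounds_override",
    "DEFAULT_FORCE_THRESHOLD",
    "DEFAULT_GRIPPER_THRESHOLD",
]

DEFAULT_FORCE_THRESHOLD = 0.06  # N, force-sensor noise floor
DEFAULT_GRIPPER_THRESHOLD = 0.5  # gripper state at or below => jaws closed


class NoTrialDetectedError(ValueError):
    """No sample satisfied the trial-detection conditions."""


def detect_trial_bounds(
    trial: UniformTrial,
    geom: TissueGeometry,
    threshold: float = DEFAULT_FORCE_THRESHOLD,
) -> tuple[int, int]:
    """First and last sample with tissue interaction (0-based, inclusive)."""
    fmag = np.linalg.norm(trial.force, axis=1)
    inside = geom.contains(trial.position)
    qualifying = (fmag > threshold) & inside
    idx = np.flatnonzero(qualifying)
    if idx.size == 0:
        raise NoTrialDetectedError(
            "no sample with force above threshold inside the tissue contour"
        )
    return int(idx[0]), int(idx[-1])


def label_driving_samples(
    trial: UniformTrial,
    geom: TissueGeometry,
    threshold: float = DEFAULT_FORCE_THRESHOLD,
    gripper_threshold: float = DEFAULT_GRIPPER_THRESHOLD,
    bounds: tuple[int, int] | None = None,
) -> np.ndarray:
    """Boolean mask of needle-driving samples.

    True iff the gripper is closed and the force magnitude exceeds the
    noise threshold; always False outside the trial bounds.
    """
    if bounds is None:
        bounds = detect_trial_bounds(trial, geom, threshold)
    i0, i1 = bounds
    fmag = np.linalg.norm(trial.force, axis=1)
    mask = (fmag > threshold) & (trial.gripper <= gripper_threshold)
    mask[:i0] = False
    mask[i1 + 1 :] = False
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) inclusive index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def classify_segments(
    trial: UniformTrial,
    geom: TissueGeometry,
    mask: np.ndarray,
    bounds: tuple[int, int] | None = None,
) -> SegmentedTrial:
    """Assign a subtask label to every sample.

    Raises
    ------
    NoTrialDetectedError
        If the mask contains no driving run.
    """
    if bounds is None:
        bounds = detect_trial_bounds(trial, geom)
    i0, i1 = bounds
    runs = _runs(mask)
    if not runs:
        raise NoTrialDetectedError("no needle-driving samples in mask")

    labels = np.full(len(trial), int(SubtaskLabel.OUTSIDE))
    labels[i0 : i1 + 1] = int(SubtaskLabel.REPOSITION)

    ent_uv = geom.to_plane(geom.entrance_point)[0]
    exit_point = geom.actual_exit if geom.actual_exit is not None else geom.desired_exit
    exit_uv = geom.to_plane(exit_point)[0]

    for k, (a, b) in enumerate(runs):
        if k == 0:
            lab = SubtaskLabel.INSERTION
        elif k == len(runs) - 1:
            lab = SubtaskLabel.EXTRACTION
        else:
            mean_uv = geom.to_plane(trial.position[a : b + 1]).mean(axis=0)
            closer_entrance = np.linalg.norm(mean_uv - ent_uv) < np.linalg.norm(
                mean_uv - exit_uv
            )
            lab = SubtaskLabel.CORRECTION if closer_entrance else SubtaskLabel.EXTRACTION
        labels[a : b + 1] = int(lab)

    return SegmentedTrial(trial=trial, bounds=bounds, labels=labels)


def segment_trial(
    trial: UniformTrial,
    geom: TissueGeometry,
    threshold: float = DEFAULT_FORCE_THRESHOLD,
    gripper_threshold: float = DEFAULT_GRIPPER_THRESHOLD,
    bounds_override: tuple[int, int] | None = None,
) -> SegmentedTrial:
    """Bounds detection + driving mask + subtask classification."""
    bounds = (
        bounds_override
        if bounds_override is not None
        else detect_trial_bounds(trial, geom, threshold)
    )
    mask = label_driving_samples(trial, geom, threshold, gripper_threshold, bounds)
    return classify_segments(trial, geom, mask, bounds)


def relative_durations(seg: SegmentedTrial) -> dict[str, float]:
    """Fraction of the bounded trial spent in each subtask.

    Fractions are sample-count ratios over the inclusive bounds and sum
    to 1 across the labels present inside the bounds.
    """
    i0, i1 = seg.bounds
    inner = seg.labels[i0 : i1 + 1]
    total = inner.size
    return {
        lab.name.lower(): float(np.sum(inner == int(lab)) / total)
        for lab in SubtaskLabel
        if lab is not SubtaskLabel.OUTSIDE
    }


def apply_bounds_override(
    trial: UniformTrial,
    geom: TissueGeometry,
    overrides: dict[str, tuple[int, int]],
    trial_id: str,
    threshold: float = DEFAULT_FORCE_THRESHOLD,
    gripper_threshold: float = DEFAULT_GRIPPER_THRESHOLD,
) -> SegmentedTrial:
    """Segment with manually validated bounds when present.

    ``overrides`` maps trial ids to corrected (i_start, i_end) pairs —
    the programmatic stand-in for manual validation of the automatic
    trial detection.
    """
    return segment_trial(
        trial,
        geom,
        threshold,
        gripper_threshold,
        bounds_override=overrides.get(trial_id),
    )
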