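"""Scoring detections against simulator ground truth.

Speckles are matched to truth centroids by optimal one-to-one assignment
(Hungarian algorithm) under a hard distance cap in voxel units; nuclei by
the same rule in pixel units. From the matches: precision, recall, phase
accuracy and compartment agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .nuclei import NucleusRecord
from .simulate import GroundTruth
from .speckles import SpeckleRecord


def match_points(
    detected: np.ndarray, truth: np.ndarray, max_distance: float
) -> list[tuple[int, int]]:
    """Optimal one-to-one matching of two point sets under a distance cap.

    Returns (detected_index, truth_index) pairs whose Euclidean distance is
    at most ``max_distance``; the assignment minimizes total distance.
    """
    if len(detected) == 0 or len(truth) == 0:
        return []
    detected = np.atleast_2d(np.asarray(detected, dtype=np.float64))
    truth = np.atleast_2d(np.asarray(truth, dtype=np.float64))
    cost = np.linalg.norm(detected[:, None, :] - truth[None, :, :], axis=2)
    big = max_distance * 1e6 + 1.0
    rows, cols = linear_sum_assignment(np.where(cost <= max_distance, cost, big))
    return [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] <= max_distance]


@dataclass
class SpeckleScore:
    recall: float
    precision: float
    compartment_agreement: float
    n_truth: int
    n_detected: int
    n_matched: int


def score_speckles(
    records: list[SpeckleRecord],
    truth: GroundTruth,
    channel: str,
    max_distance_vox: float = 3.0,
) -> SpeckleScore:
    """Recall/precision of detected speckles and compartment agreement.

    Matching is in raw voxel coordinates within ``max_distance_vox``;
    compartment agreement is computed over matched speckles that the
    pipeline assigned to a compartment (unassigned ones, e.g. in
    border-excluded cells, do not count against agreement).
    """
    det = [r for r in records if r.channel == channel]
    tru = truth.speckle_table[truth.speckle_table["channel"] == channel]
    det_pts = np.array([r.centroid for r in det]) if det else np.empty((0, 3))
    tru_pts = tru[["centroid_z", "centroid_y", "centroid_x"]].to_numpy()
    pairs = match_points(det_pts, tru_pts, max_distance_vox)
    agree = total = 0
    for i, j in pairs:
        if det[i].compartment in ("nuclear", "cytoplasmic"):
            total += 1
            agree += det[i].compartment == tru["compartment"].iloc[j]
    return SpeckleScore(
        recall=len(pairs) / len(tru) if len(tru) else 1.0,
        precision=len(pairs) / len(det) if det else 1.0,
        compartment_agreement=agree / total if total else 1.0,
        n_truth=len(tru),
        n_detected=len(det),
        n_matched=len(pairs),
    )


@dataclass
class NucleusScore:
    recall: float
    precision: float
    phase_accuracy: float
    n_truth: int
    n_detected: int
    matches: list[tuple[int, int]]


def score_nuclei(
    records: list[NucleusRecord],
    truth: GroundTruth,
    max_distance_px: float = 10.0,
) -> NucleusScore:
    """Match main detected nuclei to main truth nuclei by (y, x) centroid."""
    det = [r for r in records if not r.is_candidate]
    tru = truth.nucleus_table[~truth.nucleus_table["is_micronucleus"]]
    det_pts = np.array([r.centroid for r in det]) if det else np.empty((0, 2))
    tru_pts = tru[["centroid_y", "centroid_x"]].to_numpy()
    pairs = match_points(det_pts, tru_pts, max_distance_px)
    correct = sum(1 for i, j in pairs if det[i].phase == tru["phase"].iloc[j])
    return NucleusScore(
        recall=len(pairs) / len(tru) if len(tru) else 1.0,
        precision=len(pairs) / len(det) if det else 1.0,
        phase_accuracy=correct / len(pairs) if pairs else 1.0,
        n_truth=len(tru),
        n_detected=len(det),
        matches=pairs,
    )


def aggregate_scores(frames: list[pd.Series | dict]) -> pd.DataFrame:
    return pd.DataFrame([dict(f) for f in frames])
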