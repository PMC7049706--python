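"""Nucleus segmentation, interphase/mitotic classification and micronuclei.

Nuclei are segmented from the z-projected DAPI stack: Gaussian smoothing,
Otsu foreground threshold, Euclidean distance transform, h-maxima seeding and
a marker-controlled watershed that splits touching nuclei. Each nucleus gets
intensity and texture features, from which cells are classified as interphase
or mitotic (condensed mitotic chromatin is brighter and coarser). Small DAPI
objects near a main nucleus are flagged as micronuclei.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology, segmentation

from .stack import ImageStack

log = logging.getLogger(__name__)

INTERPHASE = "interphase"
MITOTIC = "mitotic"
UNCLASSIFIED = "unclassified"


@dataclass
class SegmentationParams:
    """Knobs of the DAPI segmentation stage.

    smooth_sigma_px
        Gaussian pre-smoothing, pixels.
    min_area_px
        Projected-area floor for a main nucleus; smaller objects are kept
        only as micronucleus candidates.
    h_maxima_px
        Depth of the h-maxima transform seeding the watershed, in distance
        units (pixels).
    texture_window_px
        Side of the local-mean window for the texture score.
    exclude_border
        Drop border-touching nuclei from statistics (their territory is
        truncated); they remain in the record table, flagged.
    micronucleus_area_frac
        Micronucleus candidates must be smaller than this fraction of the
        median main-nucleus area (exclusive bound).
    micronucleus_reach_radii
        Maximum centroid distance to the parent nucleus, in units of the
        median main-nucleus equivalent radius.
    mean_dapi_threshold, texture_threshold
        Fixed phase thresholds; ``None`` requests auto-calibration per field.
    calibration_min_fold_intensity, calibration_min_fold_texture
        Auto-calibrated thresholds never drop below these folds of the field
        median, so a field without mitotic cells yields no mitotic calls.
    """

    smooth_sigma_px: float = 1.2
    min_area_px: int = 150
    h_maxima_px: float = 2.0
    texture_window_px: int = 5
    exclude_border: bool = True
    micronucleus_area_frac: float = 0.2
    micronucleus_reach_radii: float = 3.0
    mean_dapi_threshold: float | None = None
    texture_threshold: float | None = None
    calibration_min_fold_intensity: float = 1.4
    calibration_min_fold_texture: float = 1.6


@dataclass
class NucleusRecord:
    """One segmented DAPI object (main nucleus or micronucleus candidate)."""

    nucleus_id: int
    area: int
    centroid: tuple[float, float]
    mean_dapi: float
    texture: float
    phase: str = UNCLASSIFIED
    is_micronucleus: bool = False
    parent_cell: int = 0
    touches_border: bool = False
    is_candidate: bool = False  # below min area: not a main nucleus


def records_to_frame(records: list[NucleusRecord]) -> pd.DataFrame:
    rows = [
        dict(
            nucleus_id=r.nucleus_id,
            area=r.area,
            centroid_y=r.centroid[0],
            centroid_x=r.centroid[1],
            mean_dapi=r.mean_dapi,
            texture=r.texture,
            phase=r.phase,
            is_micronucleus=r.is_micronucleus,
            parent_cell=r.parent_cell,
            touches_border=r.touches_border,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_id",
            "area",
            "centroid_y",
            "centroid_x",
            "mean_dapi",
            "texture",
            "phase",
            "is_micronucleus",
            "parent_cell",
            "touches_border",
        ],
    )


def project_dapi(stack: ImageStack, method: str = "max", channel: str = "dapi") -> np.ndarray:
    """Reduce the DAPI stack along z to a 2D map (``max`` or ``mean``)."""
    volume = stack.require(channel)
    if method == "max":
        return np.asarray(volume).max(axis=0)
    if method == "mean":
        return np.asarray(volume).mean(axis=0)
    raise ValueError(f"unknown projection method {method!r}; use 'max' or 'mean'")


def _texture_score(projection: np.ndarray, mask: np.ndarray, window: int) -> float:
    """Std of the locally mean-subtracted intensity within the mask."""
    local_mean = ndimage.uniform_filter(projection.astype(np.float64), size=window)
    residual = projection - local_mean
    vals = residual[mask]
    return float(vals.std()) if vals.size else 0.0


def segment_nuclei(
    projection: np.ndarray,
    params: SegmentationParams | None = None,
) -> tuple[np.ndarray, list[NucleusRecord]]:
    """Watershed segmentation of the z-projected DAPI image.

    Returns a label map of main nuclei (contiguous labels 1..n) and records
    for every object, including sub-minimum-area candidates (label 0 in the
    map, ``is_candidate=True``) retained for micronucleus detection and
    border-touching nuclei (flagged, excluded from statistics by policy).
    """
    params = params or SegmentationParams()
    projection = np.asarray(projection, dtype=np.float64)
    if projection.size == 0:
        raise ValueError("empty projection")
    smoothed = ndimage.gaussian_filter(projection, params.smooth_sigma_px)
    if np.ptp(smoothed) == 0:
        log.warning("segment_nuclei: constant projection, no foreground")
        return np.zeros(projection.shape, dtype=np.int32), []
    threshold = filters.threshold_otsu(smoothed)
    foreground = smoothed > threshold
    if not foreground.any():
        log.warning("segment_nuclei: no foreground after Otsu threshold")
        return np.zeros(projection.shape, dtype=np.int32), []

    distance = ndimage.distance_transform_edt(foreground)
    seeds_mask = morphology.h_maxima(distance, params.h_maxima_px)
    seeds, n_seeds = ndimage.label(seeds_mask)
    if n_seeds == 0:
        seeds, _ = ndimage.label(foreground)
    raw = segmentation.watershed(-distance, markers=seeds, mask=foreground)

    border = np.zeros_like(foreground)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True

    records: list[NucleusRecord] = []
    relabeled = np.zeros(projection.shape, dtype=np.int32)
    next_main = 1
    for lab in np.unique(raw):
        if lab == 0:
            continue
        mask = raw == lab
        area = int(mask.sum())
        cy, cx = (float(c) for c in ndimage.center_of_mass(mask))
        rec = NucleusRecord(
            nucleus_id=0,
            area=area,
            centroid=(cy, cx),
            mean_dapi=float(projection[mask].mean()),
            texture=_texture_score(projection, mask, params.texture_window_px),
            touches_border=bool((mask & border).any()),
            is_candidate=area < params.min_area_px,
        )
        if not rec.is_candidate:
            rec.nucleus_id = next_main
            relabeled[mask] = next_main
            next_main += 1
        records.append(rec)
    # candidates get ids after all main nuclei so main labels stay contiguous
    next_id = next_main
    for rec in records:
        if rec.is_candidate:
            rec.nucleus_id = next_id
            next_id += 1
    records.sort(key=lambda r: r.nucleus_id)
    return relabeled, records


def _auto_threshold(values: np.ndarray, min_fold: float) -> float:
    """Two-class split of a feature, floored at min_fold x the median.

    The Otsu split alone would force a class boundary even on a unimodal
    feature; the fold floor keeps homogeneous (all-interphase) fields from
    producing spurious mitotic calls.
    """
    values = np.asarray(values, dtype=np.float64)
    med = float(np.median(values))
    if np.ptp(values) == 0:
        return med * min_fold + 1e-9
    split = float(filters.threshold_otsu(values, nbins=128))
    return max(split, med * min_fold)


def classify_phase(
    records: list[NucleusRecord],
    params: SegmentationParams | None = None,
) -> list[NucleusRecord]:
    """Assign interphase/mitotic from mean DAPI intensity and texture.

    A nucleus is mitotic iff both features reach their thresholds; thresholds
    come from the config or are auto-calibrated by two-class splitting of
    each feature across the field's main nuclei. Deterministic given
    thresholds. With fewer than two main nuclei and no configured thresholds,
    records stay unclassified.
    """
    params = params or SegmentationParams()
    main = [r for r in records if not r.is_candidate]
    if not records:
        return records
    tau_i, tau_t = params.mean_dapi_threshold, params.texture_threshold
    if tau_i is None or tau_t is None:
        if len(main) < 2:
            if tau_i is None or tau_t is None:
                log.warning(
                    "classify_phase: %d main nuclei, auto-calibration impossible and "
                    "no configured thresholds; leaving phase unclassified",
                    len(main),
                )
                for r in records:
                    r.phase = UNCLASSIFIED
                return records
        else:
            intensities = np.array([r.mean_dapi for r in main])
            textures = np.array([r.texture for r in main])
            if tau_i is None:
                tau_i = _auto_threshold(intensities, params.calibration_min_fold_intensity)
            if tau_t is None:
                tau_t = _auto_threshold(textures, params.calibration_min_fold_texture)
    for r in records:
        r.phase = MITOTIC if (r.mean_dapi >= tau_i and r.texture >= tau_t) else INTERPHASE
    return records


def detect_micronuclei(
    label_map: np.ndarray,
    records: list[NucleusRecord],
    params: SegmentationParams | None = None,
) -> tuple[list[NucleusRecord], pd.DataFrame]:
    """Flag small DAPI objects near a main nucleus as micronuclei.

    A candidate is a micronucleus iff its area is strictly below
    ``micronucleus_area_frac`` x the median main-nucleus area and its
    centroid lies within ``micronucleus_reach_radii`` x the median
    main-nucleus equivalent radius of some main-nucleus centroid; it is
    assigned to the nearest one. Returns the updated records and a per-cell
    table with micronucleus counts and the field-level fraction of cells
    with at least one micronucleus.
    """
    params = params or SegmentationParams()
    main = [r for r in records if not r.is_candidate]
    candidates = [r for r in records if r.is_candidate]
    if not main:
        for r in candidates:
            r.is_micronucleus = False
        return records, pd.DataFrame(columns=["nucleus_id", "n_micronuclei", "has_micronuclei"])

    areas = np.array([r.area for r in main], dtype=float)
    median_area = float(np.median(areas))
    area_cutoff = params.micronucleus_area_frac * median_area
    median_radius = float(np.sqrt(median_area / np.pi))
    reach = params.micronucleus_reach_radii * median_radius
    main_centroids = np.array([r.centroid for r in main])

    counts = {r.nucleus_id: 0 for r in main}
    for cand in candidates:
        if cand.area >= area_cutoff:  # cutoff is an exclusive upper bound
            continue
        d = np.hypot(
            main_centroids[:, 0] - cand.centroid[0], main_centroids[:, 1] - cand.centroid[1]
        )
        k = int(np.argmin(d))
        if d[k] > reach:
            log.info(
                "micronucleus candidate %d has no main nucleus within %.1f px; unassigned",
                cand.nucleus_id,
                reach,
            )
            continue
        cand.is_micronucleus = True
        cand.parent_cell = main[k].nucleus_id
        counts[main[k].nucleus_id] += 1

    table = pd.DataFrame(
        [
            dict(nucleus_id=nid, n_micronuclei=n, has_micronuclei=n > 0)
            for nid, n in sorted(counts.items())
        ]
    )
    return records, table
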