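"""Cell territories by tessellation of the nuclear compartment.

Without a membrane marker, whole-cell regions are approximated by assigning
every pixel to the nucleus whose boundary is nearest in Euclidean distance
(a generalized Voronoi tessellation of the nucleus masks). The cytoplasmic
compartment of a cell is then the exact set difference of its territory and
its nucleus.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage


class ConsistencyError(ValueError):
    """Nucleus and cell maps disagree where they must not (upstream bug)."""


def tessellate_cells(
    nucleus_labels: np.ndarray,
    max_reach_px: float | None = None,
) -> np.ndarray:
    """Assign every pixel to the nucleus with the nearest boundary pixel.

    Pixels inside a nucleus keep that nucleus's label. Equidistant pixels
    tie-break to the lower nucleus label. With ``max_reach_px`` set, pixels
    farther than that from every nucleus stay 0 (unassigned); by default the
    tessellation is unbounded and covers the whole field.

    Implemented as one exact Euclidean distance transform per label with an
    argmin across labels, which realizes the nearest-nucleus-pixel rule
    (including the deterministic tie-break) exactly.
    """
    nucleus_labels = np.asarray(nucleus_labels)
    labels = np.unique(nucleus_labels)
    labels = labels[labels > 0]
    if labels.size == 0:
        warnings.warn("tessellate_cells: empty nucleus label map", stacklevel=2)
        return np.zeros_like(nucleus_labels, dtype=np.int32)

    dist = np.empty((labels.size,) + nucleus_labels.shape, dtype=np.float64)
    for k, lab in enumerate(labels):
        dist[k] = ndimage.distance_transform_edt(nucleus_labels != lab)
    nearest = np.argmin(dist, axis=0)  # first minimum = lowest label on ties
    cells = labels[nearest].astype(np.int32)
    if max_reach_px is not None:
        cells[np.min(dist, axis=0) > max_reach_px] = 0
    return cells


def derive_cytoplasm(cell_labels: np.ndarray, nucleus_labels: np.ndarray) -> np.ndarray:
    """Cytoplasm label map: the cell label wherever no nucleus is, else 0.

    Exact per-pixel set difference; raises :class:`ConsistencyError` if a
    nucleus pixel carries a different cell label than its nucleus label,
    which would mean the two maps came from different segmentations.
    """
    cell_labels = np.asarray(cell_labels)
    nucleus_labels = np.asarray(nucleus_labels)
    if cell_labels.shape != nucleus_labels.shape:
        raise ConsistencyError(
            f"shape mismatch: cells {cell_labels.shape} vs nuclei {nucleus_labels.shape}"
        )
    inside = nucleus_labels > 0
    mismatched = inside & (cell_labels != nucleus_labels)
    if np.any(mismatched):
        n = int(np.count_nonzero(mismatched))
        raise ConsistencyError(
            f"{n} nucleus pixels carry a different cell label than their nucleus label"
        )
    cytoplasm = cell_labels.copy()
    cytoplasm[inside] = 0
    return cytoplasm
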