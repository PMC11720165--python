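"""Nucleus and cell segmentation.

Nuclei come from the DNA (DAPI) channel: minimum cross-entropy (Li)
threshold, hole filling, a distance-transform watershed to split touching
nuclei, then an area filter. Cell bodies come from the phalloidin channel:
the Li-thresholded foreground is partitioned among the nucleus seeds by an
intensity-guided watershed, so each cell label contains exactly one nucleus
and cells never share pixels. Cells touching the image border are removed
together with their nuclei, without relabeling, so labels remain stable
join keys.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_li
from skimage.segmentation import watershed

from .exceptions import DegenerateImageError

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structuring element


def li_threshold(image: np.ndarray) -> float:
    """Minimum cross-entropy threshold (Li & Lee iterative scheme).

    Returns a threshold strictly between the image minimum and maximum.
    Raises :class:`DegenerateImageError` on a constant image.
    """
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if lo == hi:
        raise DegenerateImageError("cannot threshold a constant image")
    t = float(threshold_li(image))
    # Guard against numerical collapse onto an extremum.
    return float(min(max(t, np.nextafter(lo, hi)), np.nextafter(hi, lo)))


def segment_nuclei(dna_image: np.ndarray,
                   min_area: int = 200,
                   max_area: int = 20000,
                   min_peak_distance: int = 10) -> np.ndarray:
    """Label mask of nuclei from a DNA-stain image.

    Thresholds with :func:`li_threshold`, fills holes, splits touching
    nuclei by distance-transform watershed when peaks are at least
    ``min_peak_distance`` apart, and drops components outside
    ``[min_area, max_area]``. A blank image yields an empty mask.
    """
    dna_image = np.asarray(dna_image, dtype=np.float64)
    try:
        t = li_threshold(dna_image)
    except DegenerateImageError:
        return np.zeros(dna_image.shape, dtype=np.int32)
    binary = ndimage.binary_fill_holes(dna_image > t)

    distance = ndimage.distance_transform_edt(binary)
    peaks = peak_local_max(distance, min_distance=min_peak_distance,
                           labels=ndimage.label(binary, structure=_EIGHT)[0],
                           exclude_border=False)
    markers = np.zeros(dna_image.shape, dtype=np.int32)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        labels = ndimage.label(binary, structure=_EIGHT)[0].astype(np.int32)
    else:
        labels = watershed(-distance, markers, mask=binary,
                           connectivity=2).astype(np.int32)

    return _filter_area(labels, min_area, max_area)


def _filter_area(labels: np.ndarray, min_area: int, max_area: int) -> np.ndarray:
    counts = np.bincount(labels.ravel())
    bad = (counts < min_area) | (counts > max_area)
    bad[0] = False
    if bad.any():
        labels = labels.copy()
        labels[bad[labels]] = 0
    return labels


def segment_cells(factin_image: np.ndarray, nuclei: np.ndarray) -> np.ndarray:
    """Assign phalloidin foreground to nucleus seeds; one cell per nucleus.

    Foreground is ``factin > li_threshold``; each foreground pixel joins the
    seed reached by intensity-guided watershed propagation, so adjacent cells
    partition the foreground. A nucleus surrounded by no foreground keeps a
    cell equal to its own nucleus mask (logged as a warning). Cell pixels
    always contain the nucleus pixels.
    """
    factin_image = np.asarray(factin_image, dtype=np.float64)
    nuclei = np.asarray(nuclei)
    if nuclei.max() == 0:
        return np.zeros(nuclei.shape, dtype=np.int32)
    try:
        t = li_threshold(factin_image)
        foreground = factin_image > t
    except DegenerateImageError:
        foreground = np.zeros(factin_image.shape, dtype=bool)
    mask = foreground | (nuclei > 0)
    # Propagate uphill-first: bright phalloidin is claimed before dim pixels,
    # which traces cell boundaries along intensity minima between cells.
    cells = watershed(-factin_image, nuclei.astype(np.int32), mask=mask,
                      connectivity=2).astype(np.int32)
    # Propagation can only reach pixels connected to a seed; disconnected
    # foreground stays background.
    for lab in np.unique(nuclei)[1:]:
        if (cells == lab).sum() <= (nuclei == lab).sum():
            logger.warning("nucleus %d has no surrounding phalloidin foreground; "
                           "cell set to nucleus mask", lab)
    cells[nuclei > 0] = nuclei[nuclei > 0]
    return cells


def exclude_border(cells: np.ndarray,
                   nuclei: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove every cell touching the image border, with its nucleus.

    A cell is border-touching when any of its pixels lies on row 0, the last
    row, column 0 or the last column. Remaining labels are preserved (no
    relabeling).
    """
    edge = np.zeros(cells.shape, dtype=bool)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    touching = np.unique(cells[edge])
    touching = touching[touching > 0]
    if touching.size == 0:
        return cells.copy(), nuclei.copy()
    drop = np.isin(cells, touching)
    cells_out = cells.copy()
    nuclei_out = nuclei.copy()
    cells_out[drop] = 0
    nuclei_out[np.isin(nuclei, touching)] = 0
    return cells_out, nuclei_out
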