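"""Individual cell detection from the segmented wall mask.

The wall mask partitions the root into enclosed background regions, one
per cell.  After a small 2x2 dilation that closes pinhole leaks, every
4-connected background component not touching the image border becomes a
candidate cell with a traced boundary polygon.  Dark lateral-root
formations are discarded by an intensity rule, the cells touching the
outer background define the initial root boundary, and a second, relaxed
segmentation pass (threshold halved) combined with peaks of the Euclidean
distance transform recovers boundary cells whose walls were too faint for
the first pass.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .morphometrics import fit_ellipse
from .segmentation import local_threshold

__all__ = [
    "Cell",
    "RootModel",
    "SegmentationError",
    "dilate_mask",
    "detect_cells",
    "remove_lateral_roots",
    "initial_root_boundary",
    "distance_map",
    "recover_missed_cells",
    "build_root_model",
]

_FOUR_CONNECTED = ndimage.generate_binary_structure(2, 1)

#: tolerance (px) when testing whether a cell touches a region boundary:
#: 2 px of wall plus the 1-px dilation bias, with 1 px of slack
BOUNDARY_TOUCH_TOL = 4.5


class SegmentationError(RuntimeError):
    """Raised when no usable cells can be extracted from an image."""


@dataclasses.dataclass
class Cell:
    """One detected enclosed region of the root cross-section."""

    id: int
    pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols) of interior pixels
    boundary: np.ndarray  # (N, 2) closed contour, row/col order
    area: int
    centroid: tuple[float, float]
    mean_intensity: float = float("nan")
    eccentricity: float = float("nan")
    size_class: str = "unclassified"  # noise | small | large
    tissue: str = "unassigned"
    on_perimeter: bool = False


@dataclasses.dataclass
class RootModel:
    """All detected cells plus the whole-root geometry."""

    cells: list[Cell]
    gamma_ini: np.ndarray  # initial outer boundary polygon
    gamma_final: np.ndarray  # refined outer boundary polygon
    gamma_ini_mask: np.ndarray  # filled region enclosed by gamma_ini
    gamma_final_mask: np.ndarray
    mask: np.ndarray  # dilated first-pass wall mask the cells came from
    stele_centre: tuple[float, float] | None = None
    root_area: float = float("nan")
    root_eccentricity: float = float("nan")
    stele_candidates: set[int] = dataclasses.field(default_factory=set)
    endodermis_contour: np.ndarray | None = None
    endodermis_mask: np.ndarray | None = None

    def cell_by_id(self, cell_id: int) -> Cell:
        for cell in self.cells:
            if cell.id == cell_id:
                return cell
        raise KeyError(cell_id)


def dilate_mask(mask: np.ndarray) -> np.ndarray:
    """Morphological dilation with a 2x2 all-ones kernel.

    The kernel is anchored at its top-left element, so a single pixel at
    ``(r, c)`` grows into the block ``{(r, c), (r+1, c), (r, c+1),
    (r+1, c+1)}``.  Closes 1-px leaks in cell walls while barely moving
    the boundaries of small cells.
    """
    return ndimage.binary_dilation(
        mask, structure=np.ones((2, 2), dtype=bool), origin=-1
    )


def _trace_boundary(component: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    contours = measure.find_contours(component.astype(float), 0.5)
    longest = max(contours, key=len)
    return longest + np.asarray(offset, dtype=float)


def _cell_eccentricity(boundary: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> float:
    try:
        return fit_ellipse(boundary).E
    except ValueError:
        return _moment_eccentricity(rows, cols)


def _moment_eccentricity(rows: np.ndarray, cols: np.ndarray) -> float:
    """Eccentricity of the second-moment (inertia-equivalent) ellipse."""
    y = rows - rows.mean()
    x = cols - cols.mean()
    cov = np.cov(np.stack([y, x]))
    eig = np.linalg.eigvalsh(cov)
    lam2, lam1 = max(eig[0], 0.0), max(eig[1], 1e-12)
    return float(np.sqrt(max(0.0, 1.0 - lam2 / lam1)))


def detect_cells(mask_dilated: np.ndarray, image: np.ndarray | None = None) -> list[Cell]:
    """Extract every enclosed cell from the (dilated) wall mask.

    Cells are maximal 4-connected background components that do not touch
    the image border (partial border cells are unmeasurable).  Interior
    pixels, area, centroid, traced boundary and — when ``image`` is given
    — mean interior intensity are recorded per cell.
    """
    background = ~np.asarray(mask_dilated, dtype=bool)
    labels, n = ndimage.label(background, structure=_FOUR_CONNECTED)
    if n == 0:
        return []
    border = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    border_set = set(int(b) for b in border if b != 0)
    cells: list[Cell] = []
    next_id = 1
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None or lab in border_set:
            continue
        r0 = max(sl[0].start - 1, 0)
        c0 = max(sl[1].start - 1, 0)
        sub = labels[r0:sl[0].stop + 1, c0:sl[1].stop + 1] == lab
        rr, cc = np.nonzero(sub)
        rows, cols = rr + r0, cc + c0
        boundary = _trace_boundary(sub, (r0, c0))
        cell = Cell(
            id=next_id,
            pixels=(rows, cols),
            boundary=boundary,
            area=int(rows.size),
            centroid=(float(rows.mean()), float(cols.mean())),
        )
        if image is not None:
            cell.mean_intensity = float(image[rows, cols].mean())
        cell.eccentricity = _cell_eccentricity(boundary, rows, cols)
        cells.append(cell)
        next_id += 1
    return cells


def remove_lateral_roots(cells: list[Cell], image: np.ndarray,
                         fraction: float = 1.0 / 3.0) -> list[Cell]:
    """Drop regions darker than ``fraction`` of the mean region intensity.

    Lateral-root formations appear as very dark blobs attached to the
    root; their enclosed interiors are far darker than cell lumina.
    """
    if not cells:
        return cells
    for cell in cells:
        if np.isnan(cell.mean_intensity):
            rows, cols = cell.pixels
            cell.mean_intensity = float(image[rows, cols].mean())
    overall = float(np.mean([c.mean_intensity for c in cells]))
    kept = [c for c in cells if c.mean_intensity >= fraction * overall]
    for new_id, cell in enumerate(kept, start=1):
        cell.id = new_id
    return kept


def initial_root_boundary(
    cells: list[Cell], mask_dilated: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Outer root boundary from the wall mask plus all cell interiors.

    Fills enclosed holes, keeps the largest connected component and
    traces its outer contour.  Returns ``(polygon, region_mask)``.
    """
    if not cells:
        raise SegmentationError("no cells detected; cannot form a root boundary")
    union = np.asarray(mask_dilated, dtype=bool).copy()
    for cell in cells:
        union[cell.pixels] = True
    filled = ndimage.binary_fill_holes(union)
    labels, n = ndimage.label(filled)  # 8-connectivity for the foreground body
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        filled = labels == keep
    contour = _trace_boundary(filled, (0, 0))
    return contour, filled


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance from each pixel to the nearest foreground pixel."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("distance map undefined for an all-background mask")
    return ndimage.distance_transform_edt(~mask)


def _distance_peaks(dist: np.ndarray, min_height: float) -> list[tuple[int, int]]:
    """Centres of regional maxima of the distance map.

    Shallow maxima are merged by h-maxima suppression (h = 1 px) and
    peaks below ``min_height`` — sub-cell-scale structure — are ignored.
    """
    peaks_mask = morphology.h_maxima(dist, 1.0)
    peaks_mask &= dist >= min_height
    labels, n = ndimage.label(peaks_mask)
    if n == 0:
        return []
    centres = ndimage.center_of_mass(peaks_mask, labels, np.arange(1, n + 1))
    return [(int(round(y)), int(round(x))) for y, x in centres]


def recover_missed_cells(image: np.ndarray, params, model: RootModel) -> RootModel:
    """Second-chance detection of boundary cells with faint walls.

    Re-segments at half the threshold ``T`` (far too noisy for regular
    detection but often enough to complete faint boundaries), then admits
    a relaxed-pass cell only when a distance-map peak of the first-pass
    mask falls outside the initial root boundary and inside that cell.
    All other relaxed-pass regions are treated as noise and discarded.
    First-pass cells are never removed; the outer boundary is recomputed
    over the enlarged cell set.
    """
    relaxed = local_threshold(image, params.T / 2.0, params.w, params.polarity)
    relaxed_cells = detect_cells(dilate_mask(relaxed), image)

    dist = distance_map(model.mask)
    min_height = np.sqrt(params.A_s / np.pi) / 2.0
    peaks = _distance_peaks(dist, min_height)

    claimed = np.zeros(image.shape, dtype=np.int32)
    for idx, cell in enumerate(relaxed_cells, start=1):
        claimed[cell.pixels] = idx

    existing = np.zeros(image.shape, dtype=bool)
    for cell in model.cells:
        existing[cell.pixels] = True

    # promoted cells must clear the same darkness rule as first-pass cells,
    # otherwise the relaxed pass re-admits removed lateral-root interiors
    mean_cell_intensity = float(np.mean([c.mean_intensity for c in model.cells]))
    intensity_floor = params.lateral_intensity_fraction * mean_cell_intensity

    promoted_idx: list[int] = []
    for y, x in peaks:
        if model.gamma_ini_mask[y, x]:
            continue
        idx = int(claimed[y, x])
        if idx == 0 or idx in promoted_idx:
            continue
        cand = relaxed_cells[idx - 1]
        overlap = existing[cand.pixels].sum()
        if overlap > 0.5 * cand.area:
            continue  # already captured by a first-pass cell
        if cand.mean_intensity < intensity_floor:
            continue
        promoted_idx.append(idx)

    next_id = max((c.id for c in model.cells), default=0) + 1
    for idx in promoted_idx:
        cell = relaxed_cells[idx - 1]
        cell.id = next_id
        next_id += 1
        model.cells.append(cell)

    model.gamma_final, model.gamma_final_mask = initial_root_boundary(model.cells, model.mask)
    return model


def flag_perimeter_cells(model: RootModel, tol: float = BOUNDARY_TOUCH_TOL) -> None:
    """Mark cells whose boundary touches the outer background."""
    inside_depth = ndimage.distance_transform_edt(model.gamma_final_mask)
    for cell in model.cells:
        cell.on_perimeter = bool(inside_depth[cell.pixels].min() <= tol)


def build_root_model(image: np.ndarray, params) -> RootModel:
    """Segment an image and detect its cells, including the recovery pass."""
    wall_mask = local_threshold(image, params.T, params.w, params.polarity)
    dilated = dilate_mask(wall_mask)
    cells = detect_cells(dilated, image)
    cells = remove_lateral_roots(cells, image, params.lateral_intensity_fraction)
    if not cells:
        raise SegmentationError("segmentation produced no cells")
    gamma_ini, gamma_mask = initial_root_boundary(cells, dilated)
    model = RootModel(
        cells=cells,
        gamma_ini=gamma_ini,
        gamma_final=gamma_ini,
        gamma_ini_mask=gamma_mask,
        gamma_final_mask=gamma_mask,
        mask=dilated,
    )
    recover_missed_cells(image, params, model)
    flag_perimeter_cells(model)
    return model
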