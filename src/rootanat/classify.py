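"""Rule-based classification of detected cells into anatomical tissues.

The cascade relies on a-priori root morphology rather than staining
intensity: epidermal cells are the smaller cells on the root perimeter;
stele and endodermis cells are markedly smaller than cortex cells and
spatially clustered; the metaxylem vessels are much larger than the
surrounding stele cells and sit near the centre of that cluster; the
endodermis is the outermost layer of the stele cluster.

Stages (wheat path):

1. perimeter cells -> epidermis (smaller 80%) or cortex;
2. remaining cells -> noise / small / large by area gates ``A_s``/``A_l``;
3. small cells clustered by distance to their centre of mass
   (mean + 3 sigma gate on a Gaussian fitted to the distance histogram);
4. metaxylem: cells in the cluster that are significantly larger than
   the cluster cells and surrounded only by cluster members;
5. stele/endodermis candidates by k-nearest-neighbour distances,
   then refinement against the approximate endodermis boundary;
6. the candidates touching the cluster's outer contour -> endodermis,
   the rest -> stele; everything else non-noise -> cortex.

All ties are broken by ascending cell id, so the cascade is
deterministic for a given model and parameter set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .detection import BOUNDARY_TOUCH_TOL, Cell, RootModel, _trace_boundary

#: adjacency reach (px) when finding the cells sharing a wall with a cell:
#: 2 px of wall plus the dilation bias, with slack
_ADJACENCY_REACH = 4.5

__all__ = [
    "CellCluster",
    "classify_epidermis",
    "classify_by_area",
    "stele_cluster",
    "detect_metaxylem",
    "classify_stele_candidates",
    "refine_stele",
    "identify_endodermis",
    "classify_cells",
    "ClassificationError",
]


class ClassificationError(RuntimeError):
    """Raised when a root is too degenerate to classify."""


@dataclasses.dataclass
class CellCluster:
    """The small-cell cluster approximating stele plus endodermis."""

    member_ids: set[int]
    centroid: tuple[float, float]
    mean_distance: float
    std_distance: float

    @property
    def extent(self) -> float:
        """Spatial reach of the cluster (mean + 3 sigma of member distances)."""
        return self.mean_distance + 3.0 * self.std_distance


def _active_cells(model: RootModel) -> list[Cell]:
    """Cells that take part in tissue analysis (noise regions excluded)."""
    return [c for c in model.cells if c.size_class != "noise"]


def classify_epidermis(model: RootModel, params) -> RootModel:
    """Split root-perimeter cells into epidermis and stray cortex.

    Perimeter cells sorted by increasing area (ties by id): the first
    ``epidermis_fraction`` are epidermis; the larger remainder are taken
    to be cortex cells exposed by missing epidermis.
    """
    perimeter = sorted(
        (c for c in model.cells if c.on_perimeter), key=lambda c: (c.area, c.id)
    )
    if not perimeter:
        return model
    n_epi = int(np.floor(params.epidermis_fraction * len(perimeter)))
    for cell in perimeter[:n_epi]:
        cell.tissue = "epidermis"
    for cell in perimeter[n_epi:]:
        cell.tissue = "cortex"
    return model


def classify_by_area(model: RootModel, params) -> RootModel:
    """Gate non-epidermal cells into noise / small / large by area."""
    for cell in model.cells:
        if cell.tissue == "epidermis":
            cell.size_class = "epidermal-candidate"
            continue
        if cell.area < params.A_s:
            cell.size_class = "noise"
            cell.tissue = "noise"
        elif cell.area < params.A_l:
            cell.size_class = "small"
        else:
            cell.size_class = "large"
    return model


def _small_cells(model: RootModel) -> list[Cell]:
    return [
        c for c in model.cells
        if c.size_class == "small" and c.tissue != "epidermis"
    ]


def stele_cluster(model: RootModel, params) -> CellCluster:
    """Cluster the small cells around their centre of mass.

    The distances from small-cell centroids to their centre of mass are
    fitted with a Gaussian; cells within mean + 3 sigma form the
    stele/endodermis candidate cluster.  When the distance histogram is
    bimodal (small cells also scattered through the cortex), the fit is
    restricted to the lower mode, split off at the dominant gap in the
    sorted distances.
    """
    smalls = _small_cells(model)
    if len(smalls) < 3:
        raise ClassificationError(
            f"only {len(smalls)} small cells; root too degenerate to classify"
        )
    pts = np.array([c.centroid for c in smalls])
    centre = pts.mean(axis=0)
    d = np.hypot(pts[:, 0] - centre[0], pts[:, 1] - centre[1])

    # bimodal only when a clear empty band separates a lower mode (stele
    # and endodermis) from a distant upper one (small cells in the cortex)
    fit_on = np.ones(len(d), dtype=bool)
    if len(np.unique(d)) > 2:
        ds = np.sort(d)
        j = int(np.argmax(np.diff(ds)))
        gap = ds[j + 1] - ds[j]
        # the lower mode must hold the majority and the gap must dwarf the
        # overall spread, otherwise the distribution is effectively unimodal
        if j + 1 >= max(3, len(ds) // 2) and gap > max(ds.std(), 1e-9):
            fit_on = d <= ds[j]
    mu = float(d[fit_on].mean())
    sigma = float(d[fit_on].std())
    gate = mu + params.cluster_sigma_mult * sigma
    member_ids = {c.id for c, dist in zip(smalls, d) if dist <= gate}
    return CellCluster(
        member_ids=member_ids,
        centroid=(float(centre[0]), float(centre[1])),
        mean_distance=mu,
        std_distance=sigma,
    )


def _disk_close(mask: np.ndarray, radius: float) -> np.ndarray:
    """Morphological closing by a Euclidean disk, via distance thresholds."""
    dilated = ndimage.distance_transform_edt(~mask) <= radius
    return ndimage.distance_transform_edt(dilated) > radius


def _cell_labels(model: RootModel) -> np.ndarray:
    """Label image of all non-noise cells (cached: pixels never move)."""
    cached = getattr(model, "_cell_label_image", None)
    if cached is not None:
        return cached
    labels = np.zeros(model.gamma_final_mask.shape, dtype=np.int32)
    for cell in model.cells:
        if cell.size_class != "noise":
            labels[cell.pixels] = cell.id
    model._cell_label_image = labels
    return labels


def _adjacent_ids(model: RootModel, cell: Cell, reach: float = _ADJACENCY_REACH) -> set[int]:
    """ids of the cells sharing a wall with ``cell`` (within ``reach`` px)."""
    labels = _cell_labels(model)
    rows, cols = cell.pixels
    pad = int(np.ceil(reach)) + 1
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, labels.shape[0])
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, labels.shape[1])
    sub = labels[r0:r1, c0:c1]
    cell_mask = np.zeros(sub.shape, dtype=bool)
    cell_mask[rows - r0, cols - c0] = True
    near = ndimage.distance_transform_edt(~cell_mask) <= reach
    return {int(i) for i in np.unique(sub[near]) if i not in (0, cell.id)}


def _nearest_ids(cells: list[Cell], k: int) -> dict[int, list[int]]:
    """ids of the k nearest cells (by centroid) for every cell."""
    pts = np.array([c.centroid for c in cells])
    ids = np.array([c.id for c in cells])
    kk = min(k, len(cells) - 1)
    if kk < 1:
        return {int(i): [] for i in ids}
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=kk + 1)
    return {int(ids[i]): [int(ids[j]) for j in idx[i, 1:]] for i in range(len(cells))}


def detect_metaxylem(model: RootModel, cluster: CellCluster, params) -> RootModel:
    """Label the metaxylem vessel(s) and fix the stele centre.

    A cell is a metaxylem candidate when it (a) lies inside the cluster's
    spatial extent, (b) has only cluster members (or other candidates)
    among its k nearest cells, and (c) is significantly larger than the
    cluster cells (area above the cluster mean + 2 sigma).  When the
    candidate areas are clearly bimodal, only the larger mode is kept:
    large non-vessel stele cells (e.g. protoxylem elements) satisfy
    (a)-(c) as well but are markedly smaller than true vessels.  The
    stele centre is the centre of mass of the metaxylem cells, falling
    back to the cluster centroid when none is found.
    """
    active = _active_cells(model)
    by_id = {c.id: c for c in active}
    members = [by_id[i] for i in sorted(cluster.member_ids) if i in by_id]
    if not members:
        model.stele_centre = cluster.centroid
        return model
    areas = np.array([c.area for c in members], dtype=float)
    area_gate = areas.mean() + 2.0 * areas.std()

    candidates: list[Cell] = []
    for cell in active:
        if cell.tissue == "epidermis":
            continue
        dist = np.hypot(cell.centroid[0] - cluster.centroid[0],
                        cell.centroid[1] - cluster.centroid[1])
        if dist <= cluster.extent and cell.area > area_gate:
            candidates.append(cell)

    if candidates:
        # "completely surrounded by small cells": every cell sharing a wall
        # with the candidate is a cluster member or another vessel candidate
        # (adjoining vessels occur in maize), and cluster members make up at
        # least half of them — a ring of fellow large cells is not a stele
        # neighbourhood.
        allowed = cluster.member_ids | {c.id for c in candidates}
        kept: list[Cell] = []
        for c in candidates:
            nbr = _adjacent_ids(model, c)
            members_adj = sum(1 for nid in nbr if nid in cluster.member_ids)
            if (
                nbr
                and all(nid in allowed for nid in nbr)
                and members_adj >= 0.5 * len(nbr)
            ):
                kept.append(c)
        candidates = kept

    if len(candidates) >= 2:
        # vessels are the markedly larger mode; large non-vessel cells
        # (protoxylem, stray cortex) pass the gates above but are smaller.
        # With this few values, modes are peeled off at the largest area
        # gap, repeatedly, until the remaining areas form one tight group.
        areas_c = np.array(sorted(c.area for c in candidates), dtype=float)
        while len(np.unique(areas_c)) > 1:
            gaps = np.diff(areas_c)
            j = int(np.argmax(gaps))
            cut = 0.5 * (areas_c[j] + areas_c[j + 1])
            lo, hi = areas_c[: j + 1], areas_c[j + 1:]
            pooled = np.sqrt((lo.var() * len(lo) + hi.var() * len(hi))
                             / (len(lo) + len(hi)))
            if hi.mean() - lo.mean() < max(pooled, 0.2 * areas_c.mean()):
                break
            candidates = [c for c in candidates if c.area > cut]
            areas_c = hi

    for cell in candidates:
        cell.tissue = "metaxylem"
    if candidates:
        pts = np.array([c.centroid for c in candidates])
        weights = np.array([c.area for c in candidates], dtype=float)
        centre = (pts * weights[:, None]).sum(axis=0) / weights.sum()
        model.stele_centre = (float(centre[0]), float(centre[1]))
    else:
        model.stele_centre = cluster.centroid
    return model


def classify_stele_candidates(model: RootModel, cluster: CellCluster, params) -> RootModel:
    """Keep cluster cells whose k nearest small cells are all close by.

    For each small cluster cell the distances to its k nearest small
    cells are computed; the cell stays a stele/endodermis candidate only
    when the largest of those distances is at most ``neighbor_dist_max``.
    Cells failing the test (isolated small cells in the cortex) revert to
    cortex.  With fewer than k+1 small cells all available neighbours are
    used.
    """
    smalls = _small_cells(model)
    if not smalls:
        model.stele_candidates = set()
        return model
    pts = np.array([c.centroid for c in smalls])
    tree = cKDTree(pts)
    kk = min(params.k_neighbors, len(smalls) - 1)
    candidates: set[int] = set()
    for i, cell in enumerate(smalls):
        if cell.id not in cluster.member_ids or cell.tissue == "metaxylem":
            continue
        if kk < 1:
            candidates.add(cell.id)
            continue
        dists, _ = tree.query(pts[i], k=kk + 1)
        if float(np.max(dists)) <= params.neighbor_dist_max:
            candidates.add(cell.id)
        else:
            cell.tissue = "cortex"
    model.stele_candidates = candidates
    return model


def _candidate_region(model: RootModel, params) -> tuple[np.ndarray, np.ndarray]:
    """Approximate endodermis boundary: closed outer contour of the
    candidate union (morphological closing bridges the wall gaps)."""
    shape = model.gamma_final_mask.shape
    union = np.zeros(shape, dtype=bool)
    ids = model.stele_candidates | {c.id for c in model.cells if c.tissue == "metaxylem"}
    for cell in model.cells:
        if cell.id in ids:
            union[cell.pixels] = True
    if not union.any():
        raise ClassificationError("empty stele/endodermis candidate set")
    radius = max(params.neighbor_dist_max / 2.0, 1.0)
    model._closing_radius = radius
    closed = ndimage.binary_fill_holes(_disk_close(union, radius))
    labels, n = ndimage.label(closed)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        closed = labels == (int(np.argmax(sizes)) + 1)
    contour = _trace_boundary(closed, (0, 0))
    return contour, closed


def refine_stele(model: RootModel, params) -> RootModel:
    """Three corrections against the approximate endodermis boundary.

    (i) large non-metaxylem cells wholly inside the boundary join the
    candidates (protoxylem elements and similar); (ii) strongly flattened
    cells (eccentricity above ``ecc_min``) with centroid within
    ``boundary_margin`` px of the boundary join as well — these are
    mostly endodermal cells just outside the cluster; (iii) candidates
    whose k nearest cells are mostly cortex revert to cortex.
    """
    contour, region = _candidate_region(model, params)
    active = _active_cells(model)

    inside_depth = ndimage.distance_transform_edt(region)
    outside_depth = ndimage.distance_transform_edt(~region)

    for cell in active:
        if cell.tissue in ("epidermis", "metaxylem") or cell.id in model.stele_candidates:
            continue
        if cell.size_class == "large":
            rows, cols = cell.pixels
            if region[rows, cols].all():
                model.stele_candidates.add(cell.id)
                cell.tissue = "unassigned"
                continue
        cy, cx = int(round(cell.centroid[0])), int(round(cell.centroid[1]))
        dist_to_boundary = (inside_depth[cy, cx] if region[cy, cx]
                            else outside_depth[cy, cx])
        if cell.eccentricity > params.ecc_min and dist_to_boundary <= params.boundary_margin:
            model.stele_candidates.add(cell.id)
            cell.tissue = "unassigned"

    # (iii) simultaneous cortex-majority vote over the pre-vote labels,
    # using the cells that actually share a wall with the candidate
    by_id = {c.id: c for c in active}
    is_cortexish = {
        c.id: (
            c.tissue == "cortex"
            or (c.tissue == "unassigned" and c.id not in model.stele_candidates)
        )
        for c in active
    }
    demote = []
    for cid in sorted(model.stele_candidates):
        nbr = _adjacent_ids(model, by_id[cid])
        nbr = [nid for nid in nbr if nid in is_cortexish]
        if not nbr:
            continue
        votes = sum(1 for nid in nbr if is_cortexish[nid])
        if votes > params.cortex_vote_fraction * len(nbr):
            demote.append(cid)
    for cid in demote:
        model.stele_candidates.discard(cid)
        by_id[cid].tissue = "cortex"

    model.endodermis_contour = contour
    model.endodermis_mask = region
    return model


def identify_endodermis(model: RootModel, tol: float = BOUNDARY_TOUCH_TOL) -> RootModel:
    """Split the candidate set into endodermis (outer layer) and stele.

    The filled, morphologically closed union of the candidate cells is
    formed (the closing bridges wall gaps and the occasional missing
    member, so the contour follows the ring rather than dipping into
    single-cell gaps); members whose boundary touches its outer contour
    become endodermis, all other members stele.  Every remaining
    non-noise, non-epidermis cell is cortex.  A single-member set is
    endodermis by convention.
    """
    shape = model.gamma_final_mask.shape
    union = np.zeros(shape, dtype=bool)
    members = [c for c in model.cells if c.id in model.stele_candidates]
    for cell in members:
        union[cell.pixels] = True
    if members:
        radius = max((getattr(model, "_closing_radius", 25.0)), 3.0)
        filled = ndimage.binary_fill_holes(_disk_close(union, radius))
        depth = ndimage.distance_transform_edt(filled)
        for cell in members:
            touches = bool(depth[cell.pixels].min() <= tol)
            cell.tissue = "endodermis" if touches or len(members) == 1 else "stele"
        # refresh the region used for stele-area reporting and cheesewheel
        model.endodermis_mask = filled
        model.endodermis_contour = _trace_boundary(filled, (0, 0))
    for cell in model.cells:
        if cell.size_class == "noise" or cell.tissue in (
            "epidermis", "endodermis", "stele", "metaxylem", "noise",
        ):
            continue
        cell.tissue = "cortex"
    return model


def classify_cells(model: RootModel, params) -> RootModel:
    """Run the full wheat-path cascade in order."""
    classify_epidermis(model, params)
    classify_by_area(model, params)
    cluster = stele_cluster(model, params)
    detect_metaxylem(model, cluster, params)
    classify_stele_candidates(model, cluster, params)
    refine_stele(model, params)
    identify_endodermis(model)
    return model
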