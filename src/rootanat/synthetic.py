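"""Synthetic root cross-section images with exact per-cell ground truth.

Real stained cross sections show dark cell-wall lines on a bright,
spatially drifting background, with concentric anatomy: a single outer
layer of small epidermal cells, rings of large cortex cells, a single
endodermal layer of flattened cells, a stele packed with small cells and
one (wheat) or several (maize) large central metaxylem vessels.  The
generator tessellates those zones with ring-wise angular cells (jittered
so cell areas vary), renders 2-px walls darker than the local background,
and returns both the image and a :class:`GroundTruth` with per-pixel cell
identities and true tissue labels, so that every pipeline stage can be
scored without real micrographs.

Optional degradations emulate common acquisition problems: a linear
background intensity gradient, additive Gaussian noise, locally faint
outer walls (``break_probability``) that the standard threshold misses
but a relaxed one recovers, and a dark lateral-root blob attached to the
perimeter.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_root",
    "match_cells",
    "detection_rate",
    "mean_area_error",
    "label_accuracy",
]

#: tissue labels used in ground truth (shared vocabulary with the classifier)
EPIDERMIS = "epidermis"
CORTEX = "cortex"
ENDODERMIS = "endodermis"
STELE = "stele"
METAXYLEM = "metaxylem"
PROTOXYLEM = "protoxylem"
AERENCHYMA = "aerenchyma"

#: nominal background gray level at the image centre
_BG_BASE = 0.65
#: wall contrast: walls are rendered at local_background - (_BG_BASE - wall_intensity)
#: faint (broken) wall segments: intensity depression relative to local
#: background, chosen so the local intensity difference at these pixels falls
#: between T/2 and T for the default T = 0.05 (the rim window mean is itself
#: depressed by ~0.012 from nearby dark walls)
_FAINT_DEPTH = 0.050
#: arc length range (px) of a faint outer-wall segment
_BREAK_ARC = (8.0, 14.0)


@dataclasses.dataclass
class SyntheticSpec:
    """Geometry and degradation settings for one synthetic root.

    Radii are in pixels, measured from the root centre.  The concentric
    layout (inside out) is: metaxylem, stele rings, endodermis ring,
    ``n_cortex_rings`` cortex rings, epidermis ring, with the outer edge
    at ``root_radius``.
    """

    species: str = "wheat"
    seed: int = 0
    root_radius: float = 222.0
    stele_radius: float = 110.0
    n_epidermis: int = 36
    n_cortex_rings: int = 3
    cortex_cell_scale: float = 64.0  # target angular cell width, px of arc
    stele_cell_scale: float = 28.0
    endodermis_thickness: float = 22.0
    epidermis_thickness: float = 20.0
    n_metaxylem: int = 1
    metaxylem_radius: float = 28.0
    n_protoxylem: int = 0
    protoxylem_fractions: tuple[float, ...] | None = None
    protoxylem_radius: float = 20.0
    n_aerenchyma: int = 0
    wall_intensity: float = 0.45
    background_gradient_amplitude: float = 0.15
    noise_sigma: float = 0.01
    break_probability: float = 0.0
    lateral_root: bool = False
    margin: float = 34.0

    @classmethod
    def wheat(cls, **overrides) -> "SyntheticSpec":
        return cls(**overrides)

    @classmethod
    def maize(cls, **overrides) -> "SyntheticSpec":
        defaults = dict(
            species="maize",
            root_radius=245.0,
            stele_radius=123.0,
            n_epidermis=45,
            epidermis_thickness=20.0,
            n_metaxylem=6,
            metaxylem_radius=28.0,
            n_protoxylem=6,
            n_aerenchyma=5,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def validate(self) -> None:
        if self.species not in ("wheat", "maize"):
            raise ValueError(f"species must be 'wheat' or 'maize', got {self.species!r}")
        if not 0 < self.stele_radius < self.root_radius:
            raise ValueError("need 0 < stele_radius < root_radius")
        inner_cortex = self.stele_radius + self.endodermis_thickness
        outer_cortex = self.root_radius - self.epidermis_thickness
        if inner_cortex >= outer_cortex:
            raise ValueError("endodermis/epidermis rings leave no room for the cortex")
        for name in ("n_epidermis", "n_cortex_rings", "n_metaxylem", "n_protoxylem", "n_aerenchyma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_epidermis < 5 or self.n_cortex_rings < 1:
            raise ValueError("need at least 5 epidermal cells and one cortex ring")
        if not 0.0 <= self.break_probability <= 1.0:
            raise ValueError("break_probability must lie in [0, 1]")
        if not 0.0 <= self.wall_intensity < _BG_BASE:
            raise ValueError(f"wall_intensity must lie in [0, {_BG_BASE})")
        if self.noise_sigma < 0 or self.background_gradient_amplitude < 0:
            raise ValueError("noise and gradient amplitudes must be non-negative")
        if self.protoxylem_fractions is not None:
            if len(self.protoxylem_fractions) != self.n_protoxylem:
                raise ValueError("protoxylem_fractions length must equal n_protoxylem")
            if any(not 0.0 < f < 1.0 for f in self.protoxylem_fractions):
                raise ValueError("protoxylem fractions must lie in (0, 1)")

    @property
    def image_size(self) -> int:
        return int(2 * (self.root_radius + self.margin))


@dataclasses.dataclass
class GroundTruth:
    """Exact per-cell truth for one generated image."""

    label_image: np.ndarray  # per-pixel planted cell id (0 = wall/background)
    wall_mask: np.ndarray  # rendered wall pixels (bool)
    tissue_of: dict[int, str]  # planted cell id -> true tissue
    centre: tuple[float, float]  # root centre (row, col)
    true_boundaries: dict[int, np.ndarray]  # id -> (N, 2) contour, largest part
    true_stats: dict[str, dict[str, float]]  # tissue -> count/total_area/mean_area

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.tissue_of)

    def area_of(self, cell_id: int) -> int:
        return int(np.count_nonzero(self.label_image == cell_id))


class _IdAllocator:
    def __init__(self) -> None:
        self.next_id = 1

    def take(self, n: int) -> np.ndarray:
        ids = np.arange(self.next_id, self.next_id + n)
        self.next_id += n
        return ids


def _ring_sectors(
    rel_theta: np.ndarray, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sector index for each angle, under jittered angular edges.

    Returns (sector_index, edge_angles).  Edges are ``2*pi*k/n`` plus a
    per-edge jitter of up to 12% of the sector width, plus a common
    random offset, so cell areas vary realistically within a ring.
    """
    width = 2 * np.pi / n
    offset = rng.uniform(0, 2 * np.pi)
    jitter = rng.uniform(-0.12, 0.12, size=n) * width
    edges = np.arange(n) * width + jitter  # ascending: |jitter| < width/2
    rel = np.mod(rel_theta - offset, 2 * np.pi)
    idx = np.searchsorted(edges, rel, side="right") - 1
    idx = np.where(idx < 0, n - 1, idx)
    return idx, edges + offset


def generate_root(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic cross-section image and its ground truth.

    Deterministic for a fixed ``spec.seed``: the same spec yields a
    bit-identical image and truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    c = (size - 1) / 2.0
    rows, cols = np.mgrid[0:size, 0:size]
    dy = rows - c
    dx = cols - c
    r = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)

    id_image = np.zeros((size, size), dtype=np.int32)
    tissue_of: dict[int, str] = {}
    alloc = _IdAllocator()

    def fill_rings(edges_r: np.ndarray, arcs, tissue: str,
                   counts: Iterable[int] | None = None) -> list[tuple[int, np.ndarray]]:
        """Tessellate concentric rings (given radial edges) into angular cells."""
        n_rings = len(edges_r) - 1
        arcs = np.broadcast_to(np.asarray(arcs, dtype=float), (n_rings,))
        counts = None if counts is None else list(counts)
        ring_infos = []
        for k in range(n_rings):
            lo, hi = edges_r[k], edges_r[k + 1]
            mid = 0.5 * (lo + hi)
            n = counts[k] if counts is not None else max(
                4, int(round(2 * np.pi * mid / arcs[k])))
            mask = (r >= lo) & (r < hi)
            sector, _ = _ring_sectors(theta[mask], n, rng)
            ids = alloc.take(n)
            id_image[mask] = ids[sector]
            for i in ids:
                tissue_of[int(i)] = tissue
            ring_infos.append((n, ids))
        return ring_infos

    def stele_ring_layout(r0: float, r1: float) -> tuple[np.ndarray, np.ndarray]:
        """Radial edges and arc targets for the stele: the outermost ring is
        ~20% thinner and denser, like the small cells bordering the
        pericycle, which also keeps endodermal neighbour distances short."""
        scale = spec.stele_cell_scale
        n_rings = max(1, int(round((r1 - r0) / scale)))
        if n_rings == 1:
            return np.array([r0, r1]), np.array([scale])
        widths = np.full(n_rings, 1.0)
        widths[-1] = 0.8
        edges_r = r0 + np.concatenate([[0.0], np.cumsum(widths)]) * (r1 - r0) / widths.sum()
        arcs = np.full(n_rings, scale)
        arcs[-1] = 0.85 * scale
        return edges_r, arcs

    # ---- concentric anatomy, inside out -------------------------------
    endo_outer = spec.stele_radius + spec.endodermis_thickness
    cortex_outer = spec.root_radius - spec.epidermis_thickness

    if spec.species == "wheat":
        # single central metaxylem vessel, stele rings around it
        mx_id = int(alloc.take(1)[0])
        id_image[r < spec.metaxylem_radius] = mx_id
        tissue_of[mx_id] = METAXYLEM
        edges_r, arcs = stele_ring_layout(spec.metaxylem_radius, spec.stele_radius)
        fill_rings(edges_r, arcs, STELE)
    else:
        # small-cell grid across the whole stele; vessels stamped on top
        edges_r, arcs = stele_ring_layout(14.0, spec.stele_radius)
        fill_rings(edges_r, arcs, STELE)
        centre_id = int(alloc.take(1)[0])
        id_image[r < 14.0] = centre_id
        tissue_of[centre_id] = STELE

    # endodermis: single ring of flattened cells
    n_endo = max(8, int(round(2 * np.pi * (spec.stele_radius + spec.endodermis_thickness / 2)
                              / (1.35 * spec.endodermis_thickness))))
    fill_rings(np.array([spec.stele_radius, endo_outer]), [0.0], ENDODERMIS,
               counts=[n_endo])

    # cortex rings of large cells
    cortex_rings = fill_rings(
        np.linspace(endo_outer, cortex_outer, spec.n_cortex_rings + 1),
        spec.cortex_cell_scale, CORTEX)

    # aerenchyma: merge runs of 3 consecutive sectors in the middle cortex ring
    if spec.species == "maize" and spec.n_aerenchyma > 0:
        ring_idx = len(cortex_rings) // 2
        n_ring, ids_ring = cortex_rings[ring_idx]
        group = 3
        if spec.n_aerenchyma * group > n_ring:
            raise ValueError("n_aerenchyma too large for the middle cortex ring")
        lut = np.arange(alloc.next_id, dtype=np.int32)
        starts = np.linspace(0, n_ring - group, spec.n_aerenchyma).astype(int)
        for s in starts:
            head = int(ids_ring[s])
            for j in range(1, group):
                merged = int(ids_ring[s + j])
                lut[merged] = head
                tissue_of.pop(merged, None)
            tissue_of[head] = AERENCHYMA
        id_image = lut[id_image]

    # epidermis: outermost single layer of small cells
    (_, epi_ids), = fill_rings(np.array([cortex_outer, spec.root_radius]), [0.0],
                               EPIDERMIS, counts=[spec.n_epidermis])

    # maize vessels stamped over the stele grid (polyarch arrangement)
    if spec.species == "maize":
        discs: list[tuple[float, float, float, str]] = []
        ring_r = 0.5 * spec.stele_radius
        for ang in np.arange(spec.n_metaxylem) * 2 * np.pi / max(spec.n_metaxylem, 1):
            discs.append((ring_r * np.sin(ang), ring_r * np.cos(ang),
                          spec.metaxylem_radius, METAXYLEM))
        if spec.n_protoxylem > 0:
            fracs = spec.protoxylem_fractions
            if fracs is None:
                fracs = (0.7,) * spec.n_protoxylem
            half = np.pi / max(spec.n_metaxylem, 1)
            angles = (np.arange(spec.n_protoxylem) * 2 * np.pi / spec.n_protoxylem) + half
            for ang, frac in zip(angles, fracs):
                rad = frac * endo_outer
                discs.append((rad * np.sin(ang), rad * np.cos(ang),
                              spec.protoxylem_radius, PROTOXYLEM))
        for j, (y1, x1, r1, _) in enumerate(discs):
            for y2, x2, r2, _ in discs[j + 1:]:
                if np.hypot(y1 - y2, x1 - x2) < r1 + r2 + 2:
                    raise ValueError(
                        "vessel discs overlap; adjust metaxylem/protoxylem "
                        "counts, radii or fractions"
                    )
        for cy, cx, rad, tissue in discs:
            disc = (dy - cy) ** 2 + (dx - cx) ** 2 < rad**2
            i = int(alloc.take(1)[0])
            id_image[disc] = i
            tissue_of[i] = tissue
    elif spec.species == "wheat" and spec.n_metaxylem > 1:
        raise ValueError("wheat roots carry a single central metaxylem")

    # drop ids that were fully overwritten by stamped vessels
    present = set(np.unique(id_image).tolist())
    tissue_of = {i: t for i, t in tissue_of.items() if i in present}

    # ---- walls: both sides of every identity change -> ~2 px lines ----
    wall = np.zeros_like(id_image, dtype=bool)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        shifted = np.roll(id_image, shift, axis=axis)
        wall |= id_image != shifted
    # image border rows/cols are background on both sides; np.roll wrap is harmless

    # faint outer-wall breaks on randomly selected epidermal cells
    faint = np.zeros_like(wall)
    if spec.break_probability > 0:
        picked = [int(i) for i in epi_ids if rng.random() < spec.break_probability]
        if not picked:
            picked = [int(epi_ids[0])]
        rim_band = wall & (np.abs(r - spec.root_radius) < 3.0)
        for i in picked:
            cell_mask = id_image == i
            if not cell_mask.any():
                continue
            th_cell = np.mod(np.arctan2(dy[cell_mask].mean(), dx[cell_mask].mean()), 2 * np.pi)
            arc = rng.uniform(*_BREAK_ARC)
            half_ang = 0.5 * arc / spec.root_radius
            dtheta = np.abs(np.mod(theta - th_cell + np.pi, 2 * np.pi) - np.pi)
            faint |= rim_band & (dtheta < half_ang)

    # ---- rendering ----------------------------------------------------
    grad = spec.background_gradient_amplitude * (2 * cols / (size - 1) - 1.0)
    bg = _BG_BASE + grad
    image = bg.copy()
    depth = _BG_BASE - spec.wall_intensity
    image[wall] = bg[wall] - depth
    image[faint] = bg[faint] - _FAINT_DEPTH

    if spec.lateral_root:
        ang = rng.uniform(0, 2 * np.pi)
        br = spec.root_radius + 6.0
        by, bx = br * np.sin(ang), br * np.cos(ang)
        # major axis tangential so the blob stays inside the frame
        ty, tx = np.cos(ang), -np.sin(ang)
        u = (dy - by) * ty + (dx - bx) * tx
        v = (dy - by) * (-tx) + (dx - bx) * ty
        blob = (u / 28.0) ** 2 + (v / 18.0) ** 2 < 1.0
        image[blob] = 0.08

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0)

    label_image = np.where(wall, 0, id_image)
    truth = GroundTruth(
        label_image=label_image,
        wall_mask=wall,
        tissue_of=tissue_of,
        centre=(c, c),
        true_boundaries=_trace_boundaries(label_image, tissue_of),
        true_stats=_summarise(label_image, tissue_of),
    )
    return image, truth


def _trace_boundaries(label_image: np.ndarray, tissue_of: dict[int, str]) -> dict[int, np.ndarray]:
    out: dict[int, np.ndarray] = {}
    slices = ndimage.find_objects(label_image)
    for i in tissue_of:
        sl = slices[i - 1]
        if sl is None:
            continue
        r0 = max(sl[0].start - 2, 0)
        c0 = max(sl[1].start - 2, 0)
        sub = label_image[max(sl[0].start - 2, 0):sl[0].stop + 2,
                          max(sl[1].start - 2, 0):sl[1].stop + 2] == i
        contours = measure.find_contours(sub.astype(float), 0.5)
        if not contours:
            continue
        longest = max(contours, key=len)
        out[i] = longest + [r0, c0]
    return out


def _summarise(label_image: np.ndarray, tissue_of: dict[int, str]) -> dict[str, dict[str, float]]:
    stats: dict[str, dict[str, float]] = {}
    ids = np.array(sorted(tissue_of))
    if ids.size == 0:
        return stats
    areas = ndimage.sum_labels(np.ones_like(label_image), label_image, ids)
    for i, a in zip(ids, areas):
        t = tissue_of[int(i)]
        entry = stats.setdefault(t, {"count": 0, "total_area": 0.0})
        entry["count"] += 1
        entry["total_area"] += float(a)
    for entry in stats.values():
        entry["mean_area"] = entry["total_area"] / entry["count"]
    return stats


# ---------------------------------------------------------------------------
# scoring detected models against ground truth


def match_cells(cells, truth: GroundTruth) -> dict[int, int]:
    """Map each planted cell id to the detected cell that best overlaps it.

    A detected cell is assigned to the planted id covering the majority
    of its pixels; when several detected cells map to one planted id the
    largest overlap wins.  Detected cells lying mostly on walls or
    background stay unmatched.
    """
    best: dict[int, tuple[int, int]] = {}  # true id -> (overlap, detected id)
    for cell in cells:
        labels = truth.label_image[cell.pixels]
        labels = labels[labels > 0]
        if labels.size == 0:
            continue
        ids, counts = np.unique(labels, return_counts=True)
        k = int(np.argmax(counts))
        true_id, overlap = int(ids[k]), int(counts[k])
        if overlap <= cell.area / 2:
            continue
        if true_id not in best or overlap > best[true_id][0]:
            best[true_id] = (overlap, cell.id)
    return {t: d for t, (_, d) in best.items()}


def detection_rate(cells, truth: GroundTruth) -> float:
    """Fraction of planted cells recovered by detection."""
    return len(match_cells(cells, truth)) / max(len(truth.tissue_of), 1)


def mean_area_error(cells, truth: GroundTruth) -> float:
    """Mean relative area error over matched planted/detected cell pairs."""
    by_id = {cell.id: cell for cell in cells}
    errs = []
    for true_id, det_id in match_cells(cells, truth).items():
        true_area = truth.area_of(true_id)
        errs.append(abs(by_id[det_id].area - true_area) / true_area)
    if not errs:
        raise ValueError("no matched cells to score")
    return float(np.mean(errs))


def label_accuracy(model, truth: GroundTruth) -> float:
    """Fraction of planted cells whose detected match carries the true tissue.

    Planted cells with no detected match count as misclassified.
    """
    by_id = {cell.id: cell for cell in model.cells}
    matches = match_cells(model.cells, truth)
    correct = 0
    for true_id, tissue in truth.tissue_of.items():
        det_id = matches.get(true_id)
        if det_id is not None and by_id[det_id].tissue == tissue:
            correct += 1
    return correct / max(len(truth.tissue_of), 1)
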