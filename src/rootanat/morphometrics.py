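"""Morphometric statistics: ellipse fits, per-tissue summaries, cheesewheel.

Eccentricity is taken from an ellipse fitted to a boundary by least
squares: ``E = sqrt(1 - b^2/a^2)`` with semi-axes ``a >= b``, so 0 is a
circle and values near 1 are strongly flattened shapes.  The per-tissue
summary mirrors the standard primary feature table (total area, cell
count, mean cell area, mean cell eccentricity per region, plus whole-root
and stele eccentricity).  The "cheesewheel" secondary statistics divide
the stele and cortex zones into 6 annuli x 6 wedges so radial and angular
trends can be read off directly.

All internal geometry is in pixels; the micron scale enters only here,
at reporting time.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from skimage.measure import EllipseModel

if TYPE_CHECKING:  # pragma: no cover
    from .detection import RootModel

__all__ = [
    "EllipseFit",
    "fit_ellipse",
    "TissueStats",
    "compute_tissue_stats",
    "CheesewheelStats",
    "cheesewheel",
    "write_stats",
]

#: tissue rows of the summary table, in output order
WHEAT_REGIONS = ("cortex", "stele", "endodermis", "metaxylem")
MAIZE_REGIONS = WHEAT_REGIONS + ("protoxylem", "aerenchyma")


@dataclasses.dataclass(frozen=True)
class EllipseFit:
    """Least-squares ellipse: semi-axes ``a >= b``, centre, orientation."""

    a: float
    b: float
    centre: tuple[float, float]
    orientation: float

    @property
    def E(self) -> float:
        return float(np.sqrt(1.0 - (self.b / self.a) ** 2))


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Fit an ellipse to boundary points by algebraic least squares.

    Falls back to the second-moment (inertia-equivalent) ellipse when the
    algebraic fit is degenerate.  Raises ``ValueError`` for fewer than 5
    points or (near-)collinear input.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("ellipse fit needs at least 5 (row, col) points")
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("boundary points are collinear; no ellipse fit")
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        model = EllipseModel.from_estimate(pts)
    if model:
        (yc, xc), (a, b), th = model.center, model.axis_lengths, model.theta
        if b > a:
            a, b, th = b, a, th + np.pi / 2
        if np.all(np.isfinite([yc, xc, a, b, th])) and b > 0:
            return EllipseFit(a=float(a), b=float(b), centre=(float(yc), float(xc)),
                              orientation=float(th % np.pi))
    return _moment_ellipse(pts)


def _moment_ellipse(pts: np.ndarray) -> EllipseFit:
    centre = pts.mean(axis=0)
    cov = np.cov((pts - centre).T)
    vals, vecs = np.linalg.eigh(cov)
    lam2, lam1 = max(vals[0], 1e-12), max(vals[1], 1e-12)
    a, b = 2.0 * np.sqrt(lam1), 2.0 * np.sqrt(lam2)
    major = vecs[:, 1]
    return EllipseFit(a=float(a), b=float(b), centre=(float(centre[0]), float(centre[1])),
                      orientation=float(np.arctan2(major[0], major[1]) % np.pi))


# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TissueStats:
    """Primary feature table for one analysed image (areas in um^2)."""

    root_area: float
    root_eccentricity: float
    stele_eccentricity: float
    regions: dict[str, dict[str, float]]  # tissue -> feature -> value
    scale: float  # um per px, recorded for provenance

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "whole_root", "feature": "total_area_um2", "value": self.root_area},
            {"region": "whole_root", "feature": "eccentricity", "value": self.root_eccentricity},
            {"region": "stele", "feature": "region_eccentricity",
             "value": self.stele_eccentricity},
        ]
        for region, feats in self.regions.items():
            for feature in ("total_area_um2", "cell_count", "mean_cell_area_um2",
                            "mean_cell_eccentricity"):
                rows.append({"region": region, "feature": feature,
                             "value": feats.get(feature, np.nan)})
        return pd.DataFrame(rows, columns=["region", "feature", "value"])


def compute_tissue_stats(model: "RootModel", scale: float = 1.0,
                         species: str = "wheat") -> TissueStats:
    """Summarise a classified root model into the primary feature table.

    ``scale`` is microns per pixel; areas are multiplied by ``scale**2``.
    The stele total area is measured as everything enclosed by the
    endodermis outer contour (walls included, matching how the region is
    read visually); per-cell areas always exclude walls.  With exactly
    one metaxylem the "mean" fields simply report that cell's values.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    s2 = scale * scale
    region_names = MAIZE_REGIONS if species == "maize" else WHEAT_REGIONS

    regions: dict[str, dict[str, float]] = {}
    for name in region_names:
        members = [c for c in model.cells if c.tissue == name]
        feats = {
            "cell_count": float(len(members)),
            "total_area_um2": s2 * float(sum(c.area for c in members)),
            "mean_cell_area_um2": (s2 * float(np.mean([c.area for c in members]))
                                   if members else np.nan),
            "mean_cell_eccentricity": (float(np.mean([c.eccentricity for c in members]))
                                       if members else np.nan),
        }
        regions[name] = feats
    # stele region area: everything enclosed by the endodermis outer contour
    if model.endodermis_mask is not None:
        regions["stele"]["total_area_um2"] = s2 * float(model.endodermis_mask.sum())

    root_area = s2 * float(model.gamma_final_mask.sum())
    try:
        root_ecc = fit_ellipse(model.gamma_final).E
    except ValueError:
        root_ecc = np.nan
    if model.endodermis_contour is not None:
        try:
            stele_ecc = fit_ellipse(model.endodermis_contour).E
        except ValueError:
            stele_ecc = np.nan
    else:
        stele_ecc = np.nan
    model.root_area = root_area
    model.root_eccentricity = root_ecc
    return TissueStats(root_area=root_area, root_eccentricity=root_ecc,
                       stele_eccentricity=stele_ecc, regions=regions, scale=scale)


# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CheesewheelStats:
    """6 annuli x 6 wedges of per-region aggregates for one zone."""

    zone: str  # "stele-zone" | "cortex-zone"
    table: pd.DataFrame  # columns: annulus, wedge, cell_count, mean_area, mean_ecc


_STELE_ZONE_TISSUES = frozenset({"stele", "endodermis", "metaxylem", "protoxylem"})
_CORTEX_ZONE_TISSUES = frozenset({"cortex", "aerenchyma"})


def _radius_profile(contour: np.ndarray, centre: tuple[float, float]):
    """Periodic linear interpolant of contour radius as a function of angle."""
    dy = contour[:, 0] - centre[0]
    dx = contour[:, 1] - centre[1]
    th = np.mod(np.arctan2(-dy, dx), 2 * np.pi)  # east = 0, counter-clockwise
    rr = np.hypot(dy, dx)
    order = np.argsort(th)
    th, rr = th[order], rr[order]
    th = np.concatenate([[th[-1] - 2 * np.pi], th, [th[0] + 2 * np.pi]])
    rr = np.concatenate([[rr[-1]], rr, [rr[0]]])

    def profile(angles: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(angles, 2 * np.pi), th, rr)

    return profile


def cheesewheel(model: "RootModel", n_annuli: int = 6, n_wedges: int = 6
                ) -> list[CheesewheelStats]:
    """Radial/angular partition statistics for the stele and cortex zones.

    The stele zone spans from the stele centre to the endodermis outer
    contour; the cortex zone spans between the endodermis contour and the
    outer root boundary.  Annuli interpolate linearly between the two
    bounding contours along each ray, wedges are equal 60-degree sectors
    anchored at image-east and running counter-clockwise.  Cells are
    assigned by centroid; every zone cell lands in exactly one region.
    """
    if model.endodermis_contour is None or model.stele_centre is None:
        raise ValueError("cheesewheel requires a classified model with an endodermis contour")
    centre = model.stele_centre
    endo_r = _radius_profile(model.endodermis_contour, centre)
    outer_r = _radius_profile(model.gamma_final, centre)

    out: list[CheesewheelStats] = []
    for zone, tissues, r_in_of, r_out_of in (
        ("stele-zone", _STELE_ZONE_TISSUES, None, endo_r),
        ("cortex-zone", _CORTEX_ZONE_TISSUES, endo_r, outer_r),
    ):
        members = [c for c in model.cells if c.tissue in tissues]
        acc: dict[tuple[int, int], list] = {
            (i, j): [] for i in range(n_annuli) for j in range(n_wedges)
        }
        for cell in members:
            dy = cell.centroid[0] - centre[0]
            dx = cell.centroid[1] - centre[1]
            th = np.mod(np.arctan2(-dy, dx), 2 * np.pi)
            rad = np.hypot(dy, dx)
            r0 = 0.0 if r_in_of is None else float(r_in_of(np.array([th]))[0])
            r1 = float(r_out_of(np.array([th]))[0])
            span = max(r1 - r0, 1e-9)
            ann = int(np.clip(np.floor(n_annuli * (rad - r0) / span), 0, n_annuli - 1))
            wedge = int(np.clip(np.floor(n_wedges * th / (2 * np.pi)), 0, n_wedges - 1))
            acc[(ann, wedge)].append(cell)
        rows = []
        for (i, j), cells in sorted(acc.items()):
            rows.append({
                "annulus": i + 1,
                "wedge": j + 1,
                "cell_count": len(cells),
                "mean_area_px2": float(np.mean([c.area for c in cells])) if cells else np.nan,
                "mean_eccentricity": (float(np.mean([c.eccentricity for c in cells]))
                                      if cells else np.nan),
            })
        out.append(CheesewheelStats(zone=zone, table=pd.DataFrame(rows)))
    return out


# ---------------------------------------------------------------------------


def write_stats(stats: TissueStats, wheels: list[CheesewheelStats],
                model: "RootModel", outdir: str | Path, prefix: str = "root") -> dict[str, Path]:
    """Write summary, per-cell and cheesewheel CSV files.

    Returns the mapping of output kind to file path.  An empty model
    still produces headers-only files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": outdir / f"{prefix}_summary.csv",
        "cells": outdir / f"{prefix}_cells.csv",
        "cheesewheel": outdir / f"{prefix}_cheesewheel.csv",
    }
    stats.to_frame().to_csv(paths["summary"], index=False, float_format="%.6g")

    s2 = stats.scale * stats.scale
    cell_rows = [
        {
            "cell_id": c.id,
            "tissue": c.tissue,
            "area_um2": s2 * c.area,
            "eccentricity": c.eccentricity,
            "centroid_row": c.centroid[0],
            "centroid_col": c.centroid[1],
            "on_perimeter": c.on_perimeter,
        }
        for c in model.cells
    ]
    pd.DataFrame(
        cell_rows,
        columns=["cell_id", "tissue", "area_um2", "eccentricity",
                 "centroid_row", "centroid_col", "on_perimeter"],
    ).to_csv(paths["cells"], index=False, float_format="%.6g")

    if wheels:
        tables = []
        for wheel in wheels:
            t = wheel.table.copy()
            t.insert(0, "zone", wheel.zone)
            tables.append(t)
        wheel_frame = pd.concat(tables, ignore_index=True)
    else:
        wheel_frame = pd.DataFrame(
            columns=["zone", "annulus", "wedge", "cell_count",
                     "mean_area_px2", "mean_eccentricity"]
        )
    wheel_frame.to_csv(paths["cheesewheel"], index=False, float_format="%.6g")
    return paths
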