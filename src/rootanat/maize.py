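"""Maize-specific classification: protoxylem elements and aerenchyma.

Maize roots are polyarch: several metaxylem vessels sit symmetrically
around the stele centre, protoxylem elements lie near the stele
periphery, and the cortex develops large air spaces (aerenchyma).  In
wheat, protoxylem is usually indistinguishable from xylem parenchyma and
aerenchyma are absent, so both detectors are no-ops for wheat.
"""

from __future__ import annotations

import numpy as np
from sklearn.mixture import GaussianMixture

from .detection import RootModel
from .morphometrics import _radius_profile

__all__ = ["detect_protoxylem", "detect_aerenchyma", "aerenchyma_threshold", "radial_fraction"]


def radial_fraction(model: RootModel, centroid: tuple[float, float]) -> float:
    """Position of a point along its ray from the stele centre.

    The ray starts at the stele centre, passes through the point and
    ends on the stele outer boundary (the endodermis outer contour);
    the fraction is the ratio of the two collinear distances.
    """
    if model.stele_centre is None or model.endodermis_contour is None:
        raise ValueError("model must be classified before computing radial fractions")
    dy = centroid[0] - model.stele_centre[0]
    dx = centroid[1] - model.stele_centre[1]
    th = np.arctan2(-dy, dx)
    boundary_r = float(_radius_profile(model.endodermis_contour, model.stele_centre)(
        np.array([th]))[0])
    return float(np.hypot(dy, dx) / max(boundary_r, 1e-9))


def detect_protoxylem(model: RootModel, params) -> RootModel:
    """Relabel peripheral large stele cells as protoxylem (maize only).

    Candidates are the large, non-metaxylem cells labelled stele; a
    candidate whose centroid sits more than half way along its ray from
    the stele centre to the stele boundary becomes protoxylem.
    """
    if params.species != "maize":
        return model
    for cell in model.cells:
        if cell.tissue != "stele" or cell.size_class != "large":
            continue
        if radial_fraction(model, cell.centroid) > 0.5:
            cell.tissue = "protoxylem"
    return model


def aerenchyma_threshold(areas: np.ndarray, seed: int = 0) -> float | None:
    """Area threshold separating aerenchyma from regular large cortex cells.

    Fits a two-component Gaussian mixture to the areas (EM with k-means
    initialisation) and returns ``mu_larger - sigma_larger``.  Returns
    ``None`` when the fit is degenerate: fewer than two distinct values,
    or component means separated by less than one pooled standard
    deviation (effectively unimodal, hence no aerenchyma evidence).
    """
    areas = np.asarray(areas, dtype=float).reshape(-1, 1)
    if areas.shape[0] < 2 or np.unique(areas).size < 2:
        return None
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(areas)
    if areas.shape[0] >= 4:
        # one mode must not explain the data as well as two (BIC), else the
        # "two populations" premise does not hold for this root
        gm1 = GaussianMixture(n_components=1, random_state=seed).fit(areas)
        if gm1.bic(areas) <= gm.bic(areas):
            return None
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    hi = int(np.argmax(means))
    lo = 1 - hi
    pooled = float(np.sqrt(weights[lo] * sigmas[lo] ** 2 + weights[hi] * sigmas[hi] ** 2))
    if means[hi] - means[lo] < max(pooled, 1e-9):
        return None
    return float(means[hi] - sigmas[hi])


def detect_aerenchyma(model: RootModel, params, seed: int = 0) -> RootModel:
    """Relabel unusually large cortex cells as aerenchyma (maize only).

    The areas of large cortex cells are modelled as a two-Gaussian
    mixture (regular cortex vs air spaces); cells above
    ``mu_larger - sigma_larger`` become aerenchyma.  A degenerate or
    unimodal fit reports no aerenchyma.
    """
    if params.species != "maize":
        return model
    large_cortex = [
        c for c in model.cells if c.tissue == "cortex" and c.size_class == "large"
    ]
    if len(large_cortex) < 2:
        return model
    thr = aerenchyma_threshold(np.array([c.area for c in large_cortex]), seed=seed)
    if thr is None:
        return model
    for cell in large_cortex:
        if cell.area > thr:
            cell.tissue = "aerenchyma"
    return model
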