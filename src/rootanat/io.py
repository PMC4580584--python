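"""Image and parameter-file input.

Micrographs are loaded as single-channel rasters with intensities
min-max normalised to [0, 1]; every downstream stage works on that
representation ("the image ``I``").  Tunables live in :class:`Params`,
which mirrors a flat ``key = value`` text file so that a whole batch of
images can be processed with one parameter set.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["Params", "load_image", "normalize_image", "load_params", "suggest_A_l"]

#: ITU-R 601 luminance weights used to collapse RGB input to one channel.
_LUMA = np.array([0.299, 0.587, 0.114])

#: Ratio used to derive the large-cell gate from the small-cell gate when
#: only the latter is given (robust across image resolutions).
AREA_RATIO = 33.0


@dataclasses.dataclass
class Params:
    """Every tunable of the analysis pipeline.

    Attributes
    ----------
    T:
        Local-threshold intensity difference.  A pixel is wall/foreground
        when it deviates from the mean of its surrounding window by more
        than ``T``.
    w:
        Half-width of the square averaging window; the window is
        ``(2w+1) x (2w+1)`` pixels.
    A_s, A_l:
        Minimum areas (px^2) of "small" and "large" cells.  Regions below
        ``A_s`` are treated as segmentation noise.
    epidermis_fraction:
        Fraction of root-perimeter cells (sorted by increasing area)
        labelled epidermis; the remainder are taken to be cortex cells
        that reached the perimeter through damage.
    k_neighbors:
        Neighbour count used by the spatial classification rules.
    neighbor_dist_max:
        Maximum of the k nearest-neighbour distances (px) for a small
        cell to count as a stele/endodermis candidate.
    ecc_min:
        Eccentricity above which a cell near the endodermis boundary is
        pulled into the stele/endodermis set.
    boundary_margin:
        Distance (px) from the approximate endodermis boundary used by
        the same rule.
    cortex_vote_fraction:
        A candidate reverts to cortex when more than this fraction of its
        nearest neighbours are cortex cells.
    lateral_intensity_fraction:
        Detected regions darker than this fraction of the mean region
        intensity are discarded as lateral-root formations.
    cluster_sigma_mult:
        Width of the small-cell distance gate, in standard deviations.
    species:
        ``"wheat"`` or ``"maize"``; maize enables protoxylem and
        aerenchyma detection.
    scale:
        Microns per pixel; applied only when statistics are reported.
    polarity:
        ``"dark_walls"`` (stained walls darker than background, the
        usual case) or ``"bright_walls"``.
    """

    species: str = "wheat"
    T: float = 0.05
    w: int = 12
    A_s: float = 50.0
    A_l: float = 1000.0
    epidermis_fraction: float = 0.80
    k_neighbors: int = 5
    neighbor_dist_max: float = 50.0
    ecc_min: float = 0.9
    boundary_margin: float = 10.0
    cortex_vote_fraction: float = 0.5
    lateral_intensity_fraction: float = 1.0 / 3.0
    cluster_sigma_mult: float = 3.0
    scale: float = 1.0
    polarity: str = "dark_walls"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.species not in ("wheat", "maize"):
            raise ValueError(f"species must be 'wheat' or 'maize', got {self.species!r}")
        if not 0.0 < self.T < 1.0:
            raise ValueError(f"T must lie in (0, 1), got {self.T}")
        if self.w < 1:
            raise ValueError(f"w must be >= 1, got {self.w}")
        if not 0.0 < self.A_s < self.A_l:
            raise ValueError(f"need 0 < A_s < A_l, got A_s={self.A_s}, A_l={self.A_l}")
        for name in ("epidermis_fraction", "cortex_vote_fraction", "lateral_intensity_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.neighbor_dist_max <= 0:
            raise ValueError("neighbor_dist_max must be positive")
        if not 0.0 <= self.ecc_min < 1.0:
            raise ValueError("ecc_min must lie in [0, 1)")
        if self.boundary_margin < 0:
            raise ValueError("boundary_margin must be non-negative")
        if self.cluster_sigma_mult <= 0:
            raise ValueError("cluster_sigma_mult must be positive")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.polarity not in ("dark_walls", "bright_walls"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(Params)}
_INT_FIELDS = {"w", "k_neighbors"}
_STR_FIELDS = {"species", "polarity"}


def normalize_image(raw: np.ndarray) -> np.ndarray:
    """Min-max normalise a 2-D intensity raster to [0, 1].

    A constant image maps to all zeros so that a blank input yields an
    empty segmentation rather than an error.
    """
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D raster, got shape {arr.shape}")
    lo = arr.min()
    rng = arr.max() - lo
    if rng == 0:
        return np.zeros_like(arr)
    return (arr - lo) / rng


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG micrograph as a normalised grayscale array.

    RGB input is collapsed to luminance (ITU-R 601 weights); intensities
    are then min-max normalised to [0, 1].
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im, dtype=np.float64)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise IOError(f"image {path} is empty")
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    elif arr.ndim != 2:
        raise IOError(f"unsupported image layout with {arr.ndim} axes in {path}")
    return normalize_image(arr)


def load_params(path: str | Path) -> Params:
    """Parse a flat ``key = value`` parameter file.

    Lines starting with ``#`` (and inline ``#`` comments) are ignored.
    Unspecified keys take the documented defaults; ``species`` is
    required.  When ``A_s`` is given without ``A_l`` the large-cell gate
    defaults to ``33 * A_s``.
    """
    path = Path(path)
    values: dict[str, object] = {}
    for lineno, raw_line in enumerate(path.read_text().splitlines(), start=1):
        line = raw_line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw_line!r}")
        key, _, raw_value = line.partition("=")
        key, raw_value = key.strip(), raw_value.strip()
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        if not raw_value:
            raise ValueError(f"{path}:{lineno}: missing value for {key!r}")
        try:
            if key in _STR_FIELDS:
                values[key] = raw_value.lower()
            elif key in _INT_FIELDS:
                values[key] = int(raw_value)
            else:
                values[key] = float(raw_value)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad value for {key!r}: {raw_value!r}") from exc
    if "species" not in values:
        raise ValueError(f"{path}: required parameter 'species' is missing")
    if "A_s" in values and "A_l" not in values:
        values["A_l"] = AREA_RATIO * float(values["A_s"])  # resolution-robust ratio
    return Params(**values)


def suggest_A_l(d: float, a_s: float = 50.0) -> float:
    """Suggest the large-cell area gate from the root diameter ``d`` (px).

    Uses the empirical quadratic ``A_l = 0.0004 d^2 + 0.668 d - 112``,
    floored at ``a_s`` (the polynomial goes negative for very small
    roots, where no gate below the small-cell cut-off makes sense).
    """
    if d <= 0:
        raise ValueError(f"root diameter must be positive, got {d}")
    return max(0.0004 * d * d + 0.668 * d - 112.0, a_s)
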