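"""Batch driver: load -> segment -> detect -> classify -> measure -> write.

One image's failure never aborts a batch; each input ends up with an
``ok`` or ``failed`` status in the run manifest.  Given identical inputs,
parameters and mixture seed, two runs produce byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np

from . import maize
from .classify import classify_cells
from .detection import RootModel, build_root_model
from .io import Params, load_image
from .morphometrics import CheesewheelStats, TissueStats, cheesewheel, compute_tissue_stats, write_stats

__all__ = ["ImageResult", "RunManifest", "analyze_image", "run_pipeline"]

logger = logging.getLogger("rootanat")

#: default seed of the aerenchyma mixture fit, so batch runs reproduce exactly
DEFAULT_MIXTURE_SEED = 0


@dataclasses.dataclass
class ImageResult:
    path: str
    status: str  # "ok" | "failed"
    reason: str = ""
    n_cells: int = 0
    stage_seconds: dict[str, float] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class RunManifest:
    results: list[ImageResult]

    @property
    def n_ok(self) -> int:
        return sum(1 for r in self.results if r.status == "ok")

    @property
    def n_failed(self) -> int:
        return len(self.results) - self.n_ok


def analyze_image(
    image: np.ndarray,
    params: Params,
    mixture_seed: int = DEFAULT_MIXTURE_SEED,
    timings: dict[str, float] | None = None,
) -> tuple[RootModel, TissueStats, list[CheesewheelStats]]:
    """Run the full analysis on one normalised grayscale image."""

    def tick(stage: str, t0: float) -> float:
        t1 = time.perf_counter()
        if timings is not None:
            timings[stage] = t1 - t0
        return t1

    t = time.perf_counter()
    model = build_root_model(image, params)
    t = tick("detection", t)
    classify_cells(model, params)
    if params.species == "maize":
        maize.detect_protoxylem(model, params)
        maize.detect_aerenchyma(model, params, seed=mixture_seed)
    t = tick("classification", t)
    stats = compute_tissue_stats(model, scale=params.scale, species=params.species)
    wheels = cheesewheel(model)
    tick("statistics", t)
    return model, stats, wheels


def run_pipeline(
    images: list[str | Path],
    params: Params,
    outdir: str | Path,
    mixture_seed: int = DEFAULT_MIXTURE_SEED,
) -> RunManifest:
    """Analyse a batch of image files and write per-image CSV outputs."""
    if not images:
        raise ValueError("no input images given")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: list[ImageResult] = []
    for path in images:
        path = Path(path)
        timings: dict[str, float] = {}
        try:
            image = load_image(path)
            model, stats, wheels = analyze_image(
                image, params, mixture_seed=mixture_seed, timings=timings
            )
            write_stats(stats, wheels, model, outdir, prefix=path.stem)
            results.append(ImageResult(path=str(path), status="ok",
                                       n_cells=len(model.cells), stage_seconds=timings))
            logger.info("%s: ok, %d cells", path, len(model.cells))
        except Exception as exc:  # one bad image must not sink the batch
            results.append(ImageResult(path=str(path), status="failed",
                                       reason=str(exc), stage_seconds=timings))
            logger.warning("%s: failed (%s)", path, exc)
    return RunManifest(results=results)
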