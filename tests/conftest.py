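import numpy as np
import pytest

from rootanat import Params, SyntheticSpec, analyze_image, generate_root
from rootanat.detection import Cell


@pytest.fixture(scope="session")
def wheat_params():
    return Params(species="wheat")


@pytest.fixture(scope="session")
def maize_params():
    return Params(species="maize")


@pytest.fixture(scope="session")
def wheat_case(wheat_params):
    """One default synthetic wheat root, fully analysed."""
    image, truth = generate_root(SyntheticSpec.wheat(seed=1))
    model, stats, wheels = analyze_image(image, wheat_params)
    return {"image": image, "truth": truth, "model": model,
            "stats": stats, "wheels": wheels}


@pytest.fixture(scope="session")
def maize_case(maize_params):
    """One default synthetic maize root, fully analysed."""
    image, truth = generate_root(SyntheticSpec.maize(seed=0))
    model, stats, wheels = analyze_image(image, maize_params)
    return {"image": image, "truth": truth, "model": model,
            "stats": stats, "wheels": wheels}


def make_cell(cell_id, centroid, area=100, *, on_perimeter=False, size_class="small",
              tissue="unassigned", eccentricity=0.3):
    """Minimal stand-in cell for rule-level unit tests.

    Pixels are a small block near the centroid; geometry-heavy stages
    need real detected cells, but the sorting/threshold rules only read
    id, area, centroid and flags.
    """
    r, c = int(round(centroid[0])), int(round(centroid[1]))
    rows, cols = np.mgrid[r:r + 2, c:c + 2]
    rows, cols = rows.ravel(), cols.ravel()
    boundary = np.array([[r, c], [r, c + 1], [r + 1, c + 1], [r + 1, c], [r, c]], float)
    return Cell(id=cell_id, pixels=(rows, cols), boundary=boundary, area=area,
                centroid=(float(centroid[0]), float(centroid[1])),
                mean_intensity=0.5, eccentricity=eccentricity,
                size_class=size_class, tissue=tissue, on_perimeter=on_perimeter)
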