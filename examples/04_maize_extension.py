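"""Maize-only features: protoxylem elements and cortical aerenchyma.

Maize roots are polyarch (several metaxylem vessels around the stele
centre), carry protoxylem near the stele edge, and develop large air
spaces (aerenchyma) in the cortex.
"""
from collections import Counter

import numpy as np

from rootanat import Params, SyntheticSpec, build_root_model, classify_cells, generate_root
from rootanat.maize import aerenchyma_threshold, detect_aerenchyma, detect_protoxylem

params = Params(species="maize")
image, truth = generate_root(SyntheticSpec.maize(seed=0))
model = build_root_model(image, params)
classify_cells(model, params)
detect_protoxylem(model, params)
detect_aerenchyma(model, params, seed=0)

print("planted:  ", dict(Counter(truth.tissue_of.values())))
print("detected: ", dict(Counter(c.tissue for c in model.cells)))

rng = np.random.default_rng(11)
areas = np.concatenate([rng.normal(1200, 80, 60), rng.normal(4000, 300, 60)])
thr = aerenchyma_threshold(areas, seed=0)
print(f"\naerenchyma area threshold on a bimodal sample: {thr:.0f} px^2")
print("(the two-Gaussian rule puts the cut one sigma below the larger mode,")
print(" so air spaces are separated from ordinary large cortex cells)")
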