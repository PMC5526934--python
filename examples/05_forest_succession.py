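"""Stand development vs productivity from synthetic forest-inventory pixels.

Generates 2000 inventory pixels, applies the treed/vegetated cover
corrections, fits the height/cover least-squares models and the
penalized-spline deciduous model, and prints predicted stand structure at
40 years for a low- and a high-productivity landscape, plus the fitted age
of the deciduous peak (generated near 20 years — the window when moose and
bear forage, hence predation pressure on caribou, is at its worst).
"""

import numpy as np

from caribou_pva import GeneratorConfig, generate_stand_pixels
from caribou_pva.succession import (
    fit_deciduous_model,
    fit_structure_models,
    prepare_pixels,
)

cfg = GeneratorConfig(seed=7)
frame, removed = prepare_pixels(generate_stand_pixels(cfg))
print(f"{len(frame)} usable pixels ({len(removed)} removed by the cover filters)")

structure = fit_structure_models(frame)
deciduous = fit_deciduous_model(frame)

age = np.array([40.0])
for P in (0.15, 0.75):
    h = structure.predict_height(age, np.array([P]))[0]
    c = structure.predict_cover(age, np.array([P]))[0]
    d = deciduous.predict(age, np.array([P]))[0]
    print(f"P={P:.2f}: 40-yr stand height {h:5.1f} m, canopy cover {c:.2f}, "
          f"deciduous fraction {d:.2f}")
print(f"fitted deciduous peak age: {deciduous.peak_age(P=0.5):.0f} yr")
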