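"""Generate nodule phantoms and inspect their geometry.

Renders a smooth benign and a spiculated malignant phantom at the same
10 mm diameter and compares their boundary geometry: spiculation lengthens
the perimeter at equal area, which is the morphological cue the classifier
later exploits.
"""

import numpy as np

from lungcad import features, phantoms

for label, spic in (("benign", 0.0), ("malignant", 0.8)):
    spec = phantoms.PhantomSpec(nodule_diameter_mm=10, nodule_class=label,
                                spiculation_level=spic, seed=4)
    sample = phantoms.make_phantom(spec)
    shp = features.shape_features(sample.mask, sample.spacing_mm)
    d_eq = 2 * np.sqrt(sample.mask.sum() / np.pi)
    print(f"{label:9s} spiculation={spic:.1f}  "
          f"equivalent diameter {d_eq:5.2f} px  "
          f"perimeter {shp['perimeter']:6.2f} mm  "
          f"circularity {shp['circularity']:.3f}")

print("\nSame nodule area, but the spiculated boundary is much longer and "
      "its circularity drops well below the smooth nodule's.")
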