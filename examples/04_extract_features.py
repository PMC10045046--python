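"""Extract the full descriptor block for one phantom.

Shows the GLCM texture statistics, mask shape descriptors, first-order
intensity statistics and the radiologist-style semantic attributes.
"""

from lungcad import features, phantoms

sample = phantoms.make_phantom(phantoms.PhantomSpec(
    nodule_diameter_mm=12, nodule_class="malignant", spiculation_level=0.7,
    noise_sigma=10.0, seed=3))
fv = features.extract_feature_vector(sample)

print("texture  :", {k: round(v, 4) for k, v in fv.texture.items()})
print("shape    :", {k: round(v, 3) for k, v in fv.shape.items()})
print("intensity:", {k: round(v, 4) for k, v in fv.intensity.items()})
print("semantic :", fv.semantic)
print(f"\nvector length {len(fv.to_array())} "
      f"({', '.join(fv.names()[:4])}, ...)")
print("\nThe spiculated mask shows low circularity, a high spiculation "
      "score and the 'Spiculated' morphology label.")
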