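"""Perceptual colorimetry: appearance correlates and color differences.

Takes two lesion-like sRGB colors (a skin pink and a blue-gray nest
color), maps them through CIELAB and CAM16-UCS, and prints the CIECAM16
appearance correlates and the two Delta-E distances.
"""

import numpy as np

from dermccm import colorspace as cs

skin = np.array([0.87, 0.71, 0.64])
nest = np.array([0.32, 0.38, 0.52])
vc = cs.ViewingConditions()  # D65, L_A=64, Y_b=20, average surround

for name, rgb in (("skin pink", skin), ("blue-gray nest", nest)):
    app = cs.cam16_forward(cs.srgb_to_xyz(rgb), vc)
    print(f"{name:15s} J={float(app.J):6.2f}  C={float(app.C):6.2f}  "
          f"h={float(app.h):6.1f} deg  M={float(app.M):6.2f}")

lab = cs.srgb_to_working(np.stack([skin, nest]), "lab")
ucs = cs.srgb_to_working(np.stack([skin, nest]), "cam16ucs", vc)
print(f"\nDelta-E*ab (CIELAB)    = {float(cs.delta_e_lab(lab[0], lab[1])):.2f}")
print(f"Delta-E'   (CAM16-UCS) = {float(cs.delta_e_ucs(ucs[0], ucs[1])):.2f}")
print("\nBoth distances are Euclidean in their uniform space; the UCS value")
print("is on a compressed scale where ~1 unit is a just-noticeable difference.")
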