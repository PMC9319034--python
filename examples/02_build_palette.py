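"""Two-stage palette learning on synthetic pattern tiles.

Generates a few labeled tiles per dermoscopic pattern, clusters each
pattern's pixels into 18 centroids in CAM16-UCS (126 in total), merges
them down to a 20-color master palette, and prints the palette with the
patterns each color came from.
"""

from dermccm import synthdata, workflow
from dermccm.palette import write_palette

ds = synthdata.make_dataset(3, (64, 64), seed=0, include_nonbcc=False,
                            composite_fraction=0.0)
print(f"training tiles: {len(ds)} (3 per pattern)")

palette = workflow.build_palette_from_dataset(ds, k_per_pattern=18, target_n=20,
                                              space="cam16ucs", seed=0,
                                              max_pixels_per_image=2000)
print(f"master palette: {len(palette)} colors in {palette.space}\n")
for i, c in enumerate(palette.centroids):
    r, g, b = (int(round(255 * v)) for v in c.srgb)
    srcs = ",".join(sorted(c.sources)) or "-"
    print(f"  {i:2d}  sRGB #{r:02x}{g:02x}{b:02x}  weight {c.weight:8.0f}  from {srcs}")

write_palette(palette, "palette_demo.json")
print("\nwrote palette_demo.json; weights are pixel masses, and 'from' lists")
print("the patterns whose stage-1 centroids merged into each master color.")
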