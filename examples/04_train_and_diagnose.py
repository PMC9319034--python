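"""End-to-end explainable diagnosis.

Trains the pattern detector on a small synthetic collection, then
diagnoses two fresh tiles — an ovoid-nest tile (a positive BCC criterion)
and a pigment-network tile (the negative criterion) — printing the
per-pattern evidence behind each call.
"""

from dermccm import classify, synthdata, workflow

train = synthdata.make_dataset(20, (64, 64), seed=0)
palette = workflow.build_palette_from_dataset(train, seed=0,
                                              max_pixels_per_image=1500)
X = workflow.extract_features(train.images, palette)
model = classify.train_feature_classifier(X, train.labels, seed=0)
thresholds = classify.select_thresholds(model.forward(X), train.labels)

for pattern in ("ovoid_nest", "pigment_network"):
    img, _ = synthdata.make_pattern_image(
        synthdata.DEFAULT_RECIPES[pattern], (64, 64), seed=999)
    res = classify.diagnose(img, palette, model, thresholds, mode="strict")
    detected = [k for k, v in res["detections"].items() if v] or ["none"]
    print(f"{pattern} tile -> {res['diagnosis']}")
    print(f"  detected patterns: {', '.join(detected)}")
    top = sorted(res["probabilities"].items(), key=lambda kv: -kv[1])[:3]
    print("  top probabilities:", ", ".join(f"{k}={v:.2f}" for k, v in top))

print("\nThe strict clinical rule calls BCC when a positive criterion is")
print("present and the pigment network (the negative criterion) is absent.")
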