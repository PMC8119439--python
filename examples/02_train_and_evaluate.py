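"""Train the row-scoring U-Net on a small phantom cohort and evaluate it.

A scaled-down run (80 training cases, 20 epochs) of the full protocol:
fit on per-row binary cross-entropy with shift augmentation, then score
held-out cases with the four cohort metrics — slice-hit accuracy, error
distance on misses, distance to the reference-standard slice, and 1D
IoU between predicted and true bands.
"""

from pulmotrunk import PhantomParams, generate_cohort
from pulmotrunk.evaluation import evaluate_predictions
from pulmotrunk.localizer import NetConfig, build_network, predict, train

params = PhantomParams()
train_cohort = generate_cohort(params, n=80, seed=1)
heldout = generate_cohort(params, n=30, seed=2)

config = NetConfig(epochs=20, learning_rate=1e-3, seed=0)
model = train(build_network(config, params.image_rows, params.image_cols), train_cohort, config)
print(f"training loss        : {model.history[0]:.4f} (epoch 1) -> {model.history[-1]:.4f} (epoch {config.epochs})")

cases = []
for case in heldout:
    pred = predict(model, case.image)
    cases.append((pred.center_row, case.annotation, pred.region))
ev = evaluate_predictions(cases, row_spacing_mm=params.row_spacing_mm)

print(f"slice-hit accuracy   : {ev.accuracy_pct}% ({ev.n_errors}/{ev.n} errors)")
if ev.error_distance_mm is not None:
    print(f"error distance       : {ev.error_distance_mm[0]:.1f} +/- {ev.error_distance_mm[1]:.1f} mm (misses only)")
else:
    print("error distance       : - (no misses)")
print(f"reference distance   : {ev.reference_distance_mm[0]:.1f} +/- {ev.reference_distance_mm[1]:.1f} mm")
print(f"mean 1D IoU          : {ev.iou[0]:.2f} +/- {ev.iou[1]:.2f}")
print("Accuracy counts held-out cases whose selected centre row falls inside")
print("the true band; the reference distance is to the ideal tracking slice.")
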