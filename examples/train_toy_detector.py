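"""Train a toy nodule detector on synthetic scans and measure recall.

A 2-stage V-Net-style network (32^3 patches, Dice loss, Adam) trains on
five simulated tumor-bearing phantoms and is evaluated on two held-out
scans with stitched sliding-window inference and direct/near-hit matching.
Takes a few minutes on a desktop CPU.
"""

import numpy as np

from murilung.detector import NetworkSpec, TrainConfig, sliding_window_predict, train_single
from murilung.evaluate import match_detections, postprocess
from murilung.phantom import generate_thorax, generate_tumor_bank
from murilung.tumorsim import simulate_tumor_scan
from murilung.tumorsim.dataset import SimulatedSet

rng = np.random.default_rng(0)
bank = generate_tumor_bank(rng, n_templates=4, size_range_mm3=(4.0, 25.0),
                           spacing_um=300.0, mean_hu=200.0, std_hu=30.0)
sets = []
for i in range(7):
    ph = generate_thorax(rng, spacing_um=300.0, shape=(100, 80, 80), noise_hu=15.0)
    img, labels, _ = simulate_tumor_scan(
        ph.image, ph.lung_mask_truth, bank, rng, n_tumors=2, method="voxel",
        size_range_mm3=(4.0, 25.0), min_tumor_mm3=4.0)
    sets.append((SimulatedSet(img, labels, i, False), ph.lung_mask_truth))

spec = NetworkSpec(n_stages=2, channels=(4, 8), convs_per_stage=(1, 1),
                   conv_kernel=5, dropout_rate=0.01, seed=0)
cfg = TrainConfig(strategy="sim_only", epochs=150, batch_size=2, patch_size=32,
                  k_folds=2)
model, history = train_single(spec, [s for s, _ in sets[:5]], cfg,
                              np.random.default_rng(100), epochs=150)
print(f"soft-Dice loss: {history['loss'][0]:.3f} (start) -> {history['loss'][-1]:.3f} (end)")

tp = fn = fp = 0
for s, lung in sets[5:]:
    prob = sliding_window_predict(model, s.image, patch_size=32, stride=16)
    c = match_detections(postprocess(prob, lung, 0.5), s.labels)
    tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
print(f"held-out detections: TP={tp} FP={fp} FN={fn}  recall={tp / (tp + fn):.2f}")
print("Recall counts each labeled tumor hit directly (overlap) or nearly")
print("(centroid within 1.5 equivalent radii); large high-contrast tumors")
print("should be found reliably even by this toy configuration.")
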