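"""Calibrate gradient thresholds on one phantom set and classify another.

Mean boundary gradients are averaged along each estimated boundary; a
defect stripe produces a strongly positive up-boundary mean and a
strongly negative down-boundary mean, while a defect-free pearl's
boundaries fall on dim ring junctions. Thresholds are placed midway
between the two classes on a 12-phantom calibration set, then applied
unchanged to a disjoint 30-phantom test set. The printed accuracy is
the fraction of test phantoms whose label matches ground truth.
"""

from pearloct import calibrate_thresholds, classify, generate_dataset, run_pipeline


def boundary_means(items):
    out = []
    for img, truth in items:
        res = run_pipeline(img)
        out.append((truth.label, res.grade.up_mean, res.grade.down_mean))
    return out


calib = boundary_means(generate_dataset(12, 0.5, seed=1001))
normal = [(u, d) for lbl, u, d in calib if lbl == "normal"]
defect = [(u, d) for lbl, u, d in calib if lbl == "defect"]
up_thr, down_thr = calibrate_thresholds(normal, defect)
print(f"calibrated thresholds: up {up_thr:.2f}, down {down_thr:.2f}")

test = boundary_means(generate_dataset(30, 0.5, seed=1))
correct = sum(
    classify(u, d, up_threshold=up_thr, down_threshold=down_thr).label == lbl
    for lbl, u, d in test
)
print(f"accuracy on disjoint test set: {correct}/{len(test)} = {correct / len(test):.0%}")
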