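"""Apply the reference gradient thresholds to the reference boundary means.

The grading rule compares each boundary's mean vertical gradient with a
threshold: up-boundary mean above 180, or down-boundary mean below
-240, flags a defect. Applied to the reference mean pairs — a defective
sub-layer at (292.3, -343.6) and a normal ring structure at
(104.8, -169.0) — both cases classify correctly under either way of
combining the two tests.
"""

from pearloct import classify

cases = [(292.3, -343.6, "defect"), (104.8, -169.0, "normal")]
for rule in ("either", "both"):
    print(f"combine rule = {rule!r}:")
    for up_mean, down_mean, expected in cases:
        res = classify(up_mean, down_mean, up_threshold=180.0, down_threshold=-240.0,
                       combine_rule=rule)
        ok = "correct" if res.label == expected else "WRONG"
        print(f"  means ({up_mean:+.1f}, {down_mean:+.1f}) -> {res.label:7s} [{ok}]")
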