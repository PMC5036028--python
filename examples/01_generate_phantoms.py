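"""Generate a small synthetic pearl B-scan dataset with ground truth.

Builds six phantoms (three with a bright calcite defect stripe, three
defect-free), writes them as 8-bit PNGs with JSON ground-truth sidecars
and a CSV manifest, and prints the per-item labels. The printed surface
row is the parabola apex of each pearl's top edge; defect rows are the
stripe's top-edge depth range below the surface.
"""

from pathlib import Path

from pearloct import generate_dataset, write_dataset

out = Path("scratch/example_phantoms")
manifest = write_dataset(out, n=6, defect_fraction=0.5, seed=42)
print(f"manifest written to {manifest}")

for i, (img, truth) in enumerate(generate_dataset(6, 0.5, seed=42)):
    line = f"phantom_{i:03d}: {truth.label:7s} surface apex row {truth.surface.min():.1f}"
    if truth.defect_up is not None:
        top = truth.defect_up - truth.surface
        line += f", defect top {top.min():.0f}-{top.max():.0f} px below surface"
    print(line)
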