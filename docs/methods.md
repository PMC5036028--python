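# Methods

## Problem and pipeline model

A pearl B-scan is a 2-D grid of backscatter intensities, depth (rows)
by lateral position (columns). The quantity of interest is whether the
nacre contains a calcite-filled crack: a sub-layer that backscatters
much more strongly than the surrounding aragonite rings. The pipeline
reduces grading to (a) finding the two edges of the brightest internal
sub-layer and (b) thresholding the mean vertical gradient along each
edge.

The boundary search is a minimum-weight-path problem. After polarity
selection and per-image min-max normalisation of the vertical gradient
(g ∈ [0, 1]), every 8-neighbour edge between pixels *a* and *b* weighs
`w_ab = 2 − (g_a + g_b) + w_min` with `w_min = 0.01`: weights fall
toward 0.01 where both pixels sit on a strong transition and rise to
2.01 on flat regions. Two appended node columns with all incident edge
weights 10⁻⁵ free the path from any fixed start/end row: since every
interior weight is ≥ 0.01 ≫ 10⁻⁵, the optimal path uses the appended
columns as zero-cost rails and crosses the interior wherever the
gradient corridor is cheapest. Dijkstra's algorithm (on a sparse
adjacency matrix, deterministic for fixed input) returns the exact
optimum; positive weights guarantee the optimum is a simple path, which
is what the brute-force test oracle enumerates.

Assumptions inherited by this formulation: the defect presents as a
roughly lateral stripe after flattening (the graph search tolerates
bends, tilt and jumps, but not vertical walls spanning many rows); one
stripe dominates — with several candidates the path follows the
strongest-gradient corridor; and the two polarities are independent, so
the "down" boundary may legitimately sit above the "up" boundary on
defect-free pearls whose boundaries fall on different ring junctions.

## Stage parameters

| parameter | default | units | rationale |
|---|---|---|---|
| background rows / k | 10 / 7 | rows, – | noise floor μ + 7σ of the top background band |
| Canny σ, hysteresis | 2.0, 70th/90th pct of nonzero intensities | px, – | surface step dominates the edge map; percentile thresholds adapt to exposure |
| polynomial degree | 2 | – | a pearl cap is locally parabolic |
| median window | 10 × 40 | rows × cols | wide laterally to keep near-horizontal layer edges while suppressing speckle |
| crop | 600 × 300 | rows × cols | from the flattened surface downward, centred laterally |
| downscale steps | 1 (half size) | – | nearest-neighbour; 2 gives the quarter-size fast mode |
| power law C, γ | 1.2, 1.5 | – | expands bright-end contrast before gradient computation |
| w_min / endpoint weight | 0.01 / 10⁻⁵ | – | interior weight floor; appended-column rail weight |
| thresholds | 180 / −240 | gray level · px⁻¹ | reference operating point; gradient scale is acquisition-dependent, so both are exposed in config |

σ is the standard deviation (the μ + kσ form); "600 rows" run down the
depth axis and "300 columns" across the lateral axis, 0-based with
half-open ranges. Flattening shifts are integer per column with zero
fill. The power law is applied after downscaling and before gradients,
where its purpose (boundary-gradient enlargement) takes effect.
Normalisation of g is per-image; a constant rectified field maps to
all-zero g (uniform maximal weights) rather than dividing by zero. When
a path visits a column more than once, the row with maximum g is kept —
the strongest transition is the boundary. Border rows of the gradient
use one-sided differences over the interior's 2-pixel denominator so
the crop's top junction is not double-weighted. The 10×40 median runs
on a histogram rank filter over an edge-replicated padding for integer
8-bit images (bit-identical to the direct sliding-window median, which
remains the fallback path and the test oracle).

## Phantom generator

Real pearl scans are not publicly available, so the study conditions
are defined by a synthetic phantom: a downward-opening parabolic
surface (apex ≈ 200 rows, curvature 2×10⁻⁴ rows/col², ≈ 50 px sag at
the edges of a 1024×1024 frame — the acquisition size, with 3.48/6.73
μm axial/lateral pitch metadata); nacre backscatter 0.30 of full scale
decaying as exp(−depth/600 px); a thin tapered entrance-reflection band
(12 px, +0.05) at the surface; dim ring lines (8 px wide, −0.12) every
80 px of depth; optionally a defect stripe of +0.35…0.45 excess whose
top edge is a sinusoid plus linear tilt and whose thickness is 4–8 % of
the nacre depth; unit-mean gamma multiplicative speckle (coefficient of
variation 0.30) and additive Gaussian background noise (σ 0.02).
Intensities are synthesised in [0, 1] and exported as 8-bit.

The dim-nacre / bright-defect photometry mirrors the physical contrast
ordering the method relies on: the calcite stripe's boundary gradients
dominate every normal structure (air–surface junction, entrance band,
ring lines) after the power law, by roughly the factor separating the
reference defect and normal boundary-gradient means. Parameters were
fixed once at these values; the noiseless and moderate-speckle variants
used in tests override only the two noise levels.

What the phantom does **not** emulate: coherence-gated axial point
spread (edges are hard steps), depth-dependent speckle statistics,
refraction at the pearl surface, multiple scattering tails below the
defect, vendor speckle averaging, and full-round multi-angle scans.
Passing tests therefore demonstrate the pipeline's geometric and
algorithmic correctness and its separability logic — not calibrated
performance on real scanner output, whose gradient scale must be
re-thresholded (see below).

## Threshold calibration

The reference thresholds 180/−240 live on the original acquisition's
intensity scale; phantom gradients live on an 8-bit scale, so the
phantom-scale classification study calibrates thresholds once on a
disjoint 12-phantom calibration set and then freezes them. Calibration
places each boundary's threshold midway between the largest normal and
smallest defect mean. If the two classes overlap on one boundary
(typical for the up boundary when a weak, deep defect's up path falls
on the surface junction), that boundary cannot discriminate alone;
because the default combine rule is OR, its threshold is pushed one
full observed range beyond all calibration values so it never fires by
itself, leaving the decision to the separating boundary. Calibration
fails loudly if the classes overlap on both boundaries.

## Problem sizes

The test suite and examples run phantoms at the native 1024×1024
acquisition size (one full pipeline pass ≈ 1 s): 50 noiseless defect
phantoms for boundary-recovery error, 12 + 30 moderate-speckle phantoms
for the calibrate-then-classify study, 100 random ≤ 5×5 grids for the
exhaustive-search oracle, and ≤ 40×80 images for the sliding-window
median oracle. These sizes were chosen as the smallest that exercise
every contract at full acquisition resolution.

## Known limitations

- Only the single brightest sub-layer is segmented; stacked defects
  would need iterative band restriction.
- The 10×40 median orientation (rows × cols) is a fixed convention;
  the transposed reading would over-smooth the depth axis.
- Mean-gradient thresholds are scale-dependent: porting to a different
  scanner or bit depth requires recalibration on labelled examples.
- Flattening is integer-shift only; sub-pixel resampling would slightly
  sharpen boundaries at the cost of interpolating speckle.
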