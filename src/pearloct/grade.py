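"""Normal/defect classification from mean boundary gradients.

A calcite defect stripe is much brighter than the nacre around it, so
the signed vertical gradient along its boundaries is large: strongly
positive on the up (dark-to-light) boundary, strongly negative on the
down (light-to-dark) boundary. A defect-free pearl's boundaries fall on
dim ring lines with small gradients. Averaging the raw gradient along
each estimated boundary and thresholding the two means separates the
two populations; the documented default thresholds are 180 for the up
boundary and -240 for the down boundary, and both are configurable
because the absolute gradient scale depends on acquisition settings.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable

import numpy as np

from .graphseg import Boundary

DEFAULT_UP_THRESHOLD = 180.0
DEFAULT_DOWN_THRESHOLD = -240.0


@dataclass
class GradeResult:
    up_mean: float
    down_mean: float
    up_threshold: float
    down_threshold: float
    combine_rule: str  # "either" | "both"
    label: str  # "normal" | "defect"

    def to_dict(self) -> dict:
        return asdict(self)


def boundary_mean_gradient(raw: np.ndarray, boundary: Boundary) -> float:
    """Arithmetic mean of the signed raw gradient along the boundary.

    Sign is preserved: down boundaries on genuine light-to-dark edges
    yield negative means.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if boundary.rows.size != raw.shape[1]:
        raise ValueError(
            f"boundary covers {boundary.rows.size} columns but the gradient "
            f"field has {raw.shape[1]}"
        )
    return float(raw[boundary.rows, np.arange(raw.shape[1])].mean())


def classify(
    up_mean: float,
    down_mean: float,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
    combine_rule: str = "either",
) -> GradeResult:
    """Threshold the two boundary means into a normal/defect label.

    "either" (default) flags a defect when up_mean > up_threshold OR
    down_mean < down_threshold; "both" requires both exceedances.
    """
    if combine_rule not in ("either", "both"):
        raise ValueError(f"combine_rule must be 'either' or 'both', got {combine_rule!r}")
    if not (np.isfinite(up_threshold) and np.isfinite(down_threshold)):
        raise ValueError("thresholds must be finite")
    if not down_threshold < 0 < up_threshold:
        raise ValueError("expected down_threshold < 0 < up_threshold")
    up_hit = up_mean > up_threshold
    down_hit = down_mean < down_threshold
    defect = (up_hit or down_hit) if combine_rule == "either" else (up_hit and down_hit)
    return GradeResult(
        up_mean=float(up_mean),
        down_mean=float(down_mean),
        up_threshold=float(up_threshold),
        down_threshold=float(down_threshold),
        combine_rule=combine_rule,
        label="defect" if defect else "normal",
    )


def calibrate_thresholds(
    normal_means: Iterable[tuple[float, float]],
    defect_means: Iterable[tuple[float, float]],
) -> tuple[float, float]:
    """Midpoint thresholds from labelled (up_mean, down_mean) pairs.

    Each boundary's threshold is placed halfway between the two classes
    when they separate on that boundary. A boundary whose populations
    overlap cannot discriminate alone, and under the "either" combine
    rule a mid-overlap threshold would raise false alarms — so its
    threshold is instead pushed one full observed range beyond every
    calibration value, leaving the decision to the separating boundary.
    Raises if the classes overlap on both boundaries.
    """
    normal = np.asarray(list(normal_means), dtype=np.float64)
    defect = np.asarray(list(defect_means), dtype=np.float64)
    if normal.size == 0 or defect.size == 0:
        raise ValueError("calibration needs at least one example of each class")
    up_separates = normal[:, 0].max() < defect[:, 0].min()
    down_separates = normal[:, 1].min() > defect[:, 1].max()
    if not (up_separates or down_separates):
        raise ValueError("normal and defect gradient means overlap on both boundaries")
    all_up = np.concatenate([normal[:, 0], defect[:, 0]])
    all_down = np.concatenate([normal[:, 1], defect[:, 1]])
    if up_separates:
        up_thr = (normal[:, 0].max() + defect[:, 0].min()) / 2.0
    else:
        up_thr = all_up.max() + max(np.ptp(all_up), 1.0)
    if down_separates:
        down_thr = (normal[:, 1].min() + defect[:, 1].max()) / 2.0
    else:
        down_thr = all_down.min() - max(np.ptp(all_down), 1.0)
    return float(up_thr), float(down_thr)
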