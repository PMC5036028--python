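"""Pipeline configuration with YAML round-tripping.

Every stage parameter lives here with its documented default, so a
single file pins a reproducible run.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from . import grade, graphseg, preprocess


@dataclass
class PipelineConfig:
    # background denoising
    n_background_rows: int = preprocess.DEFAULT_BACKGROUND_ROWS
    k_sigma: float = preprocess.DEFAULT_K_SIGMA
    # surface detection
    canny_sigma: float = preprocess.DEFAULT_CANNY_SIGMA
    canny_low_pct: float = preprocess.DEFAULT_CANNY_LOW_PCT
    canny_high_pct: float = preprocess.DEFAULT_CANNY_HIGH_PCT
    poly_degree: int = preprocess.DEFAULT_POLY_DEGREE
    # smoothing / crop / resize
    median_window: tuple[int, int] = preprocess.DEFAULT_MEDIAN_WINDOW
    crop_size: tuple[int, int] = preprocess.DEFAULT_CROP_SIZE
    downscale_steps: int = 1  # 1 = half size, 2 = quarter size
    # contrast expansion
    power_C: float = preprocess.DEFAULT_POWER_C
    power_gamma: float = preprocess.DEFAULT_POWER_GAMMA
    # graph segmentation
    w_min: float = graphseg.W_MIN
    endpoint_weight: float = graphseg.ENDPOINT_WEIGHT
    # grading
    up_threshold: float = grade.DEFAULT_UP_THRESHOLD
    down_threshold: float = grade.DEFAULT_DOWN_THRESHOLD
    combine_rule: str = "either"
    seed: int = 0

    def __post_init__(self) -> None:
        self.median_window = tuple(self.median_window)  # type: ignore[assignment]
        self.crop_size = tuple(self.crop_size)  # type: ignore[assignment]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["median_window"] = list(data["median_window"])
        data["crop_size"] = list(data["crop_size"])
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
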