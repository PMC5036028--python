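"""Synthetic pearl B-scan phantoms with known ground truth.

Real pearl OCT images are not publicly deposited, so every downstream
stage is exercised on phantoms that emulate the salient structure of a
beadless-pearl B-scan:

* a bright, gently curved pearl surface (parabolic cap) over a dark
  speckled background, with a thin bright entrance band at the surface;
* nacre whose backscatter decays exponentially with depth;
* thin dim concentric ring sub-layers (the "annual ring" structure);
* optionally a bright irregular calcite defect stripe — a band of excess
  intensity whose top edge follows a low-order sinusoid plus linear tilt
  so shape, tilt and depth can be swept;
* unit-mean multiplicative gamma speckle and additive Gaussian
  background noise.

Intensities are synthesised in [0, 1] and exported on an 8-bit scale.
Every phantom carries a :class:`GroundTruth` with the exact surface and
defect boundary rows, so segmentation error is measurable in pixels.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image import BScanImage, save_image

#: rows of extra-bright entrance reflection just below the surface; the
#: excess tapers linearly to zero so the band's lower edge adds no sharp
#: gradient of its own
SURFACE_BAND_PX = 12
SURFACE_BAND_GAIN = 0.05
RING_LINE_PX = 8


@dataclass
class PhantomSpec:
    """Geometric and photometric parameters of one synthetic B-scan.

    The surface is the downward-opening parabola
    ``row(c) = surface_apex_row + surface_curvature * (c - width/2)**2``;
    nacre intensity below it is ``nacre_base_intensity *
    exp(-depth_decay * depth)``. Defect profiles are per-column arrays of
    offsets (pixels) measured down from the surface.
    """

    height: int = 1024
    width: int = 1024
    surface_curvature: float = 2.0e-4  # rows per column^2
    surface_apex_row: float = 200.0
    nacre_base_intensity: float = 0.30
    depth_decay: float = 1.0 / 600.0  # 1/pixels
    ring_period: float = 80.0
    ring_contrast: float = 0.12
    has_defect: bool = False
    defect_top_profile: np.ndarray | None = None  # pixels below surface
    defect_thickness_profile: np.ndarray | None = None  # pixels
    defect_contrast: float = 0.40
    speckle_level: float = 0.30
    background_noise_sigma: float = 0.02
    seed: int = 0

    def surface_rows(self) -> np.ndarray:
        c = np.arange(self.width, dtype=np.float64)
        return self.surface_apex_row + self.surface_curvature * (c - self.width / 2.0) ** 2

    def validate(self) -> None:
        if self.height < 64 or self.width < 64:
            raise ValueError("phantom must be at least 64x64 pixels")
        if not self.has_defect:
            return
        if self.defect_top_profile is None or self.defect_thickness_profile is None:
            raise ValueError("has_defect requires defect top and thickness profiles")
        top = np.asarray(self.defect_top_profile, dtype=np.float64)
        thick = np.asarray(self.defect_thickness_profile, dtype=np.float64)
        if top.shape != (self.width,) or thick.shape != (self.width,):
            raise ValueError("defect profiles must have one entry per column")
        surface = self.surface_rows()
        if np.any(top <= SURFACE_BAND_PX):
            raise ValueError("defect stripe must lie strictly below the surface band")
        if np.any(thick < 1):
            raise ValueError("defect thickness must be at least 1 pixel")
        if np.any(surface + top + thick >= self.height):
            raise ValueError("defect stripe extends below the image bottom")
        if self.defect_contrast <= self.ring_contrast:
            raise ValueError("defect_contrast must exceed ring_contrast")


@dataclass
class GroundTruth:
    """Exact per-column boundary rows for one phantom."""

    surface: np.ndarray
    defect_up: np.ndarray | None
    defect_down: np.ndarray | None
    label: str  # "normal" | "defect"

    def to_json(self) -> str:
        payload = {
            "surface": self.surface.tolist(),
            "defect_up": None if self.defect_up is None else self.defect_up.tolist(),
            "defect_down": None if self.defect_down is None else self.defect_down.tolist(),
            "label": self.label,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        up = None if d["defect_up"] is None else np.asarray(d["defect_up"], dtype=np.float64)
        dn = None if d["defect_down"] is None else np.asarray(d["defect_down"], dtype=np.float64)
        return cls(
            surface=np.asarray(d["surface"], dtype=np.float64),
            defect_up=up,
            defect_down=dn,
            label=d["label"],
        )


def sinusoid_profile(
    width: int,
    depth: float,
    amplitude: float = 0.0,
    wavelength: float | None = None,
    phase: float = 0.0,
    tilt: float = 0.0,
) -> np.ndarray:
    """Low-order sinusoid plus linear tilt: the defect top-edge family."""
    c = np.arange(width, dtype=np.float64)
    wavelength = wavelength or 2.0 * width
    return (
        depth
        + amplitude * np.sin(2.0 * np.pi * c / wavelength + phase)
        + tilt * (c - width / 2.0)
    )


def generate_phantom(spec: PhantomSpec) -> tuple[BScanImage, GroundTruth]:
    """Render one phantom B-scan and its ground truth.

    Deterministic for a fixed ``spec.seed``: with ``speckle_level`` and
    ``background_noise_sigma`` both zero the image is an exact function
    of the geometric parameters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    surface = spec.surface_rows()

    rows = np.arange(spec.height, dtype=np.float64)[:, None]
    depth = rows - surface[None, :]  # >=0 inside the pearl
    nacre = depth >= 0.0

    img = np.zeros((spec.height, spec.width), dtype=np.float64)
    img[nacre] = spec.nacre_base_intensity * np.exp(-spec.depth_decay * depth[nacre])

    band = nacre & (depth < SURFACE_BAND_PX)
    img[band] += SURFACE_BAND_GAIN * (1.0 - depth[band] / SURFACE_BAND_PX)

    ring = nacre & (depth >= spec.ring_period / 2.0) & (depth % spec.ring_period < RING_LINE_PX)
    img[ring] -= spec.ring_contrast

    if spec.has_defect:
        top = np.asarray(spec.defect_top_profile, dtype=np.float64)
        thick = np.asarray(spec.defect_thickness_profile, dtype=np.float64)
        up_rows = surface + top
        down_rows = up_rows + thick
        stripe = (depth >= top[None, :]) & (depth < (top + thick)[None, :])
        img[stripe] += spec.defect_contrast
        truth = GroundTruth(surface=surface, defect_up=up_rows, defect_down=down_rows, label="defect")
    else:
        truth = GroundTruth(surface=surface, defect_up=None, defect_down=None, label="normal")

    if spec.speckle_level > 0.0:
        # unit-mean gamma multiplicative speckle; speckle_level is its
        # coefficient of variation
        shape = 1.0 / spec.speckle_level**2
        img *= rng.gamma(shape, 1.0 / shape, size=img.shape)
    if spec.background_noise_sigma > 0.0:
        img += rng.normal(0.0, spec.background_noise_sigma, size=img.shape)

    np.clip(img, 0.0, 1.0, out=img)
    pixels = np.rint(img * 255.0)
    return BScanImage(pixels=pixels, bit_depth=8), truth


def _random_defect_spec(rng: np.random.Generator, base: PhantomSpec, seed: int) -> PhantomSpec:
    width = base.width
    curvature = rng.uniform(1.0e-4, 3.0e-4)
    apex = rng.uniform(150.0, 250.0) * base.height / 1024.0
    deepest_surface = apex + curvature * (width / 2.0) ** 2
    avail = base.height - deepest_surface  # nacre rows below the surface
    amplitude = rng.uniform(0.0, 0.03 * avail)
    tilt = rng.uniform(-1.0, 1.0) * 0.08 * avail / width
    thickness = rng.uniform(0.04, 0.08) * avail
    wobble = rng.uniform(0.0, 0.2 * thickness)
    # bounds keep the stripe strictly between the surface band and bottom
    span = amplitude + abs(tilt) * width / 2.0
    lo = SURFACE_BAND_PX + 6.0 + span
    hi = 0.5 * avail - thickness - wobble - span
    depth0 = rng.uniform(lo, max(hi, lo + 1.0))
    top = sinusoid_profile(
        width,
        depth=depth0,
        amplitude=amplitude,
        wavelength=rng.uniform(width / 2.0, 2.0 * width),
        phase=rng.uniform(0.0, 2.0 * np.pi),
        tilt=tilt,
    )
    thick = np.full(width, thickness) + wobble * np.sin(
        2.0 * np.pi * np.arange(width) / rng.uniform(width, 3.0 * width)
    )
    return PhantomSpec(
        height=base.height,
        width=base.width,
        surface_curvature=curvature,
        surface_apex_row=apex,
        nacre_base_intensity=base.nacre_base_intensity,
        depth_decay=base.depth_decay,
        ring_period=rng.uniform(60.0, 100.0) * base.height / 1024.0,
        ring_contrast=base.ring_contrast,
        has_defect=True,
        defect_top_profile=top,
        defect_thickness_profile=thick,
        defect_contrast=rng.uniform(0.35, 0.45),
        speckle_level=base.speckle_level,
        background_noise_sigma=base.background_noise_sigma,
        seed=seed,
    )


def _random_normal_spec(rng: np.random.Generator, base: PhantomSpec, seed: int) -> PhantomSpec:
    return PhantomSpec(
        height=base.height,
        width=base.width,
        surface_curvature=rng.uniform(1.0e-4, 3.0e-4),
        surface_apex_row=rng.uniform(150.0, 250.0) * base.height / 1024.0,
        nacre_base_intensity=base.nacre_base_intensity,
        depth_decay=base.depth_decay,
        ring_period=rng.uniform(60.0, 100.0) * base.height / 1024.0,
        ring_contrast=base.ring_contrast,
        has_defect=False,
        speckle_level=base.speckle_level,
        background_noise_sigma=base.background_noise_sigma,
        seed=seed,
    )


def generate_dataset(
    n: int,
    defect_fraction: float,
    seed: int,
    base: PhantomSpec | None = None,
) -> list[tuple[BScanImage, GroundTruth]]:
    """Generate ``n`` phantoms, ``round(n * defect_fraction)`` of them defective.

    Defect geometry (curvature, apex, ring period, defect shape, tilt,
    thickness, contrast) is randomised per item; per-item seeds derive
    deterministically from the master seed, so two calls with the same
    arguments return identical label sequences and bit-identical images.
    ``base`` overrides the shared photometric defaults (image size, noise
    levels and so on) for every item.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= defect_fraction <= 1.0:
        raise ValueError("defect_fraction must lie in [0, 1]")
    base = base or PhantomSpec()
    n_defect = int(round(n * defect_fraction))

    master = np.random.default_rng(seed)
    labels = np.array([True] * n_defect + [False] * (n - n_defect))
    master.shuffle(labels)
    item_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)

    out: list[tuple[BScanImage, GroundTruth]] = []
    for is_defect, item_seed in zip(labels, item_seeds):
        item_rng = np.random.default_rng(int(item_seed))
        if is_defect:
            spec = _random_defect_spec(item_rng, base, int(item_seed))
        else:
            spec = _random_normal_spec(item_rng, base, int(item_seed))
        out.append(generate_phantom(spec))
    return out


def write_dataset(
    out_dir: str | Path,
    n: int,
    defect_fraction: float,
    seed: int,
    base: PhantomSpec | None = None,
    fmt: str = "png",
) -> Path:
    """Write a phantom set to disk: images, JSON ground-truth sidecars and
    a ``manifest.csv`` (filename,label,seed). Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    items = generate_dataset(n, defect_fraction, seed, base=base)
    item_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "seed"])
        for i, ((img, truth), item_seed) in enumerate(zip(items, item_seeds)):
            name = f"phantom_{i:03d}.{fmt}"
            save_image(img, out_dir / name)
            (out_dir / f"phantom_{i:03d}.json").write_text(truth.to_json())
            writer.writerow([name, truth.label, int(item_seed)])
    return manifest
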