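"""Raw B-scan -> flattened, cropped, contrast-expanded segmentation input.

Stage order: background threshold denoising, Canny surface detection,
polynomial surface fit, column-wise flattening, median smoothing,
region-of-interest crop, nearest-neighbour half-size downscale, power-law
contrast expansion. All coordinates are 0-based with row 0 at the top
(shallowest depth); ranges are half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny
from skimage.filters import rank

from .image import BScanImage

DEFAULT_BACKGROUND_ROWS = 10
DEFAULT_K_SIGMA = 7.0
DEFAULT_POLY_DEGREE = 2
DEFAULT_MEDIAN_WINDOW = (10, 40)  # rows x cols
DEFAULT_CROP_SIZE = (600, 300)  # rows x cols
DEFAULT_POWER_C = 1.2
DEFAULT_POWER_GAMMA = 1.5
DEFAULT_CANNY_SIGMA = 2.0
DEFAULT_CANNY_LOW_PCT = 70.0
DEFAULT_CANNY_HIGH_PCT = 90.0


@dataclass
class BackgroundStats:
    """Mean/SD of the background band at the top of the scan.

    The top rows of a pearl B-scan image the air gap above the sample
    and contain only speckle; mu + k*sigma of those rows is the
    empirical noise-floor threshold (k defaults to 7).
    """

    mu: float
    sigma: float
    n_rows: int = DEFAULT_BACKGROUND_ROWS
    k: float = DEFAULT_K_SIGMA

    @property
    def threshold(self) -> float:
        return self.mu + self.k * self.sigma


@dataclass
class SurfaceCurve:
    """Per-column row index of the pearl's top surface."""

    rows: np.ndarray  # fractional pixels allowed
    fitted: bool = False
    poly_degree: int | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)


def background_stats(
    img: BScanImage, n_rows: int = DEFAULT_BACKGROUND_ROWS, k: float = DEFAULT_K_SIGMA
) -> BackgroundStats:
    """Mean and standard deviation of all pixels in the top ``n_rows`` rows."""
    if n_rows < 1 or n_rows >= img.height:
        raise ValueError(f"n_rows must be in [1, {img.height - 1}], got {n_rows}")
    region = img.pixels[:n_rows, :]
    if region.size == 0:
        raise ValueError("empty background region")
    return BackgroundStats(mu=float(region.mean()), sigma=float(region.std()), n_rows=n_rows, k=k)


def threshold_denoise(img: BScanImage, stats: BackgroundStats) -> BScanImage:
    """Zero every pixel strictly below the mu + k*sigma noise floor."""
    out = img.pixels.copy()
    out[out < stats.threshold] = 0.0
    return img.with_pixels(out)


def detect_surface(
    img: BScanImage,
    sigma: float = DEFAULT_CANNY_SIGMA,
    low_pct: float = DEFAULT_CANNY_LOW_PCT,
    high_pct: float = DEFAULT_CANNY_HIGH_PCT,
    min_edge_columns: int = DEFAULT_POLY_DEGREE + 1,
) -> SurfaceCurve:
    """Topmost Canny edge pixel per column.

    Hysteresis thresholds are set at the given percentiles of the
    denoised image's nonzero intensities, so the dominant background->
    surface step drives detection. Columns without any edge are filled
    by linear interpolation between the nearest detected neighbours
    (constant extrapolation at the ends).
    """
    pixels = img.pixels
    nonzero = pixels[pixels > 0]
    if nonzero.size == 0:
        raise ValueError("image is entirely zero; no surface to detect")
    low, high = np.percentile(nonzero, [low_pct, high_pct])
    edges = canny(pixels, sigma=sigma, low_threshold=low, high_threshold=high)

    has_edge = edges.any(axis=0)
    cols = np.flatnonzero(has_edge)
    if cols.size < min_edge_columns:
        raise ValueError(
            f"surface detection failed: only {cols.size} columns have edges "
            f"(need {min_edge_columns})"
        )
    top = edges.argmax(axis=0).astype(np.float64)  # first True per column
    all_cols = np.arange(img.width)
    rows = np.interp(all_cols, cols, top[cols])  # constant beyond the ends
    return SurfaceCurve(rows=rows, fitted=False)


def fit_surface(curve: SurfaceCurve, degree: int = DEFAULT_POLY_DEGREE) -> SurfaceCurve:
    """Least-squares polynomial fit of surface row vs column index."""
    if curve.fitted:
        raise ValueError("curve is already fitted")
    cols = np.arange(curve.rows.size, dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            coeffs = np.polyfit(cols, curve.rows, deg=degree)
        except np.exceptions.RankWarning as exc:
            raise ValueError(f"degenerate polynomial fit (degree {degree})") from exc
    fitted_rows = np.polyval(coeffs, cols)
    return SurfaceCurve(rows=fitted_rows, fitted=True, poly_degree=degree)


def flatten(img: BScanImage, fitted: SurfaceCurve) -> tuple[BScanImage, int]:
    """Shift each column up by an integer so the fitted surface becomes a
    horizontal line at ``flat_row = round(min fitted row)``.

    Vacated pixels are zero-filled; each column's pixel multiset is
    otherwise preserved. Returns (flattened image, flat_row).
    """
    if not fitted.fitted:
        raise ValueError("flatten requires a fitted surface curve")
    if fitted.rows.size != img.width:
        raise ValueError("surface curve and image widths differ")
    flat_row = int(round(float(fitted.rows.min())))
    shifts = np.rint(fitted.rows).astype(int) - flat_row
    if np.any(np.abs(shifts) >= img.height):
        raise ValueError("flattening shift would move a whole column out of frame")
    out = np.zeros_like(img.pixels)
    for c, s in enumerate(shifts):
        if s >= 0:
            out[: img.height - s, c] = img.pixels[s:, c]
        else:
            out[-s:, c] = img.pixels[: img.height + s, c]
    return img.with_pixels(out), flat_row


def median_smooth(
    img: BScanImage, window: tuple[int, int] = DEFAULT_MEDIAN_WINDOW
) -> BScanImage:
    """Sliding-window median with edge-replicated borders.

    ``window`` is (rows, cols), defaulting to the 10x40 smoothing used
    before layer segmentation — wide to preserve the near-horizontal
    ring boundaries while suppressing speckle. Integer-valued 8-bit
    images take a histogram-based fast path that is bit-identical to the
    direct sliding-window median.
    """
    wy, wx = window
    if wy < 1 or wx < 1:
        raise ValueError("window must be at least 1x1")
    if wy > img.height or wx > img.width:
        raise ValueError(f"window {window} larger than image {img.pixels.shape}")
    pixels = img.pixels
    integral_u8 = img.bit_depth == 8 and np.array_equal(pixels, np.rint(pixels))
    if integral_u8:
        out = _rank_median_u8(pixels.astype(np.uint8), window).astype(np.float64)
    else:
        out = ndimage.median_filter(pixels, size=window, mode="nearest")
    return img.with_pixels(out)


def _rank_median_u8(pixels: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    # edge-pad so the histogram rank filter reproduces replicated borders;
    # the window centre follows the size//2 convention for even sizes
    wy, wx = window
    top, left = wy // 2, wx // 2
    bot, right = wy - 1 - top, wx - 1 - left
    padded = np.pad(pixels, ((top, bot), (left, right)), mode="edge")
    out = rank.median(padded, np.ones(window, dtype=bool))
    return out[top : padded.shape[0] - bot, left : padded.shape[1] - right]


def crop_roi(
    img: BScanImage, flat_row: int, size: tuple[int, int] = DEFAULT_CROP_SIZE
) -> BScanImage:
    """Crop ``size`` = (rows, cols): rows [flat_row, flat_row + rows) and the
    cols columns centred at width/2. If the row range runs past the image
    bottom the output is zero-padded (with a warning)."""
    n_rows, n_cols = size
    if n_cols > img.width:
        raise ValueError(f"crop width {n_cols} exceeds image width {img.width}")
    col0 = img.width // 2 - n_cols // 2
    out = np.zeros((n_rows, n_cols), dtype=np.float64)
    avail = min(n_rows, img.height - flat_row)
    if avail < n_rows:
        warnings.warn(
            f"crop extends {n_rows - avail} rows past the image bottom; zero-padded",
            stacklevel=2,
        )
    if avail <= 0:
        raise ValueError("flat_row lies below the image bottom")
    out[:avail, :] = img.pixels[flat_row : flat_row + avail, col0 : col0 + n_cols]
    return img.with_pixels(out)


def downscale_half(img: BScanImage) -> BScanImage:
    """Nearest-neighbour half-size: output[i, j] = input[2i, 2j].

    No averaging, so thin nacre-layer detail survives as sampled pixels;
    odd dimensions floor.
    """
    return img.with_pixels(img.pixels[::2, ::2].copy())


def power_law(
    img: BScanImage, C: float = DEFAULT_POWER_C, gamma: float = DEFAULT_POWER_GAMMA
) -> BScanImage:
    """Power-law (gamma) transform s = C * r**gamma on normalised intensity.

    Input gray levels are normalised to r in [0, 1] by the bit-depth
    range, mapped, rescaled back and clipped. Strictly increasing on
    (0, 1] for C > 0, gamma > 0; expands the bright end of the range so
    vertical gradients at sub-layer boundaries grow before segmentation.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    r = img.pixels / img.max_gray
    s = C * np.power(r, gamma)
    return img.with_pixels(np.clip(s, 0.0, 1.0) * img.max_gray)
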