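"""Fluorescence and plate-image quantification.

Implements the measurement procedures used on spindle micrographs and
colony plates: perpendicular line scans with Gaussian fitting (integrated
spot intensity = area under the fitted curve), circular ROI intensity
with larger-circle background subtraction, thresholded growth-area
fraction inside a measurement circle, and size-gated colony counting on
binarized plate images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage import measure

log = logging.getLogger(__name__)


@dataclass
class LineScanProfile:
    """Uniformly spaced intensity samples along a scan line."""

    positions: np.ndarray  # px along the line, strictly increasing
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities length mismatch")
        d = np.diff(self.positions)
        if len(d) and (d <= 0).any():
            raise ValueError("positions must be strictly increasing")


@dataclass
class GaussianFit:
    amplitude: float
    center: float
    sigma: float
    baseline: float
    converged: bool
    auc: float | None  # A * sigma * sqrt(2*pi); None if not converged


def _check_inside(img: np.ndarray, x: float, y: float) -> None:
    h, w = img.shape
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise ValueError(f"point ({x}, {y}) outside {w}x{h} image")


def line_scan(
    img: np.ndarray,
    p1: tuple[float, float],
    p2: tuple[float, float],
    width: int = 3,
    n_samples: int | None = None,
) -> LineScanProfile:
    """Intensity profile along p1→p2, averaged across a perpendicular width.

    Points are (x, y) in pixel coordinates.  Intensities are bilinearly
    interpolated; ``width`` pixels (centered offsets) perpendicular to the
    scan direction are averaged at each sample.  ``n_samples`` defaults to
    the line length in pixels, rounded up, plus one.
    """
    img = np.asarray(img, dtype=float)
    x1, y1 = p1
    x2, y2 = p2
    _check_inside(img, x1, y1)
    _check_inside(img, x2, y2)
    length = float(np.hypot(x2 - x1, y2 - y1))
    if length == 0:
        raise ValueError("degenerate scan line (p1 == p2)")
    if n_samples is None:
        n_samples = int(np.ceil(length)) + 1
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    t = np.linspace(0.0, 1.0, n_samples)
    xs = x1 + t * (x2 - x1)
    ys = y1 + t * (y2 - y1)
    # unit normal to the scan direction
    nx, ny = -(y2 - y1) / length, (x2 - x1) / length
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    profiles = []
    for off in offsets:
        coords = np.vstack([ys + off * ny, xs + off * nx])  # (row, col)
        profiles.append(ndimage.map_coordinates(img, coords, order=1, mode="nearest"))
    return LineScanProfile(positions=t * length, intensities=np.mean(profiles, axis=0))


def _gauss(x, amp, mu, sigma, c):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2)) + c


def fit_gaussian_auc(profile: LineScanProfile) -> GaussianFit:
    """Least-squares Gaussian fit to a line-scan profile.

    Fits A·exp(−(x−µ)²/2σ²) + c with moment-based initialization and
    σ bounded in (0.5 px, profile length).  The area under the curve
    (above baseline) is A·σ·√(2π).  Non-convergence is flagged, never
    silent; the AUC is omitted in that case.
    """
    x = profile.positions
    y = profile.intensities
    if len(x) < 5:
        raise ValueError("need at least 5 samples to fit")
    span = float(x[-1] - x[0])
    c0 = float(y.min())
    a0 = float(y.max() - c0)
    w = np.clip(y - c0, 0, None)
    if w.sum() > 0:
        mu0 = float((x * w).sum() / w.sum())
        var0 = float(((x - mu0) ** 2 * w).sum() / w.sum())
        s0 = float(np.sqrt(var0)) if var0 > 0 else span / 6.0
    else:
        mu0, s0 = float(x.mean()), span / 6.0
    s0 = float(np.clip(s0, 0.51, span))
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            y,
            p0=[max(a0, 1e-9), mu0, s0, c0],
            bounds=([0.0, x[0] - span, 0.5, -np.inf], [np.inf, x[-1] + span, span, np.inf]),
            maxfev=10_000,
        )
    except (RuntimeError, ValueError) as err:
        log.warning("Gaussian fit did not converge: %s", err)
        return GaussianFit(np.nan, np.nan, np.nan, np.nan, converged=False, auc=None)
    amp, mu, sigma, c = (float(v) for v in popt)
    return GaussianFit(
        amplitude=amp,
        center=mu,
        sigma=sigma,
        baseline=c,
        converged=True,
        auc=amp * sigma * float(np.sqrt(2.0 * np.pi)),
    )


def circle_intensity(
    img: np.ndarray,
    center: tuple[float, float],
    r_inner: float,
    r_outer: float,
) -> float:
    """Integrated spot intensity with annulus background subtraction.

    Sums pixels of the inner disk and subtracts the mean per-pixel
    intensity of the surrounding annulus (r_inner..r_outer) times the
    inner pixel count.  Negative results are reported as-is.
    """
    img = np.asarray(img, dtype=float)
    if r_outer <= r_inner:
        raise ValueError("r_outer must exceed r_inner")
    x0, y0 = center
    h, w = img.shape
    if x0 - r_outer < -0.5 or x0 + r_outer > w - 0.5 or y0 - r_outer < -0.5 or y0 + r_outer > h - 0.5:
        raise ValueError("outer circle extends outside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (xx - x0) ** 2 + (yy - y0) ** 2
    inner = d2 <= r_inner**2
    annulus = (d2 > r_inner**2) & (d2 <= r_outer**2)
    if not annulus.any():
        raise ValueError("annulus contains no pixels")
    if not inner.any():
        raise ValueError("inner disk contains no pixels")
    background = img[annulus].mean()
    return float(img[inner].sum() - background * inner.sum())


def growth_area(
    img: np.ndarray,
    threshold: float,
    center: tuple[float, float],
    radius: float,
) -> float:
    """Percentage of a measurement circle above an intensity threshold."""
    img = np.asarray(img, dtype=float)
    x0, y0 = center
    h, w = img.shape
    if x0 - radius < -0.5 or x0 + radius > w - 0.5 or y0 - radius < -0.5 or y0 + radius > h - 0.5:
        raise ValueError("measurement circle extends outside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    circle = (xx - x0) ** 2 + (yy - y0) ** 2 <= radius**2
    if not circle.any():
        raise ValueError("measurement circle contains no pixels")
    return float(100.0 * (img[circle] >= threshold).mean())


def count_colonies(
    img: np.ndarray,
    threshold: float,
    min_size: int = 5,
    max_size: int | None = None,
) -> int:
    """Number of 8-connected above-threshold components within a size gate."""
    img = np.asarray(img, dtype=float)
    labels = measure.label(img >= threshold, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    upper = max_size if max_size is not None else np.inf
    return int(((sizes >= min_size) & (sizes <= upper)).sum())


# ------------------------------------------------------------------------ I/O
def read_image(path: str | Path) -> np.ndarray:
    """Read an 8/16-bit grayscale TIFF or PNG as float."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # collapse accidental RGB
        arr = arr.mean(axis=2)
    return arr


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write a float image as 16-bit grayscale TIFF (clipped to range)."""
    import tifffile

    arr = np.clip(np.asarray(img, dtype=float), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)
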