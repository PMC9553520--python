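"""Three-parameter Rayleigh speckle statistics.

The central texture statistic: pool all pixels of a 3-D region of interest
across repeat frames, histogram the intensities, and fit the
three-parameter Rayleigh probability density

    P(x; a, b, c) = a * (x - c) / b^2 * exp(-(x - c)^2 / (2 b^2)),  x >= c
    P(x; a, b, c) = 0,                                              x <  c

where ``a`` is the amplitude normalization, ``b`` the scale and ``c`` the
shift.  The goodness of fit R^2 of this curve to the histogram separates
scattering tissue-like material (poor single-Rayleigh fit) from
transparent/semi-transparent inclusions and noise (near-perfect fit), and
the fitted ``a`` and ``c`` coefficients further differentiate the
low-scattering materials.

Fits are bounded nonlinear least squares on density-normalized histogram
heights with deterministic initialization, so the same histogram always
yields the same coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .simulator import OCTVolume

__all__ = [
    "DegenerateHistogramError",
    "ROISpec",
    "IntensityHistogram",
    "RayleighFit",
    "FeatureMap",
    "rayleigh_pdf",
    "pool_roi",
    "make_histogram",
    "fit_rayleigh",
    "fit_sample",
    "r_squared",
    "feature_map",
]

logger = logging.getLogger(__name__)

#: Default ROI extent in voxels, (depth, fast, slow): 6 x 6 x 10 voxels,
#: i.e. 45 x 45 x 37.5 um at the default pitch; pooled over 24 repeats this
#: gives 8640 pixels per histogram.
DEFAULT_ROI_EXTENT = (6, 6, 10)

#: Default number of equal-width histogram bins (~135 expected counts per
#: bin at n = 8640).
DEFAULT_N_BINS = 64


class DegenerateHistogramError(ValueError):
    """Sample has zero range or too few occupied bins to fit."""


@dataclass
class ROISpec:
    """A rectangular ROI on the voxel grid.

    ``origin`` and ``extent`` are (depth, fast, slow) voxel triples;
    ``repeat_range`` is a half-open interval of repeat indices (``None``
    means all repeats).
    """

    origin: tuple[int, int, int]
    extent: tuple[int, int, int] = DEFAULT_ROI_EXTENT
    repeat_range: tuple[int, int] | None = None

    def n_pixels(self, n_repeat: int) -> int:
        r0, r1 = self.repeat_range or (0, n_repeat)
        return int(np.prod(self.extent)) * (r1 - r0)


@dataclass
class IntensityHistogram:
    """Density-normalized equal-width intensity histogram."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_pixels: int
    raw_min: float
    raw_max: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class RayleighFit:
    """Result of fitting the three-parameter Rayleigh PDF to a histogram."""

    a: float
    b: float
    c: float
    r_squared: float
    sse: float
    converged: bool
    n_pixels: int
    n_bins: int

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "r_squared": self.r_squared,
            "sse": self.sse,
            "converged": self.converged,
            "n_pixels": self.n_pixels,
            "n_bins": self.n_bins,
        }


@dataclass
class FeatureMap:
    """Per-voxel (window-centred) Rayleigh-fit feature maps.

    Arrays are NaN and ``mask`` is False wherever no window was evaluated
    (volume edges, off-lattice voxels, or degenerate windows).
    """

    r_squared: np.ndarray
    a_coeff: np.ndarray
    c_coeff: np.ndarray
    mask: np.ndarray
    window: tuple[int, int, int]
    stride: tuple[int, int, int]


def rayleigh_pdf(x, a: float, b: float, c: float):
    """Three-parameter Rayleigh PDF, zero below the shift point ``c``.

    With ``a = 1`` the curve integrates to 1 over ``[c, inf)`` for any
    ``b > 0``; ``a`` rescales the curve without changing its shape.
    Accepts scalar or array ``x``.
    """
    if b <= 0:
        raise ValueError(f"scale b must be positive, got {b}")
    x_arr = np.asarray(x, dtype=np.float64)
    u = x_arr - c
    with np.errstate(over="ignore"):
        vals = a * u / b**2 * np.exp(-(u**2) / (2.0 * b**2))
    out = np.where(u > 0, vals, 0.0)
    if np.isscalar(x) or x_arr.ndim == 0:
        return float(out)
    return out


def pool_roi(volume: OCTVolume, roi: ROISpec) -> np.ndarray:
    """Flatten all voxel intensities of an ROI across its repeat range.

    Returns a 1-D float64 array of length prod(extent) * n_repeats used.
    """
    nz, nx, ny = volume.spatial_shape
    oz, ox, oy = roi.origin
    ez, ex, ey = roi.extent
    if min(oz, ox, oy) < 0 or oz + ez > nz or ox + ex > nx or oy + ey > ny:
        raise IndexError(
            f"ROI origin {roi.origin} extent {roi.extent} exceeds volume "
            f"spatial shape {(nz, nx, ny)}"
        )
    r0, r1 = roi.repeat_range or (0, volume.n_repeat)
    if not 0 <= r0 < r1 <= volume.n_repeat:
        raise IndexError(f"repeat_range {roi.repeat_range} invalid for {volume.n_repeat} repeats")
    block = volume.intensity[oz : oz + ez, ox : ox + ex, oy : oy + ey, r0:r1]
    return np.asarray(block, dtype=np.float64).ravel()


def make_histogram(sample: Sequence[float], n_bins: int = DEFAULT_N_BINS) -> IntensityHistogram:
    """Equal-width, density-normalized histogram spanning [min, max]."""
    sample = np.asarray(sample, dtype=np.float64)
    if sample.size == 0:
        raise ValueError("empty sample")
    if n_bins < 4:
        raise ValueError(f"need at least 4 bins, got {n_bins}")
    lo, hi = float(sample.min()), float(sample.max())
    if not np.isfinite([lo, hi]).all():
        raise ValueError("sample contains non-finite values")
    if hi <= lo:
        raise DegenerateHistogramError("sample has zero intensity range")
    density, edges = np.histogram(sample, bins=n_bins, range=(lo, hi), density=True)
    return IntensityHistogram(
        bin_edges=edges,
        density=density,
        n_pixels=int(sample.size),
        raw_min=lo,
        raw_max=hi,
    )


def _fit_on_points(
    centers: np.ndarray,
    density: np.ndarray,
    ref_min: float,
    ref_range: float,
    n_pixels: int,
) -> RayleighFit:
    """Bounded least-squares fit of the Rayleigh PDF to (centre, density)."""
    # deterministic initialization: anchor c just below the sample minimum,
    # b at the distance from there to the mode bin, a from the peak height
    c0 = ref_min - 0.05 * ref_range
    peak = int(np.argmax(density))
    b0 = max(centers[peak] - c0, 1e-6 * ref_range)
    a0 = max(float(density[peak]) * b0 * np.sqrt(np.e), 1e-12)
    lower = np.array([0.0, 1e-12, ref_min - ref_range])
    upper = np.array([np.inf, 10.0 * ref_range, ref_min])
    x0 = np.clip([a0, b0, c0], lower, upper)

    def residuals(p):
        return rayleigh_pdf(centers, p[0], p[1], p[2]) - density

    res = least_squares(
        residuals,
        x0,
        bounds=(lower, upper),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    a, b, c = (float(v) for v in res.x)
    sse = float(np.sum(res.fun**2))
    ss_tot = float(np.sum((density - density.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else np.nan
    # flag fits that failed or ended pinned to a finite bound
    at_bound = bool(
        np.any(np.isclose(res.x[1:], lower[1:], rtol=0, atol=1e-9 * ref_range))
        or np.any(np.isclose(res.x[1:], upper[1:], rtol=0, atol=1e-9 * ref_range))
    )
    converged = bool(res.success) and not at_bound and np.isfinite([a, b, c]).all()
    return RayleighFit(
        a=a,
        b=b,
        c=c,
        r_squared=float(r2),
        sse=sse,
        converged=converged,
        n_pixels=n_pixels,
        n_bins=int(centers.size),
    )


def fit_rayleigh(hist: IntensityHistogram) -> RayleighFit:
    """Fit the three-parameter Rayleigh PDF to a histogram.

    Least squares on (bin centre, density) pairs; R^2 is computed on the
    bin heights about their mean.  Multimodal or otherwise non-Rayleigh
    histograms are fitted as-is — a low R^2 is the signal, not an error.
    Coefficients are always finite; ``converged`` is False if the optimizer
    failed or finished pinned at a bound.
    """
    occupied = int(np.count_nonzero(hist.density))
    if occupied < 4:
        raise DegenerateHistogramError(
            f"only {occupied} non-empty bins; need at least 4"
        )
    rng_width = hist.raw_max - hist.raw_min
    if rng_width <= 0:
        raise DegenerateHistogramError("histogram has zero range")
    return _fit_on_points(
        hist.bin_centers, hist.density, hist.raw_min, rng_width, hist.n_pixels
    )


def fit_sample(sample: Sequence[float], n_bins: int = DEFAULT_N_BINS) -> RayleighFit:
    """Convenience: histogram a pooled pixel sample and fit it."""
    return fit_rayleigh(make_histogram(sample, n_bins=n_bins))


def r_squared(hist: IntensityHistogram, fit: RayleighFit) -> float:
    """Coefficient of determination of a fit evaluated on a histogram.

    R^2 = 1 - SS_res/SS_tot over density heights; 1 for a perfect fit,
    0 for a model no better than the mean height, possibly negative for a
    worse one.
    """
    model = rayleigh_pdf(hist.bin_centers, fit.a, fit.b, fit.c)
    ss_res = float(np.sum((hist.density - model) ** 2))
    ss_tot = float(np.sum((hist.density - hist.density.mean()) ** 2))
    if ss_tot <= 0:
        raise DegenerateHistogramError("flat histogram: SS_tot is zero")
    return 1.0 - ss_res / ss_tot


def _window_centers(
    spatial_shape: tuple[int, int, int],
    window: tuple[int, int, int],
    stride: tuple[int, int, int],
) -> Iterable[tuple[int, int, int]]:
    """Window centres on the stride lattice; centre = origin + window//2."""
    for oz in range(0, spatial_shape[0] - window[0] + 1, stride[0]):
        for ox in range(0, spatial_shape[1] - window[1] + 1, stride[1]):
            for oy in range(0, spatial_shape[2] - window[2] + 1, stride[2]):
                yield (oz + window[0] // 2, ox + window[1] // 2, oy + window[2] // 2)


def center_to_origin(
    center: tuple[int, int, int], window: tuple[int, int, int]
) -> tuple[int, int, int]:
    """Window origin whose centre voxel is ``center``."""
    return tuple(int(c) - w // 2 for c, w in zip(center, window))


def feature_map(
    volume: OCTVolume,
    window: tuple[int, int, int] = DEFAULT_ROI_EXTENT,
    stride: tuple[int, int, int] = (1, 1, 1),
    n_bins: int = DEFAULT_N_BINS,
    centers: Sequence[tuple[int, int, int]] | None = None,
) -> FeatureMap:
    """Sliding-window Rayleigh-fit feature maps (R^2, a, c).

    Each valid window on the stride lattice is pooled across all repeats,
    histogrammed and fitted; the features are stored at the window's centre
    voxel.  Edge voxels whose window would leave the volume are masked (no
    padding).  If ``centers`` is given, only those window centres are
    evaluated (all others stay masked) — this is how training pixels are
    parameterized without paying for a dense map.
    """
    nz, nx, ny = volume.spatial_shape
    if any(w > s for w, s in zip(window, (nz, nx, ny))):
        raise ValueError(f"window {window} larger than volume {(nz, nx, ny)}")
    shape = (nz, nx, ny)
    r2_map = np.full(shape, np.nan)
    a_map = np.full(shape, np.nan)
    c_map = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    if centers is None:
        centers = _window_centers(shape, window, stride)
    for cz, cx, cy in centers:
        origin = center_to_origin((cz, cx, cy), window)
        roi = ROISpec(origin=origin, extent=window)
        try:
            fit = fit_sample(pool_roi(volume, roi), n_bins=n_bins)
        except DegenerateHistogramError:
            continue
        if not fit.converged:
            logger.warning("non-converged fit at window centre (%d, %d, %d)", cz, cx, cy)
        r2_map[cz, cx, cy] = fit.r_squared
        a_map[cz, cx, cy] = fit.a
        c_map[cz, cx, cy] = fit.c
        mask[cz, cx, cy] = True
    return FeatureMap(
        r_squared=r2_map,
        a_coeff=a_map,
        c_coeff=c_map,
        mask=mask,
        window=tuple(window),
        stride=tuple(stride),
    )
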