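"""Independent oracles used by the tests (kept free of package internals)."""

import numpy as np


def rayleigh_cdf(x, b: float, c: float):
    """Closed-form CDF of the shifted Rayleigh distribution."""
    u = np.maximum(np.asarray(x, dtype=float) - c, 0.0)
    return 1.0 - np.exp(-(u**2) / (2.0 * b**2))


def rayleigh_pdf_reference(x, a, b, c):
    """Direct transcription of the three-parameter Rayleigh density."""
    x = np.asarray(x, dtype=float)
    u = x - c
    return np.where(u > 0, a * u / b**2 * np.exp(-(u**2) / (2 * b**2)), 0.0)


def grid_search_sse(
    centers: np.ndarray,
    density: np.ndarray,
    a_grid: np.ndarray,
    b_grid: np.ndarray,
    c_grid: np.ndarray,
) -> float:
    """Brute-force minimum SSE of the Rayleigh PDF over a parameter grid.

    Exhaustive enumeration, vectorized over (b, c) with an outer loop over
    a to bound memory; independent of the package's optimizer.
    """
    best = np.inf
    B = b_grid[:, None, None]
    C = c_grid[None, :, None]
    X = centers[None, None, :]
    U = X - C
    shape_term = np.where(U > 0, U / B**2 * np.exp(-(U**2) / (2 * B**2)), 0.0)
    for a in a_grid:
        sse = np.sum((a * shape_term - density[None, None, :]) ** 2, axis=-1)
        best = min(best, float(sse.min()))
    return best
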