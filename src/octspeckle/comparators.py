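"""Baseline contrast mechanisms the Rayleigh-fit features are compared to.

Two classical OCT texture/contrast feature sets, trained identically to the
Rayleigh features in the classification study:

* the depth-resolved attenuation coefficient, estimated per A-line with the
  single-scattering tail-sum estimator
  ``mu[i] = I[i] / (2 * dz * sum_{j>i} I[j])`` (dz in mm, mu in 1/mm), and
* gray-level co-occurrence matrix (GLCM) Haralick metrics — contrast,
  correlation, energy (angular second moment) and homogeneity — computed in
  the repeat-averaged B-scan (depth x fast) plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.feature import graycomatrix, graycoprops

from .simulator import OCTVolume

__all__ = [
    "AttenuationMap",
    "GLCMFeatureMaps",
    "attenuation_map",
    "glcm_features",
    "glcm_window_features",
    "DEFAULT_GLCM_LEVELS",
    "DEFAULT_GLCM_ANGLES",
]

#: Quantization depth for GLCM windows.
DEFAULT_GLCM_LEVELS = 32

#: Distance-1 offsets along the four standard neighbour directions of the
#: (depth, fast) plane: (0,1), (1,0), (1,1), (1,-1); symmetric accumulation
#: makes the features invariant to offset sign.
DEFAULT_GLCM_ANGLES = (0.0, np.pi / 2, np.pi / 4, 3 * np.pi / 4)


@dataclass
class AttenuationMap:
    """Depth-resolved attenuation estimate, units 1/mm.

    ``mu`` is NaN and ``tail_mask`` True where the estimate is undefined:
    the bottom ``tail_frac`` of the depth range (the tail sum underflows
    there) and voxels whose tail sum is non-positive.
    """

    mu: np.ndarray  # (depth, fast, slow)
    tail_mask: np.ndarray  # bool, True = excluded

    @property
    def valid(self) -> np.ndarray:
        return ~self.tail_mask


def attenuation_map(volume: OCTVolume, tail_frac: float = 0.1) -> AttenuationMap:
    """Depth-resolved attenuation coefficient per voxel.

    The estimator divides each depth sample of the repeat-averaged A-line
    by the summed signal below it; it is exact (up to discretization) for a
    single-exponential decay and invariant to global intensity scaling.

    Parameters
    ----------
    volume : OCTVolume
        Needs at least 8 depth samples.
    tail_frac : float
        Fraction of the deepest samples to mask, where the tail sum has too
        few terms to be trusted.
    """
    nz = volume.spatial_shape[0]
    if nz < 8:
        raise ValueError(f"need >= 8 depth samples, got {nz}")
    intensity = np.asarray(volume.intensity, dtype=np.float64).mean(axis=3)
    dz_mm = volume.voxel_pitch[0] * 1e-3
    # tail[i] = sum_{j > i} I[j] along depth
    rev_cum = np.cumsum(intensity[::-1], axis=0)[::-1]
    tail = rev_cum - intensity
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = intensity / (2.0 * dz_mm * tail)
    tail_mask = tail <= 0
    z_cut = int(np.ceil(nz * (1.0 - tail_frac)))
    tail_mask[z_cut:, :, :] = True
    mu[tail_mask] = np.nan
    return AttenuationMap(mu=mu, tail_mask=tail_mask)


def glcm_window_features(
    window: np.ndarray,
    levels: int = DEFAULT_GLCM_LEVELS,
    angles: Sequence[float] = DEFAULT_GLCM_ANGLES,
) -> dict[str, float]:
    """Haralick features of one 2-D window, averaged over offsets.

    The window is quantized to ``levels`` gray levels over its own min-max
    range; co-occurrence matrices are accumulated symmetrically and
    normalized per offset.  A constant window follows the zero-variance
    convention: contrast 0, correlation 0, energy 1, homogeneity 1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    window = np.asarray(window, dtype=np.float64)
    lo, hi = window.min(), window.max()
    if hi <= lo:
        return {"contrast": 0.0, "correlation": 0.0, "energy": 1.0, "homogeneity": 1.0}
    quant = np.minimum(
        ((window - lo) / (hi - lo) * levels).astype(np.intp), levels - 1
    ).astype(np.uint8)
    glcm = graycomatrix(
        quant, distances=[1], angles=list(angles), levels=levels,
        symmetric=True, normed=True,
    )
    feats = {}
    for name, prop in (
        ("contrast", "contrast"),
        ("correlation", "correlation"),
        ("energy", "ASM"),  # MATLAB/Haralick "energy" = angular second moment
        ("homogeneity", "homogeneity"),
    ):
        feats[name] = float(np.mean(graycoprops(glcm, prop)))
    return feats


@dataclass
class GLCMFeatureMaps:
    """Window-centred GLCM feature maps on the voxel grid (NaN off-lattice)."""

    contrast: np.ndarray
    correlation: np.ndarray
    energy: np.ndarray
    homogeneity: np.ndarray
    mask: np.ndarray
    window: tuple[int, int]
    levels: int

    def feature_matrix(self, centers: Sequence[tuple[int, int, int]]) -> np.ndarray:
        """(n, 4) matrix of features at the given centres."""
        idx = tuple(np.asarray(centers).T)
        return np.column_stack(
            [self.contrast[idx], self.correlation[idx], self.energy[idx], self.homogeneity[idx]]
        )


def glcm_features(
    volume: OCTVolume,
    window: tuple[int, int] = (6, 6),
    levels: int = DEFAULT_GLCM_LEVELS,
    angles: Sequence[float] = DEFAULT_GLCM_ANGLES,
    stride: tuple[int, int, int] = (1, 1, 1),
    centers: Sequence[tuple[int, int, int]] | None = None,
) -> GLCMFeatureMaps:
    """GLCM Haralick features per window centre.

    Windows are 2-D (depth x fast) patches of the repeat-averaged B-scan at
    each slow position.  ``centers`` restricts evaluation to specific
    (depth, fast, slow) centres, mirroring
    :func:`octspeckle.speckle_stats.feature_map`.
    """
    nz, nx, ny = volume.spatial_shape
    wz, wx = window
    if wz > nz or wx > nx:
        raise ValueError(f"window {window} larger than B-scan plane {(nz, nx)}")
    mean_vol = np.asarray(volume.intensity, dtype=np.float64).mean(axis=3)
    shape = (nz, nx, ny)
    maps = {k: np.full(shape, np.nan) for k in ("contrast", "correlation", "energy", "homogeneity")}
    mask = np.zeros(shape, dtype=bool)
    if centers is None:
        centers = [
            (oz + wz // 2, ox + wx // 2, oy)
            for oz in range(0, nz - wz + 1, stride[0])
            for ox in range(0, nx - wx + 1, stride[1])
            for oy in range(0, ny, stride[2])
        ]
    for cz, cx, cy in centers:
        oz, ox = cz - wz // 2, cx - wx // 2
        patch = mean_vol[oz : oz + wz, ox : ox + wx, cy]
        feats = glcm_window_features(patch, levels=levels, angles=angles)
        for k, v in feats.items():
            maps[k][cz, cx, cy] = v
        mask[cz, cx, cy] = True
    return GLCMFeatureMaps(
        contrast=maps["contrast"],
        correlation=maps["correlation"],
        energy=maps["energy"],
        homogeneity=maps["homogeneity"],
        mask=mask,
        window=tuple(window),
        levels=levels,
    )
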