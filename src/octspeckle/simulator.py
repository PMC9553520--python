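"""Synthetic OCT phantom generator.

Generates 4-D OCT-like intensity volumes (depth x fast x slow x repeat)
containing the six region types of a lymph/nerve-mimicking phantom -- air,
deep noise floor, dyed water inside a micro-tube, a transparent rod, the
semi-transparent tube wall, and a scattering Intralipid-gelatin background --
together with a voxel-exact ground-truth label map.

Speckle model
-------------
Fully developed speckle amplitude follows a Rayleigh distribution.  Each
voxel's signal amplitude is drawn as the modulus of a circular complex
Gaussian field scaled by a depth-attenuated region scale ``b(z)``; a shift
``c`` and an optional additive Rayleigh noise-floor term complete the voxel
intensity::

    I = c + b(z) * |Z| + b_nf * |Z_nf|,   Z, Z_nf ~ CN(0, 1)

Repeat frames share speckle through variance-preserving mixing of the
underlying complex field, ``Z_r = sqrt(1-d) * Z0 + sqrt(d) * W_r`` with a
per-region decorrelation ``d`` (0 = frozen speckle, 1 = independent
realizations); mixing the field rather than the amplitude keeps the Rayleigh
marginal exact for every ``d``.  Departures from a single Rayleigh component
(which degrade the downstream goodness of fit, as in highly scattering
Intralipid) enter through two mechanisms: a depth-graded contaminating
Rayleigh component — with probability ``1 - rayleigh_purity`` a voxel's
scale is multiplied by a factor varying linearly from ``1 - g`` to ``1 + g``
across each ROI-depth-sized band (a sawtooth with the ROI depth period, so
every analysis window sees the full graded mixture and pooled statistics
are position-invariant) — and the additive noise-floor Rayleigh term, whose
sum with the signal term is no longer Rayleigh once the two scales are
comparable.

All randomness flows through a single :class:`numpy.random.Generator`
(PCG64) seeded explicitly; regions are filled in fixed enum order and draws
are made in a fixed order, so a given config + seed reproduces the volume
bit-for-bit on any platform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import tifffile
import yaml

from .regions import Region

__all__ = [
    "ConfigurationError",
    "MetadataError",
    "RegionSpeckleModel",
    "TubeSpec",
    "RodSpec",
    "PhantomConfig",
    "OCTVolume",
    "LabelMap",
    "generate_phantom",
    "generate_region_volume",
    "build_label_map",
    "write_volume",
    "read_volume",
    "load_phantom_config",
    "default_phantom_config",
]


class ConfigurationError(ValueError):
    """Invalid phantom configuration (geometry overflow, bad scales, ...)."""


class MetadataError(IOError):
    """Volume files present but the sidecar metadata is missing/invalid."""


@dataclass
class RegionSpeckleModel:
    """Generative speckle model for one region type.

    Parameters
    ----------
    region : Region
        Region label this model generates.
    base_scale : float
        Rayleigh scale ``b`` of the signal amplitude, arbitrary linear
        intensity units; must be > 0 (use a tiny value for a degenerate,
        near-constant region).
    shift : float
        Additive offset ``c`` in the same units.  May be negative.
    noise_floor_scale : float
        Scale of an additive, always-fresh Rayleigh detector-noise term.
    depth_attenuation : float
        Exponential decay rate of ``base_scale`` with depth below the
        region's entry surface, per micrometre.
    rayleigh_purity : float
        Fraction of voxels drawn from the single Rayleigh component; the
        remainder use the depth-graded contaminating component.
    contamination_grade : float
        Amplitude ``g`` of the linear depth grading of the contaminating
        scale (factor ramps from ``1-g`` to ``1+g`` over each
        ``contamination_period`` depth voxels).
    contamination_period : int
        Depth period, in voxels, of the contamination grading ramp;
        defaults to the ROI depth extent (6) so a pooled ROI always spans
        one full ramp.
    decorrelation : float
        Speckle decorrelation between successive repeat frames in [0, 1].
    """

    region: Region
    base_scale: float
    shift: float = 0.0
    noise_floor_scale: float = 0.0
    depth_attenuation: float = 0.0
    rayleigh_purity: float = 1.0
    contamination_grade: float = 0.6
    contamination_period: int = 6
    decorrelation: float = 1.0

    def validate(self) -> None:
        if not self.base_scale > 0:
            raise ConfigurationError(
                f"{self.region.name}: base_scale must be > 0, got {self.base_scale}"
            )
        if self.noise_floor_scale < 0:
            raise ConfigurationError(f"{self.region.name}: noise_floor_scale < 0")
        if self.depth_attenuation < 0:
            raise ConfigurationError(f"{self.region.name}: depth_attenuation < 0")
        if not 0.0 <= self.rayleigh_purity <= 1.0:
            raise ConfigurationError(f"{self.region.name}: rayleigh_purity outside [0,1]")
        if not 0.0 <= self.decorrelation <= 1.0:
            raise ConfigurationError(f"{self.region.name}: decorrelation outside [0,1]")


@dataclass
class TubeSpec:
    """Micro-tube (lumen + wall) running along the slow axis; units um."""

    center_depth: float
    center_fast: float
    inner_diameter: float
    outer_diameter: float


@dataclass
class RodSpec:
    """Solid transparent rod along the slow axis; units um."""

    center_depth: float
    center_fast: float
    diameter: float


@dataclass
class PhantomConfig:
    """Full description of a synthetic phantom acquisition.

    Geometry is expressed in micrometres; voxel ``i`` along an axis with
    pitch ``p`` spans ``[i*p, (i+1)*p)`` and its centre sits at
    ``(i + 0.5) * p``.  Depth index 0 is the top of the volume.
    """

    volume_shape: tuple[int, int, int, int]  # (n_depth, n_fast, n_slow, n_repeat)
    voxel_pitch: tuple[float, float, float]  # (dz, dx, dy) um
    surface_depth: float  # air/medium interface, um
    noise_floor_depth: float  # top of the deep low-SNR band, um
    tube: TubeSpec
    rod: RodSpec
    region_models: dict[Region, RegionSpeckleModel]
    seed: int = 0

    def validate(self) -> None:
        nz, nx, ny, nrep = self.volume_shape
        if min(nz, nx, ny, nrep) < 1:
            raise ConfigurationError("all volume dimensions must be >= 1")
        if min(self.voxel_pitch) <= 0:
            raise ConfigurationError("voxel pitches must be positive")
        if not self.tube.inner_diameter < self.tube.outer_diameter:
            raise ConfigurationError("tube inner diameter must be < outer diameter")
        z_extent = nz * self.voxel_pitch[0]
        x_extent = nx * self.voxel_pitch[1]
        for name, cz, cx, radius in (
            ("tube", self.tube.center_depth, self.tube.center_fast, self.tube.outer_diameter / 2),
            ("rod", self.rod.center_depth, self.rod.center_fast, self.rod.diameter / 2),
        ):
            if cz - radius < 0 or cz + radius > z_extent or cx - radius < 0 or cx + radius > x_extent:
                raise ConfigurationError(
                    f"{name} (centre ({cz}, {cx}) um, radius {radius} um) "
                    f"does not fit inside the {z_extent} x {x_extent} um volume"
                )
        missing = [r.name for r in Region if r not in self.region_models]
        if missing:
            raise ConfigurationError(f"missing region models: {missing}")
        for model in self.region_models.values():
            model.validate()

    # ---- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "volume_shape": list(self.volume_shape),
            "voxel_pitch_um": list(self.voxel_pitch),
            "surface_depth_um": self.surface_depth,
            "noise_floor_depth_um": self.noise_floor_depth,
            "tube": {
                "center_depth_um": self.tube.center_depth,
                "center_fast_um": self.tube.center_fast,
                "inner_diameter_um": self.tube.inner_diameter,
                "outer_diameter_um": self.tube.outer_diameter,
            },
            "rod": {
                "center_depth_um": self.rod.center_depth,
                "center_fast_um": self.rod.center_fast,
                "diameter_um": self.rod.diameter,
            },
            "seed": self.seed,
            "regions": {
                region.name.lower(): {
                    k: v
                    for k, v in dataclasses.asdict(model).items()
                    if k != "region"
                }
                for region, model in sorted(self.region_models.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        tube = TubeSpec(
            center_depth=float(d["tube"]["center_depth_um"]),
            center_fast=float(d["tube"]["center_fast_um"]),
            inner_diameter=float(d["tube"]["inner_diameter_um"]),
            outer_diameter=float(d["tube"]["outer_diameter_um"]),
        )
        rod = RodSpec(
            center_depth=float(d["rod"]["center_depth_um"]),
            center_fast=float(d["rod"]["center_fast_um"]),
            diameter=float(d["rod"]["diameter_um"]),
        )
        models = {}
        for name, params in d["regions"].items():
            region = Region[name.upper()]
            models[region] = RegionSpeckleModel(region=region, **params)
        cfg = cls(
            volume_shape=tuple(int(v) for v in d["volume_shape"]),
            voxel_pitch=tuple(float(v) for v in d["voxel_pitch_um"]),
            surface_depth=float(d["surface_depth_um"]),
            noise_floor_depth=float(d["noise_floor_depth_um"]),
            tube=tube,
            rod=rod,
            region_models=models,
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg


@dataclass
class OCTVolume:
    """4-D OCT intensity volume, indexed (depth, fast, slow, repeat)."""

    intensity: np.ndarray  # float array, shape (nz, nx, ny, n_repeat)
    voxel_pitch: tuple[float, float, float]  # (dz, dx, dy) um

    def __post_init__(self) -> None:
        if self.intensity.ndim != 4:
            raise ValueError("intensity must be 4-D (depth, fast, slow, repeat)")
        if min(self.intensity.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if min(self.voxel_pitch) <= 0:
            raise ValueError("voxel pitches must be positive")

    @property
    def n_repeat(self) -> int:
        return self.intensity.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.intensity.shape[:3]


@dataclass
class LabelMap:
    """Voxel-wise ground-truth region labels on the volume's spatial grid."""

    labels: np.ndarray  # int array, shape (nz, nx, ny)

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3-D (depth, fast, slow)")

    def region_mask(self, region: Region) -> np.ndarray:
        return self.labels == int(region)

    def counts(self) -> dict[Region, int]:
        return {r: int(np.sum(self.labels == int(r))) for r in Region}


# ---------------------------------------------------------------------------
# geometry

def build_label_map(config: PhantomConfig) -> LabelMap:
    """Analytic ground-truth labels: a voxel belongs to a cylinder iff its
    centre lies strictly inside that cylinder's circle in the (depth, fast)
    plane; the lumen takes precedence over the wall, and both tube and rod
    take precedence over the air/noise depth bands."""
    nz, nx, ny, _ = config.volume_shape
    dz, dx, _ = config.voxel_pitch
    zc = (np.arange(nz) + 0.5) * dz
    xc = (np.arange(nx) + 0.5) * dx
    plane = np.full((nz, nx), int(Region.INTRALIPID), dtype=np.int16)
    plane[zc < config.surface_depth, :] = int(Region.AIR)
    plane[zc >= config.noise_floor_depth, :] = int(Region.NOISE)

    Z = zc[:, None]
    X = xc[None, :]
    r2_rod = (Z - config.rod.center_depth) ** 2 + (X - config.rod.center_fast) ** 2
    plane[r2_rod < (config.rod.diameter / 2) ** 2] = int(Region.TRANSPARENT_SOLID)
    r2_tube = (Z - config.tube.center_depth) ** 2 + (X - config.tube.center_fast) ** 2
    wall = (r2_tube < (config.tube.outer_diameter / 2) ** 2) & (
        r2_tube >= (config.tube.inner_diameter / 2) ** 2
    )
    plane[wall] = int(Region.SEMI_TRANSPARENT_SOLID)
    plane[r2_tube < (config.tube.inner_diameter / 2) ** 2] = int(Region.DYED_WATER)

    labels = np.repeat(plane[:, :, None], ny, axis=2)
    return LabelMap(labels=labels)


# ---------------------------------------------------------------------------
# speckle synthesis

def _fill_region(
    intensity: np.ndarray,
    mask: np.ndarray,
    model: RegionSpeckleModel,
    dz_um: float,
    rng: np.random.Generator,
) -> None:
    """Draw intensities for all voxels of one region, all repeats."""
    iz, ix, iy = np.nonzero(mask)
    n = iz.size
    if n == 0:
        return
    n_repeat = intensity.shape[3]

    # depth below the region's entry surface, per (fast, slow) column
    first = np.argmax(mask, axis=0)
    f = first[ix, iy]
    depth_below = (iz - f).astype(np.float64)

    sigma = model.base_scale * np.exp(-model.depth_attenuation * depth_below * dz_um)
    if model.rayleigh_purity < 1.0:
        contaminated = rng.random(n) >= model.rayleigh_purity
        period = max(int(model.contamination_period), 2)
        frac = np.mod(depth_below, period) / (period - 1)
        grade = 1.0 + model.contamination_grade * (2.0 * frac - 1.0)
        sigma = np.where(contaminated, sigma * grade, sigma)

    d = model.decorrelation
    z0 = rng.standard_normal((2, n))
    w_frozen = np.sqrt(1.0 - d)
    w_fresh = np.sqrt(d)
    for r in range(n_repeat):
        w = rng.standard_normal((2, n))
        re = w_frozen * z0[0] + w_fresh * w[0]
        im = w_frozen * z0[1] + w_fresh * w[1]
        amp = sigma * np.hypot(re, im)
        if model.noise_floor_scale > 0:
            nf = rng.standard_normal((2, n))
            amp = amp + model.noise_floor_scale * np.hypot(nf[0], nf[1])
        intensity[iz, ix, iy, r] = model.shift + amp


def generate_phantom(
    config: PhantomConfig, seed: int | None = None
) -> tuple[OCTVolume, LabelMap]:
    """Generate a phantom volume and its ground-truth label map.

    Parameters
    ----------
    config : PhantomConfig
        Validated phantom description.
    seed : int, optional
        Overrides ``config.seed``.

    Returns
    -------
    (OCTVolume, LabelMap)
        Intensity volume (float32) and voxel-exact labels.
    """
    config.validate()
    labelmap = build_label_map(config)
    nz, nx, ny, nrep = config.volume_shape
    intensity = np.empty((nz, nx, ny, nrep), dtype=np.float32)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    for region in Region:  # fixed order for reproducibility
        _fill_region(
            intensity,
            labelmap.region_mask(region),
            config.region_models[region],
            config.voxel_pitch[0],
            rng,
        )
    return OCTVolume(intensity=intensity, voxel_pitch=config.voxel_pitch), labelmap


def generate_region_volume(
    model: RegionSpeckleModel,
    shape: tuple[int, int, int, int],
    voxel_pitch: tuple[float, float, float] = (7.5, 7.5, 3.75),
    seed: int = 0,
) -> OCTVolume:
    """Generate a homogeneous single-region volume (handy for statistics
    tests and the flow study, where only the lumen material matters)."""
    model.validate()
    nz, nx, ny, nrep = shape
    intensity = np.empty(shape, dtype=np.float32)
    mask = np.ones((nz, nx, ny), dtype=bool)
    rng = np.random.default_rng(seed)
    _fill_region(intensity, mask, model, voxel_pitch[0], rng)
    return OCTVolume(intensity=intensity, voxel_pitch=voxel_pitch)


# ---------------------------------------------------------------------------
# I/O

_META_NAME = "meta.json"


def write_volume(volume: OCTVolume, labelmap: LabelMap | None, path: str | Path) -> None:
    """Write a volume as one multi-page TIFF per repeat (pages = depth
    slices) plus a JSON sidecar with shape/pitch metadata; the label map, if
    given, is written as an integer TIFF."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nrep = volume.n_repeat
    for r in range(nrep):
        tifffile.imwrite(
            path / f"intensity_rep{r:03d}.tif",
            np.asarray(volume.intensity[:, :, :, r], dtype=np.float32),
        )
    if labelmap is not None:
        tifffile.imwrite(path / "labels.tif", labelmap.labels.astype(np.int16))
    meta = {
        "shape": list(volume.intensity.shape),
        "voxel_pitch_um": list(volume.voxel_pitch),
        "n_repeat": nrep,
        "dtype": "float32",
        "axes": "depth,fast,slow,repeat",
    }
    (path / _META_NAME).write_text(json.dumps(meta, indent=2))


def read_volume(path: str | Path) -> tuple[OCTVolume, LabelMap | None]:
    """Read back a volume written by :func:`write_volume`.

    Raises
    ------
    MetadataError
        If the sidecar metadata file is missing or inconsistent.
    """
    path = Path(path)
    meta_path = path / _META_NAME
    if not meta_path.exists():
        raise MetadataError(f"missing sidecar metadata {meta_path}")
    meta = json.loads(meta_path.read_text())
    shape = tuple(meta["shape"])
    nrep = int(meta["n_repeat"])
    intensity = np.empty(shape, dtype=np.float32)
    for r in range(nrep):
        page = tifffile.imread(path / f"intensity_rep{r:03d}.tif")
        page = np.asarray(page).reshape(shape[:3])
        intensity[:, :, :, r] = page
    labels_path = path / "labels.tif"
    labelmap = None
    if labels_path.exists():
        labels = np.asarray(tifffile.imread(labels_path)).reshape(shape[:3])
        labelmap = LabelMap(labels=labels.astype(np.int16))
    volume = OCTVolume(
        intensity=intensity, voxel_pitch=tuple(meta["voxel_pitch_um"])
    )
    return volume, labelmap


# ---------------------------------------------------------------------------
# configuration files

def load_phantom_config(path: str | Path) -> PhantomConfig:
    """Load a phantom configuration from a YAML file."""
    with open(path) as fh:
        return PhantomConfig.from_dict(yaml.safe_load(fh))


def default_phantom_config() -> PhantomConfig:
    """The packaged default phantom: a 305/762 um PTFE-like tube and a
    400 um rod embedded in attenuating Intralipid-like background, imaged at
    7.5 x 7.5 x 3.75 um voxel pitch with 24 repeat frames."""
    from importlib import resources

    ref = resources.files("octspeckle").joinpath("data/phantom_default.yaml")
    with resources.as_file(ref) as p:
        return load_phantom_config(p)
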