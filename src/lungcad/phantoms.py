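"""Synthetic CT-like nodule phantoms.

Every downstream stage of the pipeline (denoising, preprocessing, feature
extraction, classification) is exercised on reproducible grayscale phantoms:
a square lung-field background carrying a single centered nodule whose
morphology depends on the class.  Benign nodules are near-elliptical and
smooth; malignant nodules carry sinusoidal radial spikes (spiculation), the
stellate boundary distortion radiologists associate with malignancy.

Intensities are on a conventional 8-bit-like scale (background ~60,
nodule contrast ~100 by default) so that additive Gaussian noise levels of
sigma 10-20 correspond to realistic low-dose CT noise.

Alongside each image the generator can draw a fixed-length "sensor" vector
from a class-conditional Gaussian, standing in for the tabular device
measurements that accompany the imaging data; the class mean shift is
configurable and defaults to a clearly informative separation.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PhantomSpec",
    "SensorRecord",
    "NoduleSample",
    "make_phantom",
    "add_noise",
    "make_dataset",
    "separable_dataset",
    "derive_seed",
    "write_dataset",
]

BENIGN = "benign"
MALIGNANT = "malignant"
CLASSES = (BENIGN, MALIGNANT)

#: relative radial amplitude of the spiculation perturbation at level 1.0
SPICULE_AMPLITUDE = 0.35
#: number of radial spikes (odd, so they never align with the ellipse axes)
SPICULE_COUNT = 9


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; identical specs give identical output."""

    image_size: int = 64
    voxel_spacing_mm: float = 1.0
    nodule_diameter_mm: float = 10.0
    nodule_class: str = BENIGN
    spiculation_level: float = 0.0
    contrast: float = 100.0
    noise_sigma: float = 0.0
    background: float = 60.0
    gradient_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.nodule_diameter_mm <= 0:
            raise ValueError("nodule_diameter_mm must be positive")
        if not 0.0 <= self.spiculation_level <= 1.0:
            raise ValueError("spiculation_level must lie in [0, 1]")
        if self.nodule_class not in CLASSES:
            raise ValueError(f"nodule_class must be one of {CLASSES}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.voxel_spacing_mm <= 0:
            raise ValueError("voxel_spacing_mm must be positive")


@dataclasses.dataclass(frozen=True)
class SensorRecord:
    """Fixed-length vector of real-valued device measurements plus its class."""

    values: np.ndarray
    label: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("sensor values must be finite")
        object.__setattr__(self, "values", v)


@dataclasses.dataclass
class NoduleSample:
    """One image patch with its nodule mask, label and optional sensor record."""

    image: np.ndarray
    mask: np.ndarray
    label: str
    spacing_mm: float
    sensor: Optional[SensorRecord] = None
    upper_lobe: Optional[bool] = None

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes must match")
        if not self.mask.any():
            raise ValueError("mask must be nonempty")
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}")


def derive_seed(master_seed: int, index: int) -> int:
    """Counter-based child seed: SeedSequence(master, spawn_key=(index,)).

    Datasets are extensible: sample ``index`` always receives the same seed
    regardless of how many samples are generated around it.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _nodule_boundary_radius(theta: np.ndarray, radius_px: float, axis_ratio: float,
                            orientation: float, spiculation: float,
                            phase: float) -> np.ndarray:
    """Polar boundary radius of an area-preserving ellipse with radial spikes."""
    a = radius_px * np.sqrt(axis_ratio)
    b = radius_px / np.sqrt(axis_ratio)
    phi = theta - orientation
    r = a * b / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    if spiculation > 0:
        r = r * (1.0 + SPICULE_AMPLITUDE * spiculation
                 * np.sin(SPICULE_COUNT * theta + phase))
    return r


def make_phantom(spec: PhantomSpec) -> NoduleSample:
    """Render one phantom: background + centered nodule, then optional noise.

    The nodule is an area-preserving ellipse (axis ratio drawn uniformly in
    [1, 1.4]) whose boundary radius is perturbed sinusoidally with amplitude
    proportional to ``spiculation_level``; the mask marks nodule pixels
    before the mild edge smoothing applied to the intensity image.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    radius_px = spec.nodule_diameter_mm / 2.0 / spec.voxel_spacing_mm
    max_extent = radius_px * np.sqrt(1.4) * (1.0 + SPICULE_AMPLITUDE)
    if max_extent >= n / 2.0 - 1:
        raise ValueError("nodule diameter exceeds the image extent")

    axis_ratio = rng.uniform(1.0, 1.4)
    orientation = rng.uniform(0.0, np.pi)
    phase = rng.uniform(0.0, 2 * np.pi)
    # sub-pixel center jitter keeps digital masks from all sharing one grid
    cy, cx = (n - 1) / 2.0 + rng.uniform(-0.5, 0.5, size=2)

    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = _nodule_boundary_radius(theta, radius_px, axis_ratio,
                                       orientation, spec.spiculation_level, phase)
    mask = rho <= boundary

    image = np.full((n, n), float(spec.background))
    if spec.gradient_amplitude:
        image += spec.gradient_amplitude * (yy / (n - 1) - 0.5)
    image[mask] += spec.contrast

    # mild partial-volume smoothing of the intensity edge (mask untouched)
    from scipy.ndimage import gaussian_filter
    image = gaussian_filter(image, sigma=0.7)

    if spec.noise_sigma > 0:
        image = add_noise(image, spec.noise_sigma, seed=derive_seed(spec.seed, 1))

    return NoduleSample(image=image, mask=mask, label=spec.nodule_class,
                        spacing_mm=spec.voxel_spacing_mm)


def add_noise(image: np.ndarray, noise_sigma: float, seed: int) -> np.ndarray:
    """Add i.i.d. Gaussian noise; ``noise_sigma == 0`` returns the input unchanged."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    image = np.asarray(image, dtype=float)
    if noise_sigma == 0:
        return image
    rng = np.random.default_rng(seed)
    return image + rng.normal(0.0, noise_sigma, size=image.shape)


def make_dataset(
    n: int,
    class_balance: float = 0.5,
    *,
    image_size: int = 64,
    voxel_spacing_mm: float = 1.0,
    benign_diameter_mm: tuple[float, float] = (6.0, 12.0),
    malignant_diameter_mm: tuple[float, float] = (8.0, 16.0),
    benign_spiculation: tuple[float, float] = (0.0, 0.15),
    malignant_spiculation: tuple[float, float] = (0.5, 0.9),
    contrast: float = 100.0,
    noise_sigma: float = 15.0,
    sensor_dim: int = 5,
    sensor_mean_shift: float = 3.0,
    sensor_sigma: float = 1.0,
    with_sensor: bool = True,
    seed: int = 0,
) -> list[NoduleSample]:
    """Generate ``n`` phantoms, ``round(n * class_balance)`` of them malignant.

    Per-sample seeds are derived from the master seed with :func:`derive_seed`
    so extending a dataset never reshuffles existing samples.  Sensor vectors
    are drawn from N(0, sensor_sigma) for benign and
    N(sensor_mean_shift, sensor_sigma) for malignant samples (every dimension
    shifted).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must lie strictly in (0, 1)")
    n_mal = int(round(n * class_balance))
    if n_mal == 0 or n_mal == n:
        raise ValueError("class balance unsatisfiable: one class would be empty")

    samples: list[NoduleSample] = []
    for i in range(n):
        label = MALIGNANT if i < n_mal else BENIGN
        child = derive_seed(seed, i)
        rng = np.random.default_rng(child)
        dia_rng = malignant_diameter_mm if label == MALIGNANT else benign_diameter_mm
        spic_rng = malignant_spiculation if label == MALIGNANT else benign_spiculation
        spec = PhantomSpec(
            image_size=image_size,
            voxel_spacing_mm=voxel_spacing_mm,
            nodule_diameter_mm=rng.uniform(*dia_rng),
            nodule_class=label,
            spiculation_level=rng.uniform(*spic_rng),
            contrast=contrast,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(2**31)),
        )
        sample = make_phantom(spec)
        sample.upper_lobe = bool(rng.integers(2))
        if with_sensor:
            mean = sensor_mean_shift if label == MALIGNANT else 0.0
            values = rng.normal(mean, sensor_sigma, size=sensor_dim)
            sample.sensor = SensorRecord(values=values, label=label)
        samples.append(sample)
    return samples


def separable_dataset(n: int = 120, *, image_size: int = 32, noise_sigma: float = 15.0,
                      seed: int = 0, with_sensor: bool = True) -> list[NoduleSample]:
    """A well-separated two-class set: small smooth benign nodules vs large
    spiculated malignant ones at nodule contrast three times the noise sigma.

    This is the study condition used for the classifier sanity checks.
    """
    spacing = 32.0 / image_size  # keep physical sizes fixed as pixels change
    return make_dataset(
        n,
        0.5,
        image_size=image_size,
        voxel_spacing_mm=spacing,
        benign_diameter_mm=(6.0, 9.0),
        malignant_diameter_mm=(13.0, 17.0),
        benign_spiculation=(0.0, 0.1),
        malignant_spiculation=(0.6, 0.9),
        contrast=3.0 * noise_sigma,
        noise_sigma=noise_sigma,
        seed=seed,
        with_sensor=with_sensor,
    )


def write_dataset(samples: Sequence[NoduleSample], out_dir: str) -> str:
    """Write images/masks as 16-bit PNG plus a manifest CSV; returns manifest path.

    Intensities are stored as ``round((value + 128) * 128)`` clipped to
    uint16: the offset keeps noise excursions below zero representable and
    the float scale survives a write/read round trip to 1/256.
    """
    import imageio.v3 as iio
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        img_path = os.path.join(out_dir, f"sample_{i:04d}.png")
        mask_path = os.path.join(out_dir, f"sample_{i:04d}_mask.png")
        img16 = np.clip(np.round((s.image + 128.0) * 128.0), 0,
                        65535).astype(np.uint16)
        iio.imwrite(img_path, img16)
        iio.imwrite(mask_path, (s.mask.astype(np.uint16) * 65535))
        row = {
            "sample_id": i,
            "image": os.path.basename(img_path),
            "mask": os.path.basename(mask_path),
            "label": s.label,
            "spacing_mm": s.spacing_mm,
            "upper_lobe": s.upper_lobe,
        }
        if s.sensor is not None:
            for j, v in enumerate(s.sensor.values):
                row[f"sensor_{j}"] = v
        rows.append(row)
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(manifest_path: str) -> list[NoduleSample]:
    """Load a dataset previously written by :func:`write_dataset`."""
    import imageio.v3 as iio
    import pandas as pd

    base = os.path.dirname(manifest_path)
    df = pd.read_csv(manifest_path)
    sensor_cols = sorted(c for c in df.columns if c.startswith("sensor_"))
    samples = []
    for _, row in df.iterrows():
        image = iio.imread(os.path.join(base, row["image"])
                           ).astype(float) / 128.0 - 128.0
        mask = iio.imread(os.path.join(base, row["mask"])) > 0
        sensor = None
        if sensor_cols:
            sensor = SensorRecord(values=row[sensor_cols].to_numpy(dtype=float),
                                  label=row["label"])
        samples.append(NoduleSample(image=image, mask=mask, label=row["label"],
                                    spacing_mm=float(row["spacing_mm"]),
                                    sensor=sensor,
                                    upper_lobe=bool(row["upper_lobe"])))
    return samples
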