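"""Synthetic low-contrast abdominal phantoms and dataset I/O.

The generator emulates the imaging conditions the segmentation model is
built for: a noisy, low-contrast CT-like slice containing an elliptical
organ cross-section (class 1) with one or more irregular lesion blobs
inside it (class 2) whose size varies over a wide range.  Geometry is
specified as fractions of the image size so one spec scales across
resolutions.  Images are stored as 16-bit grayscale PNGs (CT-like
dynamic range), masks as indexed 8-bit PNGs with the fixed palette
0 = background, 1 = organ, 2 = lesion; a plain-text manifest pairs them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


@dataclass
class PhantomSpec:
    """Generation parameters (geometry in fractions of the image size)."""
    size: int = 224
    background_band: tuple[float, float] = (0.38, 0.42)
    organ_offset: float = 0.12
    organ_axis_frac: tuple[float, float] = (0.20, 0.32)
    lesion_offset: float = 0.10
    lesion_count: tuple[int, int] = (1, 2)
    lesion_radius_frac: tuple[float, float] = (0.06, 0.14)
    irregularity: float = 0.25        # radial-perturbation amplitude
    noise_std: float = 0.02
    contrast: float = 0.6             # in (0, 1]; scales both tissue offsets

    def __post_init__(self):
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError("contrast factor must lie in (0, 1]")
        max_lesion = self.lesion_radius_frac[1] * (1.0 + self.irregularity)
        if max_lesion >= self.organ_axis_frac[0]:
            raise ValueError(
                "infeasible geometry: largest lesion radius "
                f"({max_lesion:.3f}) reaches the smallest organ axis "
                f"({self.organ_axis_frac[0]:.3f})")


@dataclass
class PhantomSample:
    image: np.ndarray                 # (H, W) uint16
    mask: np.ndarray                  # (H, W) uint8 in {0, 1, 2}
    seed: int
    geometry: dict = field(default_factory=dict)


def tiny_phantom_spec() -> PhantomSpec:
    return PhantomSpec(size=64)


def _blob_mask(size: int, center: np.ndarray, radius: float,
               irregularity: float, rng: np.random.Generator) -> np.ndarray:
    """Radially-perturbed disc: r(theta) = r0 (1 + a * low-order Fourier)."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    wobble = np.zeros_like(theta)
    for m in (2, 3, 4):
        c, s = rng.normal(size=2)
        wobble += c * np.cos(m * theta) + s * np.sin(m * theta)
    wobble /= np.sqrt(3.0)            # unit variance across harmonics
    r_theta = radius * np.clip(1.0 + irregularity * wobble, 0.3, 1.7)
    return dx ** 2 + dy ** 2 <= r_theta ** 2


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomSample:
    """Deterministic phantom for (spec, seed); mask rendered before noise."""
    rng = np.random.default_rng(seed)
    s = spec.size

    # organ: rotated ellipse near the image centre
    center = s / 2.0 + rng.uniform(-0.05, 0.05, size=2) * s
    axes = rng.uniform(*spec.organ_axis_frac, size=2) * s
    angle = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:s, 0:s]
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    organ = (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0

    n_lesions = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
    lesion = np.zeros_like(organ)
    lesions_meta = []
    for _ in range(n_lesions):
        radius = rng.uniform(*spec.lesion_radius_frac) * s
        rho = np.sqrt(rng.uniform()) * 0.75
        phi = rng.uniform(0.0, 2 * np.pi)
        off_u = (axes[0] - radius) * rho * np.cos(phi)
        off_v = (axes[1] - radius) * rho * np.sin(phi)
        lc = center + np.array([sa * off_u + ca * off_v, ca * off_u - sa * off_v])
        blob = _blob_mask(s, lc, radius, spec.irregularity, rng)
        lesion |= blob & organ        # lesion pixels always lie inside the organ
        lesions_meta.append({"center": lc.tolist(), "radius": float(radius)})

    mask = np.zeros((s, s), dtype=np.uint8)
    mask[organ] = 1
    mask[lesion] = 2

    background = rng.uniform(*spec.background_band)
    img = np.full((s, s), background)
    img += spec.organ_offset * spec.contrast * organ
    img += spec.lesion_offset * spec.contrast * lesion
    img += rng.normal(0.0, spec.noise_std, size=(s, s))
    image = (np.clip(img, 0.0, 1.0) * 65535.0).round().astype(np.uint16)

    geometry = {"organ_center": center.tolist(), "organ_axes": axes.tolist(),
                "organ_angle": float(angle), "lesions": lesions_meta,
                "background": float(background)}
    return PhantomSample(image=image, mask=mask, seed=seed, geometry=geometry)


def augment(sample: PhantomSample, seed: int,
            free_rotation: bool = False) -> PhantomSample:
    """Random flips and rotation, identical for image and mask.

    Default rotations are multiples of 90°, so the mask needs no
    resampling; `free_rotation` enables arbitrary angles with bilinear
    image and nearest-neighbour mask interpolation.
    """
    rng = np.random.default_rng(seed)
    img, mask = sample.image, sample.mask
    if rng.uniform() < 0.5:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.uniform() < 0.5:
        img, mask = img[::-1, :], mask[::-1, :]
    if free_rotation:
        angle = rng.uniform(0.0, 360.0)
        img = ndimage.rotate(img.astype(np.float64), angle, reshape=False,
                             order=1, mode="nearest").round().astype(np.uint16)
        mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                              mode="constant", cval=0)
    else:
        k = int(rng.integers(0, 4))
        img, mask = np.rot90(img, k), np.rot90(mask, k)
    return PhantomSample(image=np.ascontiguousarray(img),
                         mask=np.ascontiguousarray(mask),
                         seed=sample.seed, geometry=dict(sample.geometry))


_PALETTE = [0, 0, 0, 255, 220, 60, 220, 40, 40] + [0] * (256 * 3 - 9)


def write_dataset(samples: list[PhantomSample], directory: str | Path):
    """16-bit image PNGs + indexed mask PNGs + a tab-separated manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = ["image\tmask\tseed"]
    for i, s in enumerate(samples):
        if s.mask.max() > 2:
            raise ValueError(f"sample {i}: mask values outside palette {{0,1,2}}")
        img_name, mask_name = f"img_{i:04d}.png", f"mask_{i:04d}.png"
        Image.fromarray(s.image.astype(np.uint16)).save(directory / img_name)
        pm = Image.fromarray(s.mask, mode="P")
        pm.putpalette(_PALETTE)
        pm.save(directory / mask_name)
        rows.append(f"{img_name}\t{mask_name}\t{s.seed}")
    (directory / "manifest.tsv").write_text("\n".join(rows) + "\n")


def read_dataset(directory: str | Path) -> list[PhantomSample]:
    directory = Path(directory)
    manifest = directory / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv in {directory}")
    samples = []
    for line in manifest.read_text().splitlines()[1:]:
        img_name, mask_name, seed = line.split("\t")[:3]
        img_path, mask_path = directory / img_name, directory / mask_name
        if not img_path.exists() or not mask_path.exists():
            raise FileNotFoundError(f"missing pair {img_name} / {mask_name}")
        image = np.asarray(Image.open(img_path)).astype(np.uint16)
        mask = np.asarray(Image.open(mask_path)).astype(np.uint8)
        samples.append(PhantomSample(image=image, mask=mask, seed=int(seed)))
    return samples


def import_nifti(image_volume: str | Path, mask_volume: str | Path,
                 directory: str | Path) -> int:
    """Slice a NIfTI image/mask volume pair into a 2-D dataset.

    Slices along the last axis; the manifest records the slice index.
    Returns the number of slices written.
    """
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_vol = np.asanyarray(nib.load(str(image_volume)).dataobj).astype(np.float64)
    mask_vol = np.asanyarray(nib.load(str(mask_volume)).dataobj).astype(np.uint8)
    if img_vol.shape != mask_vol.shape:
        raise ValueError("image and mask volumes disagree in shape")
    lo, hi = img_vol.min(), img_vol.max()
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    rows = ["image\tmask\tseed\tslice"]
    for z in range(img_vol.shape[-1]):
        img = ((img_vol[..., z] - lo) * scale).round().astype(np.uint16)
        img_name, mask_name = f"img_{z:04d}.png", f"mask_{z:04d}.png"
        Image.fromarray(img).save(directory / img_name)
        pm = Image.fromarray(mask_vol[..., z], mode="P")
        pm.putpalette(_PALETTE)
        pm.save(directory / mask_name)
        rows.append(f"{img_name}\t{mask_name}\t-1\t{z}")
    (directory / "manifest.tsv").write_text("\n".join(rows) + "\n")
    return img_vol.shape[-1]


def to_model_input(sample: PhantomSample) -> np.ndarray:
    """Per-image min-max normalisation to [0, 1]; adds the channel axis."""
    img = sample.image.astype(np.float64)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    return img[None, :, :]
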