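"""Volume containers, NIfTI I/O, preprocessing/augmentation, and a
synthetic dual-modality lumbar-spine phantom generator.

The phantom stacks superellipsoidal vertebral bodies along the height axis
with thinner disc slabs between them, and assigns the expected tissue
contrast: vertebrae bright on the T1 channel (fatty marrow), discs bright
on the T2 channel (water-rich nucleus).  Rician-like noise and a smooth
multiplicative bias field emulate MR acquisition artifacts.  Arrays follow
the (depth, height, width) convention with depth as the sagittal slice
axis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "LabelScheme", "VolumePair", "LabelVolume", "PhantomConfig",
    "ScalarVolume", "generate_phantom", "to_three_class",
    "read_volume", "write_volume", "preprocess", "augment",
]


class LabelScheme(enum.Enum):
    THREE_CLASS = "three_class"   # 0 background, 1 vertebra, 2 disc
    TEN_CLASS = "ten_class"       # 0 bg, 1-5 L1..L5, 6-9 discs L1/L2..L4/L5

    @property
    def n_classes(self) -> int:
        return 3 if self is LabelScheme.THREE_CLASS else 10


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ScalarVolume:
    """A single-channel volume with geometry metadata."""
    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")


@dataclass
class VolumePair:
    """Co-registered T1/T2 intensity volumes."""
    t1: np.ndarray
    t2: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.t1 = np.asarray(self.t1, dtype=np.float32)
        self.t2 = np.asarray(self.t2, dtype=np.float32)
        if self.t1.shape != self.t2.shape:
            raise ValueError(
                f"t1/t2 shape mismatch: {self.t1.shape} vs {self.t2.shape}")
        if self.t1.ndim != 3:
            raise ValueError("volumes must be 3D (D, H, W)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if not (np.isfinite(self.t1).all() and np.isfinite(self.t2).all()):
            raise ValueError("volumes contain non-finite values")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape


@dataclass
class LabelVolume:
    """Integer voxel mask under a declared label scheme."""
    labels: np.ndarray
    scheme: LabelScheme = LabelScheme.THREE_CLASS
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (D, H, W)")
        lmax = int(self.labels.max(initial=0))
        lmin = int(self.labels.min(initial=0))
        if lmin < 0 or lmax >= self.scheme.n_classes:
            raise ValueError(
                f"label values [{lmin}, {lmax}] invalid for {self.scheme}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (48, 256, 256)
    n_vertebrae: int = 5
    noise_sigma: float = 0.03
    bias_strength: float = 0.1
    seed: int = 0
    spacing: tuple[float, float, float] = (4.5, 1.0, 1.0)

    def __post_init__(self):
        if self.n_vertebrae < 1 or self.n_vertebrae > 5:
            raise ValueError("n_vertebrae must be in 1..5 (ten-class scheme)")
        if any(s < 8 for s in self.shape):
            raise ValueError("every shape component must be >= 8")


# base intensities per structure; noiseless voxels equal base * bias field
_T1_BASE = {"background": 0.15, "vertebra": 1.0, "disc": 0.35}
_T2_BASE = {"background": 0.15, "vertebra": 0.4, "disc": 1.0}


def _layout(shape: tuple[int, int, int], n_vert: int):
    """Height-axis extents of vertebrae and discs; raises if H is too small."""
    H = shape[1]
    margin = max(1, H // 16)
    usable = H - 2 * margin
    # vertebra height hv, disc height hv // 2 -> total = hv * (3n - 1) / 2
    hv = (2 * usable) // (3 * n_vert - 1)
    hd = hv // 2
    if hv < 3 or hd < 1:
        min_h = int(np.ceil(3 * (3 * n_vert - 1) / 2)) + 2 * margin
        raise ValueError(
            f"height {H} too small for {n_vert} vertebrae; "
            f"minimum height is {min_h}")
    spans = []
    y = margin
    for i in range(n_vert):
        spans.append(("vertebra", i + 1, y, y + hv))
        y += hv
        if i < n_vert - 1:
            spans.append(("disc", 6 + i, y, y + hd))  # disc below vertebra i+1
            y += hd
    return spans


def _superellipsoid(dd, hh, ww, centre, radii, orders) -> np.ndarray:
    terms = (np.abs((dd - centre[0]) / radii[0]) ** orders[0]
             + np.abs((hh - centre[1]) / radii[1]) ** orders[1]
             + np.abs((ww - centre[2]) / radii[2]) ** orders[2])
    return terms <= 1.0


def _bias_field(shape, strength: float, rng: np.random.Generator) -> np.ndarray:
    if strength == 0.0:
        return np.ones(shape, dtype=np.float64)
    axes = [np.linspace(0.0, np.pi, n) for n in shape]
    dd, hh, ww = np.meshgrid(*axes, indexing="ij")
    phase = rng.uniform(0.0, 2.0 * np.pi, size=3)
    amp = rng.uniform(0.5, 1.0, size=3)
    field = (amp[0] * np.cos(dd + phase[0]) + amp[1] * np.cos(hh + phase[1])
             + amp[2] * np.cos(ww + phase[2])) / amp.sum()
    return 1.0 + strength * field


def generate_phantom(cfg: PhantomConfig) -> tuple[VolumePair, LabelVolume]:
    """Build a deterministic dual-contrast spine phantom with its mask."""
    rng = np.random.default_rng(cfg.seed)
    D, H, W = cfg.shape
    labels = np.zeros(cfg.shape, dtype=np.int64)
    dd, hh, ww = np.meshgrid(np.arange(D), np.arange(H), np.arange(W),
                             indexing="ij")
    d_c, w_c = (D - 1) / 2.0, (W - 1) / 2.0
    rd = max(1.5, 0.35 * D)
    rw = max(1.5, 0.30 * W)
    for kind, lab, y0, y1 in _layout(cfg.shape, cfg.n_vertebrae):
        h_c = (y0 + y1 - 1) / 2.0
        rh = max(0.75, (y1 - y0) / 2.0)
        if kind == "vertebra":
            mask = _superellipsoid(dd, hh, ww, (d_c, h_c, w_c),
                                   (rd, rh, rw), (4, 4, 4))
        else:  # disc: wider, flatter slab
            mask = _superellipsoid(dd, hh, ww, (d_c, h_c, w_c),
                                   (rd, rh, 1.1 * rw), (4, 6, 4))
        labels[mask] = lab

    vert = (labels >= 1) & (labels <= 5)
    disc = labels >= 6
    t1 = np.full(cfg.shape, _T1_BASE["background"])
    t2 = np.full(cfg.shape, _T2_BASE["background"])
    t1[vert], t2[vert] = _T1_BASE["vertebra"], _T2_BASE["vertebra"]
    t1[disc], t2[disc] = _T1_BASE["disc"], _T2_BASE["disc"]

    bias = _bias_field(cfg.shape, cfg.bias_strength, rng)
    t1, t2 = t1 * bias, t2 * bias

    if cfg.noise_sigma > 0.0:
        # Rician: magnitude of the signal plus complex Gaussian noise
        contrast = max(_T1_BASE.values()) - min(_T1_BASE.values())
        sigma = cfg.noise_sigma * contrast
        for img in (t1, t2):
            re = img + rng.normal(0.0, sigma, size=cfg.shape)
            im = rng.normal(0.0, sigma, size=cfg.shape)
            img[...] = np.hypot(re, im)

    pair = VolumePair(t1.astype(np.float32), t2.astype(np.float32),
                      spacing=cfg.spacing)
    mask = LabelVolume(labels, scheme=LabelScheme.TEN_CLASS,
                       spacing=cfg.spacing)
    return pair, mask


def to_three_class(mask: LabelVolume) -> LabelVolume:
    """Collapse the ten-class scheme to background/vertebra/disc."""
    if mask.scheme is not LabelScheme.TEN_CLASS:
        raise ValueError(f"expected a TEN_CLASS mask, got {mask.scheme}")
    out = np.zeros_like(mask.labels)
    out[(mask.labels >= 1) & (mask.labels <= 5)] = 1
    out[mask.labels >= 6] = 2
    return LabelVolume(out, scheme=LabelScheme.THREE_CLASS,
                       spacing=mask.spacing)


def write_volume(vol: ScalarVolume | np.ndarray, path: str | Path,
                 spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 affine: np.ndarray | None = None) -> None:
    if isinstance(vol, ScalarVolume):
        data, spacing, affine = vol.data, vol.spacing, vol.affine
    else:
        data = np.asarray(vol)
    if data.ndim != 3:
        raise ValueError(f"can only write 3D volumes, got ndim={data.ndim}")
    if affine is None:
        affine = _default_affine(spacing)
    if np.issubdtype(data.dtype, np.integer):
        img = nib.Nifti1Image(data.astype(np.int16), affine)
    else:
        img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ScalarVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D image (ndim={data.ndim})")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarVolume(data, spacing, np.asarray(img.affine))


def _zoom_channel(data: np.ndarray, target: tuple[int, int, int],
                  order: int) -> np.ndarray:
    factors = [t / s for t, s in zip(target, data.shape)]
    out = ndimage.zoom(data, factors, order=order, mode="nearest",
                       grid_mode=True)
    # zoom can be off by one voxel on awkward ratios; crop/pad to be exact
    slices = tuple(slice(0, t) for t in target)
    out = out[slices]
    pads = [(0, t - s) for t, s in zip(target, out.shape)]
    if any(p[1] for p in pads):
        out = np.pad(out, pads, mode="edge")
    return out


def preprocess(vol: VolumePair, target_depth: int = 48, target_hw: int = 256,
               standardize: bool = True) -> VolumePair:
    """Resample to (target_depth, target_hw, target_hw) and z-score."""
    if any(s < 2 for s in vol.shape):
        raise ValueError(f"degenerate input shape {vol.shape}")
    target = (target_depth, target_hw, target_hw)
    channels = []
    for data in (vol.t1, vol.t2):
        out = _zoom_channel(data.astype(np.float64), target, order=1)
        if standardize:
            out = (out - out.mean()) / max(out.std(), 1e-12)
        channels.append(out.astype(np.float32))
    new_spacing = tuple(sp * s / t
                        for sp, s, t in zip(vol.spacing, vol.shape, target))
    return VolumePair(channels[0], channels[1], spacing=new_spacing)


def resize_mask(mask: LabelVolume, target: tuple[int, int, int]) -> LabelVolume:
    out = _zoom_channel(mask.labels.astype(np.float64), target, order=0)
    new_spacing = tuple(sp * s / t
                        for sp, s, t in zip(mask.spacing, mask.shape, target))
    return LabelVolume(np.rint(out).astype(mask.labels.dtype),
                       scheme=mask.scheme, spacing=new_spacing)


def augment(vol: VolumePair, mask: LabelVolume, seed: int,
            max_rotation_deg: float = 10.0,
            crop_fraction: float = 0.9) -> tuple[VolumePair, LabelVolume]:
    """Seeded in-plane rotation plus random crop, applied identically to the
    intensity pair (linear interpolation) and the mask (nearest)."""
    if vol.shape != mask.shape:
        raise ValueError(
            f"volume/mask shape mismatch: {vol.shape} vs {mask.shape}")
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg) \
        if max_rotation_deg > 0 else 0.0
    t1, t2 = vol.t1, vol.t2
    labels = mask.labels
    if angle != 0.0:
        t1 = ndimage.rotate(t1, angle, axes=(1, 2), reshape=False, order=1,
                            mode="nearest")
        t2 = ndimage.rotate(t2, angle, axes=(1, 2), reshape=False, order=1,
                            mode="nearest")
        labels = ndimage.rotate(labels, angle, axes=(1, 2), reshape=False,
                                order=0, mode="nearest")
    if crop_fraction < 1.0:
        new_shape = tuple(max(1, int(round(s * crop_fraction)))
                          for s in vol.shape)
        starts = [int(rng.integers(0, s - n + 1))
                  for s, n in zip(vol.shape, new_shape)]
        sl = tuple(slice(st, st + n) for st, n in zip(starts, new_shape))
        t1, t2, labels = t1[sl], t2[sl], labels[sl]
    return (VolumePair(t1, t2, spacing=vol.spacing),
            LabelVolume(np.ascontiguousarray(labels), scheme=mask.scheme,
                        spacing=mask.spacing))
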