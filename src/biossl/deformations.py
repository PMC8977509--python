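"""Random deformations that create positive view pairs, and the
temporal-window negative selection.

Two independently deformed copies of each image in a batch stand in for two
consecutive observations of the same object under changed viewpoint and
lighting: a random resized crop (shift + zoom of the field of view), a
random horizontal flip, colour jitter (brightness, contrast, saturation,
hue) and a random change to grayscale. Negatives for each anchor are the
``T`` batch items that cyclically follow it — the batch is read as a
temporal stream and the memory of the anchor only spans a few nearby
observations.

Images are channel-first float arrays in ``[0, 1]``. Resized crops use
bilinear interpolation; affine transforms fill uncovered pixels with zero.
Jitter is applied in a fixed order (brightness, contrast, saturation, hue)
for reproducibility; single-channel images receive brightness and contrast
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .model_core import ConfigurationError

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class DeformationConfig:
    crop_size: int = 28
    crop_scale_range: tuple = (0.2, 1.0)  # area fraction of the source image
    flip_prob: float = 0.5
    jitter_strengths: tuple = (0.4, 0.4, 0.4, 0.1)  # brightness, contrast, sat, hue
    grayscale_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.crop_scale_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("crop_scale_range must lie in (0, 1]")
        for p in (self.flip_prob, self.grayscale_prob):
            if not 0 <= p <= 1:
                raise ConfigurationError("probabilities must lie in [0, 1]")


@dataclass
class AffineConfig:
    """Test-time affine deformations (rotation / shear / translation)."""

    rotation_deg: float = 25.0
    translate_frac: float = 0.15
    shear_deg: float = 10.0
    seed: int = 0


@dataclass
class ViewBatch:
    view_A: np.ndarray
    view_B: np.ndarray
    negatives: np.ndarray | None = None  # (n, T) index array

    @property
    def n(self) -> int:
        return self.view_A.shape[0]


# ---------------------------------------------------------------------------
# negative selection

def select_negatives(n: int, T: int, anchor: int) -> np.ndarray:
    """The ``T`` batch indices cyclically following the anchor.

    Reading the batch as a temporal stream, these are the observations
    closest in time to the anchor; the anchor itself is excluded.
    """
    if not 1 <= T <= n - 1:
        raise ConfigurationError(f"need 1 <= T <= n-1, got T={T}, n={n}")
    return (anchor + 1 + np.arange(T)) % n


def negative_sets(n: int, T: int) -> np.ndarray:
    """(n, T) array stacking :func:`select_negatives` over all anchors."""
    if not 1 <= T <= n - 1:
        raise ConfigurationError(f"need 1 <= T <= n-1, got T={T}, n={n}")
    return (np.arange(n)[:, None] + 1 + np.arange(T)[None, :]) % n


# ---------------------------------------------------------------------------
# single-image deformation primitives

def _resized_crop(img: np.ndarray, rng: np.random.Generator, cfg: DeformationConfig):
    c, h, w = img.shape
    lo, hi = cfg.crop_scale_range
    frac = rng.uniform(lo, hi)
    side = max(1, int(round(np.sqrt(frac * h * w))))
    side = min(side, h, w)
    top = rng.integers(0, h - side + 1)
    left = rng.integers(0, w - side + 1)
    patch = img[:, top : top + side, left : left + side]
    if side == cfg.crop_size:
        return patch.copy()
    out = resize(
        patch,
        (c, cfg.crop_size, cfg.crop_size),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return out.astype(img.dtype)


def _jitter(img: np.ndarray, rng: np.random.Generator, strengths) -> np.ndarray:
    bs, cs, ss, hs = strengths
    c = img.shape[0]
    out = img
    if bs > 0:
        out = out * rng.uniform(1 - bs, 1 + bs)
    if cs > 0:
        f = rng.uniform(1 - cs, 1 + cs)
        out = (out - out.mean()) * f + out.mean()
    if c == 3:
        if ss > 0:
            f = rng.uniform(1 - ss, 1 + ss)
            gray = np.tensordot(_LUMA, out, axes=(0, 0))
            out = gray[None] + (out - gray[None]) * f
        if hs > 0:
            # hue rotation in the YIQ-like chroma plane; cheap and invertible
            theta = rng.uniform(-hs, hs) * 2 * np.pi
            gray = np.tensordot(_LUMA, out, axes=(0, 0))
            chroma = out - gray[None]
            cosb, sinb = np.cos(theta), np.sin(theta)
            rot = np.array(
                [
                    [cosb, -sinb, 0.0],
                    [sinb, cosb, 0.0],
                    [0.0, 0.0, 1.0],
                ]
            )
            out = gray[None] + np.tensordot(rot, chroma, axes=(1, 0))
    return np.clip(out, 0.0, 1.0)


def _deform_one(img: np.ndarray, rng: np.random.Generator,
                cfg: DeformationConfig) -> np.ndarray:
    out = _resized_crop(img, rng, cfg)
    if rng.uniform() < cfg.flip_prob:
        out = out[:, :, ::-1]
    out = _jitter(out, rng, cfg.jitter_strengths)
    if out.shape[0] == 3 and rng.uniform() < cfg.grayscale_prob:
        gray = np.tensordot(_LUMA, out, axes=(0, 0))
        out = np.repeat(gray[None], 3, axis=0)
    return np.ascontiguousarray(out, dtype=img.dtype)


def _affine_one(img: np.ndarray, rot_deg: float, shear_deg: float,
                dx: float, dy: float) -> np.ndarray:
    """Rotate/shear about the image centre, then translate; zero fill."""
    c, h, w = img.shape
    a = np.deg2rad(rot_deg)
    s = np.deg2rad(shear_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    shear = np.array([[1.0, np.tan(s)], [0.0, 1.0]])
    m = rot @ shear  # output->input mapping uses the inverse below
    minv = np.linalg.inv(m)
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = centre - minv @ (centre + np.array([dy, dx]))
    out = np.empty_like(img)
    for ch in range(c):
        out[ch] = ndimage.affine_transform(
            img[ch], minv, offset=offset, order=1, mode="constant", cval=0.0
        )
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# batch operations

def make_views(batch: np.ndarray, cfg: DeformationConfig,
               n_negatives: int | None = None) -> ViewBatch:
    """Create two independently deformed copies of every image in a batch.

    Deformation draws are independent between the two branches and across
    images, and reproducible from ``cfg.seed``. When ``n_negatives`` is
    given, the cyclic temporal negative sets are attached.
    """
    batch = np.asarray(batch)
    if batch.ndim != 4 or batch.shape[0] == 0:
        raise ConfigurationError("batch must be a nonempty (N, C, H, W) array")
    if cfg.crop_size > min(batch.shape[2], batch.shape[3]):
        raise ConfigurationError(
            f"crop_size {cfg.crop_size} exceeds image size {batch.shape[2:]}"
        )
    rng = np.random.default_rng(cfg.seed)
    n = batch.shape[0]
    view_a = np.stack([_deform_one(batch[i], rng, cfg) for i in range(n)])
    view_b = np.stack([_deform_one(batch[i], rng, cfg) for i in range(n)])
    negs = negative_sets(n, n_negatives) if n_negatives else None
    return ViewBatch(view_A=view_a, view_B=view_b, negatives=negs)


def deform_test_set(batch: np.ndarray, cfg) -> np.ndarray:
    """One deformed copy per image, for robustness evaluation.

    ``cfg`` is either a :class:`DeformationConfig` (crop/flip/jitter
    families) or an :class:`AffineConfig` (rotation/shear/translation).
    """
    batch = np.asarray(batch)
    if batch.ndim != 4 or batch.shape[0] == 0:
        raise ConfigurationError("batch must be a nonempty (N, C, H, W) array")
    if isinstance(cfg, AffineConfig):
        rng = np.random.default_rng(cfg.seed)
        h, w = batch.shape[2], batch.shape[3]
        out = np.empty_like(batch)
        for i in range(batch.shape[0]):
            rot = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
            shr = rng.uniform(-cfg.shear_deg, cfg.shear_deg)
            dx = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * w
            dy = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * h
            out[i] = _affine_one(batch[i], rot, shr, dx, dy)
        return out
    rng = np.random.default_rng(cfg.seed)
    return np.stack([_deform_one(batch[i], rng, cfg) for i in range(batch.shape[0])])


def view_stream(images: np.ndarray, batch_size: int, cfg: DeformationConfig,
                n_negatives: int, seed: int):
    """Endless generator of :class:`ViewBatch` with per-epoch shuffling.

    Every batch gets a fresh deformation seed derived from ``seed`` so runs
    are reproducible end to end.
    """
    rng = np.random.default_rng(seed)
    n = images.shape[0]
    step = 0
    while True:
        order = rng.permutation(n)
        for i in range(0, n - batch_size + 1, batch_size):
            idx = order[i : i + batch_size]
            bcfg = DeformationConfig(
                crop_size=cfg.crop_size,
                crop_scale_range=cfg.crop_scale_range,
                flip_prob=cfg.flip_prob,
                jitter_strengths=cfg.jitter_strengths,
                grayscale_prob=cfg.grayscale_prob,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            yield make_views(images[idx], bcfg, n_negatives=n_negatives)
            step += 1
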