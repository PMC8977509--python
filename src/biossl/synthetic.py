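"""Synthetic labeled image sets with known class structure.

Classes are parametric shape families (bars, rings, discs, crosses, ...)
rendered onto small grayscale or RGB canvases. Within a class, images vary
by nuisance parameters — position, scale and intensity — plus pixel noise,
so that class identity is carried by global shape and survives the crop /
flip / jitter / affine deformation families used elsewhere in the package:
a deformed image keeps its label by construction.

The default fixture (4 classes, 28x28, 1 channel, 500 images per class)
is sized so a full SSL-pretrain + linear-probe cycle runs in minutes on a
single CPU. A disjoint-class pair of datasets supports the
encoder-on-X / classifier-on-Y transfer protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .model_core import ConfigurationError

FAMILIES = (
    "h_bars",
    "v_bars",
    "ring",
    "cross",
    "disc",
    "checker",
    "diag",
    "dots",
)


@dataclass
class SyntheticDatasetSpec:
    n_classes: int = 4
    images_per_class: int = 500
    image_size: int = 28
    channels: int = 1
    families: tuple = ()  # defaults to the first n_classes of FAMILIES
    pos_jitter: int = 1  # max |offset| of the shape centre, pixels
    scale_range: tuple = (0.8, 1.2)
    intensity_range: tuple = (0.5, 1.0)
    noise_sigma: float = 0.08
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not self.families:
            if self.n_classes > len(FAMILIES):
                raise ConfigurationError(
                    f"at most {len(FAMILIES)} classes without custom families"
                )
            self.families = FAMILIES[: self.n_classes]
        if self.image_size < 12:
            raise ConfigurationError("image_size too small for the shape families")


@dataclass
class Dataset:
    images: np.ndarray  # (N, C, H, W) float32 in [0, 1]
    labels: np.ndarray  # (N,) int64
    train_idx: np.ndarray
    test_idx: np.ndarray
    spec: SyntheticDatasetSpec | None = None

    @property
    def train(self):
        return self.images[self.train_idx], self.labels[self.train_idx]

    @property
    def test(self):
        return self.images[self.test_idx], self.labels[self.test_idx]


# ---------------------------------------------------------------------------
# shape rendering

def _render(family: str, size: int, cx: float, cy: float, scale: float) -> np.ndarray:
    """Render one shape family on a ``size x size`` canvas, values in [0,1]."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    y = (yy - cy) / scale
    x = (xx - cx) / scale
    r = np.hypot(x, y)
    s = size / 28.0  # shapes are parameterised at the 28-px reference scale
    img = np.zeros((size, size))
    if family == "h_bars":
        img = (np.abs(np.sin(y * np.pi / (4.0 * s))) > 0.72).astype(float)
        img[np.abs(y) > 11 * s] = 0.0
        img[np.abs(x) > 11 * s] = 0.0
    elif family == "v_bars":
        img = (np.abs(np.sin(x * np.pi / (4.0 * s))) > 0.72).astype(float)
        img[np.abs(y) > 11 * s] = 0.0
        img[np.abs(x) > 11 * s] = 0.0
    elif family == "ring":
        img = (np.abs(r - 8.0 * s) < 1.6 * s).astype(float)
    elif family == "cross":
        img = ((np.abs(x) < 1.8 * s) | (np.abs(y) < 1.8 * s)).astype(float)
        img[r > 10 * s] = 0.0
    elif family == "disc":
        img = (r < 6.0 * s).astype(float)
    elif family == "checker":
        cell = 4.0 * s
        img = (((np.floor(x / cell) + np.floor(y / cell)) % 2) == 0).astype(float)
        img[r > 10 * s] = 0.0
    elif family == "diag":
        img = (np.abs(np.sin((x + y) * np.pi / (5.5 * s))) > 0.75).astype(float)
        img[np.abs(x) > 11 * s] = 0.0
        img[np.abs(y) > 11 * s] = 0.0
    elif family == "dots":
        cell = 6.0 * s
        gx = x - (np.floor(x / cell) + 0.5) * cell
        gy = y - (np.floor(y / cell) + 0.5) * cell
        img = (np.hypot(gx, gy) < 1.8 * s).astype(float)
        img[r > 11 * s] = 0.0
    else:
        raise ConfigurationError(f"unknown shape family {family!r}")
    return img


def generate(spec: SyntheticDatasetSpec) -> Dataset:
    """Generate a labeled, class-balanced dataset with a stratified split."""
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    n_total = spec.n_classes * spec.images_per_class
    images = np.zeros((n_total, spec.channels, size, size), dtype=np.float32)
    labels = np.zeros(n_total, dtype=np.int64)
    i = 0
    centre = (size - 1) / 2.0
    for cls, family in enumerate(spec.families[: spec.n_classes]):
        for _ in range(spec.images_per_class):
            cx = centre + rng.uniform(-spec.pos_jitter, spec.pos_jitter)
            cy = centre + rng.uniform(-spec.pos_jitter, spec.pos_jitter)
            scale = rng.uniform(*spec.scale_range)
            inten = rng.uniform(*spec.intensity_range)
            canvas = _render(family, size, cx, cy, scale) * inten
            img = np.repeat(canvas[None], spec.channels, axis=0)
            if spec.channels == 3:
                # per-channel gain gives each image a colour cast
                img = img * rng.uniform(0.6, 1.0, size=(3, 1, 1))
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
            images[i] = np.clip(img, 0.0, 1.0)
            labels[i] = cls
            i += 1
    # stratified split: the last test_fraction of each class block
    n_test_pc = int(round(spec.images_per_class * spec.test_fraction))
    train_idx, test_idx = [], []
    for cls in range(spec.n_classes):
        block = np.arange(cls * spec.images_per_class, (cls + 1) * spec.images_per_class)
        perm = rng.permutation(block)
        test_idx.append(perm[:n_test_pc])
        train_idx.append(perm[n_test_pc:])
    return Dataset(
        images=images,
        labels=labels,
        train_idx=np.sort(np.concatenate(train_idx)),
        test_idx=np.sort(np.concatenate(test_idx)),
        spec=spec,
    )


def disjoint_pair(spec: SyntheticDatasetSpec):
    """Two datasets over disjoint class sets (encoder-on-X / probe-on-Y).

    The encoder set uses families ``[0, n)``, the probe set families
    ``[n, 2n)``; both follow ``spec`` otherwise.
    """
    if 2 * spec.n_classes > len(FAMILIES):
        raise ConfigurationError("not enough shape families for a disjoint pair")
    enc_spec = SyntheticDatasetSpec(**{**asdict(spec), "families": ()})
    probe_spec = SyntheticDatasetSpec(
        **{
            **asdict(spec),
            "families": FAMILIES[spec.n_classes : 2 * spec.n_classes],
            "seed": spec.seed + 1,
        }
    )
    return generate(enc_spec), generate(probe_spec)


# ---------------------------------------------------------------------------
# export / import

def export(ds: Dataset, path) -> None:
    """Write the dataset as an array archive plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(
        path / "arrays.npz",
        images=ds.images,
        labels=ds.labels,
        train_idx=ds.train_idx,
        test_idx=ds.test_idx,
    )
    manifest = {"spec": asdict(ds.spec) if ds.spec else None}
    if manifest["spec"] is not None:
        manifest["spec"]["families"] = list(manifest["spec"]["families"])
        for k in ("scale_range", "intensity_range"):
            manifest["spec"][k] = list(manifest["spec"][k])
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load(path) -> Dataset:
    path = Path(path)
    data = np.load(path / "arrays.npz")
    manifest = json.loads((path / "manifest.json").read_text())
    spec = None
    if manifest.get("spec"):
        d = manifest["spec"]
        d["families"] = tuple(d["families"])
        d["scale_range"] = tuple(d["scale_range"])
        d["intensity_range"] = tuple(d["intensity_range"])
        spec = SyntheticDatasetSpec(**d)
    return Dataset(
        images=data["images"],
        labels=data["labels"],
        train_idx=data["train_idx"],
        test_idx=data["test_idx"],
        spec=spec,
    )
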