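"""Pseudo-retinal front end: pooling, rate coding, synthetic patterns.

Images are reduced by repeated 2x2/stride-2 average pooling (the horizontal
and amacrine networks), then each pooled "ganglion" cell emits a Poisson
spike train whose rate is proportional to the pooled intensity.  A 28x28
input becomes a 7x7 spike-train array after two stages; a 32x32 input
becomes 8x8.  The internal bipolar/ganglion dynamics of the biological
pathway are not modeled; the rate-coded surrogate preserves the interface.

The module also contains the synthetic pattern generator used throughout
the test suite: oriented bar/blob prototypes plus Gaussian pixel noise,
a desk-scale stand-in for handwritten-digit or natural-image data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EncoderConfig",
    "SpikeArray",
    "pool",
    "pool_stages",
    "encode",
    "make_patterns",
    "PatternSet",
]


@dataclass(frozen=True)
class EncoderConfig:
    window: int = 2
    stride: int = 2
    n_pool_stages: int = 2
    rate_max: float = 60.0   # Hz at intensity 1.0
    duration: float = 500.0  # ms
    seed: int = 0


@dataclass
class SpikeArray:
    """Grid of ganglion spike trains (times in ms, sorted, < duration)."""

    shape: tuple[int, int]
    trains: list  # row-major list of 1-D ndarrays of spike times
    duration: float

    def __getitem__(self, rc):
        r, c = rc
        return self.trains[r * self.shape[1] + c]

    @property
    def n_cells(self) -> int:
        return self.shape[0] * self.shape[1]

    def counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains]).reshape(self.shape)

    def to_text(self, path) -> None:
        """Columnar event list: cell_row cell_col t."""
        with open(path, "w") as fh:
            fh.write("# cell_row cell_col t\n")
            for r in range(self.shape[0]):
                for c in range(self.shape[1]):
                    for t in self[r, c]:
                        fh.write(f"{r} {c} {float(t)!r}\n")


def pool(image, window: int = 2, stride: int = 2) -> np.ndarray:
    """Average-pool one stage; dimensions must divide evenly."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # color: reduce to luminance first
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError("image must be 2-D (or HxWx3 color)")
    h, w = img.shape
    if window != stride:
        raise NotImplementedError("only non-overlapping pooling is supported")
    if h % stride or w % stride:
        raise ValueError(f"shape {img.shape} not divisible by stride {stride}")
    return img.reshape(h // stride, stride, w // stride, stride).mean(axis=(1, 3))


def pool_stages(image, cfg: EncoderConfig) -> np.ndarray:
    out = np.asarray(image, dtype=float)
    for _ in range(cfg.n_pool_stages):
        out = pool(out, cfg.window, cfg.stride)
    return out


def encode(image, cfg: EncoderConfig) -> SpikeArray:
    """Image -> ganglion spike trains (homogeneous Poisson per cell).

    Intensities must lie in [0, 1]; the per-cell rate is
    ``rate_max * pooled_intensity``.
    """
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    pooled = pool_stages(img, cfg)
    rng = np.random.default_rng(cfg.seed)
    trains = []
    for rate in pooled.ravel():
        lam = rate * cfg.rate_max / 1000.0  # events per ms
        n = rng.poisson(lam * cfg.duration)
        t = np.sort(rng.uniform(0.0, cfg.duration, size=n))
        trains.append(t)
    return SpikeArray(shape=pooled.shape, trains=trains,
                      duration=cfg.duration)


# ---------------------------------------------------------------------------
# Synthetic labeled patterns.
# ---------------------------------------------------------------------------

@dataclass
class PatternSet:
    images: np.ndarray  # (n, h, w) in [0, 1]
    labels: np.ndarray  # (n,)
    prototypes: np.ndarray = field(repr=False, default=None)

    def __len__(self):
        return self.labels.size

    def split(self, n_train_per_class: int):
        """Deterministic class-balanced train/test split."""
        tr, te = [], []
        for cls in np.unique(self.labels):
            idx = np.nonzero(self.labels == cls)[0]
            tr.extend(idx[:n_train_per_class])
            te.extend(idx[n_train_per_class:])
        tr, te = np.array(tr), np.array(te)
        return (PatternSet(self.images[tr], self.labels[tr], self.prototypes),
                PatternSet(self.images[te], self.labels[te], self.prototypes))


def _prototype(cls: int, shape: tuple[int, int]) -> np.ndarray:
    """Distinct high-contrast prototypes: bars and blobs per class."""
    h, w = shape
    img = np.zeros((h, w))
    ys, xs = np.mgrid[0:h, 0:w]
    kind = cls % 4
    band = max(2, h // 7)
    if kind == 0:      # horizontal bar
        row = h // 4 + (cls // 4) * (h // 4)
        img[(ys >= row) & (ys < row + band)] = 1.0
    elif kind == 1:    # vertical bar
        col = w // 4 + (cls // 4) * (w // 4)
        img[(xs >= col) & (xs < col + band)] = 1.0
    elif kind == 2:    # main diagonal
        img[np.abs(ys - xs) < band] = 1.0
    else:              # centered blob
        r2 = (ys - h / 2) ** 2 + (xs - w / 2) ** 2
        img[r2 < (h / 4 + cls // 4) ** 2] = 1.0
    return img


def make_patterns(n_classes: int = 3, shape: tuple[int, int] = (28, 28),
                  n_per_class: int = 12, noise: float = 0.05,
                  seed: int = 0) -> PatternSet:
    """Labeled synthetic image set: class prototypes plus pixel noise.

    ``noise`` is the standard deviation of additive Gaussian pixel noise;
    images are clipped back to [0, 1].
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(seed)
    protos = np.stack([_prototype(c, shape) for c in range(n_classes)])
    images, labels = [], []
    for cls in range(n_classes):
        for _ in range(n_per_class):
            img = protos[cls] + noise * rng.standard_normal(shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(cls)
    return PatternSet(images=np.stack(images), labels=np.array(labels),
                      prototypes=protos)
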