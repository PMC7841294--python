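"""Synthetic grayscale pattern datasets, IDX file I/O and Sobel pre-processing.

The synthetic generator emulates the statistical structure the unsupervised
spiking classifier assumes: each class is a fixed high-contrast template
(oriented bars, corner blobs, a cross, a ring) corrupted by independent
Gaussian pixel noise and clamped to the 8-bit intensity range.  It stands in
for full-scale digit benchmarks so that the complete train / fault / repair
pipeline runs at desk scale.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SynthSpec",
    "Dataset",
    "generate",
    "class_templates",
    "load_idx",
    "save_idx",
    "sobel_filter",
]


@dataclass
class SynthSpec:
    """Specification of a synthetic pattern dataset.

    Parameters
    ----------
    image_side : int
        Image height/width in pixels.
    n_classes : int
        Number of classes (at most 10 procedural templates are defined).
    noise_sd : float
        Standard deviation of the additive Gaussian pixel noise, in intensity
        units on the [0, 255] scale.
    peak_intensity : float
        Peak template intensity.  The default places the task in the
        difficulty band of the grayscale benchmarks (Poisson-encoding noise
        matters; the trained network sits below ceiling), which gives the
        fault/repair phases their dynamic range.
    n_train, n_test : int
        Number of training / test examples (balanced over classes to +-1).
    seed : int
        Base seed; train and test draws use disjoint spawned streams.
    min_template_distance : float
        Minimum pairwise Euclidean distance enforced between class templates.
    """

    image_side: int = 16
    n_classes: int = 10
    noise_sd: float = 20.0
    n_train: int = 2000
    n_test: int = 500
    seed: int = 0
    min_template_distance: float = 200.0
    peak_intensity: float = 102.0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.n_classes > 10:
            raise ValueError("at most 10 procedural class templates are defined")
        if self.image_side < 8:
            raise ValueError("image_side must be >= 8")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Dataset:
    """Labeled train/test image sets with intensities in [0, 255]."""

    train_images: np.ndarray  # (n_train, side, side) float64
    train_labels: np.ndarray  # (n_train,) int64
    test_images: np.ndarray
    test_labels: np.ndarray
    templates: np.ndarray  # (n_classes, side, side)

    @property
    def n_classes(self) -> int:
        return len(self.templates)


def _blob(side: int, cy: float, cx: float, sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    g = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)))
    return 255.0 * g / g.max()


def class_templates(spec: SynthSpec) -> np.ndarray:
    """Procedural class templates: 4 oriented bars, 4 corner blobs, cross, ring.

    Strokes carry a Gaussian cross-section so pixel intensities are graded,
    emulating the continuous stroke profiles of grayscale benchmark images
    (and hence a continuum of learned synaptic weights).
    """
    s = spec.image_side
    t = np.zeros((10, s, s))
    mid, half = s // 2, max(1, s // 10)
    band = slice(mid - half, mid + half + 1)
    # 0-3: horizontal, vertical, diagonal, anti-diagonal bars
    t[0][band, :] = 255.0
    t[1][:, band] = 255.0
    yy, xx = np.mgrid[0:s, 0:s]
    t[2][np.abs(yy - xx) <= half] = 255.0
    t[3][np.abs(yy + xx - (s - 1)) <= half] = 255.0
    # 4-7: corner blobs
    q, sig = s // 4, s / 6.5
    for i, (cy, cx) in enumerate([(q, q), (q, s - 1 - q), (s - 1 - q, q), (s - 1 - q, s - 1 - q)]):
        t[4 + i] = _blob(s, cy, cx, sig)
    # 8: central cross
    t[8][band, :] = 255.0
    t[8][:, band] = 255.0
    # 9: border ring
    w = max(1, s // 8)
    t[9][:w, :] = t[9][-w:, :] = 255.0
    t[9][:, :w] = t[9][:, -w:] = 255.0
    # soften stroke edges into graded profiles; set the contrast band
    for k in range(10):
        blurred = ndimage.gaussian_filter(t[k], sigma=s / 16.0)
        if blurred.max() > 0:
            t[k] = spec.peak_intensity * blurred / blurred.max()
    out = t[: spec.n_classes]
    flat = out.reshape(spec.n_classes, -1)
    if spec.n_classes > 1:
        d = np.linalg.norm(flat[:, None, :] - flat[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < spec.min_template_distance:
            raise ValueError(
                f"templates closer than min_template_distance ({d.min():.1f})"
            )
    return out


def _balanced_labels(n: int, n_classes: int, rng: np.random.Generator) -> np.ndarray:
    reps = np.arange(n) % n_classes  # balanced to +-1 by construction
    return rng.permutation(reps)


def _draw(templates: np.ndarray, labels: np.ndarray, noise_sd: float,
          rng: np.random.Generator) -> np.ndarray:
    imgs = templates[labels].astype(np.float64)
    if noise_sd > 0:
        imgs = imgs + rng.normal(0.0, noise_sd, size=imgs.shape)
    return np.clip(imgs, 0.0, 255.0)


def generate(spec: SynthSpec) -> Dataset:
    """Generate a balanced, labeled train/test dataset from *spec*.

    Train and test examples are drawn from disjoint RNG streams spawned from
    ``spec.seed`` so that changing ``n_test`` never perturbs the training set.
    """
    templates = class_templates(spec)
    ss_train, ss_test = np.random.SeedSequence(spec.seed).spawn(2)
    rng_train = np.random.default_rng(ss_train)
    rng_test = np.random.default_rng(ss_test)
    ytr = _balanced_labels(spec.n_train, spec.n_classes, rng_train)
    yte = _balanced_labels(spec.n_test, spec.n_classes, rng_test)
    return Dataset(
        train_images=_draw(templates, ytr, spec.noise_sd, rng_train),
        train_labels=ytr,
        test_images=_draw(templates, yte, spec.noise_sd, rng_test),
        test_labels=yte,
        templates=templates,
    )


# ---------------------------------------------------------------------------
# IDX format (the container used by the standard digit benchmarks)
# ---------------------------------------------------------------------------

_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
               0x0D: ">f4", 0x0E: ">f8"}


class IdxFormatError(ValueError):
    """Raised for malformed IDX files; message carries the byte offset."""


def load_idx(path) -> np.ndarray:
    """Read an IDX file (big-endian magic, dimension header, row-major payload)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < 4:
        raise IdxFormatError("truncated header at byte offset 0")
    zero1, zero2, dtype_code, ndim = struct.unpack(">BBBB", data[:4])
    if zero1 != 0 or zero2 != 0 or dtype_code not in _IDX_DTYPES:
        raise IdxFormatError(f"bad magic number at byte offset 0: {data[:4]!r}")
    header_end = 4 + 4 * ndim
    if len(data) < header_end:
        raise IdxFormatError(f"truncated dimension header at byte offset {len(data)}")
    shape = struct.unpack(f">{ndim}I", data[4:header_end])
    dtype = np.dtype(_IDX_DTYPES[dtype_code])
    expected = int(np.prod(shape)) * dtype.itemsize
    if len(data) - header_end != expected:
        raise IdxFormatError(
            f"payload length mismatch at byte offset {header_end}: "
            f"expected {expected} bytes, found {len(data) - header_end}"
        )
    arr = np.frombuffer(data, dtype=dtype, offset=header_end).reshape(shape)
    return arr.astype(arr.dtype.newbyteorder("="))


def save_idx(path, array: np.ndarray) -> None:
    """Write *array* in IDX format (uint8 payloads for intensity/label data)."""
    arr = np.ascontiguousarray(array)
    code = None
    for c, dt in _IDX_DTYPES.items():
        if np.dtype(dt).kind == arr.dtype.kind and np.dtype(dt).itemsize == arr.dtype.itemsize:
            code = c
            break
    if code is None:
        raise ValueError(f"dtype {arr.dtype} not representable in IDX")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, code, arr.ndim))
        fh.write(struct.pack(f">{arr.ndim}I", *arr.shape))
        fh.write(arr.astype(np.dtype(_IDX_DTYPES[code])).tobytes())


# ---------------------------------------------------------------------------
# Sobel edge pre-processing
# ---------------------------------------------------------------------------

def sobel_filter(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude, rescaled to [0, 255].

    Uses the standard 3x3 horizontal/vertical kernels with edge-replicated
    borders, so a constant image maps to exactly zero everywhere; the output
    is sqrt(Gx^2 + Gy^2) scaled by its global maximum.
    """
    img = np.asarray(image, dtype=np.float64)
    gx = ndimage.sobel(img, axis=1, mode="nearest")
    gy = ndimage.sobel(img, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag = mag * (255.0 / peak)
    return mag
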