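"""Synthetic desk-scale datasets with the statistical structure the learning rules assume.

Two generators are provided:

* :func:`make_vector_task` — multi-class Gaussian vector tasks whose difficulty is
  controlled by a single ``separation`` knob (distance between class means in units
  of the noise standard deviation).  These stand in for flattened image benchmarks
  as input to the shallow modulatory networks.
* :func:`make_glyph_bank` — procedurally rendered stroke "glyphs": many classes,
  few samples per class, each sample a jittered variant of a class prototype.
  This emulates the class/sample structure of handwritten-character corpora
  (on the order of a thousand classes with ~20 drawings each) without any
  download.  Only the class structure is emulated, not real stroke dynamics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from skimage.draw import bezier_curve
from skimage.morphology import dilation, disk
from skimage.transform import rotate


@dataclass
class VectorTask:
    """A multi-class vector classification task.

    ``features[k]`` is drawn as ``class_means[labels[k]] + noise``, with isotropic
    Gaussian noise of standard deviation ``noise_sd``.
    """

    features: np.ndarray          # (n_samples, dims)
    labels: np.ndarray            # (n_samples,) int class ids in [0, C)
    class_means: np.ndarray       # (C, dims)
    noise_sd: float

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]

    @property
    def dims(self) -> int:
        return self.class_means.shape[1]


@dataclass
class GlyphBank:
    """A bank of procedurally generated glyph classes.

    Within-class samples are jittered renderings (small rotation, translation and
    pixel noise) of one stroke prototype; between-class prototypes are distinct
    random stroke arrangements.
    """

    images: np.ndarray            # (n_classes * samples_per_class, H, W) in [0, 1]
    labels: np.ndarray            # (n,) int class ids
    classes: list[int]
    renderer_params: list[dict]   # per-class stroke description
    image_size: int = 28
    samples_per_class: int = 20

    def class_indices(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def make_vector_task(
    n_classes: int,
    dims: int,
    n_per_class: int,
    separation: float,
    noise_sd: float,
    seed: int,
) -> VectorTask:
    """Generate a ``n_classes``-way Gaussian vector task.

    Class means are random unit directions scaled by ``separation`` (a simplex-like
    arrangement: in high dimension random unit vectors are near-orthogonal, so all
    pairwise mean distances concentrate around ``separation * sqrt(2)``).  Samples
    are ``mean + N(0, noise_sd^2 I)``.  Deterministic per ``seed``.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    directions = rng.standard_normal((n_classes, dims))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    means = separation * directions
    task = VectorTask(
        features=np.empty((0, dims)), labels=np.empty(0, dtype=np.int64),
        class_means=means, noise_sd=float(noise_sd),
    )
    feats, labels = draw_samples(task, n_per_class, seed=rng.integers(0, 2**31))
    task.features, task.labels = feats, labels
    return task


def draw_samples(
    task: VectorTask, n_per_class: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a fresh labelled sample set from a task's class means (e.g. a held-out
    test split with identical class structure)."""
    rng = np.random.default_rng(seed)
    C, dims = task.class_means.shape
    labels = np.repeat(np.arange(C), n_per_class)
    feats = task.class_means[labels] + task.noise_sd * rng.standard_normal(
        (C * n_per_class, dims)
    )
    order = rng.permutation(len(labels))
    return feats[order], labels[order]


def nearest_mean_accuracy(task: VectorTask, features: np.ndarray,
                          labels: np.ndarray) -> float:
    """Accuracy of the nearest-class-mean classifier (a Bayes-optimal proxy for
    isotropic equal-covariance classes)."""
    d2 = ((features[:, None, :] - task.class_means[None, :, :]) ** 2).sum(axis=2)
    return float(np.mean(d2.argmin(axis=1) == labels))


# ---------------------------------------------------------------------------
# Glyph rendering
# ---------------------------------------------------------------------------

_SUPERSAMPLE = 4  # prototypes are rasterised at this multiple of image_size


def _random_stroke_params(rng: np.random.Generator, n_strokes: int) -> list[dict]:
    """Control points (in [0,1]^2) and thickness for ``n_strokes`` quadratic strokes."""
    strokes = []
    for _ in range(n_strokes):
        pts = rng.uniform(0.1, 0.9, size=(3, 2))
        strokes.append({
            "p0": pts[0].tolist(), "p1": pts[1].tolist(), "p2": pts[2].tolist(),
            "weight": float(rng.uniform(0.5, 2.0)),
            "thickness": int(rng.integers(1, 3)),
        })
    return strokes


def _render_strokes(strokes: list[dict], size_hi: int) -> np.ndarray:
    """Rasterise quadratic Bezier strokes onto a ``size_hi``-pixel binary canvas."""
    img = np.zeros((size_hi, size_hi), dtype=np.float64)
    for s in strokes:
        to_px = lambda p: (int(round(p[0] * (size_hi - 1))),
                           int(round(p[1] * (size_hi - 1))))
        r0, c0 = to_px(s["p0"])
        r1, c1 = to_px(s["p1"])
        r2, c2 = to_px(s["p2"])
        rr, cc = bezier_curve(r0, c0, r1, c1, r2, c2, s["weight"],
                              shape=(size_hi, size_hi))
        stroke = np.zeros_like(img)
        stroke[rr, cc] = 1.0
        stroke = dilation(stroke, disk(s["thickness"]))
        img = np.maximum(img, stroke)
    return img


def _area_pool(img: np.ndarray, out_size: int) -> np.ndarray:
    f = img.shape[0] // out_size
    return img.reshape(out_size, f, out_size, f).mean(axis=(1, 3))


def make_glyph_bank(
    n_classes: int,
    samples_per_class: int = 20,
    image_size: int = 28,
    seed: int = 0,
) -> GlyphBank:
    """Generate ``n_classes`` glyph classes with ``samples_per_class`` jittered
    samples each.

    Each class prototype is 2–5 random quadratic strokes; samples are the prototype
    under a random rotation (<=10 degrees), translation (<=2 px) and per-pixel
    Bernoulli flips (<=1%).  Pixel values are in [0, 1]; strokes are the
    high-valued foreground.
    """
    if n_classes < 5:
        raise ValueError("n_classes must be >= 5 so that 5-way episodes exist")
    if samples_per_class < 1:
        raise ValueError("samples_per_class must be >= 1")
    if image_size < 8:
        raise ValueError("image_size must be >= 8")
    rng = np.random.default_rng(seed)
    size_hi = image_size * _SUPERSAMPLE
    images = np.empty((n_classes * samples_per_class, image_size, image_size))
    labels = np.repeat(np.arange(n_classes), samples_per_class)
    renderer_params = []
    k = 0
    for c in range(n_classes):
        n_strokes = int(rng.integers(2, 6))
        strokes = _random_stroke_params(rng, n_strokes)
        renderer_params.append({"n_strokes": n_strokes, "strokes": strokes})
        proto_hi = _render_strokes(strokes, size_hi)
        for _ in range(samples_per_class):
            sample = proto_hi
            angle = rng.uniform(-10.0, 10.0)
            sample = rotate(sample, angle, order=1, mode="constant", cval=0.0)
            # translation jitter of up to 2 output pixels (in hi-res units)
            dr, dc = rng.integers(-2 * _SUPERSAMPLE, 2 * _SUPERSAMPLE + 1, size=2)
            sample = np.roll(np.roll(sample, dr, axis=0), dc, axis=1)
            img = _area_pool(sample, image_size)
            flips = rng.random(img.shape) < 0.01
            img = np.where(flips, 1.0 - img, img)
            images[k] = np.clip(img, 0.0, 1.0)
            k += 1
    return GlyphBank(
        images=images, labels=labels, classes=list(range(n_classes)),
        renderer_params=renderer_params, image_size=image_size,
        samples_per_class=samples_per_class,
    )


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------

def export_vector_task(task: VectorTask, path: str) -> None:
    """Write a vector task as delimited text: one row per sample, label last."""
    data = np.column_stack([task.features, task.labels.astype(np.float64)])
    header = f"dims={task.dims} n_classes={task.n_classes} noise_sd={task.noise_sd}"
    np.savetxt(path, data, delimiter="\t", header=header)


def load_vector_task(path: str) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, delimiter="\t")
    return data[:, :-1], data[:, -1].astype(np.int64)


def export_glyph_bank(bank: GlyphBank, root: str) -> None:
    """Write the bank as PNG files in the leaf-folder-per-class layout consumed by
    :func:`modnet.io_formats.read_image_folder` (class folders under one root)."""
    from PIL import Image

    for c in bank.classes:
        cls_dir = os.path.join(root, f"class_{c:04d}")
        os.makedirs(cls_dir, exist_ok=True)
        for n, idx in enumerate(bank.class_indices(c)):
            arr = np.round(bank.images[idx] * 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(
                os.path.join(cls_dir, f"sample_{n:03d}.png")
            )
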