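"""Readers and writers for the data formats the package touches.

* IDX (the MNIST/Fashion-MNIST on-disk dialect): big-endian header with magic
  ``0x00 0x00 <type> <ndim>`` followed by the dimension sizes and raw data.
* Image-folder corpora: one leaf directory per character class, PNG samples
  inside, normalised so strokes are the high-valued foreground.
* Area-mean downsampling (e.g. the 28x28 -> 10x10 preprocessing used for the
  shallow-network benchmarks).
* A small versioned checkpoint container with named arrays that round-trips
  byte-identically (model state includes non-gradient state such as traces and
  activity factors, so a plain weights-only format is not enough).
"""

from __future__ import annotations

import json
import os
import struct
from dataclasses import dataclass

import numpy as np


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConsistencyError(ValueError):
    """Two files that must agree (e.g. images and labels) do not."""


@dataclass
class ImageDataset:
    images: np.ndarray                 # (n, H, W), values in [0, 1]
    labels: np.ndarray                 # (n,) contiguous int ids from 0
    class_names: list[str] | None = None

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ConsistencyError(
                f"{len(self.images)} images vs {len(self.labels)} labels"
            )

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


# ---------------------------------------------------------------------------
# IDX
# ---------------------------------------------------------------------------

_IDX_DTYPES = {
    0x08: np.dtype(">u1"), 0x09: np.dtype(">i1"), 0x0B: np.dtype(">i2"),
    0x0C: np.dtype(">i4"), 0x0D: np.dtype(">f4"), 0x0E: np.dtype(">f8"),
}


def _read_idx_array(path: str) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(4)
        if len(header) < 4 or header[0] != 0 or header[1] != 0:
            raise FormatError(f"{path}: bad IDX magic bytes")
        type_code, ndim = header[2], header[3]
        if type_code not in _IDX_DTYPES:
            raise FormatError(f"{path}: unknown IDX type code 0x{type_code:02x}")
        dim_bytes = fh.read(4 * ndim)
        if len(dim_bytes) < 4 * ndim:
            raise FormatError(f"{path}: truncated IDX header")
        dims = struct.unpack(f">{ndim}I", dim_bytes)
        dtype = _IDX_DTYPES[type_code]
        count = int(np.prod(dims))
        raw = fh.read(count * dtype.itemsize)
        if len(raw) < count * dtype.itemsize:
            raise FormatError(f"{path}: truncated IDX data section")
        return np.frombuffer(raw, dtype=dtype).reshape(dims)


def read_idx(path_images: str, path_labels: str) -> ImageDataset:
    """Read an IDX image/label file pair; pixel bytes are scaled to [0, 1]."""
    images = _read_idx_array(path_images)
    labels = _read_idx_array(path_labels)
    if images.ndim != 3:
        raise FormatError(f"{path_images}: expected 3-D image array, got {images.ndim}-D")
    if labels.ndim != 1:
        raise FormatError(f"{path_labels}: expected 1-D label array")
    if len(images) != len(labels):
        raise ConsistencyError(
            f"{len(images)} images in {path_images} vs {len(labels)} labels in {path_labels}"
        )
    images = images.astype(np.float64) / 255.0
    return ImageDataset(images=images, labels=labels.astype(np.int64))


def write_idx(images: np.ndarray, labels: np.ndarray,
              path_images: str, path_labels: str) -> None:
    """Write images (float in [0,1] or uint8) and labels as an IDX pair."""
    if images.dtype != np.uint8:
        images = np.round(np.clip(images, 0, 1) * 255).astype(np.uint8)
    with open(path_images, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, 0x08, 3))
        fh.write(struct.pack(">3I", *images.shape))
        fh.write(images.tobytes())
    with open(path_labels, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, 0x08, 1))
        fh.write(struct.pack(">I", len(labels)))
        fh.write(labels.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# Image folders
# ---------------------------------------------------------------------------

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".gif", ".tif", ".tiff"}


def read_image_folder(root: str, image_size: int) -> ImageDataset:
    """Read a directory tree with one character class per leaf folder.

    Images are converted to single-channel [0, 1], resized (area interpolation)
    to ``image_size`` square, and inverted when the background is the high value
    so that strokes are always the high-valued foreground.
    """
    from PIL import Image

    leaves: list[tuple[str, list[str]]] = []
    for dirpath, dirnames, filenames in sorted(os.walk(root)):
        files = sorted(f for f in filenames
                       if os.path.splitext(f)[1].lower() in _IMAGE_EXTS)
        if files and not any(
            os.path.isdir(os.path.join(dirpath, d)) for d in dirnames
        ):
            leaves.append((dirpath, files))
    if not leaves:
        raise FormatError(f"{root}: no class folders with images found")
    images, labels, class_names = [], [], []
    for cid, (dirpath, files) in enumerate(leaves):
        class_names.append(os.path.relpath(dirpath, root))
        for fname in files:
            with Image.open(os.path.join(dirpath, fname)) as im:
                arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
            # strokes must be the foreground: invert when border pixels (assumed
            # background) are bright
            border = np.concatenate([arr[0], arr[-1], arr[:, 0], arr[:, -1]])
            if border.mean() > 0.5:
                arr = 1.0 - arr
            if arr.shape != (image_size, image_size):
                arr = _area_resize(arr, image_size)
            images.append(arr)
            labels.append(cid)
    return ImageDataset(
        images=np.stack(images), labels=np.asarray(labels, dtype=np.int64),
        class_names=class_names,
    )


def _pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic matrix whose row i averages input cells overlapping output
    cell i (exact fractional area-mean pooling)."""
    s = n_in / n_out
    W = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * s, (i + 1) * s
        for j in range(int(np.floor(lo)), min(n_in, int(np.ceil(hi)))):
            W[i, j] = min(hi, j + 1) - max(lo, j)
    return W / s


def _area_resize(img: np.ndarray, out_size: int) -> np.ndarray:
    Wr = _pool_matrix(img.shape[0], out_size)
    Wc = _pool_matrix(img.shape[1], out_size)
    return Wr @ img @ Wc.T


def downsample(images: np.ndarray, out_size: int) -> np.ndarray:
    """Area-mean pooling of (..., H, W) images to ``out_size`` square.

    Exact fractional overlap weights are used, so a constant image stays constant
    and values remain in [0, 1] (each output pixel is a convex combination of
    input pixels).
    """
    images = np.asarray(images)
    H, W = images.shape[-2:]
    if out_size > H or out_size > W:
        raise ValueError(f"out_size {out_size} exceeds input size {H}x{W}")
    Wr = _pool_matrix(H, out_size)
    Wc = _pool_matrix(W, out_size)
    return np.einsum("ij,...jk,lk->...il", Wr, images, Wc)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1
_MAGIC = b"MODNETCKPT"


def save_checkpoint(path: str, kind: str, arrays: dict[str, np.ndarray],
                    config: dict | None = None, seed: int | None = None) -> None:
    """Write a deterministic binary container: a magic string, a JSON header
    describing the named arrays (dtype, shape, byte offset), then the raw
    little-endian array bytes.  Identical state always yields identical bytes.
    """
    specs = {}
    offset = 0
    blobs = []
    for name in sorted(arrays):
        arr = np.ascontiguousarray(arrays[name])
        if arr.dtype.byteorder == ">":
            arr = arr.astype(arr.dtype.newbyteorder("<"))
        blob = arr.tobytes()
        specs[name] = {"dtype": arr.dtype.str, "shape": list(arr.shape),
                       "offset": offset}
        blobs.append(blob)
        offset += len(blob)
    header = json.dumps(
        {"version": CHECKPOINT_VERSION, "kind": kind, "seed": seed,
         "config": config or {}, "arrays": specs},
        sort_keys=True,
    ).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(header)))
        fh.write(header)
        for blob in blobs:
            fh.write(blob)


def load_checkpoint(path: str) -> dict:
    """Load a checkpoint; returns {"kind", "seed", "config", "arrays": {name: array}}."""
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise FormatError(f"{path}: not a checkpoint file")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        meta = json.loads(fh.read(hlen).decode())
        if meta["version"] != CHECKPOINT_VERSION:
            raise FormatError(f"{path}: unsupported checkpoint version {meta['version']}")
        body = fh.read()
    arrays = {}
    for name, spec in meta["arrays"].items():
        dtype = np.dtype(spec["dtype"])
        count = int(np.prod(spec["shape"])) if spec["shape"] else 1
        start = spec["offset"]
        arrays[name] = np.frombuffer(
            body, dtype=dtype, count=count, offset=start
        ).reshape(spec["shape"]).copy()
    return {"kind": meta["kind"], "seed": meta["seed"],
            "config": meta["config"], "arrays": arrays}
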