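"""Dataset reading, split rules, patch sampling and augmentation.

Datasets are read from a DRIVE-style on-disk layout::

    root/                       root/
      training/images/*.png       images/*.png
      training/masks/*.png   or   masks/*.png
      training/fov/*.png          fov/*.png        (optional)
      test/{images,masks,fov}/

When ``training/`` and ``test/`` subdirectories exist they define the
split directly (DRIVE ships this way); flat layouts are split by the
per-dataset rules below.  Images and masks are matched by sorted file
stem; a missing mask is a hard error.

Split rules for the named datasets:

* ``drive``    — 20 training / 20 test from the two subdirectories.
* ``chasedb1`` — flat, 28 images: first 20 (sorted by id) train, final
  8 test.
* ``stare``    — flat, 20 images: either a fixed 10/10 split
  (``stare_scheme="half"``) or leave-one-out (``stare_scheme=fold``
  index, that image is the test set).
* ``hrf``      — 15 train / 30 test (subdirectories or first 15 of a
  flat layout), every record downsampled twice (two successive factor-2
  reductions).
* ``phantom`` / ``custom`` — layout-defined split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.measure import block_reduce

__all__ = [
    "ImageRecord",
    "DatasetSpec",
    "load_dataset",
    "split_train_val",
    "sample_patch",
    "augment_rotation",
    "downsample_record",
    "threshold_map",
    "normalize_image",
    "save_record",
    "load_record",
    "save_probability_map",
]

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".gif", ".ppm")


@dataclass
class ImageRecord:
    """One fundus image with its vessel mask and optional FOV mask."""

    image: np.ndarray            # H x W x 3 float32 in [0, 1]
    mask: np.ndarray             # H x W uint8 in {0, 1}
    fov: np.ndarray | None       # H x W uint8 in {0, 1} or None
    id: str
    split: str = "train"

    def __post_init__(self):
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"record {self.id}: image must be HxWx3")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(f"record {self.id}: mask not aligned to image")
        if self.fov is not None and self.fov.shape != self.image.shape[:2]:
            raise ValueError(f"record {self.id}: fov not aligned to image")


@dataclass
class DatasetSpec:
    name: str
    root: Path
    stare_scheme: str | int = "half"
    hrf_downsample: int = 2

    KNOWN = ("drive", "chasedb1", "stare", "hrf", "phantom", "custom")

    def __post_init__(self):
        self.root = Path(self.root)
        if self.name not in self.KNOWN:
            raise ValueError(f"unknown dataset name {self.name!r}")


def _to_float_image(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.dtype == np.uint8:
        return (arr / 255.0).astype(np.float32)
    if arr.dtype == np.uint16:
        return (arr / 65535.0).astype(np.float32)
    return np.clip(arr, 0, 1).astype(np.float32)


def _to_binary_mask(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    thresh = 127 if arr.dtype == np.uint8 else 0.5
    return (arr > thresh).astype(np.uint8)


def _list_images(directory: Path) -> dict:
    return {p.stem: p for p in sorted(directory.iterdir())
            if p.suffix.lower() in IMAGE_EXTENSIONS}


def _read_dir(root: Path, split: str) -> list[ImageRecord]:
    images = _list_images(root / "images")
    masks = _list_images(root / "masks")
    fovs = _list_images(root / "fov") if (root / "fov").is_dir() else {}
    if not images:
        raise FileNotFoundError(f"no images found under {root / 'images'}")
    missing = sorted(set(images) - set(masks))
    if missing:
        raise FileNotFoundError(f"missing masks for ids: {missing}")
    records = []
    for stem in sorted(images):
        image = _to_float_image(iio.imread(images[stem]))
        mask = _to_binary_mask(iio.imread(masks[stem]))
        fov = _to_binary_mask(iio.imread(fovs[stem])) if stem in fovs else None
        records.append(ImageRecord(image, mask, fov, id=stem, split=split))
    return records


def load_dataset(spec: DatasetSpec) -> list[ImageRecord]:
    """Read every record of a dataset and assign train/test splits."""
    root = spec.root
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")

    if (root / "training").is_dir() and (root / "test").is_dir():
        records = (_read_dir(root / "training", "train")
                   + _read_dir(root / "test", "test"))
    else:
        records = _read_dir(root, "train")
        records = _apply_flat_split(spec, records)

    if spec.name == "hrf":
        records = [downsample_record(r, spec.hrf_downsample) for r in records]
    return records


def _apply_flat_split(spec: DatasetSpec, records: list[ImageRecord]):
    n = len(records)
    if spec.name == "chasedb1":
        cut = n - 8
    elif spec.name == "stare":
        if spec.stare_scheme == "half":
            cut = n // 2
        else:
            fold = int(spec.stare_scheme)
            if not 0 <= fold < n:
                raise ValueError(f"leave-one-out fold {fold} out of range for {n} images")
            for i, r in enumerate(records):
                r.split = "test" if i == fold else "train"
            return records
    elif spec.name == "hrf":
        cut = 15
    else:
        return records  # custom/phantom flat layout: everything is training data
    for i, r in enumerate(records):
        r.split = "train" if i < cut else "test"
    return records


def split_train_val(records, frac: float = 0.1, seed: int = 0):
    """Randomly carve a validation subset out of the training records."""
    if frac <= 0:
        raise ValueError("validation fraction must be positive")
    pool = [r for r in records if r.split != "test"]
    if not pool:
        raise ValueError("no training records to split")
    n_val = max(1, round(frac * len(pool)))
    if n_val >= len(pool):
        raise ValueError("validation split would consume all training records")
    order = np.random.default_rng(seed).permutation(len(pool))
    val_idx = set(order[:n_val].tolist())
    train = [r for i, r in enumerate(pool) if i not in val_idx]
    val = [r for i, r in enumerate(pool) if i in val_idx]
    return train, val


def sample_patch(record: ImageRecord, size: int, rng: np.random.Generator):
    """Crop a uniformly positioned size x size patch from image and mask."""
    h, w = record.mask.shape
    if h < size or w < size:
        raise ValueError(f"image {record.id} smaller than patch size {size}")
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, w - size + 1))
    return (record.image[top:top + size, left:left + size],
            record.mask[top:top + size, left:left + size])


def augment_rotation(image: np.ndarray, mask: np.ndarray,
                     rng: np.random.Generator, max_deg: float = 20.0):
    """Rotate both arrays by a shared angle ~ Uniform(−max_deg, max_deg).

    The image is bilinearly interpolated (reflect boundary); the mask is
    rotated with nearest-neighbour so it stays binary.
    """
    angle = float(rng.uniform(-max_deg, max_deg))
    if angle == 0.0:
        return image.copy(), mask.copy()
    rot_img = ndimage.rotate(image, angle, axes=(1, 0), reshape=False,
                             order=1, mode="reflect").astype(np.float32)
    rot_mask = ndimage.rotate(mask, angle, axes=(1, 0), reshape=False,
                              order=0, mode="constant", cval=0)
    return np.clip(rot_img, 0.0, 1.0), rot_mask.astype(mask.dtype)


def _halve(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape[:2]
    arr = arr[:h - h % 2, :w - w % 2]
    block = (2, 2) + (1,) * (arr.ndim - 2)
    return block_reduce(arr, block, np.mean)


def downsample_record(record: ImageRecord, times: int) -> ImageRecord:
    """Apply ``times`` successive factor-2 area reductions to a record.

    Masks are averaged then re-binarised at 0.5.
    """
    if times == 0:
        return record
    image = record.image
    mask = record.mask.astype(np.float32)
    fov = record.fov.astype(np.float32) if record.fov is not None else None
    for _ in range(times):
        image = _halve(image)
        mask = _halve(mask)
        if fov is not None:
            fov = _halve(fov)
    return ImageRecord(
        image.astype(np.float32),
        (mask >= 0.5).astype(np.uint8),
        (fov >= 0.5).astype(np.uint8) if fov is not None else None,
        id=record.id, split=record.split)


def threshold_map(prob_map: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Binarise a probability map; ties (p == t) count as vessel."""
    return (np.asarray(prob_map) >= t).astype(np.uint8)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-image, per-channel standardisation used before the network."""
    image = np.asarray(image, dtype=np.float64)
    mean = image.mean(axis=(0, 1), keepdims=True)
    std = image.std(axis=(0, 1), keepdims=True)
    return ((image - mean) / np.maximum(std, 1e-6)).astype(np.float32)


# ----------------------------------------------------------------------
# on-disk round trip
# ----------------------------------------------------------------------

def save_record(record: ImageRecord, root: Path) -> None:
    """Write a record into the flat layout under ``root``."""
    root = Path(root)
    for sub in ("images", "masks") + (("fov",) if record.fov is not None else ()):
        (root / sub).mkdir(parents=True, exist_ok=True)
    iio.imwrite(root / "images" / f"{record.id}.png",
                np.round(record.image * 255).astype(np.uint8))
    iio.imwrite(root / "masks" / f"{record.id}.png",
                (record.mask * 255).astype(np.uint8))
    if record.fov is not None:
        iio.imwrite(root / "fov" / f"{record.id}.png",
                    (record.fov * 255).astype(np.uint8))


def load_record(root: Path, record_id: str, split: str = "train") -> ImageRecord:
    root = Path(root)
    image = _to_float_image(iio.imread(root / "images" / f"{record_id}.png"))
    mask = _to_binary_mask(iio.imread(root / "masks" / f"{record_id}.png"))
    fov_path = root / "fov" / f"{record_id}.png"
    fov = _to_binary_mask(iio.imread(fov_path)) if fov_path.exists() else None
    return ImageRecord(image, mask, fov, id=record_id, split=split)


def save_probability_map(prob_map: np.ndarray, path: Path) -> None:
    """Write a probability map as an 8-bit PNG (value = round(255 p))."""
    iio.imwrite(Path(path), np.round(np.clip(prob_map, 0, 1) * 255).astype(np.uint8))
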