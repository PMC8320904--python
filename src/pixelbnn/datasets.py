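"""Dataset loaders for the public fundus layouts and the synthetic layout.

Supported directory conventions:

``drive``      root/{training,test}/{images,1st_manual,2nd_manual}; files pair
               by their leading numeric id (e.g. ``21_training.tif`` with
               ``21_manual1.gif``). Masks ship as GIF; any nonzero pixel is
               vessel.
``stare``      root/images plus root/labels-ah (first observer) and
               root/labels-vk (second observer); files pair by the ``im####``
               stem.
``chase``      a flat directory of ``Image_NNS`` images (NN patient number,
               S eye side L/R) with ``Image_NNS_1stHO`` / ``_2ndHO`` masks;
               both eyes of a patient share the patient id.
``synthetic``  the images/ + masks/ + manifest.json layout written by
               :func:`pixelbnn.synthfundus.generate_dataset`.

File lists are sorted lexicographically so ordering is deterministic across
platforms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocess import FundusImage, VesselMask

__all__ = [
    "DatasetError",
    "MissingMaskError",
    "DimensionMismatchError",
    "UnpairedFilesError",
    "DatasetSpec",
    "Sample",
    "load_dataset",
    "read_image",
    "read_mask",
]

IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".ppm", ".gif")


class DatasetError(Exception):
    """Base class for dataset-layout problems."""


class MissingMaskError(DatasetError):
    """An image has no mask for the requested observer."""


class DimensionMismatchError(DatasetError):
    """Image and mask spatial dimensions differ."""


class UnpairedFilesError(DatasetError):
    """Prediction/truth directories do not pair one-to-one."""

    def __init__(self, orphans):
        self.orphans = sorted(str(o) for o in orphans)
        super().__init__(f"unpaired files: {', '.join(self.orphans)}")


@dataclass(frozen=True)
class DatasetSpec:
    layout: str
    root: Path
    observer: str = "first"
    split: str = "training"  # drive only: training | test

    def __post_init__(self):
        object.__setattr__(self, "root", Path(self.root))
        if self.layout not in ("drive", "stare", "chase", "synthetic"):
            raise DatasetError(f"unknown layout {self.layout!r}")
        if self.observer not in ("first", "second"):
            raise DatasetError("observer must be 'first' or 'second'")


@dataclass
class Sample:
    image: FundusImage
    mask: VesselMask
    meta: dict = field(default_factory=dict)

    @property
    def id(self) -> str:
        return self.meta["id"]


def read_image(path, dataset_tag: str = "") -> FundusImage:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGBA" if im.mode == "RGBA" else "RGB"))
    return FundusImage.from_array(arr, dataset_tag=dataset_tag)


def read_mask(path) -> VesselMask:
    """Read a binary mask; any nonzero pixel (e.g. 255 in PNG/GIF) is vessel."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return VesselMask.from_array(arr)


def write_mask(mask: VesselMask, path) -> None:
    Image.fromarray(mask.pixels * np.uint8(255)).save(path)


def _list_images(directory: Path):
    if not directory.is_dir():
        raise DatasetError(f"missing directory: {directory}")
    return sorted(
        p for p in directory.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
    )


def _find_mask(mask_dir: Path, key: str, image_path: Path) -> Path:
    if not mask_dir.is_dir():
        raise MissingMaskError(f"mask directory {mask_dir} does not exist")
    hits = sorted(p for p in mask_dir.iterdir() if key in p.name)
    if not hits:
        raise MissingMaskError(f"no mask matching {key!r} in {mask_dir} for {image_path.name}")
    return hits[0]


def _build_sample(img_path: Path, mask_path: Path, tag: str, meta: dict) -> Sample:
    image = read_image(img_path, dataset_tag=tag)
    mask = read_mask(mask_path)
    if image.pixels.shape[:2] != mask.pixels.shape:
        raise DimensionMismatchError(
            f"{img_path.name}: image {image.pixels.shape[:2]} vs mask {mask.pixels.shape}"
        )
    meta = dict(meta)
    meta.setdefault("native_dims", mask.pixels.shape)
    meta["image_path"] = str(img_path)
    meta["mask_path"] = str(mask_path)
    return Sample(image=image, mask=mask, meta=meta)


def _load_drive(spec: DatasetSpec):
    base = spec.root / spec.split
    mask_dir = base / ("1st_manual" if spec.observer == "first" else "2nd_manual")
    samples = []
    for img_path in _list_images(base / "images"):
        m = re.match(r"(\d+)", img_path.stem)
        if not m:
            raise DatasetError(f"cannot parse DRIVE id from {img_path.name}")
        key = m.group(1)
        mask_path = _find_mask(mask_dir, key, img_path)
        samples.append(
            _build_sample(img_path, mask_path, "drive", {"id": key, "split": spec.split})
        )
    return samples


def _load_stare(spec: DatasetSpec):
    mask_dir = spec.root / ("labels-ah" if spec.observer == "first" else "labels-vk")
    samples = []
    for img_path in _list_images(spec.root / "images"):
        key = img_path.stem.split(".")[0]
        mask_path = _find_mask(mask_dir, key, img_path)
        samples.append(_build_sample(img_path, mask_path, "stare", {"id": key}))
    return samples


def _load_chase(spec: DatasetSpec):
    suffix = "1stHO" if spec.observer == "first" else "2ndHO"
    samples = []
    image_paths = [
        p
        for p in _list_images(spec.root)
        if re.fullmatch(r"Image_\d+[LR]", p.stem)
    ]
    if not image_paths:
        raise DatasetError(f"no CHASE images (Image_NNL/R.*) under {spec.root}")
    for img_path in image_paths:
        m = re.fullmatch(r"Image_(\d+)([LR])", img_path.stem)
        patient, eye = m.group(1), m.group(2)
        mask_path = _find_mask(spec.root, f"{img_path.stem}_{suffix}", img_path)
        samples.append(
            _build_sample(
                img_path,
                mask_path,
                "chase",
                {"id": img_path.stem, "patient": patient, "eye": eye},
            )
        )
    return samples


def _load_synthetic(spec: DatasetSpec):
    samples = []
    for img_path in _list_images(spec.root / "images"):
        mask_path = _find_mask(spec.root / "masks", img_path.stem, img_path)
        samples.append(
            _build_sample(img_path, mask_path, "synthetic", {"id": img_path.stem})
        )
    return samples


_LOADERS = {
    "drive": _load_drive,
    "stare": _load_stare,
    "chase": _load_chase,
    "synthetic": _load_synthetic,
}


def load_dataset(spec: DatasetSpec) -> list[Sample]:
    """Load aligned (image, mask, metadata) samples for a layout.

    The observer choice selects which delineation acts as ground truth; the
    second observer's masks double as the human benchmark during evaluation.
    """
    if not spec.root.exists():
        raise DatasetError(f"dataset root {spec.root} does not exist")
    return _LOADERS[spec.layout](spec)


def pair_directories(pred_dir, truth_dir):
    """One-to-one pairing of prediction and truth files by stem prefix.

    A prediction `X.png` pairs with the unique truth file whose stem starts
    with `X` (or vice versa). Orphans on either side raise
    :class:`UnpairedFilesError` listing them.
    """
    preds = _list_images(Path(pred_dir))
    truths = _list_images(Path(truth_dir))
    truth_by_stem = {p.stem: p for p in truths}
    pairs, used = [], set()
    orphans = []
    for p in preds:
        hit = truth_by_stem.get(p.stem)
        if hit is None:
            cands = [t for t in truths if t.stem.startswith(p.stem) or p.stem.startswith(t.stem)]
            hit = cands[0] if len(cands) == 1 else None
        if hit is None:
            orphans.append(p)
        else:
            pairs.append((p, hit))
            used.add(hit)
    orphans.extend(t for t in truths if t not in used)
    if orphans:
        raise UnpairedFilesError(orphans)
    return pairs
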