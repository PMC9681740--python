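"""Dataset manifests, augmentation, splitting, and image/location pairing.

The unit of data is a wound ROI: a rectangular crop around a wound (or a
background / normal-skin crop), tagged with a wound class and a body-map
location code. A CSV manifest (`index,source_index,filename,class,
location_code,split,aug_tag`) is the on-disk dataset contract.

Protocol enforced here:

* the test split is drawn first (stratified per class, 25% by default) from
  un-augmented ROIs, so no view of a test ROI ever reaches training;
* each train/val ROI receives exactly five augmented copies — horizontal and
  vertical flips and 25/45/90-degree rotations — inheriting the source's
  class and location;
* image/location pairing is keyed by the record index, never by position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .bodymap import BACKGROUND_CODE, BodyMapRegistry, encode_locations

AUG_TAGS = ("hflip", "vflip", "rot25", "rot45", "rot90")
ORIG_TAG = "orig"
SPLITS = ("train", "val", "test", "unassigned")

__all__ = [
    "AUG_TAGS",
    "DatasetManifest",
    "ManifestError",
    "PairedData",
    "SplitAssignment",
    "WoundClass",
    "WoundRecord",
    "augment_records",
    "pair_modalities",
    "read_manifest",
    "split_records",
    "subset_classes",
    "transform_image",
    "write_manifest",
]


class ManifestError(ValueError):
    """A manifest row violates the dataset contract."""


class WoundClass(str, Enum):
    """Wound-type labels: four wound classes plus background and normal skin.

    ``V`` (venous) and ``AV`` (arterial + venous) index different dataset
    rosters and never co-occur in one manifest.
    """

    D = "D"
    V = "V"
    AV = "A+V"
    P = "P"
    S = "S"
    BG = "BG"
    N = "N"

    @classmethod
    def parse(cls, token: str) -> "WoundClass":
        token = str(token).strip()
        for member in cls:
            if token == member.value or token == member.name:
                return member
        raise ManifestError(f"unknown wound class token: {token!r}")

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class WoundRecord:
    """One ROI image with its label, location, split, and provenance."""

    index: int
    source_index: int
    image_path: str
    wound_class: WoundClass
    location: int
    split: str = "unassigned"
    aug_tag: str = ORIG_TAG
    width: int | None = None
    height: int | None = None

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ManifestError(f"unknown split {self.split!r} (record {self.index})")
        if self.aug_tag != ORIG_TAG and self.aug_tag not in AUG_TAGS:
            raise ManifestError(f"unknown aug_tag {self.aug_tag!r} (record {self.index})")
        is_bg = self.wound_class == WoundClass.BG
        if is_bg != (self.location == BACKGROUND_CODE):
            raise ManifestError(
                f"record {self.index}: class {self.wound_class} with location "
                f"{self.location} (background must carry -1, and only background may)"
            )
        if self.split == "test" and self.aug_tag != ORIG_TAG:
            raise ManifestError(f"record {self.index}: augmented record in test split")

    @property
    def is_original(self) -> bool:
        return self.aug_tag == ORIG_TAG


@dataclass
class DatasetManifest:
    name: str
    records: list[WoundRecord]
    registry_version: str = "custom"
    root: Path | None = None  # directory image paths are relative to

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        seen: set[int] = set()
        classes: set[WoundClass] = set()
        by_index: dict[int, WoundRecord] = {}
        for rec in self.records:
            if rec.index in seen:
                raise ManifestError(f"duplicate record index {rec.index}")
            seen.add(rec.index)
            classes.add(rec.wound_class)
            by_index[rec.index] = rec
        if WoundClass.V in classes and WoundClass.AV in classes:
            raise ManifestError("manifest mixes V and A+V rosters")
        for rec in self.records:
            if rec.aug_tag != ORIG_TAG:
                src = by_index.get(rec.source_index)
                if src is None:
                    raise ManifestError(
                        f"augmented record {rec.index} references missing source "
                        f"{rec.source_index}"
                    )
                if (src.wound_class, src.location) != (rec.wound_class, rec.location):
                    raise ManifestError(
                        f"augmented record {rec.index} does not inherit class/location "
                        f"from source {rec.source_index}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def classes(self) -> list[WoundClass]:
        return sorted({r.wound_class for r in self.records}, key=lambda c: c.value)

    def originals(self) -> list[WoundRecord]:
        return [r for r in self.records if r.is_original]

    def by_split(self, split: str) -> list[WoundRecord]:
        return [r for r in self.records if r.split == split]

    def resolve(self, rec: WoundRecord) -> Path:
        p = Path(rec.image_path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.index, r.source_index, r.image_path, r.wound_class.value,
                 r.location, r.split, r.aug_tag)
                for r in self.records
            ],
            columns=[
                "index", "source_index", "filename", "class",
                "location_code", "split", "aug_tag",
            ],
        )


MANIFEST_COLUMNS = ["index", "source_index", "filename", "class", "location_code", "split", "aug_tag"]


def read_manifest(
    path: str | Path,
    name: str | None = None,
    registry: BodyMapRegistry | None = None,
    check_images: bool = False,
) -> DatasetManifest:
    """Load and validate a manifest CSV.

    All record invariants (unique indexes, BG <-> -1, augmentation
    provenance, no augmented test records) are enforced; with ``registry``
    given, every location code must be encodable; with ``check_images``,
    every image path must resolve to an existing file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ManifestError(f"manifest missing columns {sorted(missing)}")
    records = [
        WoundRecord(
            index=int(row["index"]),
            source_index=int(row["source_index"]),
            image_path=str(row["filename"]),
            wound_class=WoundClass.parse(row["class"]),
            location=int(row["location_code"]),
            split=str(row["split"]),
            aug_tag=str(row["aug_tag"]),
        )
        for _, row in df.iterrows()
    ]
    manifest = DatasetManifest(
        name=name or path.stem,
        records=records,
        registry_version="custom" if registry is None else registry.version,
        root=path.parent,
    )
    if registry is not None:
        for rec in records:
            if rec.location != BACKGROUND_CODE and rec.location not in registry:
                raise ManifestError(
                    f"record {rec.index}: location {rec.location} not in registry "
                    f"{registry.version!r}"
                )
    if check_images:
        for rec in records:
            if not manifest.resolve(rec).exists():
                raise ManifestError(f"record {rec.index}: missing image {rec.image_path}")
    return manifest


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_frame().to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class SplitAssignment:
    """Holdout fractions (train/val/test), drawn test-first, per class."""

    fractions: tuple[float, float, float] = (0.60, 0.15, 0.25)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1: {self.fractions}")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_records(
    records: list[WoundRecord], assignment: SplitAssignment | None = None
) -> list[WoundRecord]:
    """Assign train/val/test splits to un-augmented records.

    The test fraction is drawn first per class (round(f_test * n) records),
    then the validation fraction, and the remainder trains. Deterministic
    for a fixed seed. Classes with fewer than 3 records cannot populate all
    three splits; a warning is raised and the available records favour
    test, then train.
    """
    assignment = assignment or SplitAssignment()
    for rec in records:
        if not rec.is_original:
            raise ManifestError(f"cannot split augmented record {rec.index}")
        if rec.split != "unassigned":
            raise ManifestError(f"record {rec.index} already assigned to {rec.split!r}")
    rng = np.random.default_rng(assignment.seed)
    _, f_val, f_test = assignment.fractions

    if assignment.stratified:
        groups: dict[WoundClass, list[WoundRecord]] = {}
        for rec in records:
            groups.setdefault(rec.wound_class, []).append(rec)
        group_list = [groups[c] for c in sorted(groups, key=lambda c: c.value)]
    else:
        group_list = [list(records)]

    out: list[WoundRecord] = []
    for group in group_list:
        n = len(group)
        if n < 3:
            warnings.warn(
                f"class {group[0].wound_class} has only {n} record(s); "
                "cannot populate train, val, and test",
                stacklevel=2,
            )
        order = rng.permutation(n)
        n_test = min(_round_half_up(f_test * n), n)
        n_val = min(_round_half_up(f_val * n), n - n_test)
        for pos, gi in enumerate(order):
            if pos < n_test:
                split = "test"
            elif pos < n_test + n_val:
                split = "val"
            else:
                split = "train"
            out.append(replace(group[gi], split=split))
    out.sort(key=lambda r: r.index)
    return out


def transform_image(image: Image.Image, aug_tag: str) -> Image.Image:
    """Apply one augmentation: exact flips/right-angle rotation, or a
    25/45-degree rotation about the centre on the original canvas with
    uncovered corners filled pure black (0, 0, 0)."""
    if aug_tag == ORIG_TAG:
        return image.copy()
    if aug_tag == "hflip":
        return image.transpose(Image.Transpose.FLIP_LEFT_RIGHT)
    if aug_tag == "vflip":
        return image.transpose(Image.Transpose.FLIP_TOP_BOTTOM)
    if aug_tag == "rot90":
        return image.transpose(Image.Transpose.ROTATE_90)
    if aug_tag in ("rot25", "rot45"):
        angle = 25 if aug_tag == "rot25" else 45
        return image.rotate(
            angle, resample=Image.Resampling.BILINEAR, expand=False, fillcolor=(0, 0, 0)
        )
    raise ValueError(f"unknown aug_tag {aug_tag!r}")


def augment_records(
    manifest: DatasetManifest, out_dir: str | Path | None = None
) -> DatasetManifest:
    """Emit the five augmented copies of every train/val record.

    Test records pass through untouched (they are never augmented). New
    records inherit class and location from their source and get fresh
    indexes. With ``out_dir`` (or the manifest root) available, augmented
    images are written next to the originals; missing source images raise.
    """
    for rec in manifest.records:
        if not rec.is_original:
            raise ManifestError(f"manifest already augmented (record {rec.index})")
    out_dir = Path(out_dir) if out_dir is not None else manifest.root
    next_index = max((r.index for r in manifest.records), default=-1) + 1
    new_records: list[WoundRecord] = list(manifest.records)
    for rec in manifest.records:
        if rec.split not in ("train", "val"):
            continue
        src_path = manifest.resolve(rec)
        if not src_path.exists():
            raise ManifestError(f"cannot augment record {rec.index}: {src_path} missing")
        with Image.open(src_path) as img:
            img = img.convert("RGB")
            for tag in AUG_TAGS:
                aug = transform_image(img, tag)
                stem = Path(rec.image_path).stem
                fname = f"{stem}_{tag}.png"
                rel = str(Path(rec.image_path).parent / fname)
                dest = Path(out_dir) / rel if out_dir is not None else src_path.parent / fname
                dest.parent.mkdir(parents=True, exist_ok=True)
                aug.save(dest)
                new_records.append(
                    WoundRecord(
                        index=next_index,
                        source_index=rec.index,
                        image_path=rel,
                        wound_class=rec.wound_class,
                        location=rec.location,
                        split=rec.split,
                        aug_tag=tag,
                    )
                )
                next_index += 1
    return DatasetManifest(
        name=manifest.name,
        records=new_records,
        registry_version=manifest.registry_version,
        root=out_dir if out_dir is not None else manifest.root,
    )


def subset_classes(
    manifest: DatasetManifest, classes
) -> tuple[DatasetManifest, dict[WoundClass, int]]:
    """Filter to a class subset; the label map is fixed by sorted class order."""
    classes = {WoundClass.parse(c) if not isinstance(c, WoundClass) else c for c in classes}
    if not classes:
        raise ManifestError("empty class subset")
    present = set(manifest.classes)
    absent = classes - present
    if absent:
        raise ManifestError(f"classes absent from manifest: {sorted(c.value for c in absent)}")
    ordered = sorted(classes, key=lambda c: c.value)
    label_map = {c: i for i, c in enumerate(ordered)}
    records = [r for r in manifest.records if r.wound_class in classes]
    sub = DatasetManifest(
        name=f"{manifest.name}-{'-'.join(c.value for c in ordered)}",
        records=records,
        registry_version=manifest.registry_version,
        root=manifest.root,
    )
    return sub, label_map


@dataclass
class PairedData:
    """Index-aligned image/location/label arrays for one set of records.

    Row i of every array comes from the same record (``indices[i]``);
    alignment is by record index, so the input record order is irrelevant.
    """

    indices: np.ndarray  # (n,) record indexes, ascending
    images: np.ndarray  # (n, H, W, 3) float32 in [0, 1]
    locations: np.ndarray  # (n, L+1) one-hot float32
    labels: np.ndarray  # (n,) integer labels per label_map
    label_map: dict[WoundClass, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.indices)


def pair_modalities(
    manifest: DatasetManifest,
    registry: BodyMapRegistry,
    records: list[WoundRecord] | None = None,
    image_size: int | None = None,
    label_map: dict[WoundClass, int] | None = None,
) -> PairedData:
    """Load images and one-hot locations as index-aligned arrays.

    Pairing is keyed by the unique record index: the i-th emitted image and
    the i-th emitted location encoding always originate from the same
    record, regardless of the order records are presented in.
    """
    recs = sorted(records if records is not None else manifest.records, key=lambda r: r.index)
    seen: set[int] = set()
    for r in recs:
        if r.index in seen:
            raise ManifestError(f"duplicate record index {r.index} in pairing")
        seen.add(r.index)
        if r.location != BACKGROUND_CODE and r.location not in registry:
            raise ManifestError(
                f"record {r.index}: location {r.location} not encodable under "
                f"registry {registry.version!r}"
            )
    if label_map is None:
        ordered = sorted({r.wound_class for r in recs}, key=lambda c: c.value)
        label_map = {c: i for i, c in enumerate(ordered)}
    images = []
    for r in recs:
        with Image.open(manifest.resolve(r)) as img:
            img = img.convert("RGB")
            if image_size is not None and img.size != (image_size, image_size):
                img = img.resize((image_size, image_size), Image.Resampling.BILINEAR)
            images.append(np.asarray(img, dtype=np.float32) / 255.0)
    return PairedData(
        indices=np.array([r.index for r in recs], dtype=int),
        images=np.stack(images) if images else np.zeros((0, 0, 0, 3), dtype=np.float32),
        locations=encode_locations([r.location for r in recs], registry),
        labels=np.array([label_map[r.wound_class] for r in recs], dtype=int),
        label_map=label_map,
    )
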