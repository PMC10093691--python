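"""On-disk conventions for every artifact the pipeline reads or writes.

Conventions (binding for all modules): row-major pixel indexing, origin at
the top-left, 0-based coordinates. Images are grayscale in [0, 1] in memory
and 8-bit PNG/TIFF on disk; masks are PNG with values {0, 255}; labels are a
CSV with the fixed header below; datasets are described by a JSON manifest.
Accidental RGB inputs are collapsed to grayscale by the unweighted channel
mean (OCTA en-face images are intrinsically single-channel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import FormatError, ValidationError

LABEL_COLUMNS = [
    "subject_id",
    "image_id",
    "branch",
    "shape",
    "anastomosis_loops",
    "peripheral_arcade",
    "dark_halo",
]

FEATURES = ("branch", "shape", "anastomosis_loops", "peripheral_arcade", "dark_halo")


@dataclass(frozen=True)
class ActivityLabels:
    """The five binary activity-criterion labels (1 = feature present)."""

    branch: int
    shape: int
    anastomosis_loops: int
    peripheral_arcade: int
    dark_halo: int

    def __post_init__(self) -> None:
        for name in FEATURES:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValidationError(f"label {name!r} must be 0 or 1, got {v!r}")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.branch, self.shape, self.anastomosis_loops, self.peripheral_arcade, self.dark_halo)

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in FEATURES}


@dataclass
class EnFacePair:
    """Co-registered outer-retina and choriocapillaris en-face images."""

    outer_retina: np.ndarray
    choriocapillaris: np.ndarray
    subject_id: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.outer_retina.shape != self.choriocapillaris.shape:
            raise FormatError(
                f"channel shape mismatch: {self.outer_retina.shape} vs {self.choriocapillaris.shape}"
            )
        for name in ("outer_retina", "choriocapillaris"):
            grid = getattr(self, name)
            if grid.ndim != 2:
                raise FormatError(f"{name} must be a 2-D grid")
            if grid.size and (grid.min() < 0.0 or grid.max() > 1.0):
                raise FormatError(f"{name} intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.outer_retina.shape


# ---------------------------------------------------------------------------
# image / mask IO


def _to_gray01(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        scale = float(arr.max()) if arr.size and arr.max() > 1.0 else 1.0
    gray = arr.astype(np.float64).mean(axis=2) if arr.ndim == 3 else arr.astype(np.float64)
    return np.clip(gray / scale, 0.0, 1.0).astype(np.float32)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as a float grid in [0, 1] (RGB -> channel mean)."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim not in (2, 3):
        raise FormatError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return _to_gray01(arr)


def write_image(grid: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grid as 8-bit grayscale PNG or TIFF (by extension)."""
    if grid.ndim != 2:
        raise FormatError("only 2-D grids can be written")
    data = np.round(np.clip(grid, 0.0, 1.0) * 255.0).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def read_enface(path_outer: str | Path, path_choroid: str | Path,
                subject_id: str = "", image_id: str = "") -> EnFacePair:
    outer = read_image(path_outer)
    choroid = read_image(path_choroid)
    return EnFacePair(outer, choroid, subject_id=subject_id, image_id=image_id)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a {0, 255} PNG mask as a uint8 {0, 1} grid (threshold at 128)."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be 2-D")
    return (arr >= 128).astype(np.uint8)


def write_mask(grid: np.ndarray, path: str | Path) -> None:
    if grid.ndim != 2:
        raise FormatError("mask must be 2-D")
    Image.fromarray((np.asarray(grid) > 0).astype(np.uint8) * 255, mode="L").save(path)


# ---------------------------------------------------------------------------
# labels CSV


def read_labels(csv_path: str | Path) -> list[tuple[str, str, ActivityLabels]]:
    """Read the labels CSV -> list of (subject_id, image_id, ActivityLabels)."""
    df = pd.read_csv(csv_path, dtype={"subject_id": str, "image_id": str})
    if list(df.columns) != LABEL_COLUMNS:
        raise FormatError(f"labels CSV header must be {','.join(LABEL_COLUMNS)}")
    records = []
    for row in df.itertuples(index=False):
        values = {name: int(getattr(row, name)) for name in FEATURES}
        records.append((str(row.subject_id), str(row.image_id), ActivityLabels(**values)))
    return records


def write_labels(records: list[tuple[str, str, ActivityLabels]], csv_path: str | Path) -> None:
    rows = [
        {"subject_id": sid, "image_id": iid, **labels.as_dict()}
        for sid, iid, labels in records
    ]
    pd.DataFrame(rows, columns=LABEL_COLUMNS).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# manifest JSON


@dataclass
class SampleRecord:
    subject_id: str
    image_id: str
    outer_path: str
    choroid_path: str
    cnv_mask_path: str
    pa_mask_path: str = ""
    dh_mask_path: str = ""
    labels: dict = field(default_factory=dict)


def write_manifest(config: dict, samples: list[SampleRecord], path: str | Path) -> None:
    payload = {
        "config": config,
        "samples": [vars(s) for s in samples],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_manifest(path: str | Path) -> tuple[dict, list[SampleRecord]]:
    with open(path) as fh:
        payload = json.load(fh)
    if "samples" not in payload:
        raise FormatError("manifest missing 'samples'")
    samples = [SampleRecord(**rec) for rec in payload["samples"]]
    return payload.get("config", {}), samples


def load_sample(record: SampleRecord, root: str | Path = ".") -> tuple[EnFacePair, np.ndarray, ActivityLabels]:
    """Load one manifest record -> (pair, gt CNV mask, labels)."""
    root = Path(root)
    pair = read_enface(root / record.outer_path, root / record.choroid_path,
                       subject_id=record.subject_id, image_id=record.image_id)
    mask = read_mask(root / record.cnv_mask_path)
    labels = ActivityLabels(**{k: int(v) for k, v in record.labels.items()})
    return pair, mask, labels
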