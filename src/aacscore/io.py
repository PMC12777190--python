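"""Readers and writers for the annotation, image and record formats.

Landmarks and plaques travel as a LabelMe-dialect JSON document: corner
points labeled ``L{1..5}_{ul|ur|ll|lr}`` (upper-left, upper-right,
lower-left, lower-right) and plaque polygons labeled
``plaque_{L1..L4}_{ant|post}``.  Labels, not point order, carry the
semantics, so documents parse order-independently.  Coordinates are
0-based float pixels, origin top-left, y downward, kept at full precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .kauppila import AACSRecord, PlaqueSpec, SEGMENT_LEVELS
from .landmarks import (CORNER_KEYS, Landmark, Vertebra, VertebraSet,
                        VERTEBRA_LEVELS)
from .phantom import Phantom

SCHEMA_VERSION = "aacscore-labelme-1.0"

_CORNER_CODE = {"upper_left": "ul", "upper_right": "ur",
                "lower_left": "ll", "lower_right": "lr"}
_CODE_CORNER = {v: k for k, v in _CORNER_CODE.items()}
_WALL_CODE = {"anterior": "ant", "posterior": "post"}
_CODE_WALL = {v: k for k, v in _WALL_CODE.items()}


class SchemaError(ValueError):
    pass


def write_labelme(vertebrae: VertebraSet,
                  plaques: Iterable[PlaqueSpec],
                  image_meta: dict,
                  path: str | Path) -> Path:
    """Write landmarks + plaque annotations as a LabelMe-dialect document."""
    shapes = []
    for v in vertebrae:
        for key in CORNER_KEYS:
            lm = v.corners[key]
            shapes.append({"label": f"{v.level}_{_CORNER_CODE[key]}",
                           "points": [[lm.x, lm.y]],
                           "shape_type": "point"})
    for p in plaques:
        shapes.append({
            "label": f"plaque_{p.segment_level}_{_WALL_CODE[p.wall]}",
            "points": [],
            "shape_type": "polygon",
            "flags": {"coverage_fraction": p.coverage_fraction,
                      "thickness": p.thickness,
                      "start_fraction": p.start_fraction},
        })
    doc = {
        "version": SCHEMA_VERSION,
        "imagePath": str(image_meta.get("image_path", "")),
        "imageHeight": int(image_meta["image_height"]),
        "imageWidth": int(image_meta["image_width"]),
        "shapes": shapes,
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2))
    return path


def read_labelme(path: str | Path
                 ) -> tuple[VertebraSet, list[PlaqueSpec]]:
    """Parse a LabelMe-dialect document into landmarks + plaques."""
    doc = json.loads(Path(path).read_text())
    h, w = doc.get("imageHeight"), doc.get("imageWidth")
    corners: dict[str, dict[str, Landmark]] = {lv: {}
                                               for lv in VERTEBRA_LEVELS}
    plaques: list[PlaqueSpec] = []
    for shape in doc.get("shapes", []):
        label = shape["label"]
        if label.startswith("plaque_"):
            _, level, wall_code = label.split("_")
            flags = shape.get("flags", {})
            plaques.append(PlaqueSpec(
                segment_level=level, wall=_CODE_WALL[wall_code],
                coverage_fraction=float(flags["coverage_fraction"]),
                thickness=float(flags.get("thickness", 4.0)),
                start_fraction=float(flags.get("start_fraction", 0.0))))
            continue
        try:
            level, code = label.split("_")
            corner = _CODE_CORNER[code]
        except (ValueError, KeyError) as e:
            raise SchemaError(f"unrecognized label {label!r}") from e
        if level not in VERTEBRA_LEVELS:
            raise SchemaError(f"unknown vertebral level in label {label!r}")
        if corner in corners[level]:
            raise SchemaError(f"duplicate label {label!r}")
        (x, y), = shape["points"]
        if h is not None and w is not None:
            if not (0 <= x < w and 0 <= y < h):
                raise SchemaError(
                    f"{label}: point ({x}, {y}) outside the "
                    f"{w}x{h} image bounds")
        corners[level][corner] = Landmark(x=float(x), y=float(y))

    vertebrae = []
    for lv in VERTEBRA_LEVELS:
        missing = [k for k in CORNER_KEYS if k not in corners[lv]]
        if missing:
            raise SchemaError(
                f"missing corner label(s): "
                + ", ".join(f"{lv}_{_CORNER_CODE[k]}" for k in missing))
        vertebrae.append(Vertebra(level=lv, corners=corners[lv]))
    return VertebraSet(vertebrae), plaques


def average_annotations(a: VertebraSet, b: VertebraSet) -> VertebraSet:
    """Average two annotators' corner coordinates landmark-by-landmark."""
    vertebrae = []
    for va, vb in zip(a, b):
        if va.level != vb.level:
            raise ValueError("annotator documents disagree on levels")
        corners = {
            k: Landmark(x=(va.corners[k].x + vb.corners[k].x) / 2,
                        y=(va.corners[k].y + vb.corners[k].y) / 2)
            for k in CORNER_KEYS
        }
        vertebrae.append(Vertebra(level=va.level, corners=corners))
    return VertebraSet(vertebrae)


# ---------------------------------------------------------------------------
# images, records, manifests

def write_png(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    return path


def read_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("I")).astype(np.float32)


def write_record(record: AACSRecord, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(record.to_dict(), indent=2))
    return path


def write_cohort(cohort: Sequence[Phantom], out_dir: str | Path,
                 prefix: str = "phantom") -> Path:
    """Write a phantom cohort: PNGs, LabelMe JSONs and a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "annotation", *SEGMENT_LEVELS,
                         "total", "severity"])
        for i, ph in enumerate(cohort):
            stem = f"{prefix}_{i:04d}"
            write_png(ph.image, out / f"{stem}.png")
            write_labelme(ph.vertebrae, ph.plaques,
                          {"image_path": f"{stem}.png",
                           "image_height": ph.image.shape[0],
                           "image_width": ph.image.shape[1]},
                          out / f"{stem}.json")
            rec = ph.gt_record
            writer.writerow([f"{stem}.png", f"{stem}.json",
                             *[rec.segment_scores[lv]
                               for lv in SEGMENT_LEVELS],
                             rec.total, rec.severity])
    return manifest


def read_totals_csv(path: str | Path, column: str = "total") -> np.ndarray:
    """Read a column of total scores from a manifest-style CSV."""
    with Path(path).open(newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows or column not in rows[0]:
        raise ValueError(f"no {column!r} column in {path}")
    return np.array([float(r[column]) for r in rows])


def write_maps(path: str | Path, heatmap: np.ndarray,
               center_offset: np.ndarray, corner_offset: np.ndarray,
               stride: int) -> Path:
    path = Path(path)
    np.savez(path, heatmap=heatmap, center_offset=center_offset,
             corner_offset=corner_offset, stride=np.array(stride))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_maps(path: str | Path):
    with np.load(path) as data:
        return (data["heatmap"], data["center_offset"],
                data["corner_offset"], int(data["stride"]))
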