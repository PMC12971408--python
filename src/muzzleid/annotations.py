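"""Annotation and manifest IO for muzzle-pattern photographs.

Each photograph carries a LabelMe-compatible JSON annotation: one rectangle
delimiting the muzzle, exactly two circles marking the nostrils, and up to
two optional rectangles for antlers.  The database manifest is a CSV with
one row per photograph (individual id, path, species, sex, capture angle,
quality tier, blacklist flag).  Real photographs and synthetic ones flow
through the same interfaces.

Coordinates are 0-based pixel coordinates; rectangles are half-open
``[x0, x1) x [y0, y1)`` so cropping arithmetic is unambiguous.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationFormatError, MuzzleIdError

LABEL_MUZZLE = "muzzle"
LABEL_NOSTRIL = "nostril"
LABEL_ANTLER = "antler"

#: Manifest column order used by :func:`write_manifest`.
MANIFEST_COLUMNS = [
    "individual_id",
    "image_path",
    "species",
    "sex",
    "angle",
    "quality",
    "blacklisted",
]

QUALITY_LEVELS = ("high", "medium", "unusable")
ANGLES = ("0", "45")


@dataclass(frozen=True)
class Circle:
    """A circle given by its center and radius, in pixel coordinates."""

    cx: float
    cy: float
    r: float


@dataclass(frozen=True)
class Annotation:
    """Ground-truth shapes for one photograph.

    Attributes
    ----------
    muzzle_rect:
        ``(x0, y0, x1, y1)`` half-open rectangle bounding the muzzle.
    nostrils:
        Exactly two :class:`Circle` instances.
    antlers:
        Zero to two rectangles in the same convention as ``muzzle_rect``.
    image_size:
        ``(width, height)`` of the annotated image.
    """

    muzzle_rect: tuple[float, float, float, float]
    nostrils: tuple[Circle, Circle]
    antlers: tuple[tuple[float, float, float, float], ...] = ()
    image_size: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.muzzle_rect
        w, h = self.image_size
        if len(self.nostrils) != 2:
            raise AnnotationFormatError(
                f"expected exactly 2 nostril circles, got {len(self.nostrils)}"
            )
        if not (x0 < x1 and y0 < y1):
            raise AnnotationFormatError(f"degenerate muzzle rectangle {self.muzzle_rect}")
        if w and h and not (0 <= x0 and x1 <= w and 0 <= y0 and y1 <= h):
            raise AnnotationFormatError(
                f"muzzle rectangle {self.muzzle_rect} outside image bounds {self.image_size}"
            )


def _rect_shape(label: str, rect: Sequence[float]) -> dict:
    x0, y0, x1, y1 = rect
    return {
        "label": label,
        "points": [[float(x0), float(y0)], [float(x1), float(y1)]],
        "group_id": None,
        "shape_type": "rectangle",
        "flags": {},
    }


def write_annotation(annotation: Annotation, path: str | Path, image_path: str = "") -> None:
    """Write ``annotation`` as LabelMe-compatible JSON.

    Circles are stored LabelMe-style as ``[center, edge point]``; the edge
    point is placed at ``(cx + r, cy)`` so the radius round-trips exactly.
    """
    shapes = [_rect_shape(LABEL_MUZZLE, annotation.muzzle_rect)]
    for c in annotation.nostrils:
        shapes.append(
            {
                "label": LABEL_NOSTRIL,
                "points": [[float(c.cx), float(c.cy)], [float(c.cx + c.r), float(c.cy)]],
                "group_id": None,
                "shape_type": "circle",
                "flags": {},
            }
        )
    for rect in annotation.antlers:
        shapes.append(_rect_shape(LABEL_ANTLER, rect))
    doc = {
        "version": "5.3.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": image_path,
        "imageData": None,
        "imageWidth": int(annotation.image_size[0]),
        "imageHeight": int(annotation.image_size[1]),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_annotation(path: str | Path) -> Annotation:
    """Parse a LabelMe-compatible annotation JSON into an :class:`Annotation`.

    Raises
    ------
    AnnotationFormatError
        If the muzzle rectangle is missing, the nostril circle count is not
        two, or a shape cannot be interpreted.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationFormatError(f"cannot parse annotation {path}: {exc}") from exc

    muzzle = None
    nostrils: list[Circle] = []
    antlers: list[tuple[float, float, float, float]] = []
    for shape in doc.get("shapes", []):
        label = shape.get("label")
        pts = shape.get("points", [])
        if label == LABEL_MUZZLE and shape.get("shape_type") == "rectangle":
            (x0, y0), (x1, y1) = pts
            muzzle = (min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))
        elif label == LABEL_NOSTRIL and shape.get("shape_type") == "circle":
            (cx, cy), (ex, ey) = pts
            nostrils.append(Circle(cx, cy, math.hypot(ex - cx, ey - cy)))
        elif label == LABEL_ANTLER and shape.get("shape_type") == "rectangle":
            (x0, y0), (x1, y1) = pts
            antlers.append((min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1)))
    if muzzle is None:
        raise AnnotationFormatError(f"{path}: missing '{LABEL_MUZZLE}' rectangle")
    if len(nostrils) != 2:
        raise AnnotationFormatError(
            f"{path}: expected exactly 2 '{LABEL_NOSTRIL}' circles, found {len(nostrils)}"
        )
    return Annotation(
        muzzle_rect=muzzle,
        nostrils=(nostrils[0], nostrils[1]),
        antlers=tuple(antlers),
        image_size=(int(doc.get("imageWidth", 0)), int(doc.get("imageHeight", 0))),
    )


def crop_roi(image: np.ndarray, annotation: Annotation, mode: str = "rectangle") -> np.ndarray:
    """Extract the muzzle region of interest.

    ``rectangle`` returns the muzzle_rect subimage (the default operating
    mode of the pipeline).  ``trimmed`` additionally zeroes pixels outside an
    inscribed, slightly inset ellipse, removing corner clutter such as hair
    at the cost of discarding pattern area.
    """
    x0, y0, x1, y1 = (int(round(v)) for v in annotation.muzzle_rect)
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, image.shape[1]), min(y1, image.shape[0])
    if x1 <= x0 or y1 <= y0:
        raise MuzzleIdError(f"degenerate crop rectangle {(x0, y0, x1, y1)}")
    sub = image[y0:y1, x0:x1].copy()
    if mode == "rectangle":
        return sub
    if mode == "trimmed":
        h, w = sub.shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        # inset ellipse: 96% of the half-extent on each axis
        ay, ax = 0.48 * h, 0.48 * w
        inside = ((xx - (w - 1) / 2) / ax) ** 2 + ((yy - (h - 1) / 2) / ay) ** 2 <= 1.0
        if sub.ndim == 3:
            inside = inside[..., None]
        return np.where(inside, sub, 0)
    raise MuzzleIdError(f"unknown crop mode {mode!r}")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str, "angle": str})
    df["blacklisted"] = df["blacklisted"].astype(bool)
    return df


def filter_manifest(
    manifest: pd.DataFrame,
    quality_set: Iterable[str] | None = None,
    angle_set: Iterable[str] | None = None,
    exclude_blacklisted: bool = True,
) -> pd.DataFrame:
    """Select manifest rows by quality tier and capture angle.

    Blacklisted rows are dropped by default, mirroring the post-hoc exclusion
    of mis-acquired animals from the final evaluation.  ``None`` for either
    set means "no filtering on that axis".  Filtering is idempotent and the
    two axes commute.
    """
    out = manifest
    if quality_set is not None:
        out = out[out["quality"].isin(set(quality_set))]
    if angle_set is not None:
        angle_norm = {str(a).rstrip("°") for a in angle_set}
        out = out[out["angle"].astype(str).isin(angle_norm)]
    if exclude_blacklisted:
        out = out[~out["blacklisted"].astype(bool)]
    return out.reset_index(drop=True)


def count_acquisition_failures(manifest: pd.DataFrame) -> tuple[int, int]:
    """Return ``(n_unusable, n_attempts)`` over all non-blacklisted rows.

    Unusable captures never enter pair evaluation; they are tallied here and
    feed the fail-to-acquire rate.
    """
    rows = manifest[~manifest["blacklisted"].astype(bool)]
    return int((rows["quality"] == "unusable").sum()), int(len(rows))
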