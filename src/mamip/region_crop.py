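"""Anatomical head-and-neck cropping guided by bone-window CT projections.

The crop is defined on two orthogonal maximum intensity projections of the
bone-windowed CT: a coronal MIP (projection along the anterior-posterior
axis) and a sagittal MIP (projection along the left-right axis). A 2D
bounding box per plane — vertically spanning from roughly the
sternoclavicular joint level up to the top of the head, horizontally
between the acromioclavicular joints — is either loaded from an annotation
file or proposed by a rule-based bone-landmark heuristic. The two 2D boxes
are combined into one 3D box which is mapped onto the co-registered PET
volume through physical coordinates and applied as an index crop.

Projection images are 2D arrays indexed ``[u, v]`` where ``u`` is the
horizontal in-plane axis (x for coronal, y for sagittal) and ``v`` is the
superior-inferior axis (the volume's z index; larger v = more superior).
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .volume_io import ImageVolume

__all__ = [
    "BoundingBox2D",
    "BoundingBox3D",
    "plane_mip",
    "load_boxes_2d",
    "save_boxes_json",
    "propose_boxes_heuristic",
    "combine_boxes_3d",
    "map_box_to_volume",
    "crop",
]

_PLANES = ("coronal", "sagittal")


@dataclass(frozen=True)
class BoundingBox2D:
    """Axis-aligned half-open pixel box on a projection image."""

    plane: str
    u_min: int
    u_max: int
    v_min: int
    v_max: int

    def __post_init__(self):
        if self.plane not in _PLANES:
            raise ValueError(f"plane must be one of {_PLANES}, got {self.plane!r}")
        if not (self.u_min < self.u_max and self.v_min < self.v_max):
            raise ValueError(f"degenerate 2D box {self}")
        if min(self.u_min, self.v_min) < 0:
            raise ValueError(f"negative box indices in {self}")

    def validate_against(self, image_w: int, image_h: int) -> None:
        """Check the box lies inside a (u-size, v-size) image."""
        if self.u_max > image_w or self.v_max > image_h:
            raise ValueError(
                f"box {self} exceeds image bounds ({image_w}, {image_h})"
            )


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned half-open voxel box."""

    x_min: int
    x_max: int
    y_min: int
    y_max: int
    z_min: int
    z_max: int

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max and self.z_min < self.z_max):
            raise ValueError(f"degenerate 3D box {self}")
        if min(self.x_min, self.y_min, self.z_min) < 0:
            raise ValueError(f"negative box indices in {self}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x_max - self.x_min, self.y_max - self.y_min, self.z_max - self.z_min)


def plane_mip(vol: ImageVolume, plane: str) -> np.ndarray:
    """Maximum intensity projection onto the coronal or sagittal plane.

    Coronal projects along y (anterior-posterior) giving an image indexed
    ``[x, z]``; sagittal projects along x giving ``[y, z]``. The
    superior-inferior axis is preserved as the image's second (v) axis.
    """
    if plane == "coronal":
        return np.max(vol.voxels, axis=1)
    if plane == "sagittal":
        return np.max(vol.voxels, axis=0)
    raise ValueError(f"plane must be one of {_PLANES}, got {plane!r}")


# ---------------------------------------------------------------------------
# Box file ingestion
# ---------------------------------------------------------------------------

def _boxes_from_xml(path: Path) -> list[BoundingBox2D]:
    """Parse the Pascal-VOC-style XML dialect written by common 2D labelers.

    Each ``<object>`` must carry the plane name in ``<name>`` and a
    ``<bndbox>`` with xmin/xmax (u) and ymin/ymax (v); ``<size>`` gives the
    image bounds used for validation. Coordinates are read as 0-based with
    exclusive maxima.
    """
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed annotation XML {path}: {exc}") from exc
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise ValueError(f"{path}: missing <size> with width/height")
    image_w = int(size.find("width").text)
    image_h = int(size.find("height").text)
    boxes = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        bnd = obj.find("bndbox")
        if name is None or bnd is None:
            raise ValueError(f"{path}: <object> missing <name> or <bndbox>")
        vals = {}
        for tag in ("xmin", "xmax", "ymin", "ymax"):
            txt = bnd.findtext(tag)
            if txt is None:
                raise ValueError(f"{path}: <bndbox> missing <{tag}>")
            vals[tag] = int(round(float(txt)))
        box = BoundingBox2D(name, vals["xmin"], vals["xmax"], vals["ymin"], vals["ymax"])
        box.validate_against(image_w, image_h)
        boxes.append(box)
    if not boxes:
        raise ValueError(f"{path}: no <object> boxes found")
    return boxes


def _boxes_from_json(path: Path) -> list[BoundingBox2D]:
    """Parse the package's JSON dialect: a list of box objects."""
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = payload.get("boxes", [])
    if not isinstance(payload, list) or not payload:
        raise ValueError(f"{path}: expected a non-empty list of boxes")
    boxes = []
    for entry in payload:
        try:
            box = BoundingBox2D(
                entry["plane"],
                int(entry["u_min"]),
                int(entry["u_max"]),
                int(entry["v_min"]),
                int(entry["v_max"]),
            )
        except KeyError as exc:
            raise ValueError(f"{path}: box entry missing field {exc}") from exc
        box.validate_against(int(entry["image_w"]), int(entry["image_h"]))
        boxes.append(box)
    return boxes


def load_boxes_2d(path) -> list[BoundingBox2D]:
    """Load per-plane 2D boxes from an XML or JSON annotation file."""
    path = Path(path)
    if path.suffix.lower() == ".xml":
        return _boxes_from_xml(path)
    if path.suffix.lower() == ".json":
        return _boxes_from_json(path)
    raise ValueError(f"unsupported annotation format {path.suffix!r} for {path}")


def save_boxes_json(boxes, image_sizes, path) -> None:
    """Write boxes in the JSON dialect.

    ``image_sizes`` maps plane -> (image_w, image_h).
    """
    payload = [
        {
            "plane": b.plane,
            "u_min": b.u_min,
            "u_max": b.u_max,
            "v_min": b.v_min,
            "v_max": b.v_max,
            "image_w": image_sizes[b.plane][0],
            "image_h": image_sizes[b.plane][1],
        }
        for b in boxes
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Rule-based landmark heuristic
# ---------------------------------------------------------------------------

def _heuristic_one_plane(
    image: np.ndarray, plane: str, threshold_hu: float, margin: int
) -> BoundingBox2D:
    mask = image > threshold_hu
    if not mask.any():
        raise ValueError("no bone detected above threshold in bone-window MIP")
    nu, nv = image.shape
    rows = np.where(mask.any(axis=0))[0]  # v rows containing bone
    top_v = int(rows.max())
    # Horizontal bone extent per row; the widest row proxies the shoulder
    # girdle (AC/SC joint level). Ties resolve to the most inferior row.
    widths = np.zeros(nv, dtype=int)
    for v in rows:
        cols = np.where(mask[:, v])[0]
        widths[v] = cols.max() - cols.min() + 1
    shoulder_v = int(np.argmax(widths))
    v_min, v_max = shoulder_v, top_v + 1
    if v_max - v_min < 2:  # bone collapsed onto one row; take full bone extent
        v_min, v_max = int(rows.min()), top_v + 1
        if v_max - v_min < 2:
            v_max = min(v_min + 2, nv)
            v_min = max(v_max - 2, 0)
    # u extent: bone columns within the upper half of the vertical extent
    # (head/spine column, excluding the shoulder bar), dilated by a margin.
    upper_lo = v_min + (v_max - v_min) // 2
    sub = mask[:, upper_lo:v_max]
    cols = np.where(sub.any(axis=1))[0]
    if cols.size == 0:
        cols = np.where(mask.any(axis=1))[0]
    u_min = max(int(cols.min()) - margin, 0)
    u_max = min(int(cols.max()) + 1 + margin, nu)
    return BoundingBox2D(plane, u_min, u_max, v_min, v_max)


def propose_boxes_heuristic(
    bone_coronal: np.ndarray,
    bone_sagittal: np.ndarray,
    threshold_hu: float = 700.0,
    margin: int = 4,
) -> tuple[BoundingBox2D, BoundingBox2D]:
    """Propose head-and-neck boxes from bone-window CT MIPs.

    Rule per plane: the vertical extent runs from the row of maximal
    above-threshold horizontal bone width (shoulder-girdle proxy for the
    SC/AC joint level) up to the topmost bone row (top of the head); the
    horizontal extent is the bone column span within the upper half of that
    vertical extent, dilated by ``margin`` pixels. The comparison is
    strictly above ``threshold_hu`` because clamp-windowed MIP backgrounds
    sit exactly at the window's lower bound.
    """
    cor = _heuristic_one_plane(np.asarray(bone_coronal), "coronal", threshold_hu, margin)
    sag = _heuristic_one_plane(np.asarray(bone_sagittal), "sagittal", threshold_hu, margin)
    return cor, sag


# ---------------------------------------------------------------------------
# 2D -> 3D combination and cropping
# ---------------------------------------------------------------------------

def combine_boxes_3d(
    coronal: BoundingBox2D,
    sagittal: BoundingBox2D,
    vol_shape: tuple[int, int, int],
    z_mode: str = "union",
) -> BoundingBox3D:
    """Combine the two per-plane boxes into a 3D box, clipped to a volume.

    x from the coronal u-extent, y from the sagittal u-extent, z from the
    two v-extents. The default reconciles the two vertical extents by
    union (over-inclusion keeps all primary tumors / involved nodes in the
    crop); ``z_mode="intersection"`` is the stricter alternative.
    """
    if coronal.plane != "coronal" or sagittal.plane != "sagittal":
        raise ValueError("boxes must be tagged coronal and sagittal respectively")
    if z_mode == "union":
        z_min = min(coronal.v_min, sagittal.v_min)
        z_max = max(coronal.v_max, sagittal.v_max)
    elif z_mode == "intersection":
        z_min = max(coronal.v_min, sagittal.v_min)
        z_max = min(coronal.v_max, sagittal.v_max)
    else:
        raise ValueError(f"unknown z_mode {z_mode!r}")
    nx, ny, nz = vol_shape
    box = (
        max(coronal.u_min, 0), min(coronal.u_max, nx),
        max(sagittal.u_min, 0), min(sagittal.u_max, ny),
        max(z_min, 0), min(z_max, nz),
    )
    if box[0] >= box[1] or box[2] >= box[3] or box[4] >= box[5]:
        raise ValueError(f"combined box {box} has empty intersection with volume {vol_shape}")
    return BoundingBox3D(*box)


def map_box_to_volume(box: BoundingBox3D, src: ImageVolume, dst: ImageVolume) -> BoundingBox3D:
    """Map a voxel box from one volume's grid to a co-registered volume's.

    The mapping goes through physical coordinates (origin + index*spacing)
    rather than raw indices, so PET grids that are registered but not
    identically sampled to the CT are handled correctly. The result is
    clipped to the destination volume.
    """
    lo_idx = np.array([box.x_min, box.y_min, box.z_min], dtype=float)
    hi_idx = np.array([box.x_max, box.y_max, box.z_max], dtype=float)
    s_sp, s_or = np.asarray(src.spacing_mm), np.asarray(src.origin_mm)
    d_sp, d_or = np.asarray(dst.spacing_mm), np.asarray(dst.origin_mm)
    lo_mm = s_or + lo_idx * s_sp
    hi_mm = s_or + hi_idx * s_sp
    lo = np.floor((lo_mm - d_or) / d_sp).astype(int)
    hi = np.ceil((hi_mm - d_or) / d_sp).astype(int)
    lo = np.clip(lo, 0, np.asarray(dst.shape) - 1)
    hi = np.clip(hi, 1, np.asarray(dst.shape))
    return BoundingBox3D(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])


def crop(vol: ImageVolume, box: BoundingBox3D) -> ImageVolume:
    """Extract the half-open box from a volume, shifting the origin."""
    nx, ny, nz = vol.shape
    if box.x_max > nx or box.y_max > ny or box.z_max > nz:
        raise ValueError(f"box {box} exceeds volume shape {vol.shape}")
    voxels = vol.voxels[box.x_min:box.x_max, box.y_min:box.y_max, box.z_min:box.z_max]
    origin = tuple(
        o + lo * s
        for o, lo, s in zip(vol.origin_mm, (box.x_min, box.y_min, box.z_min), vol.spacing_mm)
    )
    return ImageVolume(voxels.copy(), vol.spacing_mm, origin, vol.modality)
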