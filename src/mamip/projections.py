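"""Multi-angle maximum intensity projections (MA-MIPs) of a cropped PET.

The cropped PET volume is rotated about its superior-inferior (z) axis in
fixed angular steps and a maximum intensity projection is captured per
rotation — 72 views at the default 5 degree step, covering one full axial
turn. Each projection is then mapped to a 3-channel, square, standardized
array suitable as input for a 2D convolutional backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .volume_io import ImageVolume

__all__ = [
    "MipImage",
    "MipStack",
    "PrepConfig",
    "rotate_axial",
    "generate_ma_mips",
    "prep_for_backbone",
]

#: Channel normalization constants customary for ImageNet-trained backbones;
#: applied after mapping intensities to [0, 1].
CHANNEL_MEAN = (0.485, 0.456, 0.406)
CHANNEL_STD = (0.229, 0.224, 0.225)


@dataclass
class MipImage:
    """One maximum intensity projection at a given axial rotation angle."""

    pixels: np.ndarray
    angle_deg: float
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"MIP pixels must be 2D, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("MIP pixels must be finite")
        if not (0.0 <= self.angle_deg < 360.0):
            raise ValueError(f"angle_deg must lie in [0, 360), got {self.angle_deg}")


@dataclass
class MipStack:
    """Ordered multi-angle MIP set; ``mips[i]`` is at angle ``i * step_deg``."""

    mips: list[MipImage]
    step_deg: float

    def __post_init__(self):
        expected = int(round(360.0 / self.step_deg))
        if len(self.mips) != expected:
            raise ValueError(
                f"stack of {len(self.mips)} views inconsistent with step {self.step_deg}"
            )
        for i, m in enumerate(self.mips):
            if abs(m.angle_deg - i * self.step_deg) > 1e-9:
                raise ValueError(f"view {i} has angle {m.angle_deg}, expected {i * self.step_deg}")

    def __len__(self) -> int:
        return len(self.mips)

    def __iter__(self):
        return iter(self.mips)

    def __getitem__(self, i) -> MipImage:
        return self.mips[i]

    @property
    def angles(self) -> list[float]:
        return [m.angle_deg for m in self.mips]


def rotate_axial(vol: ImageVolume, angle_deg: float) -> ImageVolume:
    """Rotate a volume about the z axis through the volume center.

    A point at azimuth phi in the (x, y) plane moves to phi + angle
    (counterclockwise, x toward y). Linear interpolation, zero fill
    outside the grid, output grid identical to the input grid. Angles
    that are exact multiples of 360 short-circuit to an identity copy.
    """
    angle = float(angle_deg) % 360.0
    if angle == 0.0:
        return vol.copy()
    nx, ny, nz = vol.shape
    # exact grid rotations avoid interpolation entirely (odd quarter-turns
    # only when the in-plane grid is square, else the extent would change)
    if angle % 90.0 == 0.0:
        k = int(angle // 90.0)
        if k % 2 == 0 or nx == ny:
            out = np.rot90(vol.voxels, k=k, axes=(0, 1)).copy()
            return ImageVolume(out, vol.spacing_mm, vol.origin_mm, vol.modality)
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    theta = np.deg2rad(angle)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    xs = np.arange(nx) - cx
    ys = np.arange(ny) - cy
    xg, yg = np.meshgrid(xs, ys, indexing="ij")
    # inverse map: output index -> input index (rotate by -angle)
    src_x = cos_t * xg + sin_t * yg + cx
    src_y = -sin_t * xg + cos_t * yg + cy
    coords = np.stack([src_x, src_y])
    out = np.empty_like(vol.voxels, dtype=np.float32)
    for k in range(nz):  # per-slice 2D interpolation keeps memory flat
        out[:, :, k] = ndi.map_coordinates(
            np.asarray(vol.voxels[:, :, k], dtype=np.float32),
            coords,
            order=1,
            mode="constant",
            cval=0.0,
        )
    return ImageVolume(out, vol.spacing_mm, vol.origin_mm, vol.modality)


def generate_ma_mips(vol: ImageVolume, step_deg: float = 5.0) -> MipStack:
    """Generate the multi-angle MIP stack of a (cropped) PET volume.

    For each rotation angle ``i * step_deg`` the volume is rotated axially
    and projected along the anterior-posterior axis, so the angle-0 view
    reproduces the coronal MIP. ``step_deg`` must divide 360; the default
    5 degree step yields 72 views.
    """
    n_views_f = 360.0 / step_deg
    n_views = int(round(n_views_f))
    if step_deg <= 0 or abs(n_views_f - n_views) > 1e-9:
        raise ValueError(f"step_deg must be a positive divisor of 360, got {step_deg}")
    spacing = (vol.spacing_mm[0], vol.spacing_mm[2])
    mips = []
    for i in range(n_views):
        rotated = rotate_axial(vol, i * step_deg)
        pixels = np.max(rotated.voxels, axis=1)  # project along y; image [x, z]
        mips.append(MipImage(pixels, i * step_deg, spacing))
    return MipStack(mips, step_deg)


@dataclass
class PrepConfig:
    """How a MIP is normalized before entering the backbone.

    ``normalization="minmax"`` rescales each image by its own min/max
    (shape-only information); ``"fixed"`` uses the absolute window
    ``fixed_window`` so uptake intensity remains comparable across
    patients.
    """

    input_size: int = 64
    normalization: str = "minmax"
    fixed_window: tuple[float, float] = (0.0, 12.0)
    channel_mean: tuple[float, float, float] = CHANNEL_MEAN
    channel_std: tuple[float, float, float] = CHANNEL_STD


def prep_for_backbone(mip, config: PrepConfig | None = None) -> np.ndarray:
    """Map one MIP to a standardized (3, S, S) backbone input.

    Intensities are mapped to [0, 1] (per-image min-max by default, or a
    fixed window), the image is center zero-padded to square, resized to
    ``input_size``, replicated to 3 channels and channel-standardized. A
    constant image maps to all zeros before standardization rather than
    raising.
    """
    config = config or PrepConfig()
    pixels = np.asarray(mip.pixels if isinstance(mip, MipImage) else mip, dtype=np.float64)
    if config.normalization == "minmax":
        lo, hi = float(pixels.min()), float(pixels.max())
        scaled = np.zeros_like(pixels) if hi <= lo else (pixels - lo) / (hi - lo)
    elif config.normalization == "fixed":
        lo, hi = config.fixed_window
        if hi <= lo:
            raise ValueError(f"invalid fixed window {config.fixed_window}")
        scaled = np.clip((pixels - lo) / (hi - lo), 0.0, 1.0)
    else:
        raise ValueError(f"unknown normalization {config.normalization!r}")
    # center pad to square, preserving aspect ratio
    nu, nv = scaled.shape
    side = max(nu, nv)
    padded = np.zeros((side, side), dtype=np.float64)
    off_u, off_v = (side - nu) // 2, (side - nv) // 2
    padded[off_u:off_u + nu, off_v:off_v + nv] = scaled
    if side != config.input_size:
        padded = resize(
            padded,
            (config.input_size, config.input_size),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    mean = np.asarray(config.channel_mean)[:, None, None]
    std = np.asarray(config.channel_std)[:, None, None]
    channels = np.repeat(padded[None, :, :], 3, axis=0)
    return ((channels - mean) / std).astype(np.float32)
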