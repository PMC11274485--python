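"""Frozen convolutional feature extraction and global pooling.

Each MIP view is passed through a frozen 2D convolutional encoder and the
resulting channel x height x width activation tensor is reduced to a
length-C vector by one of four global poolings (average, max, median,
standard deviation). Stacking the per-view vectors gives the patient's
views x channels feature matrix.

The encoder family here is a registry of deterministic random-feature
convolutional networks: stacks of stride-2 3x3 convolutions with ReLU,
whose weights are drawn once from a fixed counter-based generator keyed by
the backbone id and then frozen. Random convolutional features are a
well-studied featurization: they preserve spatial structure, are strictly
deterministic, train nothing, and need no external weight files. The
registry exposes three scales (small / medium / large) with increasing
depth and width; channel count is always taken from the instantiated
model, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projections import MipStack, PrepConfig, prep_for_backbone

__all__ = [
    "FeatureTensor",
    "FeatureMatrix",
    "BACKBONES",
    "get_backbone",
    "extract_feature_tensor",
    "global_pool",
    "extract_mamip_features",
    "POOLINGS",
]

POOLINGS = ("avg", "max", "median", "std")


@dataclass
class FeatureTensor:
    """Pre-pooling activation tensor of one image, indexed (c, h, w)."""

    values: np.ndarray
    backbone_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"feature tensor must be (C, H, W), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature tensor contains non-finite values")


@dataclass
class FeatureMatrix:
    """Views x channels matrix of pooled features for one patient."""

    values: np.ndarray
    backbone_id: str
    pooling_id: str
    view_angles: list[float]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"feature matrix must be (V, C), got {self.values.shape}")
        if len(self.view_angles) != self.values.shape[0]:
            raise ValueError("view_angles length must match the number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_views(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Backbone registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _BackboneSpec:
    widths: tuple[int, ...]
    weight_key: int  # fixed key of the counter-based weight generator


#: Three scales with increasing depth/width, mirroring a small/medium/large
#: pretrained-encoder family. Weight keys are fixed constants so weights are
#: identical across processes and runs.
BACKBONES: dict[str, _BackboneSpec] = {
    "small": _BackboneSpec((16, 32, 64), 101),
    "medium": _BackboneSpec((24, 48, 96, 160), 202),
    "large": _BackboneSpec((32, 64, 128, 256, 384), 303),
}


class RandomConvBackbone:
    """Frozen stack of stride-2 3x3 convolutions with ReLU.

    Weights use He-scaled Gaussian initialization drawn from a Philox
    generator keyed by the backbone id, generated once per process and
    cached; inference is pure numpy (im2col + matmul) and bit-stable for a
    fixed input on a given platform.
    """

    def __init__(self, backbone_id: str):
        if backbone_id not in BACKBONES:
            raise KeyError(
                f"unknown backbone {backbone_id!r}; available: {sorted(BACKBONES)}. "
                "Register custom encoders by adding an entry to BACKBONES."
            )
        spec = BACKBONES[backbone_id]
        self.backbone_id = backbone_id
        rng = np.random.Generator(np.random.Philox(key=spec.weight_key))
        self.layers = []
        c_in = 3
        for c_out in spec.widths:
            w = rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / (c_in * 9))
            b = np.zeros(c_out)
            self.layers.append((w.astype(np.float32), b.astype(np.float32)))
            c_in = c_out
        self.n_channels = c_in

    @staticmethod
    def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 2) -> np.ndarray:
        # x: (C_in, H, W); w: (C_out, C_in, 3, 3); padding 1
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        win = win[:, ::stride, ::stride]  # (C_in, Ho, Wo, 3, 3)
        out = np.einsum("ihwkl,oikl->ohw", win, w, optimize=True)
        return out + b[:, None, None]

    def forward(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=np.float32)
        if x.ndim != 3 or x.shape[0] != 3:
            raise ValueError(f"backbone input must be (3, H, W), got {x.shape}")
        for i, (w, b) in enumerate(self.layers):
            x = self._conv2d(x, w, b)
            if i < len(self.layers) - 1:
                x = np.maximum(x, 0.0)
        return x.astype(np.float32)


_BACKBONE_CACHE: dict[str, RandomConvBackbone] = {}


def get_backbone(backbone_id: str) -> RandomConvBackbone:
    """Return the (cached) frozen encoder for a registry id."""
    if backbone_id not in _BACKBONE_CACHE:
        _BACKBONE_CACHE[backbone_id] = RandomConvBackbone(backbone_id)
    return _BACKBONE_CACHE[backbone_id]


def extract_feature_tensor(image: np.ndarray, backbone_id: str = "small") -> FeatureTensor:
    """Run one prepared (3, S, S) image through the frozen encoder.

    Returns the final convolutional activation tensor (the stage a
    classifier head would consume). Deterministic: the same image always
    yields a bit-identical tensor.
    """
    backbone = get_backbone(backbone_id)
    return FeatureTensor(backbone.forward(image), backbone_id)


def global_pool(t: FeatureTensor, method: str) -> np.ndarray:
    """Reduce a (C, H, W) tensor to a length-C vector per channel.

    ``avg``/``max``/``median`` are the per-channel spatial statistics;
    ``std`` is the population (divide-by-N) standard deviation over the
    H*W spatial positions — a feature summary, not a variance estimator.
    """
    v = t.values if isinstance(t, FeatureTensor) else np.asarray(t)
    if v.shape[1] < 1 or v.shape[2] < 1:
        raise ValueError(f"empty spatial dimensions in tensor of shape {v.shape}")
    flat = v.reshape(v.shape[0], -1).astype(np.float64)
    if method == "avg":
        return flat.mean(axis=1)
    if method == "max":
        return flat.max(axis=1)
    if method == "median":
        return np.median(flat, axis=1)
    if method == "std":
        return flat.std(axis=1)  # population convention (ddof=0)
    raise ValueError(f"unknown pooling method {method!r}; expected one of {POOLINGS}")


def extract_mamip_features(
    stack: MipStack,
    backbone_id: str = "small",
    pooling: str = "avg",
    prep: PrepConfig | None = None,
) -> FeatureMatrix:
    """Pool frozen encoder features for every view of a MIP stack.

    Row i of the result is ``global_pool(encoder(prep(mip_i)))``; rows are
    ordered by rotation angle. Views are processed independently, so the
    result equals single-image evaluation view by view.
    """
    prep = prep or PrepConfig()
    rows = []
    for mip in stack:
        tensor = extract_feature_tensor(prep_for_backbone(mip, prep), backbone_id)
        rows.append(global_pool(tensor, pooling))
    return FeatureMatrix(np.vstack(rows), backbone_id, pooling, stack.angles)
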