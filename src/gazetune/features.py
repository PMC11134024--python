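"""Convolutional feature extraction.

Two backbone variants behind one interface:

* ``vgg19`` — the standard VGG-19 stack (sixteen 3x3 convolution layers in
  five blocks of 64/128/256/512/512 channels, each block closed by 2x2
  max-pooling) truncated at the first 4096-unit fully connected layer, whose
  activations are the feature vector. One image in, 4096 features out.
* ``tiny`` — two small convolution blocks plus one fully connected layer of
  configurable width, for desk-scale experiments.

Both run forward-only in numpy with seeded He-initialized weights; extraction
is therefore fully deterministic for a fixed configuration and seed.
Pretrained weights can be loaded from an ``.npz`` file but are never required:
only the feature-space geometry (shape, determinism) is contracted here.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .synthetic import SyntheticEyeImage

_VGG19_PLAN: tuple = (
    64, 64, "M",
    128, 128, "M",
    256, 256, 256, 256, "M",
    512, 512, 512, 512, "M",
    512, 512, 512, 512, "M",
)


@dataclass(frozen=True)
class BackboneConfig:
    """Backbone selection and geometry.

    For ``vgg19`` the feature dimension is fixed at 4096 and the first
    convolution stage has 64 kernels of size 3x3; ``tiny`` exposes both the
    input size and feature width.
    """

    variant: str = "tiny"
    input_size: int = 224
    feature_dim: int = 4096
    conv_kernel: int = 3
    first_layer_kernels: int = 64

    def __post_init__(self):
        if self.variant not in ("vgg19", "tiny"):
            raise ValueError(f"unknown backbone variant {self.variant!r}")
        if self.variant == "vgg19":
            if self.feature_dim != 4096:
                raise ValueError("vgg19 variant has feature_dim = 4096")
            if self.first_layer_kernels != 64:
                raise ValueError("vgg19 variant has 64 first-layer kernels")

    @staticmethod
    def tiny(input_size: int = 32, feature_dim: int = 32) -> "BackboneConfig":
        return BackboneConfig(
            variant="tiny",
            input_size=input_size,
            feature_dim=feature_dim,
            first_layer_kernels=8,
        )


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padding 3x3 convolution via im2col. x: (N,C,H,W), w: (O,C,k,k)."""
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # (N, C, H, W, k, k) windows -> (N, H, W, C*k*k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    n, c, hh, ww = win.shape[:4]
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, hh, ww, c * k * k)
    out = col @ w.reshape(w.shape[0], -1).T + b
    return out.transpose(0, 3, 1, 2)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    x = x[:, :, : h2 * 2, : w2 * 2]
    return x.reshape(n, c, h2, 2, w2, 2).max(axis=(3, 5))


class ConvFeatureExtractor:
    """Seeded, forward-only convolutional feature extractor."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        if cfg.variant == "vgg19":
            self.plan = _VGG19_PLAN
            self.in_channels = 3
        else:
            self.plan = (cfg.first_layer_kernels, "M", cfg.first_layer_kernels * 2, "M")
            self.in_channels = 1
        k = cfg.conv_kernel
        self.conv_weights: list[tuple[np.ndarray, np.ndarray]] = []
        cin = self.in_channels
        spatial = cfg.input_size
        for item in self.plan:
            if item == "M":
                spatial //= 2
                continue
            fan_in = cin * k * k
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(item, cin, k, k)).astype(
                np.float32
            )
            b = np.zeros(item, dtype=np.float32)
            self.conv_weights.append((w, b))
            cin = item
        self.flat_dim = cin * spatial * spatial
        self.fc_w = rng.normal(
            0.0, np.sqrt(2.0 / self.flat_dim), size=(self.flat_dim, cfg.feature_dim)
        ).astype(np.float32)
        self.fc_b = np.zeros(cfg.feature_dim, dtype=np.float32)

    @property
    def feature_dim(self) -> int:
        return self.cfg.feature_dim

    def layer_shapes(self) -> list[tuple[int, int, int]]:
        """(channels, height, width) after every stage, for one input image."""
        shapes = []
        c, s = self.in_channels, self.cfg.input_size
        for item in self.plan:
            if item == "M":
                s //= 2
            else:
                c = item
            shapes.append((c, s, s))
        return shapes

    def _prepare(self, images: list[SyntheticEyeImage]) -> np.ndarray:
        s = self.cfg.input_size
        batch = []
        for im in images:
            px = np.asarray(im.pixels, dtype=np.float32)
            if px.ndim == 2:
                px = px[:, :, None]
            if px.shape[0] != s or px.shape[1] != s:
                px = resize(px, (s, s), anti_aliasing=True, preserve_range=True)
            if self.in_channels == 3 and px.shape[2] == 1:
                px = np.repeat(px, 3, axis=2)
            elif self.in_channels == 1 and px.shape[2] == 3:
                px = px.mean(axis=2, keepdims=True)
            batch.append(px.transpose(2, 0, 1))
        return np.asarray(batch, dtype=np.float32)

    def forward(self, x: np.ndarray, trace: list | None = None) -> np.ndarray:
        i = 0
        for item in self.plan:
            if item == "M":
                x = _maxpool2(x)
            else:
                w, b = self.conv_weights[i]
                x = np.maximum(_conv2d(x, w, b), 0.0)
                i += 1
            if trace is not None:
                trace.append(x.shape)
        x = x.reshape(x.shape[0], -1)
        return np.maximum(x @ self.fc_w + self.fc_b, 0.0)

    def load_weights(self, path: str | pathlib.Path) -> None:
        """Load conv/fc weights from an .npz (keys conv{i}_w, conv{i}_b, fc_w, fc_b)."""
        data = np.load(path)
        self.conv_weights = [
            (data[f"conv{i}_w"], data[f"conv{i}_b"])
            for i in range(len(self.conv_weights))
        ]
        self.fc_w, self.fc_b = data["fc_w"], data["fc_b"]


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> ConvFeatureExtractor:
    """Instantiate a seeded feature extractor for the given configuration."""
    return ConvFeatureExtractor(cfg, seed=seed)


@dataclass
class FeatureMatrix:
    """n x d feature matrix with row identifiers."""

    F: np.ndarray
    source_ids: list

    def __post_init__(self):
        if not np.isfinite(self.F).all():
            raise ValueError("features must be finite")

    def save(self, path: str | pathlib.Path, meta: dict | None = None) -> None:
        path = pathlib.Path(path)
        np.savetxt(path, self.F, delimiter=",", fmt="%.6e")
        header = {"n": int(self.F.shape[0]), "d": int(self.F.shape[1])}
        header.update(meta or {})
        path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def extract_features(
    extractor: ConvFeatureExtractor,
    images: list[SyntheticEyeImage],
    batch_size: int = 32,
) -> FeatureMatrix:
    """One feature row per image; width = the backbone's feature dimension."""
    if len(images) == 0:
        raise ValueError("need at least one image")
    rows = []
    for i in range(0, len(images), batch_size):
        rows.append(extractor.forward(extractor._prepare(images[i : i + batch_size])))
    return FeatureMatrix(
        F=np.vstack(rows).astype(np.float64), source_ids=list(range(len(images)))
    )
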