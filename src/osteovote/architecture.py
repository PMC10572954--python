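"""CNN architecture specification with closed-form shape and parameter accounting.

The model here is a plain sequential stack described layer by layer, so
shapes and parameter counts can be verified without instantiating any
weights. Conventions (the only ones that reproduce the published
224 -> 112 -> 56 -> 28 -> 14 -> 7 -> 3 -> 1 chain and the 715,311 total):

* convolutions use "same" padding, stride 1: spatial size is preserved,
  parameters = (f^2 * C_in + 1) * C_out;
* max pooling uses stride = pool size with floor division on the spatial
  dimensions, no parameters;
* batch normalization carries 4 parameters per channel (scale, shift and
  the two moving statistics — the moving statistics are non-trainable but
  counted);
* dense layers have (n_in + 1) * n_out parameters;
* flatten and dropout are parameter-free.

:func:`proposed_architecture` builds the 19-layer classifier used for the
three-class osteosarcoma problem: input batch-norm, seven conv/pool pairs
with channel progression 32, 32, 64, 64, 128, 128, 256 (all conv 3x3, all
pool 2x2), flatten, a 512-unit ReLU dense layer, dropout, and a 3-way
softmax head — 715,311 parameters at 224x224x3 input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

LAYER_KINDS = ("batch_norm", "conv2d", "max_pool", "flatten", "dense", "dropout")


class ShapeError(ValueError):
    """Raised when a layer stack cannot chain shapes consistently."""


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    filter_size: int | None = None  # side length f for conv/pool
    depth_or_units: int | None = None  # output channels or dense units
    activation: str = "none"
    dropout_rate: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv2d", "max_pool") and (self.filter_size or 0) < 1:
            raise ValueError(f"{self.kind} needs filter_size >= 1")
        if self.kind in ("conv2d", "dense") and (self.depth_or_units or 0) < 1:
            raise ValueError(f"{self.kind} needs depth_or_units >= 1")
        if self.activation not in ("relu", "softmax", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.kind == "dropout" and not (self.dropout_rate is not None and 0 <= self.dropout_rate < 1):
            raise ValueError("dropout needs a rate in [0, 1)")


@dataclass
class ArchitectureSpec:
    """Ordered layer stack plus derived shapes and parameter counts."""

    input_shape: tuple[int, int, int]
    layers: list[LayerSpec]
    output_shapes: list[tuple] = field(default_factory=list)
    per_layer_params: list[int] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(self.per_layer_params)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "input_shape": list(self.input_shape),
            "layers": [
                {
                    "kind": l.kind,
                    "filter_size": l.filter_size,
                    "depth_or_units": l.depth_or_units,
                    "activation": l.activation,
                    "dropout_rate": l.dropout_rate,
                }
                for l in self.layers
            ],
            "output_shapes": [list(s) for s in self.output_shapes],
            "per_layer_params": self.per_layer_params,
            "total_params": self.total_params,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ArchitectureSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        spec = cls(
            input_shape=tuple(payload["input_shape"]),
            layers=[LayerSpec(**l) for l in payload["layers"]],
        )
        finalize(spec)
        return spec


def infer_shapes(spec: ArchitectureSpec) -> list[tuple]:
    """Chain output shapes through the stack; raises on pooling underflow."""
    shapes: list[tuple] = []
    current: tuple = tuple(spec.input_shape)
    for i, layer in enumerate(spec.layers):
        if layer.kind == "batch_norm":
            pass
        elif layer.kind == "conv2d":
            if len(current) != 3:
                raise ShapeError(f"layer {i}: conv2d needs an HxWxC input, got {current}")
            current = (current[0], current[1], layer.depth_or_units)
        elif layer.kind == "max_pool":
            if len(current) != 3:
                raise ShapeError(f"layer {i}: max_pool needs an HxWxC input, got {current}")
            f = layer.filter_size
            h, w = current[0] // f, current[1] // f
            if h < 1 or w < 1:
                raise ShapeError(f"layer {i}: pooling {current[0]}x{current[1]} by {f} underflows")
            current = (h, w, current[2])
        elif layer.kind == "flatten":
            n = 1
            for d in current:
                n *= d
            current = (n,)
        elif layer.kind == "dense":
            if len(current) != 1:
                raise ShapeError(f"layer {i}: dense needs a flat input, got {current}")
            current = (layer.depth_or_units,)
        elif layer.kind == "dropout":
            pass
        shapes.append(current)
    return shapes


def count_parameters(spec: ArchitectureSpec) -> tuple[list[int], int]:
    """Closed-form per-layer parameter counts and their total."""
    if not spec.output_shapes:
        raise ShapeError("infer shapes before counting parameters (or use finalize)")
    per_layer: list[int] = []
    prev: tuple = tuple(spec.input_shape)
    for layer, out_shape in zip(spec.layers, spec.output_shapes):
        if layer.kind == "batch_norm":
            per_layer.append(4 * prev[-1])
        elif layer.kind == "conv2d":
            f, c_in, c_out = layer.filter_size, prev[2], layer.depth_or_units
            per_layer.append((f * f * c_in + 1) * c_out)
        elif layer.kind == "dense":
            per_layer.append((prev[0] + 1) * layer.depth_or_units)
        else:
            per_layer.append(0)
        prev = out_shape
    return per_layer, sum(per_layer)


def finalize(spec: ArchitectureSpec) -> ArchitectureSpec:
    """Fill in output shapes and parameter counts in place."""
    spec.output_shapes = infer_shapes(spec)
    spec.per_layer_params, _ = count_parameters(spec)
    return spec


def proposed_architecture(dropout_rate: float = 0.5,
                          input_shape: tuple[int, int, int] = (224, 224, 3),
                          n_classes: int = 3) -> ArchitectureSpec:
    """The 19-layer three-class histology classifier (715,311 parameters).

    The dropout rate does not change any parameter count; it defaults to
    the common 0.5 and is configurable.
    """
    channels = (32, 32, 64, 64, 128, 128, 256)
    layers: list[LayerSpec] = [LayerSpec("batch_norm")]
    for c in channels:
        layers.append(LayerSpec("conv2d", filter_size=3, depth_or_units=c, activation="relu"))
        layers.append(LayerSpec("max_pool", filter_size=2))
    layers.append(LayerSpec("flatten"))
    layers.append(LayerSpec("dense", depth_or_units=512, activation="relu"))
    layers.append(LayerSpec("dropout", dropout_rate=dropout_rate))
    layers.append(LayerSpec("dense", depth_or_units=n_classes, activation="softmax"))
    return finalize(ArchitectureSpec(input_shape=input_shape, layers=layers))


def small_architecture(input_shape: tuple[int, int, int] = (32, 32, 3),
                       channels: tuple[int, ...] = (8, 16),
                       dense_units: int = 32,
                       dropout_rate: float = 0.25,
                       n_classes: int = 3) -> ArchitectureSpec:
    """A reduced-width stack of the same design for desk-scale training."""
    layers: list[LayerSpec] = [LayerSpec("batch_norm")]
    for c in channels:
        layers.append(LayerSpec("conv2d", filter_size=3, depth_or_units=c, activation="relu"))
        layers.append(LayerSpec("max_pool", filter_size=2))
    layers.append(LayerSpec("flatten"))
    layers.append(LayerSpec("dense", depth_or_units=dense_units, activation="relu"))
    layers.append(LayerSpec("dropout", dropout_rate=dropout_rate))
    layers.append(LayerSpec("dense", depth_or_units=n_classes, activation="softmax"))
    return finalize(ArchitectureSpec(input_shape=input_shape, layers=layers))
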