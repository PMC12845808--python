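"""Layer-wise FLOPs accounting for convolutional detectors.

One multiply-accumulate counts as two floating-point operations, so a 2D
convolution costs ``2 * Hout * Wout * Cout * (Cin/g) * Kh * Kw`` FLOPs and
a 3D convolution additionally multiplies by ``Dout * Kd``.  Only
convolution layers are counted — activations, pooling and normalization
have no standard formula here and are excluded; totals are therefore
conv-only and exact integers until the final division by 1e9.

The audit of interest compares a baseline detector (single stride-2 stem
conv, downstream at H/2) against the dual-stream stem (output stride 4,
downstream at H/4): since conv FLOPs are linear in ``Hout * Wout``, every
downstream layer becomes exactly 4x cheaper, which is where the bulk of
the reduction comes from.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ConvLayerSpec",
    "conv_flops",
    "model_gflops",
    "layers_from_descriptor",
    "stem_comparison",
    "reference_downstream",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """Geometry of one convolution layer for FLOPs accounting.

    ``kernel`` is (Kh, Kw) for conv2d, (Kd, Kh, Kw) for conv3d; ``output``
    is (Hout, Wout) or (Dout, Hout, Wout) correspondingly.
    """

    kind: str
    cin: int
    cout: int
    kernel: tuple[int, ...]
    output: tuple[int, ...]
    groups: int = 1
    name: str = ""

    def validate(self) -> None:
        if self.kind not in ("conv2d", "conv3d"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        ndim = 2 if self.kind == "conv2d" else 3
        if len(self.kernel) != ndim or len(self.output) != ndim:
            raise ValueError(f"{self.kind} needs {ndim}-tuples for kernel and output")
        if min(self.cin, self.cout, self.groups, *self.kernel, *self.output) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.cin % self.groups:
            raise ValueError("cin must be divisible by groups")


def conv_flops(spec: ConvLayerSpec) -> int:
    """Exact FLOPs of one convolution layer (2 ops per multiply-accumulate)."""
    spec.validate()
    flops = 2 * spec.cout * (spec.cin // spec.groups)
    for k in spec.kernel:
        flops *= k
    for o in spec.output:
        flops *= o
    return flops


def model_gflops(layers: list[ConvLayerSpec]) -> float:
    """Sum of layer FLOPs divided by 1e9."""
    if not layers:
        raise ValueError("model_gflops: empty layer list")
    return sum(conv_flops(s) for s in layers) / 1e9


def _out_hw(hw: tuple[int, int], stride: int) -> tuple[int, int]:
    return (hw[0] // stride, hw[1] // stride)


def layers_from_descriptor(descriptor: dict, input_hw: tuple[int, int]) -> list[ConvLayerSpec]:
    """Resolve a stem descriptor's conv layers into sized ConvLayerSpecs.

    Branch convs see the full input resolution; the fusion layer sees the
    half-resolution maps.  Non-conv entries (pooling) are skipped.
    """
    specs: list[ConvLayerSpec] = []
    h, w = input_hw
    half = _out_hw((h, w), 2)
    quarter = _out_hw((h, w), 4)
    for layer in descriptor["layers"]:
        kind = layer["kind"]
        count = int(layer.get("count", 1))
        if kind == "conv2d":
            out = half if layer["name"].endswith("branch_conv") else quarter
            spec = ConvLayerSpec(
                kind="conv2d", cin=layer["cin"], cout=layer["cout"],
                kernel=tuple(layer["kernel"]), output=out, name=layer["name"],
            )
        elif kind == "conv3d":
            kd = layer["kernel"][0]
            spec = ConvLayerSpec(
                kind="conv3d", cin=layer["cin"], cout=layer["cout"],
                kernel=tuple(layer["kernel"]), output=(2, *quarter), name=layer["name"],
            )
        else:
            continue
        specs.extend([spec] * count)
    return specs


def baseline_stem_layers(channels: int, input_hw: tuple[int, int]) -> list[ConvLayerSpec]:
    """The baseline single stride-2 stem conv (3 -> C at H/2)."""
    return [
        ConvLayerSpec(
            kind="conv2d", cin=3, cout=channels, kernel=(3, 3),
            output=_out_hw(input_hw, 2), name="baseline_stem",
        )
    ]


def _resolve_downstream(
    downstream: list[dict], start_hw: tuple[int, int]
) -> list[ConvLayerSpec]:
    """Size a downstream conv layer list starting at the given resolution."""
    specs = []
    h, w = start_hw
    for layer in downstream:
        stride = int(layer.get("stride", 1))
        h, w = h // stride, w // stride
        specs.append(
            ConvLayerSpec(
                kind="conv2d", cin=layer["cin"], cout=layer["cout"],
                kernel=tuple(layer.get("kernel", (3, 3))), output=(h, w),
                groups=int(layer.get("groups", 1)), name=layer.get("name", "body"),
            )
        )
    return specs


def stem_comparison(
    baseline_layers: list[ConvLayerSpec],
    bsi_descriptor: dict,
    downstream: list[dict],
    input_hw: tuple[int, int] = (640, 640),
) -> dict:
    """GFLOPs audit: baseline stem + downstream at H/2 vs dual stem + downstream at H/4.

    ``downstream`` is a list of conv dicts (cin, cout, kernel, stride) shared
    by both configurations; its resolution halves under the dual-stream stem
    because that stem downsamples to stride 4 before the body starts.
    """
    h, w = input_hw
    base_down = _resolve_downstream(downstream, _out_hw((h, w), 2))
    bsi_down = _resolve_downstream(downstream, _out_hw((h, w), 4))
    bsi_stem_layers = layers_from_descriptor(bsi_descriptor, input_hw)
    baseline_total = model_gflops(list(baseline_layers) + base_down)
    bsi_total = model_gflops(bsi_stem_layers + bsi_down)
    return {
        "input_hw": list(input_hw),
        "baseline_gflops": baseline_total,
        "bsi_gflops": bsi_total,
        "ratio": bsi_total / baseline_total,
        "baseline_stem_gflops": model_gflops(list(baseline_layers)),
        "bsi_stem_gflops": model_gflops(bsi_stem_layers),
        "downstream_gflops_baseline": model_gflops(base_down) if downstream else 0.0,
        "downstream_gflops_bsi": model_gflops(bsi_down) if downstream else 0.0,
    }


def reference_downstream(
    widths: tuple[int, ...] = (32, 64, 128, 256, 512),
    convs_per_stage: int = 3,
    stem_channels: int = 8,
) -> list[dict]:
    """A 5-stage reference backbone layer list for the FLOPs audit.

    Each stage opens with a stride-2 3x3 conv to the stage width followed
    by ``convs_per_stage - 1`` stride-1 3x3 convs, a realistic small-detector
    budget (~8 GFLOPs at 640 x 640 behind a baseline stem).
    """
    layers: list[dict] = []
    cin = stem_channels
    for s, width in enumerate(widths):
        layers.append({"cin": cin, "cout": width, "kernel": [3, 3], "stride": 2,
                       "name": f"stage{s}_down"})
        for i in range(convs_per_stage - 1):
            layers.append({"cin": width, "cout": width, "kernel": [3, 3], "stride": 1,
                           "name": f"stage{s}_conv{i}"})
        cin = width
    return layers
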