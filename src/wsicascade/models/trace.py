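"""Spatial-dimension trace of the modified FCN-32s.

Pure convolution arithmetic, independent of any weights: each entry is the
output spatial size of a layer for a given input size.  For a 512x512
input the trace runs 512 -> 710 (pad-100 conv1_2) -> pools 355 / 178 / 89 /
45 / 23 -> fc6 17 -> fc7 17 -> upsample 576 -> crop 512.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["FCN32sSpec", "trace_shapes"]


@dataclass(frozen=True)
class FCN32sSpec:
    """Architecture hyperparameters of the modified FCN-32s.

    ``channels`` are the five VGG block widths; ``width`` below 1.0 scales
    them down uniformly (reduced-width variant for CPU-scale experiments).
    """

    input_size: int = 512
    channels: tuple[int, int, int, int, int] = (64, 128, 256, 512, 512)
    fc_channels: int = 4096
    n_classes: int = 3  # (background, lesion, ignore) score planes
    first_pad: int = 100
    fc6_kernel: int = 7
    upsample_stride: int = 32
    upsample_kernel: int = 64

    def __post_init__(self) -> None:
        if self.first_pad < 0 or self.fc6_kernel < 1:
            raise ValueError("invalid FCN32sSpec")
        if self.upsample_kernel != 2 * self.upsample_stride:
            raise ValueError(
                "upsample kernel must be twice the stride (bilinear geometry)"
            )

    def scaled(self, width: float) -> "FCN32sSpec":
        """Reduced-width variant: all channel counts scaled by ``width``."""
        ch = tuple(max(1, int(round(c * width))) for c in self.channels)
        fc = max(1, int(round(self.fc_channels * width)))
        return FCN32sSpec(
            input_size=self.input_size,
            channels=ch,  # type: ignore[arg-type]
            fc_channels=fc,
            n_classes=self.n_classes,
            first_pad=self.first_pad,
            fc6_kernel=self.fc6_kernel,
            upsample_stride=self.upsample_stride,
            upsample_kernel=self.upsample_kernel,
        )


def _conv_out(size: int, kernel: int, pad: int, stride: int = 1) -> int:
    return (size + 2 * pad - kernel) // stride + 1


def trace_shapes(
    spec: FCN32sSpec | None = None, input_hw: int | tuple[int, int] | None = None
) -> list[tuple[str, tuple[int, int, int]]]:
    """Ordered (layer name, (height, width, channels)) trace.

    Raises ``ValueError`` when the input is too small for the 7x7 fc6
    receptive field or too small for the post-upsampling crop.
    """
    if spec is None:
        spec = FCN32sSpec()
    if input_hw is None:
        input_hw = spec.input_size
    if isinstance(input_hw, int):
        input_hw = (input_hw, input_hw)
    h, w = input_hw
    if h < 1 or w < 1:
        raise ValueError("input size must be >= 1")
    c1, c2, c3, c4, c5 = spec.channels

    out: list[tuple[str, tuple[int, int, int]]] = [("input", (h, w, 3))]

    def conv(name: str, kernel: int, pad: int, ch: int) -> None:
        nonlocal h, w
        h = _conv_out(h, kernel, pad)
        w = _conv_out(w, kernel, pad)
        if h < 1 or w < 1:
            raise ValueError(f"input too small at layer {name}")
        out.append((name, (h, w, ch)))

    def pool(name: str) -> None:
        nonlocal h, w
        h = math.ceil(h / 2)  # ceil-mode 2x2 stride-2 pooling
        w = math.ceil(w / 2)
        out.append((name, (h, w, out[-1][1][2])))

    conv("conv1_1", 3, 1, c1)
    conv("conv1_2", 3, spec.first_pad, c1)
    pool("pool1")
    conv("conv2_1", 3, 1, c2)
    conv("conv2_2", 3, 1, c2)
    pool("pool2")
    conv("conv3_1", 3, 1, c3)
    conv("conv3_2", 3, 1, c3)
    conv("conv3_3", 3, 1, c3)
    pool("pool3")
    conv("conv4_1", 3, 1, c4)
    conv("conv4_2", 3, 1, c4)
    conv("conv4_3", 3, 1, c4)
    pool("pool4")
    conv("conv5_1", 3, 1, c5)
    conv("conv5_2", 3, 1, c5)
    conv("conv5_3", 3, 1, c5)
    pool("pool5")
    if h < spec.fc6_kernel or w < spec.fc6_kernel:
        raise ValueError(
            f"feature map {h}x{w} after pool5 is smaller than the "
            f"{spec.fc6_kernel}x{spec.fc6_kernel} fc6 kernel; increase input size"
        )
    conv("fc6", spec.fc6_kernel, 0, spec.fc_channels)
    out.append(("drop6", out[-1][1]))
    conv("fc7", 1, 0, spec.fc_channels)
    out.append(("drop7", out[-1][1]))
    conv("score", 1, 0, spec.n_classes)

    s, k = spec.upsample_stride, spec.upsample_kernel
    h = (h - 1) * s + k
    w = (w - 1) * s + k
    out.append(("upsampled", (h, w, spec.n_classes)))
    ih, iw = input_hw
    if h < ih or w < iw:
        raise ValueError("upsampled map smaller than the input; cannot crop")
    out.append(("output", (ih, iw, spec.n_classes)))
    return out
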