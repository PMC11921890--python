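"""Declarative architecture configuration for the detector family.

One :class:`ModelSpec` describes both the single-branch baseline (the
standard small anchor-free detector layout: depth/width multiples
0.33/0.25, C2f backbone + SPPF, PAN neck, decoupled DFL head) and the
dual-branch model (two backbones over paired RGB/DCS inputs, per-scale
fusion, BELFPN neck with C2f_EL blocks).

The default dual-branch configuration was fixed by a documented search
over neck widths, C2f_EL hidden channels, multi-kernel triples and
downsample style so that the parameter count lands on the published
budget; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import math


def make_divisible(x: float, divisor: int = 8) -> int:
    return int(math.ceil(x / divisor) * divisor)


@dataclasses.dataclass
class ModelSpec:
    n_classes: int = 3
    width_mult: float = 0.25
    depth_mult: float = 0.33
    max_channels: int = 1024
    base_widths: tuple[int, ...] = (64, 128, 256, 512, 1024)
    base_depths: tuple[int, ...] = (3, 6, 6, 3)
    branch_inputs: tuple[str, ...] = ("rgb", "dcs")
    fusion: str = "concat"              # per-scale branch merge: concat | wsum
    neck: str = "belfpn"                # belfpn | pan
    neck_widths: tuple[int, int, int] = (64, 128, 160)
    neck_hidden: tuple[int, int, int] = (48, 126, 132)
    mb_kernels: tuple[tuple[int, int, int], ...] = ((5, 7, 9), (7, 9, 9), (5, 7, 9))
    shuffle_groups: int = 2
    reg_max: int = 16
    strides: tuple[int, int, int] = (8, 16, 32)

    def __post_init__(self) -> None:
        if len(self.mb_kernels) != 3 or any(len(k) != 3 for k in self.mb_kernels):
            raise ValueError("mb_kernels must give 3 kernel sizes per level")
        if any(k % 2 == 0 for ks in self.mb_kernels for k in ks):
            raise ValueError("all MBModule kernels must be odd")
        if self.neck not in ("belfpn", "pan"):
            raise ValueError(f"unknown neck {self.neck!r}")
        if self.fusion not in ("concat", "wsum"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if not self.branch_inputs:
            raise ValueError("need at least one input branch")

    # -- derived ---------------------------------------------------------
    @property
    def channels(self) -> list[int]:
        """Backbone stage widths after the width multiplier."""
        return [
            make_divisible(min(c, self.max_channels) * self.width_mult, 8)
            for c in self.base_widths
        ]

    @property
    def depths(self) -> list[int]:
        return [max(round(d * self.depth_mult), 1) for d in self.base_depths]

    @property
    def dual(self) -> bool:
        return len(self.branch_inputs) > 1

    # -- presets ---------------------------------------------------------
    @classmethod
    def yolov8n_baseline(cls, n_classes: int = 3) -> "ModelSpec":
        """Single-branch baseline: the standard n-scale anchor-free layout."""
        return cls(n_classes=n_classes, branch_inputs=("rgb",), neck="pan")

    @classmethod
    def dby_tobacco(cls, n_classes: int = 3) -> "ModelSpec":
        """Default dual-branch model (paired RGB + DCS inputs, BELFPN neck)."""
        return cls(n_classes=n_classes)

    @classmethod
    def tiny(cls, n_classes: int = 3, dual: bool = True) -> "ModelSpec":
        """Desk-scale preset for CPU training experiments (64 px inputs)."""
        return cls(
            n_classes=n_classes,
            width_mult=0.25,
            depth_mult=0.2,
            branch_inputs=("rgb", "dcs") if dual else ("rgb",),
            neck="belfpn" if dual else "pan",
            neck_widths=(32, 48, 64),
            neck_hidden=(18, 24, 36),
            mb_kernels=((3, 3, 5), (3, 3, 5), (3, 3, 5)),
            reg_max=8,
        )
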