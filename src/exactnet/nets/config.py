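"""Shared network configuration."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class NetConfig:
    """Size and shape knobs for the 3D segmentation and detection networks.

    The networks are fully convolutional, so ``patch_size`` only fixes the
    training patch; any input whose sides are divisible by
    ``2**(depth-1)`` is accepted at inference.  ``anchor_sizes_mm`` lists
    one cubic anchor edge per detection pyramid level (levels sit at
    strides >= 4).  Defaults are desk-scale; the full-scale counterpart of
    this architecture trains at 96^3 patches.
    """

    in_channels: int = 1
    base_channels: int = 8
    depth: int = 3
    n_classes: int = 2
    anchor_sizes_mm: tuple[float, ...] = (8.0, 16.0, 32.0)
    patch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be at least 2")
        if self.patch_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"patch size {self.patch_size} incompatible with depth {self.depth}: "
                f"must be divisible by {2 ** (self.depth - 1)}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anchor_sizes_mm"] = list(self.anchor_sizes_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        d["anchor_sizes_mm"] = tuple(d.get("anchor_sizes_mm", (8.0, 16.0, 32.0)))
        return cls(**d)

    def channels(self, level: int) -> int:
        # widths double per level, capped so desk-scale nets stay tiny
        return min(self.base_channels * 2**level, self.base_channels * 8)
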