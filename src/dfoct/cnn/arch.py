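"""Architecture description and closed-form analytics.

``count_parameters`` and ``receptive_fields`` are analytic: they follow from
the layer arithmetic alone and never instantiate weights, so they can sanity
check any instantiated network.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ArchitectureSpec",
    "FULL_PROFILE",
    "REDUCED_PROFILE",
    "count_parameters",
    "receptive_fields",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Blocks of (n_convs, out_channels) 3x3/stride-1/same convolutions, each
    block followed by a 2x2 stride-2 max pool; GAP -> FC(head_width) ->
    sigmoid output."""

    blocks: tuple[tuple[int, int], ...]
    in_channels: int = 3
    kernel: int = 3
    head_width: int = 1024

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one block required")
        for n, c in self.blocks:
            if n < 1 or c < 1:
                raise ValueError("blocks must have positive conv count and channels")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and positive")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def last_channels(self) -> int:
        return self.blocks[-1][1]

    def feature_map_size(self, h: int, w: int) -> tuple[int, int]:
        """Spatial size of the last conv feature map for an input (h, w)."""
        d = 2**self.n_blocks
        if h % d or w % d:
            raise ValueError(f"input size ({h}, {w}) not divisible by {d}")
        return h // d, w // d


#: 13-conv backbone (VGG16 convolutional profile) with the GAP/1024 head.
FULL_PROFILE = ArchitectureSpec(blocks=((2, 64), (2, 128), (3, 256), (3, 512), (3, 512)))

#: small profile for desk-scale experiments and tests.
REDUCED_PROFILE = ArchitectureSpec(blocks=((1, 8), (1, 16), (1, 32)), head_width=64)


def count_parameters(spec: ArchitectureSpec) -> tuple[int, int, int]:
    """(total, backbone, head) trainable parameter counts.

    Per conv: k^2 * c_in * c_out + c_out. Head: GAP contributes nothing;
    FC c_last -> head_width with bias; output head_width -> 1 with bias.
    """
    k2 = spec.kernel**2
    backbone = 0
    c_in = spec.in_channels
    for n_convs, c_out in spec.blocks:
        for _ in range(n_convs):
            backbone += k2 * c_in * c_out + c_out
            c_in = c_out
    head = spec.last_channels * spec.head_width + spec.head_width + spec.head_width + 1
    return backbone + head, backbone, head


def receptive_fields(spec: ArchitectureSpec) -> list[int]:
    """Receptive-field side (input pixels) at each pooling layer.

    Standard recurrence over layers in order: RF <- RF + (k - 1) * jump,
    then jump <- jump * stride.
    """
    rf, jump = 1, 1
    out = []
    for n_convs, _ in spec.blocks:
        for _ in range(n_convs):
            rf += (spec.kernel - 1) * jump
            # stride 1: jump unchanged
        rf += (2 - 1) * jump  # 2x2 pool
        jump *= 2
        out.append(rf)
    return out
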