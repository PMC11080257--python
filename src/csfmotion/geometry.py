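"""Voxel-grid geometry shared by all simulated and fitted volumes."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PhantomGeometry:
    """Matrix size, voxel size and world affine of a 3-D acquisition grid.

    Defaults mirror a 2-D EPI protocol with 1.8 x 1.8 mm in-plane resolution
    and 4 mm slices over a 64 x 64 x 28 matrix.
    """

    shape: tuple[int, int, int] = (64, 64, 28)
    voxel_size_mm: tuple[float, float, float] = (1.8, 1.8, 4.0)
    origin_mm: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel size must be strictly positive, got {self.voxel_size_mm}")

    @property
    def affine(self) -> np.ndarray:
        """Scaling+translation voxel->world transform (always invertible)."""
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def matches(self, other: "PhantomGeometry") -> bool:
        return (tuple(self.shape) == tuple(other.shape)
                and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
                and np.allclose(self.origin_mm, other.origin_mm))
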