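"""Biofilm thickness-grid summary metrics.

Mature-biofilm confocal stacks are conventionally summarised by average
thickness and a roughness coefficient (normalised mean absolute deviation
of local thickness).  Inputs here are 2-D local-thickness grids L_f (um);
reducing a z-stack to a thickness grid is upstream image processing and
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, StructuralError


@dataclass
class HeightMap:
    """n x m grid of local biofilm thickness values (um)."""

    grid: np.ndarray
    pixel_size: float = 1.0  # um per pixel

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.size == 0:
            raise StructuralError("height map grid is empty")
        if np.any(self.grid < 0):
            raise ParameterError("thickness values must be nonnegative")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")


def mean_thickness(hmap: HeightMap) -> float:
    """Average thickness (um): arithmetic mean of the grid."""
    return float(hmap.grid.mean())


def roughness_coefficient(hmap: HeightMap) -> float:
    """Roughness coefficient Ra* = mean(|L_f - mean|) / mean (dimensionless).

    Zero iff the map is constant; invariant under uniform scaling of
    thickness.  Undefined (domain error) for an all-zero map.
    """
    mean = hmap.grid.mean()
    if mean <= 0:
        raise ParameterError("roughness undefined for zero mean thickness")
    return float(np.mean(np.abs(hmap.grid - mean)) / mean)
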