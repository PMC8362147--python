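"""In-memory containers: CT image stacks and sinograms.

Axis conventions
----------------
``CTImage.values`` has shape ``(n_slices, rows, cols)`` in Hounsfield
units.  The in-plane grid is square and centered at ``origin`` (the
physical position of the grid center relative to the isocenter, mm).
Column index grows with +x, row index grows with +y ("up" is the couch
direction along which the phantom is shifted).

``Sinogram.values`` has shape ``(n_slices, n_angles, n_channels)`` and
holds line integrals of the linear attenuation coefficient
(dimensionless).  ``measured`` flags, per channel, whether the channel was
physically measured; it is a single contiguous central block shared by all
rows, which is all the truncation bookkeeping this model needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import ScanGeometry

__all__ = ["CTImage", "Sinogram"]


@dataclass
class CTImage:
    values: np.ndarray  # (n_slices, rows, cols), HU
    pixel_spacing_mm: float
    slice_thickness_mm: float = 3.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[None]
        if self.values.ndim != 3:
            raise ValueError("CTImage values must be (n_slices, rows, cols)")
        if self.values.shape[1] != self.values.shape[2]:
            raise ValueError("in-plane grid must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite HU values")
        if self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("spacings must be > 0")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def matrix(self) -> int:
        return self.values.shape[1]

    @property
    def extent_mm(self) -> float:
        return self.matrix * self.pixel_spacing_mm

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of pixel centers, each (rows, cols)."""
        n = self.matrix
        ax = (np.arange(n) - (n - 1) / 2.0) * self.pixel_spacing_mm
        x = self.origin[0] + ax[None, :] + np.zeros((n, 1))
        y = self.origin[1] + ax[:, None] + np.zeros((1, n))
        return x, y

    def radius_map(self) -> np.ndarray:
        """Distance of each pixel center from the isocenter (rows, cols)."""
        x, y = self.grid_coords()
        return np.hypot(x, y)

    def copy(self) -> "CTImage":
        return replace(self, values=self.values.copy())


@dataclass
class Sinogram:
    values: np.ndarray  # (n_slices, n_angles, n_channels)
    geometry: ScanGeometry
    measured: np.ndarray = field(default=None)  # (n_channels,) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[None]
        if self.values.ndim != 3:
            raise ValueError("Sinogram values must be (n_slices, n_angles, n_channels)")
        ns, na, nc = self.values.shape
        if na != self.geometry.n_angles or nc != self.geometry.n_channels:
            raise ValueError(
                f"values shape {self.values.shape} does not match geometry "
                f"({self.geometry.n_angles} angles, {self.geometry.n_channels} channels)"
            )
        if self.measured is None:
            self.measured = np.ones(nc, dtype=bool)
        self.measured = np.asarray(self.measured, dtype=bool)
        if self.measured.shape != (nc,):
            raise ValueError("measured mask must be (n_channels,)")
        idx = np.flatnonzero(self.measured)
        if idx.size == 0:
            raise ValueError("measured mask must flag at least one channel")
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ValueError("measured channels must form one contiguous block")

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def measured_range(self) -> tuple[int, int]:
        """Half-open channel index range [start, stop) of measured data."""
        idx = np.flatnonzero(self.measured)
        return int(idx[0]), int(idx[-1] + 1)

    def copy(self) -> "Sinogram":
        return replace(self, values=self.values.copy(), measured=self.measured.copy())
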