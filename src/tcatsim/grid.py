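"""1-D cell-centered finite-volume grids (Cartesian slab or spherical shell)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .species import ValidationError

__all__ = ["Grid1D"]


@dataclass(frozen=True)
class Grid1D:
    """Cell-centered 1-D grid with half-open cells [r_k, r_{k+1}).

    ``geometry`` is ``'cartesian'`` (unit cross-section slab) or
    ``'spherical'`` (shells with exact 4/3 pi r^3 volumes and 4 pi r^2 face
    areas).  Edges are in metres and strictly increasing.
    """

    geometry: str
    edges: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        if self.geometry not in ("cartesian", "spherical"):
            raise ValidationError(f"unknown grid geometry {self.geometry!r}")
        if self.edges.ndim != 1 or self.edges.size < 2:
            raise ValidationError("grid needs at least two edges")
        if np.any(np.diff(self.edges) <= 0.0):
            raise ValidationError("grid edges must be strictly increasing")
        if self.geometry == "spherical" and self.edges[0] < 0.0:
            raise ValidationError("spherical grid edges must be nonnegative")

    @classmethod
    def uniform(cls, geometry: str, r_min: float, r_max: float, n_cells: int) -> "Grid1D":
        return cls(geometry, np.linspace(r_min, r_max, n_cells + 1))

    @property
    def n_cells(self) -> int:
        return self.edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def volumes(self) -> np.ndarray:
        if self.geometry == "cartesian":
            return np.diff(self.edges)
        return (4.0 / 3.0) * np.pi * np.diff(self.edges**3)

    @property
    def face_areas(self) -> np.ndarray:
        """Area of every face, including the two boundary faces (n_cells+1,)."""
        if self.geometry == "cartesian":
            return np.ones(self.edges.size)
        return 4.0 * np.pi * self.edges**2

    @property
    def center_spacing(self) -> np.ndarray:
        """Distance between adjacent cell centers (interior faces only)."""
        return np.diff(self.centers)
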