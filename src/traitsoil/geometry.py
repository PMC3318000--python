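"""Plot geometry: rectangular mapped forest plots divided into square quadrats."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PlotGeometry:
    """A rectangular census plot partitioned into square quadrats.

    Parameters
    ----------
    width, height
        Plot extent in metres. Must be positive integer multiples of
        ``quadrat_size`` (the census convention: e.g. a 600 x 400 m plot
        with 20 m quadrats gives a 30 x 20 quadrat lattice).
    quadrat_size
        Quadrat edge length in metres (default 20).
    """

    width: float
    height: float
    quadrat_size: float = 20.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.quadrat_size <= 0:
            raise ValueError("quadrat_size must be positive")
        for dim, name in ((self.width, "width"), (self.height, "height")):
            ratio = dim / self.quadrat_size
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"{name}={dim} is not an integer multiple of "
                    f"quadrat_size={self.quadrat_size}"
                )

    @property
    def n_qx(self) -> int:
        """Number of quadrat columns."""
        return round(self.width / self.quadrat_size)

    @property
    def n_qy(self) -> int:
        """Number of quadrat rows."""
        return round(self.height / self.quadrat_size)

    @property
    def n_quadrats(self) -> int:
        return self.n_qx * self.n_qy

    def quadrat_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Half-open binning: a stem at x=20.0 falls in column 1, not 0."""
        col = np.floor(np.asarray(x) / self.quadrat_size).astype(int)
        row = np.floor(np.asarray(y) / self.quadrat_size).astype(int)
        return row, col

    def quadrat_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Centre coordinates of every quadrat as (x_grid, y_grid), each (n_qy, n_qx)."""
        cx = (np.arange(self.n_qx) + 0.5) * self.quadrat_size
        cy = (np.arange(self.n_qy) + 0.5) * self.quadrat_size
        return np.meshgrid(cx, cy)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= 0) & (x < self.width) & (y >= 0) & (y < self.height)
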