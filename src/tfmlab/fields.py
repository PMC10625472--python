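"""Regular-grid vector fields: bead displacements (µm) and tractions (Pa).

Both fields live on the same kind of regular node lattice: node (i, j) sits
at physical position ``x = x0 + j*spacing``, ``y = y0 + i*spacing`` in the
image frame (row = +y, col = +x, µm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DisplacementField", "TractionField"]


def _check_grid(vx: np.ndarray, vy: np.ndarray, spacing: float) -> None:
    if vx.shape != vy.shape or vx.ndim != 2:
        raise ValueError(f"component arrays must be 2D and same shape, got {vx.shape} vs {vy.shape}")
    if not (spacing > 0):
        raise ValueError(f"grid spacing must be > 0, got {spacing}")


@dataclass
class DisplacementField:
    """Bead displacement field u(r) (µm) on a regular grid with a validity mask.

    ``ux[i, j]`` / ``uy[i, j]`` are the x/y displacement components at node
    (i, j). ``valid_mask`` marks nodes whose vectors come from a trusted
    measurement; nodes in-filled from neighbors are carried with
    ``valid_mask == False`` but still hold finite values.
    """

    ux: np.ndarray
    uy: np.ndarray
    spacing_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)  # (x0, y0) of node [0, 0]
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ux = np.asarray(self.ux, dtype=np.float64)
        self.uy = np.asarray(self.uy, dtype=np.float64)
        _check_grid(self.ux, self.uy, self.spacing_um)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.ux.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.ux.shape:
                raise ValueError("valid_mask shape mismatch")
        bad = ~np.isfinite(self.ux[self.valid_mask]) | ~np.isfinite(self.uy[self.valid_mask])
        if np.any(bad):
            raise ValueError("displacement components must be finite at valid nodes")

    @property
    def n_rows(self) -> int:
        return self.ux.shape[0]

    @property
    def n_cols(self) -> int:
        return self.ux.shape[1]

    @property
    def grid_x(self) -> np.ndarray:
        """x coordinate (µm) of every node, shape (n_rows, n_cols)."""
        x = self.origin_um[0] + self.spacing_um * np.arange(self.n_cols)
        return np.broadcast_to(x[None, :], self.ux.shape)

    @property
    def grid_y(self) -> np.ndarray:
        y = self.origin_um[1] + self.spacing_um * np.arange(self.n_rows)
        return np.broadcast_to(y[:, None], self.ux.shape)

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.ux, self.uy)

    def copy(self) -> "DisplacementField":
        return DisplacementField(
            self.ux.copy(), self.uy.copy(), self.spacing_um, self.origin_um, self.valid_mask.copy()
        )


@dataclass
class TractionField:
    """Traction stress field F(r) (Pa) on the same regular-lattice layout."""

    tx: np.ndarray
    ty: np.ndarray
    spacing_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.tx = np.asarray(self.tx, dtype=np.float64)
        self.ty = np.asarray(self.ty, dtype=np.float64)
        _check_grid(self.tx, self.ty, self.spacing_um)
        if not (np.all(np.isfinite(self.tx)) and np.all(np.isfinite(self.ty))):
            raise ValueError("traction components must be finite")

    @property
    def n_rows(self) -> int:
        return self.tx.shape[0]

    @property
    def n_cols(self) -> int:
        return self.tx.shape[1]

    @property
    def grid_x(self) -> np.ndarray:
        x = self.origin_um[0] + self.spacing_um * np.arange(self.n_cols)
        return np.broadcast_to(x[None, :], self.tx.shape)

    @property
    def grid_y(self) -> np.ndarray:
        y = self.origin_um[1] + self.spacing_um * np.arange(self.n_rows)
        return np.broadcast_to(y[:, None], self.tx.shape)

    @property
    def magnitude(self) -> np.ndarray:
        """Nodewise stress magnitude sqrt(tx² + ty²), Pa."""
        return np.hypot(self.tx, self.ty)

    def net_force(self) -> tuple[float, float]:
        """Integrated (Fx, Fy) over the grid, Pa·µm² (= pN)."""
        a = self.spacing_um**2
        return float(self.tx.sum() * a), float(self.ty.sum() * a)

    def copy(self) -> "TractionField":
        return TractionField(self.tx.copy(), self.ty.copy(), self.spacing_um, self.origin_um)
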