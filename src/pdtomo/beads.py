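"""Pseudo-atomic bead models and rigid transforms.

A :class:`BeadModel` is a list of weighted Gaussian spheres — a coarse
stand-in for an atomic model at the 30–40 Å resolutions relevant here
(roughly one bead per ~15 residues).  Models round-trip through PDB-format
pseudo-atom records (weight in the occupancy column, radius in the B column)
and plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .euler import canonical_angles, rotation_matrix

__all__ = ["BeadModel", "Transform", "read_beads_pdb", "write_beads_pdb"]


@dataclass
class Transform:
    """Rigid transform: rotate by ZXZ Euler angles, then translate (nm)."""

    euler_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.euler_deg = canonical_angles(*self.euler_deg)
        self.translation_nm = np.asarray(self.translation_nm, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix(*self.euler_deg)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T + self.translation_nm


@dataclass
class BeadModel:
    """Weighted spheres: positions (N, 3) nm, weights (N,), radii (N,) nm."""

    positions_nm: np.ndarray
    weights: np.ndarray
    radii_nm: np.ndarray
    label: str = "model"

    def __post_init__(self) -> None:
        self.positions_nm = np.atleast_2d(np.asarray(self.positions_nm, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.radii_nm = np.atleast_1d(np.asarray(self.radii_nm, dtype=float))
        if len(self.positions_nm) == 0:
            raise ValueError("BeadModel needs at least one bead")
        if np.any(self.weights <= 0):
            raise ValueError("bead weights must be positive")
        if len(self.weights) != len(self.positions_nm) or len(self.radii_nm) != len(self.positions_nm):
            raise ValueError("positions, weights and radii must have equal length")

    def __len__(self) -> int:
        return len(self.positions_nm)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def centroid(self) -> np.ndarray:
        return np.average(self.positions_nm, axis=0, weights=self.weights)

    def transformed(self, t: Transform, label: str | None = None) -> "BeadModel":
        return BeadModel(
            t.apply(self.positions_nm),
            self.weights.copy(),
            self.radii_nm.copy(),
            label or self.label,
        )

    def centered(self) -> "BeadModel":
        """Copy translated so the weighted centroid sits at the origin."""
        return BeadModel(
            self.positions_nm - self.centroid(), self.weights.copy(), self.radii_nm.copy(), self.label
        )

    @classmethod
    def concatenate(cls, models: list["BeadModel"], label: str = "tiled") -> "BeadModel":
        return cls(
            np.vstack([m.positions_nm for m in models]),
            np.concatenate([m.weights for m in models]),
            np.concatenate([m.radii_nm for m in models]),
            label,
        )


def write_beads_pdb(model: BeadModel, path: str) -> None:
    """One HETATM record per bead; positions in Å, weight in occupancy."""
    with open(path, "w") as fh:
        fh.write(f"REMARK   bead model {model.label}\n")
        for i, (p, w, r) in enumerate(zip(model.positions_nm, model.weights, model.radii_nm), 1):
            x, y, z = 10.0 * p
            fh.write(
                f"HETATM{i:5d}  C   BED A{i % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{w:6.2f}{10.0 * r:6.2f}           C\n"
            )
        fh.write("END\n")


def read_beads_pdb(path: str, label: str | None = None) -> BeadModel:
    pos, w, r = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("ATOM", "HETATM")):
                pos.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
                w.append(float(line[54:60]))
                r.append(float(line[60:66]))
    return BeadModel(
        np.array(pos) / 10.0, np.array(w), np.array(r) / 10.0, label or "model"
    )
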