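"""Particle seeding and bookkeeping along desmotubule contours.

The picking scheme: a contour (two points or a polyline) is sampled at
fixed 1-nm arc-length intervals, each sample is assigned an orientation
whose z axis runs along the local contour tangent with a randomized
in-plane spin phi, the seeds are pseudo-symmetry expanded onto the tubule
surface (default 11 positions shifted 6 nm radially outward, ~33 degrees
apart), and after alignment the oversampled set is distance-filtered
(default 8 nm), keeping the highest-scoring particle in each neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .euler import euler_aligning_z, euler_from_matrix, rotation_matrix, zaxis_from_euler
from .volume import Volume

__all__ = [
    "Contour",
    "ParticleSet",
    "sample_contour",
    "init_orientations",
    "seed_particles",
    "expand_on_tube",
    "distance_filter",
    "extract_subvolumes",
]

logger = logging.getLogger(__name__)

STAGES = ("seeded", "aligned1", "expanded", "aligned2", "filtered")

PARTICLE_COLUMNS = [
    "particle_id", "seed_id", "x_nm", "y_nm", "z_nm",
    "phi_deg", "theta_deg", "psi_deg", "score", "stage",
]


@dataclass
class Contour:
    """Ordered polyline marking a desmotubule segment (>= 2 distinct points)."""

    points: np.ndarray
    label: str = "contour"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.points) < 2:
            raise ValueError("contour needs at least 2 points")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) < 1e-9):
            raise ValueError("consecutive contour points must be distinct")

    @property
    def length_nm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class ParticleSet:
    """Table of particles plus a pipeline-stage provenance tag."""

    table: pd.DataFrame
    stage: str = "seeded"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        missing = [c for c in PARTICLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"particle table missing columns {missing}")
        if self.table["particle_id"].duplicated().any():
            raise ValueError("particle_id values must be unique")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)

    @property
    def eulers(self) -> np.ndarray:
        return self.table[["phi_deg", "theta_deg", "psi_deg"]].to_numpy(dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy(dtype=float)

    def zaxes(self) -> np.ndarray:
        return np.array([zaxis_from_euler(*e) for e in self.eulers])

    def with_stage(self, stage: str) -> "ParticleSet":
        return ParticleSet(self.table.copy(), stage)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str) -> None:
        df = self.table.copy()
        df["stage"] = self.stage
        df.to_csv(path, sep="\t", index=False, float_format="%.5f")

    @classmethod
    def from_tsv(cls, path: str) -> "ParticleSet":
        df = pd.read_csv(path, sep="\t")
        stage = str(df["stage"].iloc[0]) if len(df) else "seeded"
        return cls(df[PARTICLE_COLUMNS], stage)

    def to_star(self, path: str) -> None:
        """STAR-style particle table (one data_particles loop)."""
        with open(path, "w") as fh:
            fh.write("data_particles\n\nloop_\n")
            for i, c in enumerate(PARTICLE_COLUMNS, 1):
                fh.write(f"_pd{''.join(p.capitalize() for p in c.split('_'))} #{i}\n")
            for _, row in self.table.iterrows():
                vals = [row[c] if c != "stage" else self.stage for c in PARTICLE_COLUMNS]
                fh.write(
                    " ".join(
                        f"{v:d}" if isinstance(v, (int, np.integer))
                        else (f"{v:.5f}" if isinstance(v, (float, np.floating)) else str(v))
                        for v in vals
                    )
                    + "\n"
                )

    @classmethod
    def from_star(cls, path: str) -> "ParticleSet":
        rows, in_loop, cols = [], False, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("loop_"):
                    in_loop = True
                    continue
                if in_loop and line.startswith("_"):
                    cols.append(line.split()[0])
                    continue
                if in_loop and line and not line.startswith(("data_", "#")):
                    rows.append(line.split())
        df = pd.DataFrame(rows, columns=PARTICLE_COLUMNS[: len(cols)])
        for c in PARTICLE_COLUMNS:
            if c in ("stage",):
                continue
            df[c] = pd.to_numeric(df[c])
        df["particle_id"] = df["particle_id"].astype(int)
        df["seed_id"] = df["seed_id"].astype(int)
        stage = str(df["stage"].iloc[0]) if len(df) else "seeded"
        return cls(df, stage)


def _make_table(positions, eulers, seed_ids, scores=None, start_id: int = 0) -> pd.DataFrame:
    n = len(positions)
    positions = np.asarray(positions, dtype=float)
    eulers = np.asarray(eulers, dtype=float)
    return pd.DataFrame(
        {
            "particle_id": np.arange(start_id, start_id + n, dtype=int),
            "seed_id": np.asarray(seed_ids, dtype=int),
            "x_nm": positions[:, 0],
            "y_nm": positions[:, 1],
            "z_nm": positions[:, 2],
            "phi_deg": eulers[:, 0],
            "theta_deg": eulers[:, 1],
            "psi_deg": eulers[:, 2],
            "score": np.zeros(n) if scores is None else np.asarray(scores, dtype=float),
            "stage": "seeded",
        }
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sample_contour(contour: Contour, interval_nm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length resampling: positions every ``interval_nm`` plus both ends.

    Returns (positions (N, 3), unit tangents (N, 3)).  A contour shorter
    than one interval yields just its two endpoints.
    """
    if interval_nm <= 0:
        raise ValueError("interval must be positive")
    pts = contour.points
    seg = np.diff(pts, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total < interval_nm:
        s_vals = np.array([0.0, total])
    else:
        s_vals = np.arange(0.0, total + 1e-9, interval_nm)
        if total - s_vals[-1] > 1e-9:
            s_vals = np.append(s_vals, total)
    positions, tangents = [], []
    for s in s_vals:
        i = min(int(np.searchsorted(arclen, s, side="right")) - 1, len(seg) - 1)
        frac = (s - arclen[i]) / seglen[i]
        positions.append(pts[i] + frac * seg[i])
        tangents.append(seg[i] / seglen[i])
    return np.array(positions), np.array(tangents)


def init_orientations(axes: np.ndarray, seed: int = 0) -> np.ndarray:
    """Euler triplets rotating the reference z axis onto each local tangent.

    theta and psi are computed from the tangent; phi (the spin about the
    tubule axis) is drawn uniformly from [0, 360) with one shared seeded
    generator, so a fixed seed reproduces the same phi sequence.
    """
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    rng = np.random.default_rng(seed)
    phis = rng.uniform(0.0, 360.0, size=len(axes))
    return np.array([euler_aligning_z(t, phi=p) for t, p in zip(axes, phis)])


def seed_particles(contour: Contour, interval_nm: float = 1.0, seed: int = 0) -> ParticleSet:
    """sample_contour + init_orientations packaged as a seeded ParticleSet."""
    pos, tan = sample_contour(contour, interval_nm)
    eul = init_orientations(tan, seed=seed)
    return ParticleSet(_make_table(pos, eul, seed_ids=np.arange(len(pos))), "seeded")


def expand_on_tube(
    particles: ParticleSet, radial_shift_nm: float = 6.0, n_positions: int = 11
) -> ParticleSet:
    """Pseudo-symmetry expansion onto the tubule surface.

    Each input particle yields ``n_positions`` new particles on the circle
    of radius ``radial_shift_nm`` in the plane normal to its z axis, at
    uniform 360/n angular spacing; each new particle's z axis points
    radially outward and its x axis along the tubule axis.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    out_pos, out_eul, out_seed = [], [], []
    for _, row in particles.table.iterrows():
        mat = rotation_matrix(row.phi_deg, row.theta_deg, row.psi_deg)
        ex, ey, ez = mat[:, 0], mat[:, 1], mat[:, 2]
        centre = np.array([row.x_nm, row.y_nm, row.z_nm])
        for k in range(n_positions):
            a = np.radians(360.0 * k / n_positions)
            radial = np.cos(a) * ex + np.sin(a) * ey
            out_pos.append(centre + radial_shift_nm * radial)
            new_mat = np.column_stack([ez, np.cross(radial, ez), radial])
            out_eul.append(euler_from_matrix(new_mat))
            out_seed.append(row.seed_id)
    table = _make_table(out_pos, out_eul, out_seed)
    table["stage"] = "expanded"
    return ParticleSet(table, "expanded")


def distance_filter(particles: ParticleSet, min_dist_nm: float = 8.0) -> ParticleSet:
    """Greedy score-descending thinning: keep local score maxima >= min_dist apart.

    The highest-scoring particle is always retained; any particle within
    ``min_dist_nm`` of an already-retained one is removed.  Score ties break
    toward the lower particle_id.  Idempotent.
    """
    if min_dist_nm < 0:
        raise ValueError("min_dist_nm must be non-negative")
    df = particles.table
    order = df.sort_values(
        ["score", "particle_id"], ascending=[False, True]
    ).index.to_numpy()
    pos = particles.positions
    tree = cKDTree(pos)
    retained_mask = np.zeros(len(df), dtype=bool)
    removed = np.zeros(len(df), dtype=bool)
    loc = {idx: i for i, idx in enumerate(df.index)}
    for idx in order:
        i = loc[idx]
        if removed[i]:
            continue
        retained_mask[i] = True
        for j in tree.query_ball_point(pos[i], min_dist_nm):
            if j != i and not retained_mask[j]:
                removed[j] = True
    out = df.iloc[np.flatnonzero(retained_mask)].copy()
    out["stage"] = "filtered"
    return ParticleSet(out.reset_index(drop=True), "filtered")


def extract_subvolumes(
    vol: Volume, particles: ParticleSet, box_voxels: int = 48
) -> tuple[np.ndarray, ParticleSet]:
    """Axis-aligned cubes centred on each particle (nearest voxel centre).

    Rotations are NOT applied here — they are applied during alignment and
    averaging.  Particles whose box would cross the volume border are
    dropped with a logged warning (drop, don't pad).  Returns the stack
    (N, b, b, b) and the surviving particles in matching order.
    """
    b = int(box_voxels)
    half = b // 2
    shape = np.array(vol.shape)
    keep_rows, cubes = [], []
    n_dropped = 0
    for idx, row in particles.table.iterrows():
        c = np.round(vol.nm_to_voxel([row.x_nm, row.y_nm, row.z_nm])).astype(int)
        lo = c - half
        hi = lo + b
        if np.any(lo < 0) or np.any(hi > shape):
            n_dropped += 1
            continue
        cubes.append(vol.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].copy())
        keep_rows.append(idx)
    if n_dropped:
        logger.warning("extract_subvolumes: dropped %d out-of-bounds particle(s)", n_dropped)
    if not cubes:
        return np.zeros((0, b, b, b), dtype=np.float32), ParticleSet(
            particles.table.iloc[[]].copy(), particles.stage
        )
    kept = particles.table.loc[keep_rows].reset_index(drop=True)
    return np.stack(cubes).astype(np.float32), ParticleSet(kept, particles.stage)
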