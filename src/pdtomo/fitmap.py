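"""Candidate screening by model-to-map fitting.

A candidate subunit (bead model) is turned into a synthetic density map at
the working resolution, tiled along the helical coat lattice, rigid-body
fitted into the experimental or synthetic average and scored by masked,
normalized real-space cross-correlation.  Only a unit that recapitulates
the periodic lattice features scores competitively; fits below a
null-calibrated floor (default 0.3) are flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import optimize

from .beads import BeadModel, Transform
from .euler import rotation_matrix
from .phantom import CoatSpec, helical_lattice_points
from .volume import Volume

__all__ = [
    "simulate_density",
    "map_cross_correlation",
    "rigid_fit",
    "tile_helical_model",
    "FitResult",
]

logger = logging.getLogger(__name__)

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class FitResult:
    transform: Transform
    score: float
    flagged: bool = False


def simulate_density(
    model: BeadModel,
    resolution_nm: float,
    voxel_size_nm: float,
    box_voxels: int,
    centre_nm: np.ndarray | None = None,
) -> Volume:
    """Sum of isotropic Gaussians; map integral equals total bead weight.

    Each bead contributes a normalized Gaussian of width
    sigma^2 = (resolution / 2.355)^2 + (radius/2)^2 scaled by its weight.
    ``centre_nm`` places the model origin; default is the box centre.
    """
    b = int(box_voxels)
    vol = Volume(np.zeros((b, b, b), dtype=np.float32), voxel_size_nm)
    if centre_nm is None:
        centre_nm = vol.centre_nm()
    pos = model.positions_nm + np.asarray(centre_nm)
    idx = vol.nm_to_voxel(pos)
    if np.any(idx < 0) or np.any(idx > b - 1):
        bad = np.flatnonzero(np.any((idx < 0) | (idx > b - 1), axis=1))
        raise ValueError(f"beads outside box: indices {bad.tolist()}")
    data = np.zeros((b, b, b), dtype=np.float64)
    sigma_res = resolution_nm / GAUSS_FWHM
    for p, w, r in zip(idx, model.weights, model.radii_nm):
        sigma = np.sqrt(sigma_res**2 + (r / 2.0) ** 2) / voxel_size_nm
        half = max(int(np.ceil(4.0 * sigma)), 2)
        lo = np.maximum(np.floor(p).astype(int) - half, 0)
        hi = np.minimum(np.floor(p).astype(int) + half + 1, b)
        gx = np.exp(-((np.arange(lo[0], hi[0]) - p[0]) ** 2) / (2 * sigma**2))
        gy = np.exp(-((np.arange(lo[1], hi[1]) - p[1]) ** 2) / (2 * sigma**2))
        gz = np.exp(-((np.arange(lo[2], hi[2]) - p[2]) ** 2) / (2 * sigma**2))
        norm = w / ((2 * np.pi) ** 1.5 * sigma**3)
        data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            norm * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        )
    # per-bead Gaussians are normalized on the voxel grid, so the voxel sum
    # of the map equals the total bead weight
    return Volume(data.astype(np.float32), voxel_size_nm)


def map_cross_correlation(
    a: Volume | np.ndarray, b: Volume | np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Masked, normalized real-space cross-correlation in [-1, 1]."""
    da = (a.data if isinstance(a, Volume) else np.asarray(a)).astype(np.float64)
    db = (b.data if isinstance(b, Volume) else np.asarray(b)).astype(np.float64)
    if da.shape != db.shape:
        raise ValueError("maps must share the same grid")
    m = np.ones_like(da) if mask is None else np.asarray(mask, dtype=float)
    ws = m.sum()
    am, bm = (da * m).sum() / ws, (db * m).sum() / ws
    va = (m * (da - am) ** 2).sum()
    vb = (m * (db - bm) ** 2).sum()
    if va <= 0 or vb <= 0:
        warnings.warn("map_cross_correlation: zero variance inside mask")
        return 0.0
    return float((m * (da - am) * (db - bm)).sum() / np.sqrt(va * vb))


def _best_shift(sim: np.ndarray, tgt_f: np.ndarray, tgt_norm: float, shift_mask: np.ndarray):
    s = sim - sim.mean()
    n = np.sqrt((s**2).sum())
    if n == 0 or tgt_norm == 0:
        return -np.inf, np.zeros(3)
    cc = sfft.irfftn(tgt_f * np.conj(sfft.rfftn(s)), s=sim.shape) / (n * tgt_norm)
    cc_m = np.where(shift_mask, cc, -np.inf)
    idx = np.unravel_index(np.argmax(cc_m), cc.shape)
    return float(cc[idx]), np.array(idx, dtype=float)


def rigid_fit(
    model: BeadModel,
    target: Volume,
    resolution_nm: float,
    angular_step_deg: float = 20.0,
    shift_range_nm: float | None = None,
    score_floor: float = 0.3,
    refine: bool = True,
) -> FitResult:
    """Exhaustive coarse rotation/translation search, then local refinement.

    Rotations on a global ZXZ grid at ``angular_step_deg``; for each, the
    model density is simulated and the best translation found by FFT
    cross-correlation on the voxel grid within ``shift_range_nm``.  A
    Nelder–Mead polish over the six rigid parameters follows.  Scores below
    ``score_floor`` (the null level of fits into unrelated density) are
    flagged.
    """
    if angular_step_deg <= 0:
        raise ValueError("empty rotation search range")
    box = target.shape[0]
    vs = target.voxel_size_nm
    if shift_range_nm is None:
        shift_range_nm = box * vs / 4.0
    if shift_range_nm < 0:
        raise ValueError("empty translation search range")
    tgt = target.data.astype(np.float64)
    tgt -= tgt.mean()
    tgt_norm = np.sqrt((tgt**2).sum())
    tgt_f = sfft.rfftn(tgt)
    d = np.fft.fftfreq(box) * box * vs
    dx, dy, dz = np.meshgrid(d, d, d, indexing="ij", sparse=True)
    shift_mask = dx**2 + dy**2 + dz**2 <= shift_range_nm**2

    centred = model.centered()
    from .stavg import _angle_grid  # same global ZXZ grid

    best = (-np.inf, (0.0, 0.0, 0.0), np.zeros(3))
    for euler in _angle_grid(angular_step_deg):
        rot = centred.transformed(Transform(euler_deg=euler))
        try:
            sim = simulate_density(rot, resolution_nm, vs, box).data.astype(np.float64)
        except ValueError:
            continue
        score, idx = _best_shift(sim, tgt_f, tgt_norm, shift_mask)
        if score > best[0]:
            s = idx.copy()
            s[s > box / 2] -= box
            best = (score, euler, s * vs)

    score, euler, shift = best

    if refine:
        def neg_cc(params: np.ndarray) -> float:
            t = Transform(euler_deg=tuple(params[:3]), translation_nm=params[3:])
            try:
                sim = simulate_density(centred.transformed(t), resolution_nm, vs, box).data
            except ValueError:
                return 1.0
            return -map_cross_correlation(sim, target.data)

        x0 = np.array([*euler, *shift])
        res = optimize.minimize(
            neg_cc, x0, method="Nelder-Mead",
            options={"xatol": 0.05, "fatol": 1e-5, "maxiter": 300},
        )
        if -res.fun >= score:
            score = -res.fun
            euler = tuple(res.x[:3])
            shift = res.x[3:]

    t = Transform(euler_deg=tuple(euler), translation_nm=np.asarray(shift))
    flagged = score < score_floor
    if flagged:
        logger.warning("rigid_fit: score %.3f below acceptance floor %.2f", score, score_floor)
    return FitResult(t, float(score), flagged)


def tile_helical_model(
    unit: BeadModel,
    coat: CoatSpec,
    axis: np.ndarray,
    n_per_wrap: int | None = None,
) -> BeadModel:
    """Copy a dimer unit to every helical lattice site.

    The unit must be centred at the origin with its radial axis along +z
    and its helix-tangent axis along +x (matching lattice site frames).
    Bead count of the result is len(unit) * n_starts * n_per_wrap.
    """
    axis = np.atleast_2d(np.asarray(axis, dtype=float))
    if n_per_wrap is not None:
        length = n_per_wrap * coat.axial_rise_nm
        seglen = np.linalg.norm(np.diff(axis, axis=0), axis=1).sum()
        length = min(length, seglen)
        intervals = [(0.0, length)]
    else:
        intervals = [(0.0, np.linalg.norm(np.diff(axis, axis=0), axis=1).sum())]
    sites = helical_lattice_points(coat, axis, intervals)
    copies = []
    for pos, eul in sites:
        mat = rotation_matrix(*eul)
        copies.append(
            BeadModel(unit.positions_nm @ mat.T + pos, unit.weights, unit.radii_nm, unit.label)
        )
    tiled = BeadModel.concatenate(copies, label=f"{unit.label}_tiled")
    # overlap warning: nearest site spacing vs unit extent
    if len(sites) > 1:
        d_min = np.inf
        ps = np.array([p for p, _ in sites])
        for i in range(len(ps)):
            dd = np.linalg.norm(ps[i + 1 :] - ps[i], axis=1)
            if len(dd):
                d_min = min(d_min, dd.min())
        ext = np.linalg.norm(
            unit.positions_nm.max(axis=0) - unit.positions_nm.min(axis=0)
        ) + 2 * float(np.max(unit.radii_nm))
        if d_min < 0.5 * ext:
            logger.warning(
                "tile_helical_model: site spacing %.2f nm < half unit diameter %.2f nm", d_min, ext / 2
            )
    return tiled
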