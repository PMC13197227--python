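"""Missing-wedge-aware subtomogram alignment, averaging and FSC.

Two-stage scheme: (1) constrained alignment of axis-seeded particles —
shifts allowed only perpendicular to each particle's z axis (the tubule
axis), no in-plane angle search, reference low-pass filtered to 3.5–4 nm,
the first reference being the unaligned mean of the stack; (2) after
pseudo-symmetry expansion, exhaustive search over all three Euler angles on
a coarse global grid with local refinement at a fifth of the step, shifts
bounded (default 11 nm).  Cross-correlations are computed over the
intersection of the Fourier-space sampling wedges; averages are wedge-
compensated (Fourier sum divided by summed rotated wedge coverage).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from ._wedge import wedge_mask_array
from .euler import rotation_matrix
from .geometry import ParticleSet
from .volume import Volume

__all__ = [
    "WedgeDescriptor",
    "AlignmentConstraints",
    "FSCCurve",
    "wedge_mask",
    "masked_cc",
    "soft_sphere_mask",
    "lowpass",
    "constrained_align",
    "exhaustive_align",
    "average_particles",
    "compute_fsc",
    "resolution_at_threshold",
]

logger = logging.getLogger(__name__)


@dataclass
class WedgeDescriptor:
    """Single-axis tilt geometry (tilt axis fixed to y)."""

    tilt_min_deg: float = -60.0
    tilt_max_deg: float = 60.0
    tilt_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)

    def __post_init__(self) -> None:
        if not (-90.0 < self.tilt_min_deg < self.tilt_max_deg < 90.0):
            raise ValueError("wedge requires -90 < min < max < 90")
        if tuple(self.tilt_axis) != (0.0, 1.0, 0.0):
            raise ValueError("only the y tilt axis is supported")


@dataclass
class AlignmentConstraints:
    """Knobs of the constrained first-stage alignment."""

    shift_mode: str = "perpendicular_only"  # or "free"
    max_shift_nm: float = 8.0
    search_phi: bool = False
    angular_step_deg: float = 10.0
    lowpass_nm: float = 3.75  # reference filter, midpoint of the 3.5-4.0 nm band

    def __post_init__(self) -> None:
        if self.shift_mode not in ("perpendicular_only", "free"):
            raise ValueError("shift_mode must be 'perpendicular_only' or 'free'")
        if self.max_shift_nm < 0:
            raise ValueError("max_shift_nm must be >= 0")
        if self.angular_step_deg <= 0:
            raise ValueError("angular_step_deg must be positive")


@dataclass
class FSCCurve:
    shell_freq_inv_nm: np.ndarray
    correlation: np.ndarray

    def __post_init__(self) -> None:
        self.shell_freq_inv_nm = np.asarray(self.shell_freq_inv_nm, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if len(self.shell_freq_inv_nm) != len(self.correlation):
            raise ValueError("frequency and correlation lengths differ")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("freq_inv_nm\tfsc\n")
            for f, c in zip(self.shell_freq_inv_nm, self.correlation):
                fh.write(f"{f:.6f}\t{c:.6f}\n")


# ---------------------------------------------------------------------------
# masks and filters
# ---------------------------------------------------------------------------

def wedge_mask(box_voxels: int, wedge: WedgeDescriptor, voxel_size_nm: float = 1.0) -> np.ndarray:
    """Binary Fourier mask (numpy fft ordering): 1 where data was sampled."""
    shape = (box_voxels,) * 3 if np.isscalar(box_voxels) else tuple(box_voxels)
    return wedge_mask_array(shape, wedge.tilt_min_deg, wedge.tilt_max_deg)


def soft_sphere_mask(box_voxels: int, radius_frac: float = 0.4, edge_vox: float = 3.0) -> np.ndarray:
    """Soft-edged sphere used as the real-space correlation mask."""
    b = int(box_voxels)
    c = (b - 1) / 2.0
    g = np.indices((b, b, b), dtype=float)
    r = np.sqrt(((g - c) ** 2).sum(axis=0))
    return np.clip((radius_frac * b - r) / edge_vox + 0.5, 0.0, 1.0)


def coat_slab_mask(
    box_voxels: int,
    voxel_size_nm: float,
    half_thickness_nm: float = 3.0,
    lateral_radius_frac: float = 0.4,
    edge_vox: float = 2.0,
) -> np.ndarray:
    """Soft slab |z - centre| <= half_thickness within a lateral cylinder.

    In the reference frame of surface-oriented particles (z radial) the
    coat layer lies in the central z-slab of the box; masking the reference
    to that slab focuses alignment scores on the lattice instead of the
    azimuthally smooth membranes above and below it.
    """
    b = int(box_voxels)
    c = (b - 1) / 2.0
    g = np.indices((b, b, b), dtype=float)
    rho = np.sqrt((g[0] - c) ** 2 + (g[1] - c) ** 2)
    ht = half_thickness_nm / voxel_size_nm
    slab = np.clip((ht - np.abs(g[2] - c)) / edge_vox + 0.5, 0.0, 1.0)
    lat = np.clip((lateral_radius_frac * b - rho) / edge_vox + 0.5, 0.0, 1.0)
    return slab * lat


def coat_shell_mask(
    box_voxels: int,
    voxel_size_nm: float,
    tube_radius_nm: float,
    half_thickness_nm: float = 3.0,
    edge_vox: float = 2.0,
) -> np.ndarray:
    """Soft cylindrical shell following the tubule surface.

    In the reference frame of a surface-oriented particle (z radial, x
    along the tubule) the tube axis runs along x at z = centre - radius;
    the coat layer is the shell |rho - radius| <= half_thickness about it.
    Unlike a flat slab, the shell keeps the whole visible azimuth of the
    patch inside the mask, which couples neighbouring expansion azimuths
    during register alignment and breaks alias-register degeneracies.
    """
    b = int(box_voxels)
    c = (b - 1) / 2.0
    r_vox = tube_radius_nm / voxel_size_nm
    g = np.indices((b, b, b), dtype=float)
    rho = np.sqrt((g[1] - c) ** 2 + (g[2] - (c - r_vox)) ** 2)
    ht = half_thickness_nm / voxel_size_nm
    return np.clip((ht - np.abs(rho - r_vox)) / edge_vox + 0.5, 0.0, 1.0)


def lowpass(data: np.ndarray, voxel_size_nm: float, resolution_nm: float) -> np.ndarray:
    """Gaussian low-pass to the given resolution (falls to ~0.5 at 1/res)."""
    k = np.sqrt(
        sum(
            np.fft.fftfreq(n, d=voxel_size_nm)[tuple(
                slice(None) if i == j else None for j in range(3)
            )] ** 2
            for i, n in enumerate(data.shape)
        )
    )
    kc = 1.0 / resolution_nm
    filt = np.exp(-(k**2) * np.log(2.0) / (2 * kc**2) * 4.0)
    return np.fft.ifftn(np.fft.fftn(data) * filt).real


def _rfft_mask(mask: np.ndarray) -> np.ndarray:
    return mask[:, :, : mask.shape[2] // 2 + 1]


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def masked_cc(
    a: Volume | np.ndarray,
    b: Volume | np.ndarray,
    wedge_a: np.ndarray | None = None,
    wedge_b: np.ndarray | None = None,
    real_mask: np.ndarray | None = None,
) -> float:
    """Wedge-constrained, mask-normalized cross-correlation in [-1, 1].

    Both volumes are restricted to the intersection of their Fourier
    sampling wedges, then correlated with mean/variance normalization
    inside ``real_mask`` (a soft 0.4-box-radius sphere by default).
    """
    da = (a.data if isinstance(a, Volume) else np.asarray(a)).astype(np.float64)
    db = (b.data if isinstance(b, Volume) else np.asarray(b)).astype(np.float64)
    if da.shape != db.shape:
        raise ValueError("volumes must share dimensions")
    inter = None
    if wedge_a is not None or wedge_b is not None:
        inter = np.ones(da.shape, dtype=bool)
        if wedge_a is not None:
            inter &= wedge_a.astype(bool)
        if wedge_b is not None:
            inter &= wedge_b.astype(bool)
        if not inter.all():
            da = np.fft.ifftn(np.fft.fftn(da) * inter).real
            db = np.fft.ifftn(np.fft.fftn(db) * inter).real
    m = soft_sphere_mask(da.shape[0]) if real_mask is None else np.asarray(real_mask, dtype=float)
    wsum = m.sum()
    am = (da * m).sum() / wsum
    bm = (db * m).sum() / wsum
    va = (m * (da - am) ** 2).sum()
    vb = (m * (db - bm) ** 2).sum()
    if va <= 0 or vb <= 0:
        warnings.warn("masked_cc: zero variance inside mask; returning 0")
        return 0.0
    return float((m * (da - am) * (db - bm)).sum() / np.sqrt(va * vb))


def _rotate_volume(data: np.ndarray, mat: np.ndarray, order: int = 1) -> np.ndarray:
    """out(x) = data(mat @ x) about the box centre, trilinear by default."""
    c = (np.array(data.shape) - 1) / 2.0
    offset = c - mat @ c
    return ndimage.affine_transform(
        data, mat, offset=offset, order=order, mode="constant", cval=0.0, prefilter=order > 1
    )


def _shift_mask(box: int, voxel_size_nm: float, max_shift_nm: float) -> np.ndarray:
    """Boolean mask over the (fft-ordered) CC map of admissible shifts."""
    d = np.fft.fftfreq(box) * box * voxel_size_nm  # displacement in nm per index
    dx, dy, dz = np.meshgrid(d, d, d, indexing="ij", sparse=True)
    return dx**2 + dy**2 + dz**2 <= max_shift_nm**2


def _shift_vectors_nm(box: int, voxel_size_nm: float) -> tuple[np.ndarray, ...]:
    d = np.fft.fftfreq(box) * box * voxel_size_nm
    return np.meshgrid(d, d, d, indexing="ij", sparse=True)


def _prep(volume: np.ndarray) -> np.ndarray:
    v = volume.astype(np.float64)
    return v - v.mean()


def _cc_peak(
    fp: np.ndarray,
    ref_wedged: np.ndarray,
    p_norm: float,
    allowed: np.ndarray,
    box: int,
) -> tuple[float, np.ndarray]:
    """Best normalized CC over admissible shifts; returns (score, shift_idx)."""
    fr = sfft.rfftn(ref_wedged)
    r_norm = np.sqrt((ref_wedged**2).sum())
    if r_norm == 0 or p_norm == 0:
        return 0.0, np.zeros(3)
    cc = sfft.irfftn(fp * np.conj(fr), s=(box,) * 3) / (p_norm * r_norm)
    cc_masked = np.where(allowed, cc, -np.inf)
    idx = np.unravel_index(np.argmax(cc_masked), cc.shape)
    return float(cc[idx]), np.array(idx, dtype=float)


def _idx_to_shift_nm(idx: np.ndarray, box: int, voxel_size_nm: float) -> np.ndarray:
    s = np.asarray(idx, dtype=float).copy()
    s[s > box / 2] -= box
    # cc[s] = sum ref(x - s) p(x): peak index = displacement of ref toward particle
    return s * voxel_size_nm


def constrained_align(
    stack: np.ndarray,
    particles: ParticleSet,
    wedge: WedgeDescriptor,
    constraints: AlignmentConstraints | None = None,
    n_iter: int = 5,
    voxel_size_nm: float = 0.76,
    stop_mean_shift_vox: float = 0.5,
) -> tuple[ParticleSet, Volume]:
    """First-stage alignment: perpendicular-only shifts, no phi search.

    The iteration-1 reference is the unaligned mean of the stack; each later
    reference is the wedge-compensated aligned average of the previous
    iteration, low-pass filtered to ``constraints.lowpass_nm``.  Returns the
    updated particles (stage ``aligned1``) and the final average.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    constraints = constraints or AlignmentConstraints()
    box = stack.shape[1]
    mask = wedge_mask(box, wedge)
    mask_r = _rfft_mask(mask)
    table = particles.table.copy().reset_index(drop=True)
    table["score"] = table["score"].astype(float)
    extract_pos = table[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float).copy()

    cubes = [_prep(c) for c in stack]
    fps = [sfft.rfftn(c) for c in cubes]
    p_norms = [np.sqrt((c**2).sum()) for c in cubes]
    rots = [rotation_matrix(r.phi_deg, r.theta_deg, r.psi_deg) for r in table.itertuples()]
    zaxes = [m[:, 2] for m in rots]

    reference = np.mean(stack, axis=0).astype(np.float64)
    shift_ok_base = _shift_mask(box, voxel_size_nm, constraints.max_shift_nm)
    dx, dy, dz = _shift_vectors_nm(box, voxel_size_nm)

    offsets = np.zeros((len(cubes), 3))
    for it in range(n_iter):
        ref = lowpass(_prep(reference), voxel_size_nm, constraints.lowpass_nm)
        shifts_this_iter = []
        for i in range(len(cubes)):
            rot_ref = _rotate_volume(ref, np.linalg.inv(rots[i]))
            rot_ref = sfft.irfftn(sfft.rfftn(rot_ref) * mask_r, s=(box,) * 3)
            allowed = shift_ok_base.copy()
            if constraints.shift_mode == "perpendicular_only":
                n = zaxes[i]
                along = dx * n[0] + dy * n[1] + dz * n[2]
                allowed &= np.abs(along) <= 0.6 * voxel_size_nm
            score, idx = _cc_peak(fps[i], rot_ref, p_norms[i], allowed, box)
            s_nm = _idx_to_shift_nm(idx, box, voxel_size_nm)
            if constraints.shift_mode == "perpendicular_only":
                s_nm = s_nm - zaxes[i] * (s_nm @ zaxes[i])
            shifts_this_iter.append(np.linalg.norm(s_nm - offsets[i]))
            offsets[i] = s_nm
            table.loc[i, "score"] = score
        reference = _build_average(cubes, rots, offsets, mask, voxel_size_nm)
        mean_step = float(np.mean(shifts_this_iter)) / voxel_size_nm
        logger.info("constrained_align iter %d: mean shift step %.3f vox", it + 1, mean_step)
        if mean_step < stop_mean_shift_vox:
            break

    table[["x_nm", "y_nm", "z_nm"]] = extract_pos + offsets
    if n_iter == 0:
        ref = lowpass(_prep(reference), voxel_size_nm, constraints.lowpass_nm)
        for i in range(len(cubes)):
            rot_ref = _rotate_volume(ref, np.linalg.inv(rots[i]))
            rot_ref = sfft.irfftn(sfft.rfftn(rot_ref) * mask_r, s=(box,) * 3)
            r_norm = np.sqrt((rot_ref**2).sum())
            table.loc[i, "score"] = float(
                (cubes[i] * rot_ref).sum() / (p_norms[i] * r_norm)
            ) if r_norm > 0 else 0.0
    table["stage"] = "aligned1"
    avg = Volume(reference.astype(np.float32), voxel_size_nm).normalized()
    return ParticleSet(table, "aligned1"), avg


def _angle_grid(step: float) -> list[tuple[float, float, float]]:
    phis = np.arange(0.0, 360.0, step)
    thetas = np.arange(0.0, 180.0 + 1e-9, step)
    grid = []
    for th in thetas:
        if th < 1e-9 or th > 180.0 - 1e-9:
            grid.extend((p, th, 0.0) for p in phis)
        else:
            grid.extend((p, th, ps) for p in phis for ps in phis)
    return grid


def exhaustive_align(
    stack: np.ndarray,
    particles: ParticleSet,
    reference: Volume | np.ndarray,
    wedge: WedgeDescriptor,
    angular_step_deg: float = 30.0,
    max_shift_nm: float = 11.0,
    voxel_size_nm: float = 0.76,
    lowpass_nm: float | None = 3.75,
    local_deg: float | None = None,
    ref_mask: np.ndarray | None = None,
) -> ParticleSet:
    """Second-stage alignment: global Euler grid plus step/5 local refinement.

    For every particle the best (phi, theta, psi) over a global grid at
    ``angular_step_deg`` is found (shift bounded by ``max_shift_nm``), then
    refined on the 3x3x3 neighbourhood at a fifth of the step.  Scores and
    positions are updated; stage becomes ``aligned2``.

    ``local_deg``, if given, restricts each particle's search to grid
    orientations within that rotation distance of its current orientation —
    an orientation prior for tubule-surface particles whose normals are
    already known from the picking geometry.  Default is the full grid.
    ``ref_mask`` is a real-space mask applied to the reference in its own
    frame before rotation (e.g. :func:`coat_slab_mask`), focusing the score
    on the structured layer.
    """
    if angular_step_deg <= 0:
        raise ValueError("angular_step_deg must be positive")
    if len(stack) == 0:
        raise ValueError("empty stack")
    box = stack.shape[1]
    ref = (reference.data if isinstance(reference, Volume) else np.asarray(reference)).astype(np.float64)
    ref = _prep(ref)
    if lowpass_nm:
        ref = lowpass(ref, voxel_size_nm, lowpass_nm)
    if ref_mask is not None:
        ref = ref * np.asarray(ref_mask, dtype=float)
    mask_r = _rfft_mask(wedge_mask(box, wedge))
    allowed = _shift_mask(box, voxel_size_nm, max_shift_nm)
    flat_allowed = np.flatnonzero(allowed.ravel())

    cubes = [_prep(c).astype(np.float32) for c in stack]
    n = len(cubes)
    fps = np.stack([sfft.rfftn(c) for c in cubes]).astype(np.complex64)
    p_norms = np.array([np.sqrt((c.astype(np.float64) ** 2).sum()) for c in cubes])

    best_score = np.full(n, -np.inf)
    best_euler = np.zeros((n, 3))
    best_idx = np.zeros((n, 3))

    def rotated_ref(euler: tuple[float, float, float]) -> np.ndarray:
        mat = rotation_matrix(*euler)
        rr = _rotate_volume(ref, np.linalg.inv(mat))
        return sfft.irfftn(sfft.rfftn(rr) * mask_r, s=(box,) * 3)

    def score_some(fr: np.ndarray, r_norm: float, sel: np.ndarray):
        """Best admissible-shift CC of selected particles against one rotation."""
        cc = sfft.irfftn(fps[sel] * np.conj(fr)[None], s=(box,) * 3, axes=(1, 2, 3))
        cc_flat = cc.reshape(len(sel), -1)[:, flat_allowed]
        j = np.argmax(cc_flat, axis=1)
        return cc_flat[np.arange(len(sel)), j] / (p_norms[sel] * r_norm), flat_allowed[j]

    grid = _angle_grid(angular_step_deg)
    all_idx = np.arange(n)
    if local_deg is None:
        selections = [all_idx] * len(grid)
    else:
        priors = np.stack(
            [rotation_matrix(r.phi_deg, r.theta_deg, r.psi_deg)
             for r in particles.table.itertuples()]
        )  # (n, 3, 3)
        grid_mats = np.stack([rotation_matrix(*e) for e in grid])  # (g, 3, 3)
        tr = np.einsum("nij,gij->ng", priors, grid_mats)
        dist = np.degrees(np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0)))
        selections = [np.flatnonzero(dist[:, g] <= local_deg) for g in range(len(grid))]

    for euler, sel in zip(grid, selections):
        if len(sel) == 0:
            continue
        rr = rotated_ref(euler)
        fr = sfft.rfftn(rr).astype(np.complex64)
        r_norm = np.sqrt((rr**2).sum())
        if r_norm == 0:
            continue
        scores, flat_idx = score_some(fr, r_norm, sel)
        better = scores > best_score[sel]
        if np.any(better):
            upd = sel[better]
            best_score[upd] = scores[better]
            best_euler[upd] = euler
            best_idx[upd] = np.column_stack(
                np.unravel_index(flat_idx[better], (box,) * 3)
            )

    if local_deg is not None:
        # the prior orientation itself is always a candidate (the grid may
        # have no point inside a tight local_deg neighbourhood)
        for i, row in enumerate(particles.table.itertuples()):
            e = (row.phi_deg, row.theta_deg, row.psi_deg)
            rr = rotated_ref(e)
            fr = sfft.rfftn(rr).astype(np.complex64)
            r_norm = np.sqrt((rr**2).sum())
            if r_norm == 0:
                continue
            scores, flat_idx = score_some(fr, r_norm, np.array([i]))
            if scores[0] > best_score[i]:
                best_score[i] = scores[0]
                best_euler[i] = e
                best_idx[i] = np.unravel_index(flat_idx[0], (box,) * 3)

    # local refinement at a fifth of the coarse step
    fine = angular_step_deg / 5.0
    cache: dict = {}
    for i in range(n):
        for d_phi in (-2, -1, 0, 1, 2):
            for d_th in (-1, 0, 1):
                for d_psi in (-1, 0, 1):
                    if d_phi == d_th == d_psi == 0:
                        continue
                    e = (
                        (best_euler[i][0] + d_phi * fine) % 360.0,
                        float(np.clip(best_euler[i][1] + d_th * fine, 0.0, 180.0)),
                        (best_euler[i][2] + d_psi * fine) % 360.0,
                    )
                    key = tuple(np.round(e, 3))
                    if key not in cache:
                        rr = rotated_ref(e)
                        cache[key] = (sfft.rfftn(rr), np.sqrt((rr**2).sum()))
                    fr, r_norm = cache[key]
                    if r_norm == 0:
                        continue
                    cc = sfft.irfftn(fps[i] * np.conj(fr), s=(box,) * 3) / (p_norms[i] * r_norm)
                    cc_m = np.where(allowed, cc, -np.inf)
                    idx = np.unravel_index(np.argmax(cc_m), cc.shape)
                    if cc[idx] > best_score[i]:
                        best_score[i] = cc[idx]
                        best_euler[i] = e
                        best_idx[i] = idx

    table = particles.table.copy().reset_index(drop=True)
    shifts = np.array(
        [_idx_to_shift_nm(best_idx[i], box, voxel_size_nm) for i in range(n)]
    )
    table[["x_nm", "y_nm", "z_nm"]] = (
        table[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float) + shifts
    )
    table[["phi_deg", "theta_deg", "psi_deg"]] = best_euler
    table["score"] = best_score
    table["stage"] = "aligned2"
    return ParticleSet(table, "aligned2")


def _build_average(
    cubes: list[np.ndarray],
    rots: list[np.ndarray],
    offsets_nm: np.ndarray,
    mask: np.ndarray,
    voxel_size_nm: float,
    axial_apodization_nm: float | None = None,
) -> np.ndarray:
    """Wedge-compensated average in the reference frame.

    ``axial_apodization_nm`` applies a Gaussian window of that sigma along
    the reference x axis (the tubule direction for surface particles) to
    each rotated cube, so every particle contributes only its local
    neighbourhood.  For helical registers known only modulo the lattice
    period this suppresses ghost replicas of aperiodic features (assembly
    ends) that otherwise alias into sub-harmonic stripe patterns.
    """
    box = cubes[0].shape[0]
    f_sum = np.zeros((box,) * 3, dtype=np.complex128)
    cov = np.zeros((box,) * 3, dtype=np.float64)
    mask_shifted = np.fft.fftshift(mask.astype(np.float64))
    kx, ky, kz = np.meshgrid(
        np.fft.fftfreq(box), np.fft.fftfreq(box), np.fft.fftfreq(box), indexing="ij", sparse=True
    )
    window = None
    if axial_apodization_nm is not None:
        x = (np.arange(box) - (box - 1) / 2.0) * voxel_size_nm
        window = np.exp(-(x**2) / (2.0 * axial_apodization_nm**2))[:, None, None]
    for cube, mat, off in zip(cubes, rots, offsets_nm):
        off_vox = np.asarray(off) / voxel_size_nm
        # shift object back to the box centre, then rotate into reference frame
        phase = np.exp(2j * np.pi * (kx * off_vox[0] + ky * off_vox[1] + kz * off_vox[2]))
        centred = np.fft.ifftn(np.fft.fftn(cube) * phase).real
        rot = _rotate_volume(centred, mat)
        if window is not None:
            rot = rot * window
        f_sum += np.fft.fftn(rot)
        cov += np.fft.ifftshift(_rotate_volume(mask_shifted, mat))
    # zero-coverage voxels stay 0; covered voxels are compensated with the
    # denominator guarded at >= 1
    avg_f = np.where(cov > 0.01, f_sum / np.maximum(cov, 1.0), 0.0)
    return np.fft.ifftn(avg_f).real


def average_particles(
    stack: np.ndarray,
    particles: ParticleSet,
    wedge: WedgeDescriptor,
    voxel_size_nm: float = 0.76,
    extract_positions_nm: np.ndarray | None = None,
    return_coverage: bool = False,
    axial_apodization_nm: float | None = None,
):
    """Wedge-compensated average of rotated/shifted subtomograms.

    Each cube is shifted by the difference between its particle position and
    its extraction centre, rotated into the reference frame by the inverse
    of its particle rotation, and summed in Fourier space; the sum is
    divided by the accumulated rotated wedge coverage (guarded at >= 1) and
    normalized to zero mean, unit variance.  Zero-coverage voxels stay 0.
    """
    if len(stack) == 0:
        raise ValueError("cannot average an empty particle set")
    box = stack.shape[1]
    mask = wedge_mask(box, wedge)
    table = particles.table.reset_index(drop=True)
    pos = table[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    offsets = np.zeros_like(pos) if extract_positions_nm is None else pos - np.asarray(extract_positions_nm)
    rots = [rotation_matrix(r.phi_deg, r.theta_deg, r.psi_deg) for r in table.itertuples()]
    cubes = [_prep(c) for c in stack]
    avg = _build_average(cubes, rots, offsets, mask, voxel_size_nm, axial_apodization_nm)
    vol = Volume(avg.astype(np.float32), voxel_size_nm).normalized()
    if return_coverage:
        cov = np.zeros((box,) * 3)
        mask_shifted = np.fft.fftshift(mask.astype(np.float64))
        for mat in rots:
            cov += np.fft.ifftshift(_rotate_volume(mask_shifted, mat))
        return vol, cov
    return vol


def remove_cylindrical_average(
    data: np.ndarray, axis_offset_vox: float, support: np.ndarray | None = None
) -> np.ndarray:
    """Subtract the azimuthal mean about a tube axis along x at z = c - offset.

    The azimuthally uniform component (membranes, smooth sheaths) carries no
    information about the helical register; removing it from an alignment
    reference leaves the lattice-modulated signal that does.  Radial bins
    are one voxel wide.  ``support`` (0..1) weights the mean for references
    with partial coverage (e.g. a single rotated cube); the result is also
    re-multiplied by it so unsupported voxels stay zero.
    """
    b = data.shape[0]
    c = (b - 1) / 2.0
    g = np.indices(data.shape, dtype=float)
    rho = np.sqrt((g[1] - c) ** 2 + (g[2] - (c - axis_offset_vox)) ** 2)
    n_r = int(np.ceil(rho.max())) + 2
    xi = g[0].astype(int)
    ri = np.clip(np.round(rho).astype(int), 0, n_r - 1)
    flat = xi.ravel() * n_r + ri.ravel()
    w = np.ones_like(data) if support is None else np.asarray(support, dtype=float)
    sums = np.bincount(flat, weights=(data * w).ravel(), minlength=b * n_r)
    cnts = np.bincount(flat, weights=w.ravel(), minlength=b * n_r)
    mean = np.where(cnts > 1e-3, sums / np.maximum(cnts, 1e-3), 0.0)
    return (data - mean[flat].reshape(data.shape)) * w


def lock_lattice_register(
    stack: np.ndarray,
    particles: ParticleSet,
    wedge: WedgeDescriptor,
    tube_radius_nm: float,
    voxel_size_nm: float = 0.76,
    n_iter: int = 3,
    max_shift_nm: float = 4.0,
    anchor_seed: int = 0,
    slab_half_thickness_nm: float = 3.0,
    n_anchors: int = 3,
    axial_apodization_nm: float | None = 8.0,
) -> tuple[ParticleSet, Volume]:
    """Snap surface-expanded particles into a common helical register.

    Pseudo-symmetry expansion samples a helical lattice at azimuths that are
    generally incommensurate with its start symmetry, so the unaligned
    expanded average is smeared along the symmetry direction.  This stage
    recovers the register: starting from one seeded anchor particle as
    reference, each iteration scores every particle against the reference
    restricted to the coat layer (slab mask) with its cylindrically
    symmetric background removed, allowing shifts only along the tube axis
    (the register degree of freedom, sub-voxel by parabolic interpolation),
    then rebuilds the wedge-compensated average.  Orientations stay at
    their geometry-derived values.

    The iteration is a multi-start optimization: it is repeated from
    ``n_anchors`` seeded anchor particles and the result whose average
    carries the strongest azimuthally structured (helical) spectral signal
    is kept, since a poorly chosen anchor can trap the register in a
    mixed-phase state.  Returns particles with updated positions and
    scores plus the final average.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    if n_anchors > 1:
        from .lattice import scan_radius  # internal contrast metric

        best = None
        for a in range(n_anchors):
            parts, avg = lock_lattice_register(
                stack, particles, wedge, tube_radius_nm, voxel_size_nm,
                n_iter, max_shift_nm, anchor_seed + 7919 * a,
                slab_half_thickness_nm, n_anchors=1,
                axial_apodization_nm=axial_apodization_nm,
            )
            axis_point = avg.centre_nm() - np.array([0.0, 0.0, tube_radius_nm])
            res, _ = scan_radius(
                avg, axis_point, (1.0, 0.0, 0.0), tube_radius_nm,
                axial_range_nm=(-13.0, 13.0), azimuth_range_deg=(15.0, 165.0),
            )
            logger.info("register anchor %d: lattice confidence %.4f", a, res.confidence)
            if best is None or res.confidence > best[0]:
                best = (res.confidence, parts, avg)
        return best[1], best[2]
    box = stack.shape[1]
    table = particles.table.copy().reset_index(drop=True)
    table["score"] = table["score"].astype(float)
    extract_pos = table[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float).copy()
    rots = [rotation_matrix(r.phi_deg, r.theta_deg, r.psi_deg) for r in table.itertuples()]
    axes = [m[:, 0] for m in rots]  # tube axis in the tomogram frame
    cubes = [_prep(c) for c in stack]
    fps = [sfft.rfftn(c) for c in cubes]
    p_norms = [np.sqrt((c**2).sum()) for c in cubes]
    mask = wedge_mask(box, wedge)
    mask_r = _rfft_mask(mask)
    slab = coat_shell_mask(
        box, voxel_size_nm, tube_radius_nm, half_thickness_nm=slab_half_thickness_nm
    )
    dx, dy, dz = _shift_vectors_nm(box, voxel_size_nm)

    rng = np.random.default_rng(anchor_seed)
    k0 = int(rng.integers(len(cubes)))
    reference = _build_average([cubes[k0]], [rots[k0]], np.zeros((1, 3)), mask, voxel_size_nm)
    ones = np.ones((box,) * 3)
    support = _rotate_volume(ones, rots[k0])
    support_all = np.mean([_rotate_volume(ones, m) for m in rots], axis=0)

    offsets = np.zeros((len(cubes), 3))
    for it in range(n_iter):
        mref = remove_cylindrical_average(
            _prep(reference), tube_radius_nm / voxel_size_nm, support=support
        ) * slab
        support = support_all
        for i in range(len(cubes)):
            a = axes[i]
            along = dx * a[0] + dy * a[1] + dz * a[2]
            perp2 = (dx**2 + dy**2 + dz**2) - along**2
            allowed = (np.abs(along) <= max_shift_nm) & (perp2 <= (0.9 * voxel_size_nm) ** 2)
            rr = _rotate_volume(mref, np.linalg.inv(rots[i]))
            rr = sfft.irfftn(sfft.rfftn(rr) * mask_r, s=(box,) * 3)
            r_norm = np.sqrt((rr**2).sum())
            if r_norm == 0:
                continue
            cc = sfft.irfftn(fps[i] * np.conj(sfft.rfftn(rr)), s=(box,) * 3)
            cc_m = np.where(allowed, cc, -np.inf)
            idx = np.unravel_index(np.argmax(cc_m), cc.shape)
            s = _idx_to_shift_nm(np.array(idx, dtype=float), box, voxel_size_nm)
            # sub-voxel parabola along the dominant axis of the tube direction
            ax_dim = int(np.argmax(np.abs(a)))
            im, i0, ip = list(idx), list(idx), list(idx)
            im[ax_dim] = (idx[ax_dim] - 1) % box
            ip[ax_dim] = (idx[ax_dim] + 1) % box
            y0, y1, y2 = cc[tuple(im)], cc[tuple(i0)], cc[tuple(ip)]
            denom = y0 - 2 * y1 + y2
            frac = 0.0 if denom == 0 else float(np.clip(0.5 * (y0 - y2) / denom, -1, 1))
            s[ax_dim] += frac * voxel_size_nm
            offsets[i] = s
            table.loc[i, "score"] = float(cc[idx] / (p_norms[i] * r_norm))
        reference = _build_average(
            cubes, rots, offsets, mask, voxel_size_nm, axial_apodization_nm
        )

    table[["x_nm", "y_nm", "z_nm"]] = extract_pos + offsets
    avg = Volume(reference.astype(np.float32), voxel_size_nm).normalized()
    return ParticleSet(table, particles.stage), avg


# ---------------------------------------------------------------------------
# FSC
# ---------------------------------------------------------------------------

def compute_fsc(half_a: Volume, half_b: Volume) -> FSCCurve:
    """Per-shell normalized correlation between two half-maps."""
    if half_a.shape != half_b.shape or abs(half_a.voxel_size_nm - half_b.voxel_size_nm) > 1e-9:
        raise ValueError("half-maps must share grid and voxel size")
    n = half_a.shape[0]
    fa = np.fft.fftn(half_a.data.astype(np.float64))
    fb = np.fft.fftn(half_b.data.astype(np.float64))
    k = np.sqrt(
        sum(
            (np.fft.fftfreq(s) * s)[tuple(slice(None) if i == j else None for j in range(3))] ** 2
            for i, s in enumerate(half_a.shape)
        )
    )
    shells = np.round(k).astype(int)
    nshell = n // 2 + 1
    num = np.zeros(nshell)
    da = np.zeros(nshell)
    db = np.zeros(nshell)
    flat = shells.ravel()
    sel = flat < nshell
    np.add.at(num, flat[sel], (fa * np.conj(fb)).real.ravel()[sel])
    np.add.at(da, flat[sel], (np.abs(fa) ** 2).ravel()[sel])
    np.add.at(db, flat[sel], (np.abs(fb) ** 2).ravel()[sel])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(da * db)
    corr = np.nan_to_num(corr, nan=0.0)
    freqs = np.arange(nshell) / (n * half_a.voxel_size_nm)
    return FSCCurve(freqs, corr)


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.143) -> tuple[float, bool]:
    """Inverse frequency of the first threshold crossing (linear interpolation).

    Returns (resolution_nm, reached).  If the curve never drops below the
    threshold, the Nyquist-limited bound is returned with reached=False.
    """
    f = curve.shell_freq_inv_nm
    c = curve.correlation
    for i in range(1, len(c)):
        if c[i] < threshold <= c[i - 1]:
            frac = (c[i - 1] - threshold) / (c[i - 1] - c[i])
            fc = f[i - 1] + frac * (f[i] - f[i - 1])
            return float(1.0 / fc), True
    return float(1.0 / f[-1]), False
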