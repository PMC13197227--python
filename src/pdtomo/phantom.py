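"""Synthetic plasmodesma phantoms with exact ground truth.

A phantom emulates a single plasmodesma (PD): a cell-wall slab pierced by a
cylindrical channel, lined by the plasma membrane (PM), traversed by a
central desmotubule (DT, an ER-derived membrane tubule) whose diameter
varies along the channel, decorated at the neck regions by a multi-start
helical protein coat with flexible tethers reaching the PM, and optionally
sealed at one or both apertures by a granulated callose-like plug.

Four presets correspond to the imaged conditions: wild-type protonemata
(``wt_proto``: DT wider at the necks, 24.1 nm, narrower at the centre,
10.5 nm), wild-type gametophores (``wt_gameto``: uniformly 24.5 nm, fully
coated), ABA-treated protonemata (``aba_proto``: constricted, a fraction of
apertures sealed) and a glucanase-overexpressor (``ghl17_proto``: shorter
and wider channels with resolvable coat-to-PM tethers, 19.8 +/- 4.2 nm,
max 26.4 nm).

Geometry conventions: the channel axis runs along z through the lateral box
centre; all diameters are membrane midline-to-midline (between the two
leaflet midplanes); lengths in nm; density is positive (protein/membrane
bright) unless inverted downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from ._wedge import wedge_mask_array
from .beads import BeadModel
from .volume import Volume, DEFAULT_VOXEL_NM

__all__ = [
    "CoatSpec",
    "TetherSpec",
    "PhantomSpec",
    "GroundTruth",
    "helical_lattice_points",
    "build_phantom",
    "apply_imaging_model",
    "simulate_tomogram",
    "preset",
    "PRESETS",
]

MEMBRANE_SIGMA_NM = 1.0  # Gaussian width of one leaflet shell
PM_WALL_CLEARANCE_NM = 2.75  # gap between PM midline and wall fill / face plane


def _default_subunit() -> BeadModel:
    # one coat dimer footprint, elongated along the helix tangent (x) so
    # consecutive subunits on a wrap join into a continuous strand (the
    # coats appear as intertwined wraps, not beaded rings), with a central
    # hump marking the repeating unit
    return BeadModel(
        positions_nm=[
            [-2.8, 0.0, 0.0],
            [-1.4, 0.0, 0.0],
            [0.0, 0.0, 0.6],
            [1.4, 0.0, 0.0],
            [2.8, 0.0, 0.0],
        ],
        weights=[1.0, 1.0, 1.2, 1.0, 1.0],
        radii_nm=[1.0, 1.0, 1.0, 1.0, 1.0],
        label="coat_dimer",
    )


@dataclass
class CoatSpec:
    """Multi-start helical lattice of coat subunits on the desmotubule.

    ``n_starts`` intertwined wraps; subunit centres at ``tube_radius_nm``
    from the axis; one wrap advances ``axial_rise_nm`` per subunit and
    carries ``subunits_per_turn`` subunits per 360 degrees, so its pitch is
    ``axial_rise_nm * subunits_per_turn`` and adjacent wraps are separated
    axially by pitch / n_starts.
    """

    n_starts: int = 4
    tube_radius_nm: float = 6.0
    axial_rise_nm: float = 1.65
    subunits_per_turn: float = 11.0
    coated_fraction_per_side: float = 1.0 / 3.0
    subunit_template: BeadModel = field(default_factory=_default_subunit)

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not (0.0 <= self.coated_fraction_per_side <= 0.5):
            raise ValueError("coated_fraction_per_side must be in [0, 0.5]")
        if not self.tube_radius_nm > 0:
            raise ValueError("tube_radius_nm must be positive")

    @property
    def pitch_nm(self) -> float:
        return self.axial_rise_nm * self.subunits_per_turn

    @property
    def subunit_radius_nm(self) -> float:
        return float(np.max(self.subunit_template.radii_nm))


@dataclass
class TetherSpec:
    """Truncated-normal tether length distribution (nm) and surface density."""

    mean_nm: float = 19.8
    sd_nm: float = 4.2
    max_nm: float = 26.4
    density_per_turn: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.mean_nm <= self.max_nm):
            raise ValueError("need 0 < mean_nm <= max_nm")
        if self.sd_nm < 0:
            raise ValueError("sd_nm must be >= 0")


@dataclass
class PhantomSpec:
    """Full generative description of one plasmodesma phantom."""

    condition: str = "wt_proto"
    box_voxels: tuple[int, int, int] = (128, 128, 128)
    voxel_size_nm: float = DEFAULT_VOXEL_NM
    wall_thickness_nm: float = 50.0
    pd_length_nm: float = 50.0
    aperture_diameter_nm: float = 38.0
    desmotubule_neck_diameter_nm: float = 24.1
    desmotubule_central_diameter_nm: float = 10.5
    membrane_leaflet_separation_nm: float = 3.5
    coat: CoatSpec = field(default_factory=CoatSpec)
    tethers: TetherSpec = field(default_factory=TetherSpec)
    sealed: tuple[bool, bool] | float = (False, False)
    amplitudes: dict = field(
        default_factory=lambda: {"wall": 0.4, "membrane": 1.0, "protein": 1.0}
    )
    noise_snr: float = 3.0
    tilt_range_deg: tuple[float, float] = (-60.0, 60.0)
    tilt_increment_deg: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "wall_thickness_nm",
            "pd_length_nm",
            "aperture_diameter_nm",
            "desmotubule_neck_diameter_nm",
            "desmotubule_central_diameter_nm",
            "membrane_leaflet_separation_nm",
            "voxel_size_nm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.condition not in ("wt_proto", "wt_gameto", "aba_proto", "ghl17_proto"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if max(self.desmotubule_neck_diameter_nm, self.desmotubule_central_diameter_nm) >= self.aperture_diameter_nm:
            raise ValueError("desmotubule diameter must be smaller than the aperture diameter")

    def box_extent_nm(self) -> np.ndarray:
        return np.array(self.box_voxels) * self.voxel_size_nm

    def resolve_sealed(self, rng: np.random.Generator) -> tuple[bool, bool]:
        if isinstance(self.sealed, (tuple, list)):
            return bool(self.sealed[0]), bool(self.sealed[1])
        p = float(self.sealed)
        return bool(rng.random() < p), bool(rng.random() < p)

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["coat"]["subunit_template"] = {
            "positions_nm": np.asarray(self.coat.subunit_template.positions_nm).tolist(),
            "weights": np.asarray(self.coat.subunit_template.weights).tolist(),
            "radii_nm": np.asarray(self.coat.subunit_template.radii_nm).tolist(),
            "label": self.coat.subunit_template.label,
        }
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "coat" in d and isinstance(d["coat"], dict):
            coat = dict(d["coat"])
            if isinstance(coat.get("subunit_template"), dict):
                coat["subunit_template"] = BeadModel(**coat["subunit_template"])
            d["coat"] = CoatSpec(**coat)
        if "tethers" in d and isinstance(d["tethers"], dict):
            d["tethers"] = TetherSpec(**d["tethers"])
        for key in ("box_voxels", "tilt_range_deg"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if isinstance(d.get("sealed"), list):
            d["sealed"] = tuple(d["sealed"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Exact geometry emitted with a phantom."""

    axis_polyline: np.ndarray  # (N, 3) nm, ordered along +z
    subunits: list  # of (position (3,), euler_deg (3,))
    tether_segments: list  # of (start (3,), end (3,))
    aperture_state: tuple[str, str]  # per side, 'connected' | 'sealed'
    station_diameters: dict  # {'neck1': nm, 'centre': nm, 'neck2': nm}
    station_z_nm: dict  # axial position of each station
    wall_bounds_nm: tuple[float, float]
    coat_intervals_nm: list  # axial [lo, hi] ranges that are coated
    coat_radius_nm: float = 0.0
    coat_n_starts: int = 0
    coat_pitch_nm: float = 0.0
    coat_rise_nm: float = 0.0
    pm_midline_radius_nm: float = 0.0

    def tether_spans_nm(self) -> np.ndarray:
        return np.array(
            [np.linalg.norm(np.asarray(e) - np.asarray(s)) for s, e in self.tether_segments]
        )

    def write(self, outdir: str, prefix: str = "gt") -> None:
        """TSV tables (subunits, tethers, stations) plus a JSON summary."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"{prefix}_subunits.tsv", "w") as fh:
            fh.write("x_nm\ty_nm\tz_nm\tphi_deg\ttheta_deg\tpsi_deg\n")
            for p, e in self.subunits:
                fh.write("\t".join(f"{v:.4f}" for v in (*p, *e)) + "\n")
        with open(out / f"{prefix}_tethers.tsv", "w") as fh:
            fh.write("x0_nm\ty0_nm\tz0_nm\tx1_nm\ty1_nm\tz1_nm\tspan_nm\n")
            for s, e in self.tether_segments:
                span = float(np.linalg.norm(np.asarray(e) - np.asarray(s)))
                fh.write("\t".join(f"{v:.4f}" for v in (*s, *e, span)) + "\n")
        with open(out / f"{prefix}_stations.tsv", "w") as fh:
            fh.write("station\tz_nm\tdiameter_nm\n")
            for k in ("neck1", "centre", "neck2"):
                fh.write(f"{k}\t{self.station_z_nm[k]:.4f}\t{self.station_diameters[k]:.4f}\n")
        summary = {
            "axis_polyline": np.asarray(self.axis_polyline).tolist(),
            "aperture_state": list(self.aperture_state),
            "wall_bounds_nm": list(self.wall_bounds_nm),
            "coat_intervals_nm": [list(iv) for iv in self.coat_intervals_nm],
            "coat_radius_nm": self.coat_radius_nm,
            "coat_n_starts": self.coat_n_starts,
            "coat_pitch_nm": self.coat_pitch_nm,
            "coat_rise_nm": self.coat_rise_nm,
            "pm_midline_radius_nm": self.pm_midline_radius_nm,
            "station_z_nm": {k: float(v) for k, v in self.station_z_nm.items()},
            "station_diameters_nm": {k: float(v) for k, v in self.station_diameters.items()},
            "n_subunits": len(self.subunits),
            "n_tethers": len(self.tether_segments),
        }
        with open(out / f"{prefix}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)

    @classmethod
    def read(cls, outdir: str, prefix: str = "gt") -> "GroundTruth":
        """Load ground truth written by :meth:`write`."""
        import pandas as pd

        out = Path(outdir)
        with open(out / f"{prefix}_summary.json") as fh:
            s = json.load(fh)
        sub = pd.read_csv(out / f"{prefix}_subunits.tsv", sep="\t")
        subunits = [
            (np.array([r.x_nm, r.y_nm, r.z_nm]), (r.phi_deg, r.theta_deg, r.psi_deg))
            for r in sub.itertuples()
        ]
        teth = pd.read_csv(out / f"{prefix}_tethers.tsv", sep="\t")
        tethers = [
            (np.array([r.x0_nm, r.y0_nm, r.z0_nm]), np.array([r.x1_nm, r.y1_nm, r.z1_nm]))
            for r in teth.itertuples()
        ]
        return cls(
            axis_polyline=np.array(s["axis_polyline"]),
            subunits=subunits,
            tether_segments=tethers,
            aperture_state=tuple(s["aperture_state"]),
            station_diameters=s["station_diameters_nm"],
            station_z_nm=s["station_z_nm"],
            wall_bounds_nm=tuple(s["wall_bounds_nm"]),
            coat_intervals_nm=s["coat_intervals_nm"],
            coat_radius_nm=s["coat_radius_nm"],
            coat_n_starts=s["coat_n_starts"],
            coat_pitch_nm=s["coat_pitch_nm"],
            coat_rise_nm=s["coat_rise_nm"],
            pm_midline_radius_nm=s["pm_midline_radius_nm"],
        )


# ---------------------------------------------------------------------------
# presets: generator parameters for the four imaged conditions
# ---------------------------------------------------------------------------

def _coat(radius: float, frac: float) -> CoatSpec:
    return CoatSpec(tube_radius_nm=radius, coated_fraction_per_side=frac)


PRESETS: dict = {
    # DT wider at necks (24.1 nm), narrow centre (10.5 nm); coats cover ~the
    # first third of the DT from each aperture.  Coat subunit centres sit
    # ~2 nm above the outer DT leaflet so the assembly reads as a distinct
    # layer, as it does in the averages.
    "wt_proto": dict(
        condition="wt_proto",
        wall_thickness_nm=50.0,
        pd_length_nm=50.0,
        aperture_diameter_nm=42.0,
        desmotubule_neck_diameter_nm=24.1,
        desmotubule_central_diameter_nm=10.5,
        coat=_coat(radius=16.0, frac=1.0 / 3.0),
    ),
    # uniformly wide DT (24.5 nm), single continuous coat over the whole PD
    "wt_gameto": dict(
        condition="wt_gameto",
        wall_thickness_nm=60.0,
        pd_length_nm=60.0,
        aperture_diameter_nm=44.0,
        desmotubule_neck_diameter_nm=24.5,
        desmotubule_central_diameter_nm=24.5,
        coat=_coat(radius=16.0, frac=0.5),
    ),
    # constricted necks; a fraction of apertures fully sealed by callose
    "aba_proto": dict(
        condition="aba_proto",
        wall_thickness_nm=50.0,
        pd_length_nm=50.0,
        aperture_diameter_nm=38.0,
        desmotubule_neck_diameter_nm=22.0,
        desmotubule_central_diameter_nm=10.5,
        coat=_coat(radius=14.8, frac=1.0 / 3.0),
        sealed=15.0 / 33.0,
    ),
    # shorter, wider channels; wide coat-free central DT; tethers resolvable
    "ghl17_proto": dict(
        condition="ghl17_proto",
        wall_thickness_nm=40.0,
        pd_length_nm=40.0,
        aperture_diameter_nm=58.0,
        desmotubule_neck_diameter_nm=24.0,
        desmotubule_central_diameter_nm=16.0,
        coat=_coat(radius=16.0, frac=1.0 / 3.0),
    ),
}


def preset(condition: str, **overrides) -> PhantomSpec:
    """PhantomSpec for one of the four imaged conditions, with overrides."""
    if condition not in PRESETS:
        raise ValueError(f"unknown condition {condition!r}")
    kw = dict(PRESETS[condition])
    kw.update(overrides)
    return PhantomSpec(**kw)


# ---------------------------------------------------------------------------
# helical lattice
# ---------------------------------------------------------------------------

def _axis_arclength(axis: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(axis, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _axis_frame(axis: np.ndarray, s: float, arclen: np.ndarray):
    """Point, tangent and a transported normal at arc length s."""
    s = np.clip(s, 0.0, arclen[-1])
    i = int(np.searchsorted(arclen, s, side="right") - 1)
    i = min(i, len(axis) - 2)
    seg = axis[i + 1] - axis[i]
    t = seg / np.linalg.norm(seg)
    frac = (s - arclen[i]) / max(np.linalg.norm(seg), 1e-12)
    p = axis[i] + frac * seg
    # reference normal: any unit vector perpendicular to t
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n = a - t * (a @ t)
    n /= np.linalg.norm(n)
    return p, t, n


def helical_lattice_points(
    coat: CoatSpec,
    axis: np.ndarray,
    coated_intervals: list[tuple[float, float]],
    phase_deg: float = 0.0,
) -> list[tuple[np.ndarray, tuple[float, float, float]]]:
    """Subunit (position, euler) sites of a multi-start helix along an axis.

    Each of the ``n_starts`` wraps is an independent helix, phase-offset by
    360/n_starts degrees.  ``coated_intervals`` are half-open arc-length
    ranges ``[lo, hi)`` along the axis polyline.  Site orientations have
    their z axis radial (outward) and their x axis tangent to the helix.
    """
    from .euler import euler_from_matrix

    axis = np.atleast_2d(np.asarray(axis, dtype=float))
    if len(axis) < 2:
        raise ValueError("axis needs at least 2 points")
    if coat.axial_rise_nm <= 0:
        raise ValueError("axial rise must be positive")
    arclen = _axis_arclength(axis)
    total = arclen[-1]
    sites = []
    for lo, hi in coated_intervals:
        if hi <= lo:
            continue
        if lo < -1e-9 or hi > total + 1e-9:
            raise ValueError("coated interval outside axis extent")
        n_sub = int(np.floor((hi - lo) / coat.axial_rise_nm - 1e-9)) + 1
        for w in range(coat.n_starts):
            wrap_phase = phase_deg + 360.0 * w / coat.n_starts
            for j in range(n_sub):
                s = lo + j * coat.axial_rise_nm
                if s >= hi - 1e-9:
                    continue
                p, t, n0 = _axis_frame(axis, s, arclen)
                az = np.radians(wrap_phase + 360.0 * (s - lo) / coat.pitch_nm)
                b0 = np.cross(t, n0)
                radial = np.cos(az) * n0 + np.sin(az) * b0
                pos = p + coat.tube_radius_nm * radial
                # helix tangent: axial advance rise per angular step
                azdir = np.cos(az) * b0 - np.sin(az) * n0
                dz = coat.pitch_nm / (2 * np.pi * coat.tube_radius_nm)
                tan = t * dz + azdir
                tan /= np.linalg.norm(tan)
                ez = radial
                ex = tan - ez * (tan @ ez)
                ex /= np.linalg.norm(ex)
                ey = np.cross(ez, ex)
                mat = np.column_stack([ex, ey, ez])
                sites.append((pos, euler_from_matrix(mat)))
    return sites


# ---------------------------------------------------------------------------
# density rendering
# ---------------------------------------------------------------------------

def _splat_gaussian(data: np.ndarray, vol: Volume, centre_nm, sigma_nm: float, amp: float) -> None:
    """Add amp * exp(-|x-c|^2 / 2 sigma^2) within a 3.5-sigma patch."""
    vs = vol.voxel_size_nm
    c = vol.nm_to_voxel(centre_nm)
    half = max(int(np.ceil(3.5 * sigma_nm / vs)), 2)
    lo = np.maximum(np.round(c).astype(int) - half, 0)
    hi = np.minimum(np.round(c).astype(int) + half + 1, data.shape)
    if np.any(lo >= hi):
        return
    ix = np.arange(lo[0], hi[0])[:, None, None]
    iy = np.arange(lo[1], hi[1])[None, :, None]
    iz = np.arange(lo[2], hi[2])[None, None, :]
    d2 = (ix - c[0]) ** 2 + (iy - c[1]) ** 2 + (iz - c[2]) ** 2
    data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(
        -d2 * vs**2 / (2.0 * sigma_nm**2)
    )


def _smoothstep(x: np.ndarray, edge_nm: float = 0.8) -> np.ndarray:
    """0 -> 1 logistic ramp with ~edge_nm transition width."""
    return 1.0 / (1.0 + np.exp(np.clip(-4.0 * x / edge_nm, -60, 60)))


def build_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Render the noise-free phantom density and its ground truth.

    Identical (spec, seed) gives bit-identical output; the geometry skeleton
    (wall, membranes, coat lattice) is deterministic and only tether draws,
    sealed-state draws and plug texture use the RNG.
    """
    rng = np.random.default_rng(spec.seed)
    vs = spec.voxel_size_nm
    shape = tuple(int(v) for v in spec.box_voxels)
    extent = np.array(shape) * vs
    if spec.pd_length_nm + 2 * PM_WALL_CLEARANCE_NM + 8 > extent[2]:
        raise ValueError("box too small to contain pd_length plus cytoplasm")
    if abs(spec.pd_length_nm - spec.wall_thickness_nm) > 1e-9:
        raise ValueError("pd_length_nm must equal wall_thickness_nm (slab construction)")

    vol = Volume(np.zeros(shape, dtype=np.float32), voxel_size_nm=vs)
    data = vol.data
    amp = spec.amplitudes
    sep2 = spec.membrane_leaflet_separation_nm / 2.0
    sig = MEMBRANE_SIGMA_NM

    cx, cy, cz = vol.centre_nm()
    z_lo, z_hi = cz - spec.pd_length_nm / 2.0, cz + spec.pd_length_nm / 2.0
    r_pm = spec.aperture_diameter_nm / 2.0

    x = (np.arange(shape[0], dtype=np.float32) * vs)[:, None, None]
    y = (np.arange(shape[1], dtype=np.float32) * vs)[None, :, None]
    z = (np.arange(shape[2], dtype=np.float32) * vs)[None, None, :]
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)

    # -- sealed state -------------------------------------------------------
    sealed = spec.resolve_sealed(rng)
    plug_in = 0.2 * spec.pd_length_nm  # plug reach into the pore from the aperture

    # -- desmotubule radius profile ----------------------------------------
    st_z = {
        "neck1": z_lo + 0.1 * spec.pd_length_nm,
        "centre": cz,
        "neck2": z_hi - 0.1 * spec.pd_length_nm,
    }
    # linear neck -> centre -> neck interpolation with 2-nm plateaus at the
    # stations (so station diameters are exact and locally flat); constant
    # neck value from the stations out to the apertures and beyond
    w_st = 2.0
    rn = spec.desmotubule_neck_diameter_nm / 2.0
    rc = spec.desmotubule_central_diameter_nm / 2.0
    knots_z = np.array(
        [st_z["neck1"] + w_st, st_z["centre"] - w_st, st_z["centre"] + w_st, st_z["neck2"] - w_st]
    )
    knots_r = np.array([rn, rc, rc, rn])
    if knots_z[0] >= knots_z[1]:  # short pore: no room for ramps
        knots_z = np.array([st_z["neck1"], st_z["centre"], st_z["neck2"]])
        knots_r = np.array([rn, rc, rn])
    z1d = z.ravel()
    rdt = np.interp(z1d, knots_z, knots_r)[None, None, :]

    dt_shell = np.exp(-((np.abs(r - rdt) - sep2) ** 2) / (2 * sig**2))
    # truncate DT on sealed sides: membrane ends cytoplasm-proximal to the plug
    dt_taper = np.ones_like(z1d)
    if sealed[0]:
        dt_taper *= _smoothstep(z1d - (z_lo + plug_in + 3.0))
    if sealed[1]:
        dt_taper *= _smoothstep((z_hi - plug_in - 3.0) - z1d)
    dt = amp["membrane"] * dt_shell * dt_taper[None, None, :]

    # -- plasma membrane ----------------------------------------------------
    z_face_lo, z_face_hi = z_lo - PM_WALL_CLEARANCE_NM, z_hi + PM_WALL_CLEARANCE_NM
    # distance to the finite PM cylinder patch (r = r_pm, z in faces range)
    dz_cyl = np.maximum(np.maximum(z_face_lo - z, z - z_face_hi), 0.0)
    d_cyl = np.sqrt((r - r_pm) ** 2 + dz_cyl**2)
    cyl_shell = np.exp(-((d_cyl - sep2) ** 2) / (2 * sig**2))
    cyl_taper = np.ones_like(z1d)
    if sealed[0]:
        cyl_taper *= _smoothstep(z1d - (z_lo + plug_in + 3.0))
    if sealed[1]:
        cyl_taper *= _smoothstep((z_hi - plug_in - 3.0) - z1d)
    pm = cyl_shell * cyl_taper[None, None, :]
    # face planes (annulus r >= r_pm); on sealed sides terminated outside the plug rim
    for z_face, is_sealed in ((z_face_lo, sealed[0]), (z_face_hi, sealed[1])):
        r_inner = r_pm + (2.5 if is_sealed else 0.0)
        d_pl = np.sqrt((z - z_face) ** 2 + np.maximum(r_inner - r, 0.0) ** 2)
        pm += np.exp(-((d_pl - sep2) ** 2) / (2 * sig**2))
    pm = amp["membrane"] * np.minimum(pm, 1.0)

    # -- cell wall ----------------------------------------------------------
    wall_mask = (
        _smoothstep(r - (r_pm + PM_WALL_CLEARANCE_NM))
        * _smoothstep(z - z_lo)
        * _smoothstep(z_hi - z)
    )
    wall = amp["wall"] * wall_mask

    data += (dt + pm + wall).astype(np.float32)
    del dt, pm, wall, dt_shell, cyl_shell

    # -- coat lattice --------------------------------------------------------
    axis = np.array([[cx, cy, 0.0], [cx, cy, extent[2]]])
    frac_len = spec.coat.coated_fraction_per_side * spec.pd_length_nm
    intervals = [(z_lo, min(z_lo + frac_len, z_hi)), (max(z_hi - frac_len, z_lo), z_hi)]
    if intervals[0][1] >= intervals[1][0]:  # merged single coat (gametophores)
        intervals = [(z_lo, z_hi)]
    # sealed sides lose the aperture-proximal part of the coat
    adj = []
    for lo, hi in intervals:
        if sealed[0]:
            lo = max(lo, z_lo + plug_in + 4.0)
        if sealed[1]:
            hi = min(hi, z_hi - plug_in - 4.0)
        if hi > lo:
            adj.append((lo, hi))
    intervals = adj
    # fixed lattice phase: the geometry skeleton is deterministic; only
    # tether draws, sealed-state draws and plug texture consume the RNG
    sites = helical_lattice_points(spec.coat, axis, intervals, phase_deg=0.0)
    from .euler import rotation_matrix

    for pos, eul in sites:
        mat = rotation_matrix(*eul)
        for bpos, bw, brad in zip(
            spec.coat.subunit_template.positions_nm,
            spec.coat.subunit_template.weights,
            spec.coat.subunit_template.radii_nm,
        ):
            _splat_gaussian(data, vol, pos + mat @ bpos, brad, amp["protein"] * bw)

    # -- tethers -------------------------------------------------------------
    r_start = spec.coat.tube_radius_nm + spec.coat.subunit_radius_nm
    gap = r_pm - r_start
    tether_segments: list = []
    if gap <= 0:
        raise ValueError("PM midline must lie outside the coat surface")
    if gap < spec.tethers.max_nm:  # tethers only renderable if they can span
        lo_trunc = max(gap + 0.05, 1e-3)
        a = (lo_trunc - spec.tethers.mean_nm) / max(spec.tethers.sd_nm, 1e-9)
        b = (spec.tethers.max_nm - spec.tethers.mean_nm) / max(spec.tethers.sd_nm, 1e-9)
        for lo, hi in intervals:
            n_turns = (hi - lo) / spec.coat.pitch_nm
            n_teth = int(round(spec.tethers.density_per_turn * n_turns))
            if n_teth == 0:
                continue
            zs = rng.uniform(lo + 1.0, hi - 1.0, size=n_teth)
            azs = rng.uniform(0, 2 * np.pi, size=n_teth)
            lens = stats.truncnorm.rvs(
                a, b, loc=spec.tethers.mean_nm, scale=spec.tethers.sd_nm,
                size=n_teth, random_state=rng,
            )
            fracs = rng.uniform(0, 1, size=n_teth)
            signs = rng.choice([-1.0, 1.0], size=n_teth)
            for zt, az, ln, f, sn in zip(zs, azs, lens, fracs, signs):
                start = np.array(
                    [cx + r_start * np.cos(az), cy + r_start * np.sin(az), zt]
                )
                h2 = ln**2 - gap**2
                dzt = sn * np.sqrt(f * h2)
                if not (z_face_lo + 2 < zt + dzt < z_face_hi - 2):
                    dzt = -dzt
                cosb = (r_start**2 + r_pm**2 - (ln**2 - dzt**2)) / (2 * r_start * r_pm)
                beta = np.arccos(np.clip(cosb, -1.0, 1.0)) * sn
                end = np.array(
                    [cx + r_pm * np.cos(az + beta), cy + r_pm * np.sin(az + beta), zt + dzt]
                )
                tether_segments.append((start, end))
                # rod density terminates membrane-proximal (3 nm inside the PM
                # midline) so the tether does not blend into the leaflets
                n_samp = max(int(np.ceil(ln / 0.7)), 2)
                for tfrac in np.linspace(0, 1, n_samp):
                    pt = start + tfrac * (end - start)
                    if np.hypot(pt[0] - cx, pt[1] - cy) >= r_pm - 3.0:
                        continue
                    _splat_gaussian(
                        data, vol, pt, 0.8,
                        0.5 * amp["protein"] / max(n_samp / (ln / 0.7), 1.0),
                    )

    # -- callose plugs --------------------------------------------------------
    for side, is_sealed in enumerate(sealed):
        if not is_sealed:
            continue
        if side == 0:
            z0, z1 = z_face_lo - 2.0, z_lo + plug_in
        else:
            z0, z1 = z_hi - plug_in, z_face_hi + 2.0
        n_gran = int(40 * (z1 - z0))  # granulated texture, cosmetic
        gz = rng.uniform(z0, z1, size=n_gran)
        grr = (r_pm + 2.0) * np.sqrt(rng.uniform(0, 1, size=n_gran))
        gaz = rng.uniform(0, 2 * np.pi, size=n_gran)
        for zg, rg, ag in zip(gz, grr, gaz):
            _splat_gaussian(
                data, vol,
                np.array([cx + rg * np.cos(ag), cy + rg * np.sin(ag), zg]),
                1.1, 0.5 * amp["wall"],
            )

    gt = GroundTruth(
        axis_polyline=axis,
        subunits=sites,
        tether_segments=tether_segments,
        aperture_state=tuple("sealed" if s else "connected" for s in sealed),
        station_diameters={
            "neck1": spec.desmotubule_neck_diameter_nm,
            "centre": spec.desmotubule_central_diameter_nm,
            "neck2": spec.desmotubule_neck_diameter_nm,
        },
        station_z_nm=st_z,
        wall_bounds_nm=(z_lo, z_hi),
        coat_intervals_nm=[list(iv) for iv in intervals],
        coat_radius_nm=spec.coat.tube_radius_nm,
        coat_n_starts=spec.coat.n_starts,
        coat_pitch_nm=spec.coat.pitch_nm,
        coat_rise_nm=spec.coat.axial_rise_nm,
        pm_midline_radius_nm=r_pm,
    )
    return vol, gt


# ---------------------------------------------------------------------------
# imaging model
# ---------------------------------------------------------------------------

def apply_imaging_model(
    vol: Volume,
    tilt_range_deg: tuple[float, float] = (-60.0, 60.0),
    increment_deg: float = 3.0,
    snr: float = np.inf,
    seed: int = 0,
) -> Volume:
    """Single-axis missing wedge plus white noise at a target power SNR.

    Fourier coefficients inside the missing wedge are zeroed; Gaussian white
    noise, band-limited to the retained region, is scaled so that
    signal power / noise power = ``snr`` there.  ``snr = inf`` with a full
    (-90, 90) tilt range is the identity.  The tilt increment is accepted
    for provenance; at these box sizes the tilt sampling is effectively
    continuous and only the wedge bounds shape the transfer function.
    """
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("non-finite input density")
    tmin, tmax = tilt_range_deg
    full_range = tmin <= -90.0 + 1e-9 and tmax >= 90.0 - 1e-9
    if full_range and np.isinf(snr):
        return vol.copy()
    data = vol.data.astype(np.float64)
    if full_range:
        filtered = data
        mask = None
    else:
        mask = wedge_mask_array(data.shape, tmin, tmax)
        F = np.fft.fftn(data)
        F[~mask] = 0.0
        filtered = np.fft.ifftn(F).real
    if np.isinf(snr):
        out = filtered
    else:
        if snr <= 0:
            raise ValueError("snr must be positive or infinite")
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(data.shape)
        if mask is not None:
            N = np.fft.fftn(noise)
            N[~mask] = 0.0
            noise = np.fft.ifftn(N).real
        p_sig = filtered.var()
        p_noise = noise.var()
        out = filtered + noise * np.sqrt(p_sig / (snr * p_noise))
    return Volume(out.astype(np.float32), vol.voxel_size_nm, vol.origin_nm.copy())


def simulate_tomogram(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """build_phantom followed by the PhantomSpec's imaging settings (wedge + noise)."""
    vol, gt = build_phantom(spec)
    tomo = apply_imaging_model(
        vol,
        tilt_range_deg=spec.tilt_range_deg,
        increment_deg=spec.tilt_increment_deg,
        snr=spec.noise_snr,
        seed=spec.seed + 7_000_003,
    )
    return tomo, gt
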