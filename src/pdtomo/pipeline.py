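"""End-to-end orchestration: phantom → picking → two-stage averaging →
lattice report → morphometry → statistics, with a checksummed run manifest.

Stage order: simulate, seed, extract(64), align1, expand, extract(48),
align2, distance filter, average, FSC on half-sets, lattice analysis,
morphometry, group statistics, optional model fitting.  Identical config
and master seed give identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import geometry, lattice, morpho, phantom, stavg
from .config import PipelineConfig
from .volume import Volume, write_mrc

__all__ = ["run_pipeline", "StageFailure"]

logger = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "artifacts": {}, "config_seed": config.master_seed}
    rng_master = np.random.default_rng(config.master_seed)
    stage_seeds = {
        name: int(rng_master.integers(0, 2**31 - 1))
        for name in ("phantom", "orientations")
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    def run_stage(name: str, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:  # manifest records the failure, artifacts kept
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=1)
            raise StageFailure(name, exc) from exc
        manifest["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
        logger.info("stage %s done in %.1f s", name, time.time() - t0)
        return result

    # ---------------------------------------------------------------- simulate
    def do_simulate():
        tomos = []
        for i, ph in enumerate(config.phantoms):
            ph = dict(ph)
            cond = ph.pop("condition", "wt_proto")
            seed = ph.pop("seed", stage_seeds["phantom"] + i)
            spec = phantom.preset(cond, seed=seed, **ph)
            vol, gt = phantom.simulate_tomogram(spec)
            if config.invert_contrast:
                vol = Volume(-vol.data, vol.voxel_size_nm, vol.origin_nm)
            p = out / f"tomo_{i:02d}_{cond}.mrc"
            write_mrc(vol, p)
            record(f"tomo_{i:02d}", p)
            gt.write(out, prefix=f"gt_{i:02d}")
            record(f"gt_{i:02d}_summary", out / f"gt_{i:02d}_summary.json")
            tomos.append((spec, vol, gt))
        return tomos

    tomos = run_stage("simulate", do_simulate)
    # averaging runs on the first phantom; morphometry uses all
    spec0, vol0, gt0 = tomos[0]
    wedge = stavg.WedgeDescriptor(*spec0.tilt_range_deg)
    vs = spec0.voxel_size_nm
    gcfg, acfg = config.geometry, config.alignment

    # ---------------------------------------------------------------- seed
    def do_seed():
        cx, cy = gt0.axis_polyline[0][:2]
        intervals = gt0.coat_intervals_nm
        if gcfg.contours == "first":  # one contour per coating assembly
            intervals = intervals[:1]
        contours = [
            geometry.Contour(
                [[cx, cy, iv[0]], [cx, cy, iv[1]]], label=f"coat{j}"
            )
            for j, iv in enumerate(intervals)
        ]
        parts = []
        for j, c in enumerate(contours):
            ps = geometry.seed_particles(
                c, gcfg.interval_nm, seed=stage_seeds["orientations"] + j
            )
            ps.table["seed_id"] += 1000 * j
            ps.table["particle_id"] += 100000 * j
            parts.append(ps.table)
        import pandas as pd

        seeded = geometry.ParticleSet(pd.concat(parts, ignore_index=True), "seeded")
        p = out / "particles_seeded.star"
        seeded.to_star(p)
        record("particles_seeded", p)
        return seeded

    seeded = run_stage("seed", do_seed)

    # ---------------------------------------------------------------- align1
    def do_align1():
        stack, kept = geometry.extract_subvolumes(vol0, seeded, gcfg.box_seeded)
        constraints = stavg.AlignmentConstraints(
            max_shift_nm=acfg.max_shift_stage1_nm, lowpass_nm=acfg.lowpass_nm
        )
        aligned1, avg1 = stavg.constrained_align(
            stack, kept, wedge, constraints, n_iter=acfg.n_iter, voxel_size_nm=vs
        )
        write_mrc(avg1, out / "average_stage1.mrc")
        record("average_stage1", out / "average_stage1.mrc")
        p = out / "particles_aligned1.star"
        aligned1.to_star(p)
        record("particles_aligned1", p)
        return aligned1

    aligned1 = run_stage("align1", do_align1)

    # ---------------------------------------------------------------- expand
    def do_expand():
        radius = gcfg.expansion_radius_nm
        if radius == "auto":
            radius = gt0.coat_radius_nm
        expanded = geometry.expand_on_tube(aligned1, float(radius), gcfg.expansion_positions)
        p = out / "particles_expanded.star"
        expanded.to_star(p)
        record("particles_expanded", p)
        return expanded

    expanded = run_stage("expand", do_expand)

    # ---------------------------------------------------------------- align2
    def do_align2():
        stack, kept = geometry.extract_subvolumes(vol0, expanded, gcfg.box_expanded)
        extract_pos = kept.positions.copy()
        radius = gcfg.expansion_radius_nm
        if radius == "auto":
            radius = gt0.coat_radius_nm
        # register lock-in: exhaustive translational search along the tubule
        # surface with orientations held at their geometry-derived values
        # (grid-quantized angular search displaces the patch by more than
        # half a lattice period at these radii; see docs/methods.md)
        locked, avg2 = stavg.lock_lattice_register(
            stack, kept, wedge, float(radius),
            voxel_size_nm=vs,
            n_iter=acfg.lock_iterations,
            max_shift_nm=acfg.lock_max_shift_nm,
            anchor_seed=config.master_seed,
        )
        aligned2 = geometry.ParticleSet(locked.table.assign(stage="aligned2"), "aligned2")
        p = out / "particles_aligned2.star"
        aligned2.to_star(p)
        record("particles_aligned2", p)
        write_mrc(avg2, out / "average_stage2.mrc")
        record("average_stage2", out / "average_stage2.mrc")
        return stack, extract_pos, aligned2, avg2

    stack2, extract_pos2, aligned2, avg_stage2 = run_stage("align2", do_align2)

    # ---------------------------------------------------------------- filter
    def do_filter():
        filtered = geometry.distance_filter(aligned2, gcfg.min_distance_nm)
        p = out / "particles_filtered.star"
        filtered.to_star(p)
        record("particles_filtered", p)
        return filtered

    filtered = run_stage("filter", do_filter)
    id_to_row = {pid: i for i, pid in enumerate(aligned2.table["particle_id"])}
    keep_idx = np.array([id_to_row[pid] for pid in filtered.table["particle_id"]])

    # ---------------------------------------------------------------- average
    def do_average():
        avg = stavg.average_particles(
            stack2[keep_idx], filtered, wedge,
            voxel_size_nm=vs, extract_positions_nm=extract_pos2[keep_idx],
        )
        write_mrc(avg, out / "average_final.mrc")
        record("average_final", out / "average_final.mrc")
        return avg

    avg_final = run_stage("average", do_average)

    # ---------------------------------------------------------------- fsc
    def do_fsc():
        import pandas as pd

        halves = []
        for parity in (0, 1):
            sel = np.arange(len(filtered))[parity::2]
            if len(sel) == 0:
                raise ValueError("too few particles for half-set FSC")
            sub = geometry.ParticleSet(
                filtered.table.iloc[sel].reset_index(drop=True), "filtered"
            )
            halves.append(
                stavg.average_particles(
                    stack2[keep_idx][sel], sub, wedge,
                    voxel_size_nm=vs,
                    extract_positions_nm=extract_pos2[keep_idx][sel],
                )
            )
        curve = stavg.compute_fsc(halves[0], halves[1])
        res, reached = stavg.resolution_at_threshold(curve, acfg.fsc_threshold)
        curve.to_tsv(out / "fsc.tsv")
        record("fsc", out / "fsc.tsv")
        with open(out / "fsc_resolution.json", "w") as fh:
            json.dump({"resolution_nm": res, "threshold": acfg.fsc_threshold,
                       "reached": reached}, fh)
        record("fsc_resolution", out / "fsc_resolution.json")
        return res

    run_stage("fsc", do_fsc)

    # ---------------------------------------------------------------- lattice
    def do_lattice():
        radius = gcfg.expansion_radius_nm
        if radius == "auto":
            radius = gt0.coat_radius_nm
        # the register-locked stage-2 average pools every expanded particle;
        # the post-filter average (kept as the final map) has ~10x fewer
        centre = avg_stage2.centre_nm()
        axis_point = centre - np.array([0.0, 0.0, float(radius)])
        lcfg = config.lattice
        res, sheet = lattice.scan_radius(
            avg_stage2, axis_point, (1.0, 0.0, 0.0), float(radius),
            scan_nm=lcfg.radius_scan_nm,
            azimuth_step_deg=lcfg.azimuth_step_deg,
            axial_step_nm=lcfg.axial_step_nm,
            axial_range_nm=(-lcfg.axial_halfwidth_nm, lcfg.axial_halfwidth_nm),
            azimuth_range_deg=tuple(lcfg.azimuth_window_deg),
        )
        res.to_json(out / "lattice.json")
        record("lattice", out / "lattice.json")
        return res

    lattice_res = run_stage("lattice", do_lattice)

    # ---------------------------------------------------------------- measure
    def do_measure():
        records = []
        for i, (spec, vol, gt) in enumerate(tomos):
            rec = morpho.measure_profiles(vol, gt)
            rec.pd_id = f"pd_{i:02d}"
            rec.condition = spec.condition
            records.append(rec)
        df = morpho.records_to_dataframe(records)
        df.to_csv(out / "morphometry.tsv", sep="\t", index=False)
        record("morphometry", out / "morphometry.tsv")
        return records

    records = run_stage("measure", do_measure)

    # ---------------------------------------------------------------- stats
    def do_stats():
        conds = {r.condition for r in records}
        if len(conds) < 2 or "wt_proto" not in conds:
            return "skipped"
        import pandas as pd

        tables = []
        for measure in ("pd_length_nm", "neck_diameter_nm", "central_diameter_nm"):
            tables.append(morpho.summarize_groups(records, measure, "wt_proto"))
        stats_df = pd.concat(tables, ignore_index=True)
        stats_df.to_csv(out / "group_stats.tsv", sep="\t", index=False)
        record("group_stats", out / "group_stats.tsv")
        return "ok"

    stats_status = run_stage("stats", do_stats)
    if stats_status == "skipped":
        manifest["stages"]["stats"]["status"] = "skipped"

    # ---------------------------------------------------------------- fit
    if config.fit is None:
        manifest["stages"]["fit"] = {"status": "skipped"}
    else:
        def do_fit():
            from . import fitmap
            from .beads import read_beads_pdb

            unit = read_beads_pdb(config.fit.unit_pdb).centered()
            coat = spec0.coat
            axis = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, config.fit.n_per_wrap * coat.axial_rise_nm]])
            tiled = fitmap.tile_helical_model(unit, coat, axis, config.fit.n_per_wrap)
            fit = fitmap.rigid_fit(
                tiled, avg_final.normalized(), config.fit.resolution_nm,
                angular_step_deg=config.fit.angular_step_deg,
            )
            with open(out / "fit.json", "w") as fh:
                json.dump({
                    "score": fit.score, "flagged": fit.flagged,
                    "euler_deg": list(fit.transform.euler_deg),
                    "translation_nm": fit.transform.translation_nm.tolist(),
                }, fh, indent=1)
            record("fit", out / "fit.json")
            return fit

        run_stage("fit", do_fit)

    manifest["lattice_n_starts"] = int(lattice_res.n_starts)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
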