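"""Shared fixtures: measured phantom batches reused across test modules.

Batches are generated at the preset study conditions (SNR 3, +/-60 degree
wedge) and measured once per session; individual tests consume the records.
"""

from __future__ import annotations

import numpy as np
import pytest

from pdtomo import morpho, phantom


def _measure_batch(condition: str, seeds: range) -> list[morpho.MorphometryRecord]:
    records = []
    for s in seeds:
        tomo, gt = phantom.simulate_tomogram(phantom.preset(condition, seed=s))
        rec = morpho.measure_profiles(tomo, gt)
        rec.pd_id = f"{condition}_{s}"
        rec.condition = condition
        records.append(rec)
    return records


@pytest.fixture(scope="session")
def wt_records() -> list[morpho.MorphometryRecord]:
    """20 wild-type protonemata phantoms at SNR 3, measured."""
    return _measure_batch("wt_proto", range(1, 21))


@pytest.fixture(scope="session")
def ghl17_records() -> list[morpho.MorphometryRecord]:
    """20 glucanase-overexpressor phantoms at SNR 3, measured."""
    return _measure_batch("ghl17_proto", range(1, 21))


@pytest.fixture(scope="session")
def aba_sealed_batch() -> tuple[int, int, int]:
    """33 ABA-treated apertures generated with a planned 15/33 sealed split.

    Returns (n_detected_sealed, n_true_sealed, n_apertures) from the
    membrane-connectivity classifier.
    """
    rng = np.random.default_rng(0)
    plan = np.array([True] * 15 + [False] * 18)
    rng.shuffle(plan)
    n_det = 0
    n_eval = 0
    for i in range(17):
        s0 = bool(plan[2 * i])
        s1 = bool(plan[2 * i + 1]) if 2 * i + 1 < 33 else False
        spec = phantom.preset("aba_proto", seed=100 + i, sealed=(s0, s1))
        tomo, gt = phantom.simulate_tomogram(spec)
        for side in (0, 1):
            if 2 * i + side >= 33:
                break
            state = morpho.classify_aperture_state(
                tomo, side, gt.wall_bounds_nm, gt.pm_midline_radius_nm
            )
            n_eval += 1
            if state == "sealed":
                n_det += 1
    return n_det, int(plan.sum()), n_eval
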