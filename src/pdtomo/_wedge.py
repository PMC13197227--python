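"""Missing-wedge geometry shared by the imaging model and the averaging code.

Single-axis tomography about the y axis: at tilt t the measured Fourier
plane is the (x, y) plane rotated by t about y.  Sweeping t over
[tilt_min, tilt_max] fills the region of Fourier space where the angle of
(kx, kz) from the kx axis lies in the tilt range (plus its Friedel mate);
the remainder is the missing wedge.
"""

from __future__ import annotations

import numpy as np


def wedge_mask_array(
    shape: tuple[int, int, int],
    tilt_min_deg: float,
    tilt_max_deg: float,
) -> np.ndarray:
    """Boolean mask over the FFT grid (numpy fft ordering): True where sampled.

    Friedel-symmetric by construction; the DC term is always kept.
    """
    if not (-90.0 < tilt_min_deg < tilt_max_deg < 90.0):
        raise ValueError("tilt range must satisfy -90 < min < max < 90")
    if tilt_min_deg <= -89.95 and tilt_max_deg >= 89.95:
        return np.ones(shape, dtype=bool)  # continuum limit: nothing missing
    kx = np.fft.fftfreq(shape[0])[:, None]
    kz = np.fft.fftfreq(shape[2])[None, :]
    ang = np.degrees(np.arctan2(kz, kx))  # (-180, 180]
    hit = (
        ((ang >= tilt_min_deg) & (ang <= tilt_max_deg))
        | ((ang - 180.0 >= tilt_min_deg) & (ang - 180.0 <= tilt_max_deg))
        | ((ang + 180.0 >= tilt_min_deg) & (ang + 180.0 <= tilt_max_deg))
    )
    hit[0, 0] = True
    # enforce Friedel symmetry exactly (the Nyquist row of an even grid has
    # no positive-frequency partner and would otherwise break it for
    # asymmetric tilt ranges)
    hit |= np.roll(hit[::-1, ::-1], 1, axis=(0, 1))
    return np.broadcast_to(hit[:, None, :], shape).copy()
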