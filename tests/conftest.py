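import numpy as np
import pytest

import dopplerquant as dq
from dopplerquant.synthetic import LesionParams, VesselSpec


@pytest.fixture(scope="session")
def lut():
    return dq.build_lut(dq.default_lut())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def small_calibration():
    """A minimal valid calibration with a 4+4-entry colorbar."""
    entries = [((255, g, 0), v) for g, v in zip((0, 60, 120, 180), (1.0, 2.0, 3.0, 4.0))]
    entries += [((0, g, 255), -v) for g, v in zip((0, 60, 120, 180), (1.0, 2.0, 3.0, 4.0))]
    return dq.Calibration(pixel_spacing=0.01, frame_rate=15.0, lut=entries)


@pytest.fixture()
def tiny_cine():
    """A 2-frame 4x4 cine with a hand-painted perfused pixel."""
    cal = small_calibration()
    frames = np.full((2, 4, 4, 3), 100, dtype=np.uint8)
    frames[0, 1, 1] = (255, 60, 0)  # LUT entry for +2 cm/s
    roi = np.ones((4, 4), dtype=bool)
    return dq.CineSequence(frames=frames, calibration=cal, roi_mask=roi, case_id="tiny", label="unknown")


def noiseless_params(angle_deg=45.0, pulsatility=0.3, tfv=2.0, fraction=0.004,
                     peak=6.0, diameter=0.12, ri_pulsatility=None):
    return LesionParams(
        target_tfv=tfv,
        pulsatility=pulsatility,
        vascular_fraction=fraction,
        vessel_count=3,
        main_vessel=VesselSpec(peak, diameter, angle_deg),
        heart_rate=72.0,
        noise=0.0,
        vessel_pulsatility=ri_pulsatility if ri_pulsatility is not None else pulsatility,
    )


@pytest.fixture(scope="session")
def noiseless_case():
    seq = dq.synthesize_case(noiseless_params(), seed=7, case_id="nl", label="malignant")
    return seq


@pytest.fixture(scope="session")
def decoded_noiseless(noiseless_case):
    return dq.decode_sequence(noiseless_case)
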