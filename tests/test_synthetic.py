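"""Synthetic cine generator: waveform, determinism, calibration fidelity."""

import numpy as np
import pytest

import dopplerquant as dq
from dopplerquant.errors import FrameRateError, PerpendicularFlowError
from dopplerquant.synthetic import (
    CohortCalibration,
    make_waveform,
    waveform_peak_frames,
)

from conftest import noiseless_params


def test_waveform_pulsatility_one_is_constant():
    s = make_waveform(72.0, 15.0, 60, pulsatility=1.0)
    np.testing.assert_allclose(s, 1.0)


def test_waveform_pulsatility_zero_touches_zero_each_cycle():
    s = make_waveform(72.0, 15.0, 75, pulsatility=0.0)
    assert s.max() == pytest.approx(1.0)
    peaks = waveform_peak_frames(72.0, 15.0, 75)
    for a, b in zip(peaks, peaks[1:]):
        assert s[a:b].min() == 0.0  # diastolic no-flow in every cycle


def test_waveform_peaks_at_analytic_frames():
    s = make_waveform(72.0, 15.0, 75, pulsatility=0.2)
    peaks = waveform_peak_frames(72.0, 15.0, 75)
    assert len(peaks) == 6  # 72 bpm for 5 s
    # analytic peak frames sample near the systolic maximum and are spaced
    # by one cardiac period (12.5 frames at 72 bpm / 15 Hz)
    assert (s[peaks] >= 0.93).all()
    assert np.all(np.abs(np.diff(peaks) - 12.5) <= 0.5)


def test_waveform_range_is_pulsatility_to_one():
    s = make_waveform(100.0, 20.0, 80, pulsatility=0.35)
    assert s.min() == pytest.approx(0.35)
    assert s.max() == pytest.approx(1.0)


def test_unresolvable_frame_rate_rejected():
    with pytest.raises(FrameRateError, match="frame rate too low"):
        make_waveform(180.0, 5.0, 30, pulsatility=0.5)


def test_same_seed_gives_bit_identical_case():
    p = noiseless_params()
    a = dq.synthesize_case(p, seed=11, case_id="x", label="malignant")
    b = dq.synthesize_case(p, seed=11, case_id="x", label="malignant")
    np.testing.assert_array_equal(a.frames, b.frames)
    np.testing.assert_array_equal(a.roi_mask, b.roi_mask)
    assert a.truth.to_dict() == b.truth.to_dict()


def test_different_seeds_give_different_cases():
    p = noiseless_params()
    a = dq.synthesize_case(p, seed=11)
    b = dq.synthesize_case(p, seed=12)
    assert not np.array_equal(a.frames, b.frames)


def test_realized_vascular_fraction_matches_draw(noiseless_case, decoded_noiseless):
    """Decode-and-count oracle: the time-averaged perfused area fraction of
    the rendered case stays within 10% of the drawn vascular fraction."""
    tr = dq.perfusion_trace(decoded_noiseless)
    realized = (tr.area / tr.roi_area).mean()
    assert realized == pytest.approx(0.004, rel=0.10)


def test_horizontal_vessel_is_perpendicular_to_beam():
    p = noiseless_params(angle_deg=90.0)
    seq = dq.synthesize_case(p, seed=3)
    assert seq.truth.true_angle_deg == 90.0
    assert seq.truth.true_fv == 0.0  # no measurable single-vessel flow
    # the perpendicular vessel projects zero velocity onto the beam, so it
    # is invisible in the decoded cine
    v = dq.decode_sequence(seq)
    assert np.all(~np.isfinite(v.fields[:, seq.truth.vessel_mask]))


def test_perpendicular_segment_rejected_by_spectral_trace():
    from dopplerquant.svfm import VesselSegment, spectral_trace
    from dopplerquant.codec import VelocityFieldSequence

    fields = np.full((2, 6, 6), 1.0, dtype=np.float32)
    seg = VesselSegment(mask=np.ones((6, 6), dtype=bool), axis=(1.0, 0.0),
                        angle_deg=90.0, diameter=0.1, direction_known=True)
    vseq = VelocityFieldSequence(fields=fields, roi_mask=np.ones((6, 6), bool),
                                 frame_rate=15.0, pixel_spacing=0.01)
    with pytest.raises(PerpendicularFlowError):
        spectral_trace(seg, vseq)


def test_malignant_pulsatility_zero_gives_tri_one():
    p = noiseless_params(pulsatility=0.0, ri_pulsatility=0.0)
    seq = dq.synthesize_case(p, seed=9)
    assert seq.truth.true_tri == pytest.approx(1.0)


def test_cohort_manifest_shape_and_labels(tmp_path):
    man = dq.generate_cohort(2, 1, seed=5, out_dir=tmp_path)
    assert list(man.label) == ["malignant"] * 2 + ["inflammatory"]
    assert (tmp_path / "manifest.csv").exists()
    man2 = dq.generate_cohort(2, 1, seed=6)
    assert list(man.columns) == list(man2.columns)
    assert not np.allclose(man.true_tfv, man2.true_tfv)


def test_calibration_fidelity_of_drawn_cohort():
    """At n = 500 per label the drawn parameters reproduce the published
    group summaries: TFV means and the medians of the skewed parameters."""
    df = dq.draw_cohort_params(500, 500, seed=1)
    mal = df[df.label == "malignant"]
    inf = df[df.label == "inflammatory"]
    assert mal.tfv.mean() == pytest.approx(1.422, rel=0.05)
    assert inf.tfv.mean() == pytest.approx(2.653, rel=0.05)
    assert mal.tri.median() == pytest.approx(1.000, abs=1e-9)
    assert inf.tri.median() == pytest.approx(0.776, abs=0.05)
    assert mal.tpi.median() == pytest.approx(0.004, rel=0.15)
    assert inf.tpi.median() == pytest.approx(0.016, rel=0.10)
    assert mal.fv.median() == pytest.approx(1.592, rel=0.10)
    assert inf.fv.median() == pytest.approx(3.397, rel=0.05)
    assert mal.ri.median() == pytest.approx(1.000, abs=1e-9)
    assert inf.ri.median() == pytest.approx(0.843, abs=0.05)
    assert mal.volf.median() == pytest.approx(0.010, rel=0.15)
    assert inf.volf.median() == pytest.approx(0.032, rel=0.10)


def test_stochastic_ordering_of_group_distributions():
    df = dq.draw_cohort_params(400, 400, seed=2)
    mal = df[df.label == "malignant"]
    inf = df[df.label == "inflammatory"]
    for p in ("tfv", "tpi", "fv", "volf"):
        assert mal[p].median() < inf[p].median()
    for p in ("tri", "ri"):
        assert mal[p].median() > inf[p].median()


def test_infeasible_geometry_rejected():
    calib = CohortCalibration(angle_bounds=(89.9, 89.9))
    # impossible angle window: every draw falls outside the normal's support
    with pytest.raises(Exception):
        calib.draw_measurements("malignant", np.random.default_rng(0))
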