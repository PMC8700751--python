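"""Single-vessel flow: segmentation, axis/angle geometry, angle correction."""

import numpy as np
import pytest

import dopplerquant as dq
from dopplerquant.codec import VelocityFieldSequence
from dopplerquant.errors import (
    AxisUndefinedError,
    NoVesselError,
    PerpendicularFlowError,
    VesselDirectionError,
)
from dopplerquant.svfm import VesselSegment, compute_svfm, spectral_trace, vessel_envelope


def vfs(fields, spacing=0.01, rate=15.0, roi=None):
    fields = np.asarray(fields, dtype=np.float32)
    if roi is None:
        roi = np.ones(fields.shape[1:], dtype=bool)
    return VelocityFieldSequence(fields=fields, roi_mask=roi, frame_rate=rate, pixel_spacing=spacing)


def flood_fill_components(mask):
    """Independent 4-connectivity labeling by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], set()
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.add((r, c))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]:
                            if mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(frozenset(comp))
    return set(comps)


def test_single_blob_segmentation():
    fields = np.full((3, 10, 10), np.nan, dtype=np.float32)
    fields[:, 2:5, 2:12] = 1.5
    cands = dq.segment_vessels(vfs(fields))
    assert len(cands) == 1
    assert cands[0].n_pixels == 24
    assert cands[0].direction_consistency == 1.0


def test_two_blobs_ordered_by_size():
    fields = np.full((2, 12, 12), np.nan, dtype=np.float32)
    fields[:, 1:4, 1:11] = 1.0  # 30 px
    fields[:, 8:10, 2:7] = -1.0  # 10 px
    cands = dq.segment_vessels(vfs(fields))
    assert [c.n_pixels for c in cands] == [30, 10]
    assert cands[0].modal_sign == 1 and cands[1].modal_sign == -1


def test_components_match_flood_fill_oracle(rng):
    fields = np.full((4, 20, 20), np.nan, dtype=np.float32)
    blob = rng.random((20, 20)) < 0.25
    fields[:, blob] = 1.0
    cands = dq.segment_vessels(vfs(fields))
    ours = {frozenset(zip(*np.nonzero(c.mask))) for c in cands}
    assert ours == flood_fill_components(blob)


def test_no_perfusion_raises_no_vessel():
    with pytest.raises(NoVesselError, match="no vessel visible"):
        dq.segment_vessels(vfs(np.full((2, 5, 5), np.nan)))


def test_direction_rule_prefers_consistent_smaller_vessel():
    fields = np.full((10, 14, 14), np.nan, dtype=np.float32)
    # large blob alternates sign every frame (consistency 0.5)
    for t in range(10):
        fields[t, 1:5, 1:11] = 1.0 if t % 2 == 0 else -1.0
    fields[:, 9:11, 2:8] = 2.0  # smaller but consistent
    cands = dq.segment_vessels(vfs(fields))
    chosen = dq.select_largest_vessel(cands)
    assert chosen.n_pixels == 12
    assert chosen.direction_consistency == 1.0


def test_all_inconsistent_vessels_excluded():
    fields = np.full((10, 8, 8), np.nan, dtype=np.float32)
    for t in range(10):
        fields[t, 2:4, 2:6] = 1.0 if t % 2 == 0 else -1.0
    with pytest.raises(VesselDirectionError, match="no vessel with known flow direction"):
        dq.select_largest_vessel(dq.segment_vessels(vfs(fields)))


def test_axis_of_vertical_line_is_parallel_to_beam():
    mask = np.zeros((24, 9), dtype=bool)
    mask[2:22, 4] = True
    _, angle, _ = dq.estimate_axis_and_angle(mask, 0.01, (0.0, -1.0))
    assert angle == pytest.approx(0.0, abs=1e-6)


def test_axis_of_diagonal_line_is_45_degrees():
    mask = np.zeros((25, 25), dtype=bool)
    for i in range(20):
        mask[i + 2, i + 2] = True
    _, angle, _ = dq.estimate_axis_and_angle(mask, 0.01, (0.0, -1.0))
    assert angle == pytest.approx(45.0, abs=1.0)


@pytest.mark.parametrize("true_deg", [10.0, 35.0, 60.0, 80.0])
def test_axis_recovers_ellipse_orientation(true_deg, rng):
    yy, xx = np.mgrid[0:60, 0:60]
    th = np.radians(true_deg)
    # ellipse elongated along direction (sin th, -cos th): angle th to the beam
    u = (xx - 30) * np.sin(th) - (yy - 30) * np.cos(th)
    w = (xx - 30) * np.cos(th) + (yy - 30) * np.sin(th)
    mask = (u / 22.0) ** 2 + (w / 5.0) ** 2 <= 1.0
    _, angle, _ = dq.estimate_axis_and_angle(mask, 0.01, (0.0, -1.0))
    assert angle == pytest.approx(true_deg, abs=2.0)


def test_axis_undefined_for_tiny_mask():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 2] = True
    with pytest.raises(AxisUndefinedError, match="axis undefined"):
        dq.estimate_axis_and_angle(mask, 0.01, (0.0, -1.0))


def test_diameter_of_rectangular_strip():
    mask = np.zeros((30, 30), dtype=bool)
    mask[10:15, 5:25] = True  # 5 px wide, 20 px long
    _, _, diameter = dq.estimate_axis_and_angle(mask, 0.01, (0.0, -1.0))
    assert diameter == pytest.approx(5 * 0.01, rel=0.05)


def segment_with(angle_deg, mask_shape=(6, 6)):
    mask = np.ones(mask_shape, dtype=bool)
    return VesselSegment(mask=mask, axis=(0.0, -1.0), angle_deg=angle_deg,
                         diameter=0.1, direction_known=True)


def test_correction_at_60_degrees_doubles_velocity():
    fields = np.full((2, 6, 6), np.nan, dtype=np.float32)
    fields[:, 2, 2] = 1.5
    trace = spectral_trace(segment_with(60.0), vfs(fields))
    assert trace[0] == pytest.approx(3.0, rel=1e-6)


def test_correction_at_zero_degrees_is_identity():
    fields = np.full((2, 6, 6), np.nan, dtype=np.float32)
    fields[:, 3, 3] = -2.2
    trace = spectral_trace(segment_with(0.0), vfs(fields))
    assert trace[0] == pytest.approx(2.2, rel=1e-6)


def test_perpendicular_flow_is_unmeasurable():
    fields = np.full((2, 6, 6), 1.0, dtype=np.float32)
    with pytest.raises(PerpendicularFlowError, match="perpendicular"):
        spectral_trace(segment_with(90.0), vfs(fields))


def test_angle_above_60_is_flagged_invalid():
    trace = np.array([4.0, 1.0, 4.0, 1.0, 4.0])
    res = compute_svfm(trace, frame_rate=15.0, diameter=0.1, angle_deg=75.0,
                       cycles=[dq.CardiacCycle(0, 2, 4.0, 1.0), dq.CardiacCycle(2, 4, 4.0, 1.0)])
    assert res.angle_valid is False
    res60 = compute_svfm(trace, 15.0, 0.1, 60.0, cycles=[dq.CardiacCycle(0, 2, 4.0, 1.0)])
    assert res60.angle_valid is True


def test_resistive_index_and_volume_flow_formulas():
    trace = np.array([4.0, 1.0])
    res = compute_svfm(trace, 15.0, diameter=0.1, angle_deg=30.0,
                       cycles=[dq.CardiacCycle(0, 2, 4.0, 1.0)])
    assert res.ri == pytest.approx(0.75)
    assert res.fv == pytest.approx(2.5)
    # VolF at fv = 3 cm/s, d = 0.1 cm
    res2 = compute_svfm(np.array([3.0, 3.0]), 15.0, 0.1, 0.0,
                        cycles=[dq.CardiacCycle(0, 2, 3.0, 3.0)])
    assert res2.volf == pytest.approx(3.0 * np.pi * 0.0025, rel=1e-6)
    assert res2.volf == pytest.approx(0.0236, abs=5e-4)


def test_ri_is_invariant_to_angle_correction():
    base = np.array([5.0, 2.0, 5.0, 2.0])
    cycles = [dq.CardiacCycle(0, 2, 5.0, 2.0), dq.CardiacCycle(2, 4, 5.0, 2.0)]
    r0 = compute_svfm(base, 15.0, 0.1, 0.0, cycles=cycles)
    r60 = compute_svfm(base / np.cos(np.radians(60.0)), 15.0, 0.1, 60.0, cycles=cycles)
    assert r60.ri == pytest.approx(r0.ri)


def test_volf_scales_with_diameter_squared():
    trace = np.array([2.0, 2.0])
    cycles = [dq.CardiacCycle(0, 2, 2.0, 2.0)]
    a = compute_svfm(trace, 15.0, 0.1, 0.0, cycles=cycles)
    b = compute_svfm(trace, 15.0, 0.2, 0.0, cycles=cycles)
    assert b.volf == pytest.approx(4.0 * a.volf)


def test_envelope_ignores_unperfused_frames():
    block = np.full((3, 5), np.nan)
    block[1] = [1.0, 2.0, 3.0, 4.0, 5.0]
    env = vessel_envelope(block, percentile=100)
    assert env[0] == 0.0 and env[2] == 0.0
    assert env[1] == pytest.approx(5.0)
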