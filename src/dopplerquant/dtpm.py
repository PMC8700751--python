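"""Dynamic tissue perfusion measurement: TFV, TRI, TPI.

For every frame the decoded velocity field is reduced to three numbers
over the ROI:

* ``mean_v`` -- mean velocity magnitude over *perfused* pixels (cm/s);
  zero when no pixel is perfused (that frame *is* the diastolic no-flow
  state, and excluding it would bias TFV upward and make TRI = 1
  unreachable),
* ``area``  -- perfused area (cm^2),
* ``intensity`` -- perfusion intensity I = mean_v * area / roi_area,
  algebraically equal to (sum of |v| over perfused pixels) / (ROI pixel
  count); a velocity weighted by the instantaneous vascular fraction.

Cardiac cycles are delimited by successive systolic peaks of the intensity
signal (intensity pools velocity and area pulsation and is the smoother
of the two).  The summary parameters are

* TFV = time average of mean_v over the union of complete cycles [cm/s],
* TPI = time average of intensity over the same frames [cm/s],
* TRI = mean over cycles of (vmax - vmin) / vmax on the mean_v trace,
  with TRI = 0 for a cycle whose vmax = 0.

Velocity magnitudes are used throughout: arterial and venous flow pool
into one perfusion estimate, and the sign only matters for single-vessel
direction checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .codec import VelocityFieldSequence
from .errors import EmptyInputError, NoCompleteCycleError

#: Physiological heart-rate search window, beats per minute.
DEFAULT_HR_BOUNDS = (40.0, 180.0)

#: Peak prominence required, as a fraction of the intensity signal range.
PEAK_PROMINENCE_FRACTION = 0.2


@dataclass
class PerfusionTrace:
    """Per-frame perfusion summaries of one cine."""

    t: np.ndarray  # frame times, s
    mean_v: np.ndarray  # cm/s
    area: np.ndarray  # cm^2
    roi_area: float  # cm^2
    intensity: np.ndarray  # cm/s
    frame_rate: float  # Hz

    @property
    def n_frames(self) -> int:
        return int(self.t.size)


@dataclass(frozen=True)
class CardiacCycle:
    """Half-open frame interval [start_frame, end_frame) between two systolic peaks."""

    start_frame: int
    end_frame: int
    vmax: float  # cm/s, max of mean_v within the cycle
    vmin: float  # cm/s, min of mean_v within the cycle

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("cycle must span at least one frame")
        if not (self.vmax >= self.vmin >= 0):
            raise ValueError("cycle extrema must satisfy vmax >= vmin >= 0")


@dataclass
class DtpmResult:
    """The three tissue-perfusion parameters of one case."""

    tfv: float  # cm/s
    tri: float  # ratio in [0, 1]
    tpi: float  # cm/s
    n_cycles: int
    fallback: bool = False  # True when no complete cycle was found


def perfusion_trace(v_seq: VelocityFieldSequence) -> PerfusionTrace:
    """Reduce a velocity-field sequence to its per-frame perfusion trace."""
    roi = v_seq.roi_mask
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise EmptyInputError("empty input: ROI has no pixel")
    px_area = v_seq.pixel_spacing**2
    roi_area = n_roi * px_area

    sub = np.abs(v_seq.fields[:, roi])  # (n_frames, n_roi)
    perfused = np.isfinite(sub)
    counts = perfused.sum(axis=1)
    sums = np.where(perfused, sub, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_v = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    area = counts * px_area
    intensity = sums / n_roi  # == mean_v * area / roi_area

    t = np.arange(v_seq.n_frames) / v_seq.frame_rate
    return PerfusionTrace(
        t=t,
        mean_v=mean_v.astype(float),
        area=area.astype(float),
        roi_area=float(roi_area),
        intensity=intensity.astype(float),
        frame_rate=v_seq.frame_rate,
    )


def detect_cycles(
    trace: PerfusionTrace,
    hr_bounds: tuple[float, float] = DEFAULT_HR_BOUNDS,
) -> list[CardiacCycle]:
    """Delimit cardiac cycles by successive systolic peaks of the intensity signal.

    Peaks must have prominence of at least 20% of the signal range and be
    spaced consistently with ``hr_bounds``.  Frames before the first and
    after the last peak are discarded by the downstream averages.

    Raises
    ------
    NoCompleteCycleError
        If fewer than two qualifying peaks are found.
    """
    sig = np.asarray(trace.intensity, dtype=float)
    if sig.size == 0:
        raise EmptyInputError("empty input: empty trace")
    rng = float(sig.max() - sig.min())
    if rng <= 0:
        raise NoCompleteCycleError("no complete cardiac cycle: constant trace")
    min_bpm, max_bpm = hr_bounds
    min_dist = max(1, int(np.floor(trace.frame_rate * 60.0 / max_bpm)))
    max_dist = int(np.ceil(trace.frame_rate * 60.0 / min_bpm))
    peaks, _ = find_peaks(sig, prominence=PEAK_PROMINENCE_FRACTION * rng, distance=min_dist)
    cycles: list[CardiacCycle] = []
    for a, b in zip(peaks, peaks[1:]):
        if (b - a) > max_dist:
            continue  # gap longer than the slowest plausible beat
        seg = trace.mean_v[a:b]
        cycles.append(
            CardiacCycle(start_frame=int(a), end_frame=int(b), vmax=float(seg.max()), vmin=float(seg.min()))
        )
    if not cycles:
        raise NoCompleteCycleError("no complete cardiac cycle")
    return cycles


def compute_dtpm(trace: PerfusionTrace, cycles: list[CardiacCycle]) -> DtpmResult:
    """Average the trace over complete cycles into the TFV/TRI/TPI triple."""
    if trace.n_frames == 0:
        raise EmptyInputError("empty input: empty trace")
    if not cycles:
        raise NoCompleteCycleError("no complete cardiac cycle")
    start = min(c.start_frame for c in cycles)
    end = max(c.end_frame for c in cycles)
    tfv = float(trace.mean_v[start:end].mean())
    tpi = float(trace.intensity[start:end].mean())
    tris = [(c.vmax - c.vmin) / c.vmax if c.vmax > 0 else 0.0 for c in cycles]
    return DtpmResult(tfv=tfv, tri=float(np.mean(tris)), tpi=tpi, n_cycles=len(cycles))


def analyze_dtpm(
    v_seq: VelocityFieldSequence,
    hr_bounds: tuple[float, float] = DEFAULT_HR_BOUNDS,
) -> DtpmResult:
    """Full DTPM of one decoded cine, with a flagged whole-trace fallback.

    When no complete cardiac cycle can be delimited the parameters are
    computed over the whole trace (TRI from the global extrema) and the
    result carries ``fallback=True``.
    """
    trace = perfusion_trace(v_seq)
    try:
        cycles = detect_cycles(trace, hr_bounds)
    except NoCompleteCycleError:
        warnings.warn("no complete cardiac cycle; falling back to whole-trace extrema", stacklevel=2)
        vmax = float(trace.mean_v.max())
        vmin = float(trace.mean_v.min())
        tri = (vmax - vmin) / vmax if vmax > 0 else 0.0
        return DtpmResult(
            tfv=float(trace.mean_v.mean()),
            tri=tri,
            tpi=float(trace.intensity.mean()),
            n_cycles=0,
            fallback=True,
        )
    return compute_dtpm(trace, cycles)
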