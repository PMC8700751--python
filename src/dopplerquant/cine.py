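"""Cine container: RGB frame stacks with calibration, ROI and label sidecars.

A *case* is one color-Doppler recording of one lesion.  On disk it is a
directory holding

``frames.tif``
    multi-page RGB TIFF, lossless (uncompressed or deflate),
``calibration.json``
    pixel spacing [cm/px], frame rate [Hz], colorbar LUT, beam axis,
    case id and label,
``roi.png``
    8-bit mask, 0/255, marking the region of interest,
``truth.json`` (optional, synthetic cases only)
    analytic ground-truth parameters of the rendered flow field.

Losslessness matters: velocity decoding is an exact nearest-color lookup
against the colorbar, and any chroma drift introduced by a lossy codec
would corrupt the decoded velocities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import CalibrationError, FrameError, RoiError, LutError

LABELS = ("malignant", "inflammatory", "unknown")

#: Default acquisition constants.  The source recordings' device constants
#: are not published; these are configuration, not claims.
DEFAULT_PIXEL_SPACING = 0.01  # cm per pixel
DEFAULT_FRAME_RATE = 15.0  # Hz
DEFAULT_BEAM_AXIS = (0.0, -1.0)  # (dx, dy), image rows grow downward

#: Clip duration accepted for analysis, seconds.  Recordings of 3-5 s are
#: typical; anything in [1, 30] s is analyzable.
MIN_DURATION_S = 1.0
MAX_DURATION_S = 30.0


@dataclass(frozen=True)
class ColorLutEntry:
    """One colorbar entry: an RGB triple mapped to a signed velocity [cm/s]."""

    rgb: tuple[int, int, int]
    velocity: float

    def __post_init__(self) -> None:
        rgb = tuple(int(c) for c in self.rgb)
        if len(rgb) != 3 or any(c < 0 or c > 255 for c in rgb):
            raise LutError(f"invalid colorbar: RGB triple out of range: {rgb}")
        object.__setattr__(self, "rgb", rgb)
        object.__setattr__(self, "velocity", float(self.velocity))


@dataclass
class Calibration:
    """Acquisition constants attached to a cine sequence.

    Parameters
    ----------
    pixel_spacing : float
        Isotropic pixel size, cm per pixel.
    frame_rate : float
        Frames per second, Hz.
    lut : sequence of ColorLutEntry
        The scanner colorbar.  Entries within one sign branch must be
        strictly monotone in velocity and no two entries may share an RGB
        triple.
    beam_axis : tuple of float
        Unit 2-vector (dx, dy) of the insonation direction in image
        coordinates (origin top-left, y down).  Default (0, -1): beam
        pointing up toward the transducer.
    """

    pixel_spacing: float = DEFAULT_PIXEL_SPACING
    frame_rate: float = DEFAULT_FRAME_RATE
    lut: list[ColorLutEntry] = field(default_factory=list)
    beam_axis: tuple[float, float] = DEFAULT_BEAM_AXIS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.pixel_spacing > 0 and np.isfinite(self.pixel_spacing)):
            raise CalibrationError("calibration invalid: pixel_spacing must be > 0")
        if not (self.frame_rate > 0 and np.isfinite(self.frame_rate)):
            raise CalibrationError("calibration invalid: frame_rate must be > 0")
        ax = np.asarray(self.beam_axis, dtype=float)
        n = np.linalg.norm(ax)
        if ax.shape != (2,) or not np.isfinite(n) or n == 0:
            raise CalibrationError("calibration invalid: beam_axis must be a nonzero 2-vector")
        self.beam_axis = tuple(ax / n)
        self.lut = [e if isinstance(e, ColorLutEntry) else ColorLutEntry(*e) for e in self.lut]
        _validate_lut_entries(self.lut)

    def to_dict(self) -> dict:
        return {
            "pixel_spacing_cm": self.pixel_spacing,
            "frame_rate_hz": self.frame_rate,
            "beam_axis": list(self.beam_axis),
            "lut": [[list(e.rgb), e.velocity] for e in self.lut],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        try:
            return cls(
                pixel_spacing=float(d["pixel_spacing_cm"]),
                frame_rate=float(d["frame_rate_hz"]),
                lut=[ColorLutEntry(tuple(rgb), v) for rgb, v in d.get("lut", [])],
                beam_axis=tuple(d.get("beam_axis", DEFAULT_BEAM_AXIS)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise CalibrationError(f"calibration invalid: {exc}") from exc


def _validate_lut_entries(entries: Sequence[ColorLutEntry]) -> None:
    """Check colorbar invariants shared by Calibration and the codec."""
    if len(entries) < 2:
        raise LutError("invalid colorbar: need at least 2 LUT entries")
    seen: dict[tuple[int, int, int], float] = {}
    for e in entries:
        if e.rgb in seen:
            raise LutError(f"ambiguous LUT: RGB {e.rgb} maps to both {seen[e.rgb]} and {e.velocity}")
        seen[e.rgb] = e.velocity
    for sign, name in ((1, "positive"), (-1, "negative")):
        branch = [e.velocity for e in entries if np.sign(e.velocity) == sign]
        if branch and len(branch) < 2:
            raise LutError(f"invalid colorbar: {name} branch has a single entry")
        increasing = all(b2 > b1 for b1, b2 in zip(branch, branch[1:]))
        decreasing = all(b2 < b1 for b1, b2 in zip(branch, branch[1:]))
        if branch and not (increasing or decreasing):
            raise LutError(f"invalid colorbar: {name} branch not strictly monotone")


@dataclass
class GroundTruth:
    """Analytic parameters of a synthetic case, written as ``truth.json``.

    All flows are magnitudes (>= 0); both resistive indices live in [0, 1].
    """

    true_tfv: float
    true_tri: float
    true_tpi: float
    true_fv: float
    true_ri: float
    true_volf: float
    true_angle_deg: float
    vessel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_tri <= 1.0 and 0.0 <= self.true_ri <= 1.0):
            raise CalibrationError("truth invalid: resistive indices must lie in [0, 1]")
        if min(self.true_tfv, self.true_tpi, self.true_fv, self.true_volf) < 0:
            raise CalibrationError("truth invalid: flows must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("vessel_mask")
        return d


@dataclass
class CineSequence:
    """One lesion recording: frames + calibration + ROI + label."""

    frames: np.ndarray  # (n_frames, H, W, 3) uint8
    calibration: Calibration
    roi_mask: np.ndarray  # (H, W) bool
    case_id: str = "case"
    label: str = "unknown"
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.frames = np.ascontiguousarray(self.frames, dtype=np.uint8)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3 or self.frames.shape[0] == 0:
            raise FrameError("inconsistent frames: expected a (n, H, W, 3) stack")
        if self.roi_mask.shape != self.frames.shape[1:3]:
            raise RoiError("degenerate ROI: mask shape does not match frames")
        if not self.roi_mask.any():
            raise RoiError("degenerate ROI: no pixel selected")
        if self.label not in LABELS:
            raise CalibrationError(f"calibration invalid: label must be one of {LABELS}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.calibration.frame_rate

    def check_analyzable(self) -> None:
        """Raise unless the clip duration is inside the analysis window."""
        if not (MIN_DURATION_S <= self.duration_s <= MAX_DURATION_S):
            raise FrameError(
                f"clip duration {self.duration_s:.2f} s outside "
                f"[{MIN_DURATION_S}, {MAX_DURATION_S}] s analysis window"
            )


def write_cine(seq: CineSequence, path: str | Path) -> Path:
    """Write a case directory; the write->read round trip is exact.

    Frames go to a multi-page deflate-compressed TIFF (lossless), the ROI
    to an 8-bit PNG, calibration/label and optional ground truth to JSON.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path / "frames.tif", seq.frames, compression="zlib", photometric="rgb")
    iio.imwrite(path / "roi.png", (seq.roi_mask.astype(np.uint8) * 255))
    sidecar = seq.calibration.to_dict()
    sidecar["case_id"] = seq.case_id
    sidecar["label"] = seq.label
    (path / "calibration.json").write_text(json.dumps(sidecar, indent=1))
    if seq.truth is not None:
        (path / "truth.json").write_text(json.dumps(seq.truth.to_dict(), indent=1))
        if seq.truth.vessel_mask is not None:
            iio.imwrite(path / "vessel.png", seq.truth.vessel_mask.astype(np.uint8) * 255)
    return path


def read_cine(path: str | Path) -> CineSequence:
    """Read a case directory written by :func:`write_cine`.

    Raises
    ------
    CalibrationError
        If ``calibration.json`` is missing or invalid.
    FrameError, RoiError
        If the frame stack or ROI violates a container invariant.
    """
    path = Path(path)
    calib_path = path / "calibration.json"
    if not calib_path.exists():
        raise CalibrationError(f"calibration missing: {calib_path}")
    try:
        sidecar = json.loads(calib_path.read_text())
    except json.JSONDecodeError as exc:
        raise CalibrationError(f"calibration invalid: {exc}") from exc
    calibration = Calibration.from_dict(sidecar)

    frames_path = path / "frames.tif"
    if frames_path.exists():
        frames = tifffile.imread(frames_path)
    else:
        pngs = sorted(p for p in path.glob("frame_*.png"))
        if not pngs:
            raise FrameError(f"inconsistent frames: no frames.tif or frame_*.png in {path}")
        stack = [iio.imread(p) for p in pngs]
        if len({a.shape for a in stack}) != 1:
            raise FrameError("inconsistent frames: PNG frames differ in shape")
        frames = np.stack(stack)
    if frames.ndim == 3:  # single page
        frames = frames[None]

    roi_path = path / "roi.png"
    if not roi_path.exists():
        raise RoiError(f"degenerate ROI: missing {roi_path}")
    roi = np.asarray(iio.imread(roi_path))
    if roi.ndim == 3:
        roi = roi[..., 0]
    roi = roi > 127

    truth = None
    truth_path = path / "truth.json"
    if truth_path.exists():
        td = json.loads(truth_path.read_text())
        vessel = None
        if (path / "vessel.png").exists():
            vm = np.asarray(iio.imread(path / "vessel.png"))
            if vm.ndim == 3:
                vm = vm[..., 0]
            vessel = vm > 127
        truth = GroundTruth(vessel_mask=vessel, **td)

    return CineSequence(
        frames=frames,
        calibration=calibration,
        roi_mask=roi,
        case_id=str(sidecar.get("case_id", path.name)),
        label=str(sidecar.get("label", "unknown")),
        truth=truth,
    )
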