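"""Colorbar codec: RGB color-Doppler overlays <-> signed velocity fields.

The scanner overlays color-coded velocities on a gray B-mode background.
Decoding inverts that coding: a pixel is *perfused* when its chroma
(max(R,G,B) - min(R,G,B)) exceeds a threshold -- the B-mode background is
gray by construction -- and its velocity is that of the nearest colorbar
entry in Euclidean RGB distance.  Nearest-color ties resolve toward the
smaller |velocity|, which is the conservative choice (never inflates
perfusion).  Encoding (used by the synthetic generator) paints the nearest
colorbar color for finite velocities and copies the background elsewhere.

Round trip: decode(encode(v)) quantizes v to the nearest LUT velocity, so
the residual is at most half the local LUT velocity step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cine import Calibration, CineSequence, ColorLutEntry
from .errors import LutError, OutOfRangeError

#: Default perfused-pixel chroma threshold (8-bit counts).
DEFAULT_CHROMA_THRESHOLD = 24.0


@dataclass
class VelocityFieldSequence:
    """Decoded signed velocities per pixel per frame; NaN = not perfused."""

    fields: np.ndarray  # (n_frames, H, W) float32, cm/s
    roi_mask: np.ndarray  # (H, W) bool
    frame_rate: float  # Hz
    pixel_spacing: float  # cm / pixel
    beam_axis: tuple[float, float] = (0.0, -1.0)

    @property
    def n_frames(self) -> int:
        return int(self.fields.shape[0])


class ColorLUT:
    """Indexed colorbar supporting nearest-color decode and nearest-velocity encode.

    Entries are stored sorted by |velocity| (then by velocity) so that
    ``argmin`` over RGB distances, which returns the first minimum, breaks
    ties toward the smaller velocity magnitude.
    """

    def __init__(self, entries: Sequence[ColorLutEntry]):
        entries = [e if isinstance(e, ColorLutEntry) else ColorLutEntry(*e) for e in entries]
        self._validate(entries)
        order = sorted(range(len(entries)), key=lambda i: (abs(entries[i].velocity), entries[i].velocity))
        self.entries = [entries[i] for i in order]
        self.colors = np.array([e.rgb for e in self.entries], dtype=np.float32)  # (N, 3)
        self.velocities = np.array([e.velocity for e in self.entries], dtype=np.float64)
        self._vel_order = np.argsort(self.velocities, kind="stable")
        self._vel_sorted = self.velocities[self._vel_order]

    @staticmethod
    def _validate(entries: Sequence[ColorLutEntry]) -> None:
        """Order-free colorbar invariants (entry order is irrelevant here;
        the ordered-sidecar layout check lives in the calibration)."""
        if len(entries) < 2:
            raise LutError("invalid colorbar: need at least 2 LUT entries")
        seen: dict[tuple[int, int, int], float] = {}
        for e in entries:
            if e.rgb in seen:
                raise LutError(
                    f"ambiguous LUT: RGB {e.rgb} maps to both {seen[e.rgb]} and {e.velocity}"
                )
            seen[e.rgb] = e.velocity
        for sign, name in ((1, "positive"), (-1, "negative")):
            branch = sorted(e.velocity for e in entries if np.sign(e.velocity) == sign)
            if branch and len(branch) < 2:
                raise LutError(f"invalid colorbar: {name} branch has a single entry")
            if any(b2 <= b1 for b1, b2 in zip(branch, branch[1:])):
                raise LutError(f"invalid colorbar: {name} branch not strictly monotone")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def vmax(self) -> float:
        """Largest representable velocity magnitude."""
        return float(np.abs(self.velocities).max())

    @property
    def vmin(self) -> float:
        """Smallest representable nonzero velocity magnitude."""
        nz = np.abs(self.velocities[self.velocities != 0])
        return float(nz.min()) if nz.size else 0.0

    def nearest_velocity(self, v: np.ndarray) -> np.ndarray:
        """Quantize velocities to the nearest LUT velocity (ties: smaller |v|)."""
        v = np.asarray(v, dtype=np.float64)
        idx = np.searchsorted(self._vel_sorted, v)
        lo = np.clip(idx - 1, 0, len(self._vel_sorted) - 1)
        hi = np.clip(idx, 0, len(self._vel_sorted) - 1)
        vlo, vhi = self._vel_sorted[lo], self._vel_sorted[hi]
        d_lo, d_hi = np.abs(v - vlo), np.abs(v - vhi)
        pick_hi = (d_hi < d_lo) | ((d_hi == d_lo) & (np.abs(vhi) < np.abs(vlo)))
        return np.where(pick_hi, vhi, vlo)

    def nearest_color_index(self, rgb: np.ndarray) -> np.ndarray:
        """Index of the nearest LUT entry for each RGB row (Euclidean distance)."""
        rgb = np.asarray(rgb, dtype=np.float32).reshape(-1, 3)
        # (n, N) distance matrix; LUTs are small (tens of entries).
        d2 = ((rgb[:, None, :] - self.colors[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def build_lut(entries: Sequence[ColorLutEntry]) -> ColorLUT:
    """Build the lookup structure; order of the input entries is irrelevant."""
    return ColorLUT(entries)


def default_lut(n_per_branch: int = 48, vmax: float = 20.0, vmin: float = 0.25) -> list[ColorLutEntry]:
    """A generic two-branch colorbar: red/yellow ramp toward the probe,
    blue/cyan ramp away, geometrically spaced velocities from ``vmin`` to
    ``vmax`` (constant ~5% relative step, so quantization error is a fixed
    fraction of the velocity at every scale).

    Adjacent entries are >= 4 counts apart in RGB, above typical pixel
    noise, and every color has chroma far above the gray threshold.
    """
    if n_per_branch < 2:
        raise LutError("invalid colorbar: need at least 2 entries per branch")
    vel = np.geomspace(vmin, vmax, n_per_branch)
    ramp = np.round(np.linspace(0, 215, n_per_branch)).astype(int)
    entries = [ColorLutEntry((255, int(g), 0), float(v)) for g, v in zip(ramp, vel)]
    entries += [ColorLutEntry((0, int(g), 255), float(-v)) for g, v in zip(ramp, vel)]
    return entries


def chroma(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel chroma max(R,G,B) - min(R,G,B) of an (..., 3) uint8 image."""
    arr = np.asarray(rgb)
    return arr.max(axis=-1).astype(np.int16) - arr.min(axis=-1).astype(np.int16)


def decode_frame(
    rgb: np.ndarray,
    lut: ColorLUT,
    roi: np.ndarray | None = None,
    chroma_threshold: float = DEFAULT_CHROMA_THRESHOLD,
) -> np.ndarray:
    """Decode one RGB frame to a signed velocity map (NaN = not perfused).

    Pixels with chroma <= ``chroma_threshold``, or outside ``roi``, are NaN.
    Decoding factors through the unique colors present, so cost scales with
    the number of distinct perfused colors rather than the pixel count.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("decode_frame expects an (H, W, 3) image")
    perfused = chroma(rgb) > chroma_threshold
    if roi is not None:
        if roi.shape != rgb.shape[:2]:
            raise ValueError("ROI shape does not match frame")
        perfused &= roi
    out = np.full(rgb.shape[:2], np.nan, dtype=np.float32)
    if perfused.any():
        px = rgb[perfused].reshape(-1, 3)
        uniq, inverse = np.unique(px, axis=0, return_inverse=True)
        idx = lut.nearest_color_index(uniq)
        out[perfused] = lut.velocities[idx][inverse].astype(np.float32)
    return out


def encode_frame(v: np.ndarray, lut: ColorLUT, background: np.ndarray) -> np.ndarray:
    """Render a velocity map over a gray background through the colorbar.

    Finite pixels take the color of the nearest LUT velocity; NaN pixels
    copy the background.  Velocities beyond the colorbar range are refused.
    """
    v = np.asarray(v, dtype=np.float64)
    bg = np.asarray(background)
    if bg.ndim == 2:
        bg = np.repeat(bg[..., None], 3, axis=-1)
    if bg.shape[:2] != v.shape:
        raise ValueError("background shape does not match velocity map")
    finite = np.isfinite(v)
    if finite.any() and np.abs(v[finite]).max() > lut.vmax + 1e-9:
        raise OutOfRangeError(
            f"out of colorbar range: |v| max {np.abs(v[finite]).max():.3g} > {lut.vmax:.3g} cm/s"
        )
    out = np.ascontiguousarray(bg, dtype=np.uint8).copy()
    if finite.any():
        q = lut.nearest_velocity(v[finite])
        # map quantized velocity -> entry index (exact match by construction)
        pos = np.searchsorted(lut._vel_sorted, q)
        entry_idx = lut._vel_order[pos]
        out[finite] = lut.colors[entry_idx].astype(np.uint8)
    return out


def decode_sequence(
    seq: CineSequence,
    chroma_threshold: float = DEFAULT_CHROMA_THRESHOLD,
) -> VelocityFieldSequence:
    """Decode every frame of a cine through its own calibration LUT."""
    cal: Calibration = seq.calibration
    lut = build_lut(cal.lut)
    fields = np.stack(
        [decode_frame(f, lut, seq.roi_mask, chroma_threshold) for f in seq.frames]
    )
    return VelocityFieldSequence(
        fields=fields,
        roi_mask=seq.roi_mask,
        frame_rate=cal.frame_rate,
        pixel_spacing=cal.pixel_spacing,
        beam_axis=cal.beam_axis,
    )
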