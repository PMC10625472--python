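"""Lateral drift estimation and correction for time-lapse series.

Stage drift is modeled as a rigid translation per frame, estimated against
the equilibrium (cell-detached) reference bead image by cross-correlation
with 3-point parabolic sub-pixel refinement.  The identical shifts and the
single global crop are then applied to every channel of the position, so
bead and cell frames stay registered in the reference frame that the
displacement mapping uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import GridImage

__all__ = ["DriftTrace", "estimate_shift", "build_drift_trace", "apply_drift_correction"]


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:  # not a maximum; no refinement
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))


def estimate_shift(
    moving: GridImage, reference: GridImage, max_drift_px: float | None = None
) -> tuple[float, float]:
    """Sub-pixel rigid translation (dx, dy) of ``moving`` relative to ``reference``.

    Positive dx means the moving image content sits ``dx`` pixels to the
    right of the reference (i.e. translating moving by −dx re-aligns it).
    Found from the FFT cross-correlation peak with a 3-point parabolic fit
    per axis; the peak must lie within ``max_drift_px`` (default: a quarter
    of the smaller image dimension) of zero shift.
    """
    if moving.shape != reference.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {reference.shape}")
    nr, nc = moving.shape
    if max_drift_px is None:
        max_drift_px = min(nr, nc) / 4.0
    a = reference.pixels - reference.pixels.mean()
    b = moving.pixels - moving.pixels.mean()
    corr = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    corr = np.fft.fftshift(corr)
    rows = np.fft.fftshift(np.fft.fftfreq(nr) * nr)
    cols = np.fft.fftshift(np.fft.fftfreq(nc) * nc)
    i, j = np.unravel_index(np.argmax(corr), corr.shape)
    dy_int, dx_int = rows[i], cols[j]
    if abs(dy_int) > max_drift_px or abs(dx_int) > max_drift_px:
        raise ValueError(
            f"drift exceeds max_drift_px={max_drift_px}: correlation peak at "
            f"({dx_int}, {dy_int}) px is outside the search window"
        )
    dy = dy_int + _parabolic_offset(
        corr[(i - 1) % nr, j], corr[i, j], corr[(i + 1) % nr, j]
    )
    dx = dx_int + _parabolic_offset(
        corr[i, (j - 1) % nc], corr[i, j], corr[i, (j + 1) % nc]
    )
    return float(dx), float(dy)


@dataclass
class DriftTrace:
    """Per-frame sub-pixel shifts plus the single global crop box.

    ``crop_box`` is half-open pixel bounds (row0, row1, col0, col1): the
    original frame minus ``ceil(max |shift|)`` margins on the corresponding
    sides, so that every translated frame is fully defined inside it.
    """

    shifts_px: np.ndarray  # (n_t, 2) as (dx, dy)
    crop_box: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        self.shifts_px = np.asarray(self.shifts_px, dtype=np.float64).reshape(-1, 2)

    @property
    def max_abs_shift(self) -> float:
        return float(np.abs(self.shifts_px).max()) if len(self.shifts_px) else 0.0


def build_drift_trace(series: list[GridImage], reference: GridImage, max_drift_px: float | None = None) -> DriftTrace:
    """Estimate per-frame drift of a bead series against the reference and
    derive the common crop box."""
    shifts = np.array([estimate_shift(f, reference, max_drift_px) for f in series])
    nr, nc = reference.shape
    if len(shifts):
        mx = int(np.ceil(np.abs(shifts[:, 0]).max()))
        my = int(np.ceil(np.abs(shifts[:, 1]).max()))
    else:
        mx = my = 0
    crop = (my, nr - my, mx, nc - mx)
    if crop[0] >= crop[1] or crop[2] >= crop[3]:
        raise ValueError("drift so large that no common crop region remains")
    return DriftTrace(shifts_px=shifts, crop_box=crop)


def apply_drift_correction(series: list[GridImage], trace: DriftTrace) -> list[GridImage]:
    """Translate each frame by −shift (bilinear interpolation) and crop all
    frames to the trace's crop box.

    The same trace must be applied to every channel of one position — the
    correction is computed once on the bead channel and reused, which keeps
    channels registered by construction.
    """
    if len(series) != len(trace.shifts_px):
        raise ValueError(
            f"trace has {len(trace.shifts_px)} shifts but series has {len(series)} frames"
        )
    r0, r1, c0, c1 = trace.crop_box
    out = []
    for img, (dx, dy) in zip(series, trace.shifts_px):
        # ndimage.shift(input, s) moves content by +s; undo the drift with -shift
        moved = ndimage.shift(img.pixels, (-dy, -dx), order=1, mode="nearest")
        g = GridImage(
            moved[r0:r1, c0:c1],
            img.pixel_size_um,
            channel_tag=img.channel_tag,
            t_index=img.t_index,
            z_index=img.z_index,
        )
        out.append(g)
    return out


def crop_only(img: GridImage, trace: DriftTrace) -> GridImage:
    """Crop an un-drifted image (e.g. the reference) to the trace's crop box."""
    r0, r1, c0, c1 = trace.crop_box
    return GridImage(img.pixels[r0:r1, c0:c1], img.pixel_size_um, channel_tag=img.channel_tag,
                     t_index=img.t_index, z_index=img.z_index)
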