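"""ROI displacement tracking by zero-normalized cross-correlation.

The core of the contraction-quantification pipeline: a template cropped
from a reference frame is matched against every frame of the movie within
a bounded search window.  Zero-normalized cross-correlation (mean
subtracted, variance normalized) is used because brightfield illumination
drifts; the integer peak is refined to subpixel precision by a separable
three-point quadratic fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import match_template

from .io import ImageStack, RoiSpec


@dataclass(frozen=True)
class TrackingParams:
    search_radius: int = 15  # px, must exceed the expected peak displacement
    subpixel: bool = True
    reference: str = "first_frame"  # or "quiescent_auto"
    min_correlation: float = 0.5
    quiescent_window: int = 25  # frames, for reference="quiescent_auto"

    def __post_init__(self):
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1 px")
        if not (0 < self.min_correlation < 1):
            raise ValueError("min_correlation must lie in (0, 1)")
        if self.reference not in ("first_frame", "quiescent_auto"):
            raise ValueError(f"unknown reference mode {self.reference!r}")


@dataclass
class DisplacementTrace:
    """Per-frame 2D displacement of one ROI relative to a reference frame."""

    dx_um: np.ndarray
    dy_um: np.ndarray
    score: np.ndarray  # peak ZNCC per frame, in [-1, 1]
    ref_index: int
    roi: RoiSpec
    pixel_size: float
    frame_interval: float
    border_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def __post_init__(self):
        n = len(self.dx_um)
        if not (len(self.dy_um) == len(self.score) == n):
            raise ValueError("trace arrays must share one length")
        if self.border_flags.size == 0:
            self.border_flags = np.zeros(n, bool)

    def __len__(self) -> int:
        return len(self.dx_um)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_interval

    def axial(self, axis_angle_deg: float) -> np.ndarray:
        """Displacement component along a given axis direction, um."""
        a = np.deg2rad(axis_angle_deg)
        return self.dx_um * np.cos(a) + self.dy_um * np.sin(a)

    def transverse(self, axis_angle_deg: float) -> np.ndarray:
        a = np.deg2rad(axis_angle_deg)
        return -self.dx_um * np.sin(a) + self.dy_um * np.cos(a)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "t_s": self.times,
                "dx_um": self.dx_um,
                "dy_um": self.dy_um,
                "score": self.score,
            }
        )


def _quadratic_offset(cm, c0, cp) -> float:
    """Separable 3-point parabola vertex; clamped to +/-0.5 px."""
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:  # not a local max in this axis (flat/degenerate)
        return 0.0
    delta = 0.5 * (cm - cp) / denom
    return float(np.clip(delta, -0.5, 0.5))


def _match_frame(frame, template, roi, radius):
    """ZNCC of *template* against *frame* within +/-radius of the ROI centre.

    Returns the (2r+1, 2r+1) correlation surface whose centre element is
    the zero-displacement score.
    """
    r0, r1, c0, c1 = roi.bounds()
    w_r0, w_r1 = r0 - radius, r1 + radius
    w_c0, w_c1 = c0 - radius, c1 + radius
    if w_r0 < 0 or w_c0 < 0 or w_r1 > frame.shape[0] or w_c1 > frame.shape[1]:
        raise ValueError(
            f"search window for ROI {roi.label!r} (radius {radius} px) is "
            f"clipped by the frame edge"
        )
    window = frame[w_r0:w_r1, w_c0:w_c1]
    return match_template(window.astype(np.float64), template)


def track_roi(stack: ImageStack, roi: RoiSpec, params: TrackingParams | None = None) -> DisplacementTrace:
    """Track one ROI across all frames of *stack*.

    For each frame the displacement is the argmax of the zero-normalized
    cross-correlation between the reference-frame template and the frame,
    searched within ``+/-search_radius`` px, refined to subpixel precision
    when ``params.subpixel``.  Displacements are reported in micrometres;
    the per-frame peak correlation is recorded as a quality score.  Frames
    whose correlation peak sits on the search-window border are flagged
    (the search radius is likely too small).
    """
    params = params or TrackingParams()
    frames = stack.frames
    ref_index = 0
    if params.reference == "quiescent_auto":
        ref_index = _quiescent_reference(stack, roi, params)

    r0, r1, c0, c1 = roi.bounds()
    template = frames[ref_index, r0:r1, c0:c1].astype(np.float64)
    if template.std() == 0:
        raise ValueError("reference template has zero variance; nothing to track")

    n = stack.n_frames
    rad = params.search_radius
    dx = np.zeros(n)
    dy = np.zeros(n)
    score = np.zeros(n)
    border = np.zeros(n, bool)
    for t in range(n):
        corr = _match_frame(frames[t], template, roi, rad)
        pk = np.unravel_index(int(np.argmax(corr)), corr.shape)
        score[t] = float(np.clip(corr[pk], -1.0, 1.0))
        on_border = (
            pk[0] == 0 or pk[1] == 0 or pk[0] == corr.shape[0] - 1 or pk[1] == corr.shape[1] - 1
        )
        border[t] = on_border
        sub_r = sub_c = 0.0
        if params.subpixel and not on_border:
            sub_r = _quadratic_offset(corr[pk[0] - 1, pk[1]], corr[pk], corr[pk[0] + 1, pk[1]])
            sub_c = _quadratic_offset(corr[pk[0], pk[1] - 1], corr[pk], corr[pk[0], pk[1] + 1])
        dy[t] = (pk[0] - rad + sub_r) * stack.pixel_size
        dx[t] = (pk[1] - rad + sub_c) * stack.pixel_size

    # re-reference so displacement at the reference frame is exactly zero
    dx -= dx[ref_index]
    dy -= dy[ref_index]
    return DisplacementTrace(
        dx_um=dx,
        dy_um=dy,
        score=score,
        ref_index=ref_index,
        roi=roi,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        border_flags=border,
    )


def _quiescent_reference(stack: ImageStack, roi: RoiSpec, params: TrackingParams) -> int:
    """Pick the frame at the centre of the window with least ROI motion.

    Spontaneously beating tissues may start a movie mid-beat, so "first
    frame" is not always at rest.  A quick integer-precision pre-track
    against frame 0 gives a motion estimate; the reference is the centre of
    the rolling window minimizing total frame-to-frame motion.
    """
    quick = TrackingParams(
        search_radius=params.search_radius,
        subpixel=False,
        reference="first_frame",
        min_correlation=params.min_correlation,
    )
    pre = track_roi(stack, roi, quick)
    speed = np.hypot(np.diff(pre.dx_um, prepend=pre.dx_um[0]), np.diff(pre.dy_um, prepend=pre.dy_um[0]))
    w = min(params.quiescent_window, len(speed))
    rolling = np.convolve(speed, np.ones(w), mode="valid")
    return int(np.argmin(rolling)) + w // 2


def symmetry_index(
    prox: DisplacementTrace,
    dist: DisplacementTrace,
    axis_angle_deg: float,
    noise_floor_um: float = 0.05,
) -> np.ndarray:
    """Per-frame symmetrical-motion index in [0, 1] (NaN below noise floor).

    With ``a_p``/``a_d`` the long-axis displacement components of the two
    ROIs, the index is ``|a_p + a_d| / (|a_p| + |a_d|)``: 0 for perfectly
    opposing (contractile) motion, 1 for common-mode rigid translation.
    """
    if len(prox) != len(dist):
        raise ValueError("traces must have the same length")
    a_p = prox.axial(axis_angle_deg)
    a_d = dist.axial(axis_angle_deg)
    denom = np.abs(a_p) + np.abs(a_d)
    out = np.full(len(prox), np.nan)
    ok = denom > noise_floor_um
    out[ok] = np.abs(a_p[ok] + a_d[ok]) / denom[ok]
    return out


@dataclass(frozen=True)
class QCResult:
    accepted: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.accepted


def qc_trace(
    prox: DisplacementTrace,
    dist: DisplacementTrace,
    axis_angle_deg: float,
    params: TrackingParams | None = None,
    symmetry_cutoff: float = 0.5,
    transverse_frac: float = 0.5,
    noise_floor_um: float = 0.05,
) -> QCResult:
    """Accept or reject a tracked ROI pair, with enumerated reasons.

    Rejection criteria: any frame correlating below ``min_correlation``;
    median symmetry index over moving frames above ``symmetry_cutoff``
    (common-mode / rigid motion); peak transverse displacement exceeding
    ``transverse_frac`` of the peak axial displacement (off-axis motion).
    """
    params = params or TrackingParams()
    reasons: list[str] = []
    for trace in (prox, dist):
        bad = np.flatnonzero(trace.score < params.min_correlation)
        if bad.size:
            reasons.append(
                f"low correlation at frame {int(bad[0])} "
                f"({trace.roi.label}, score {trace.score[bad[0]]:.2f})"
            )
        if trace.border_flags.any():
            k = int(np.flatnonzero(trace.border_flags)[0])
            reasons.append(f"correlation peak on search border at frame {k} ({trace.roi.label})")

    sym = symmetry_index(prox, dist, axis_angle_deg, noise_floor_um)
    moving = np.isfinite(sym)
    if moving.any():
        med = float(np.median(sym[moving]))
        if med > symmetry_cutoff:
            reasons.append(
                f"asymmetric/common-mode motion (median symmetry index {med:.2f} "
                f"> {symmetry_cutoff})"
            )
    axial_peak = max(
        np.abs(prox.axial(axis_angle_deg)).max(), np.abs(dist.axial(axis_angle_deg)).max()
    )
    trans_peak = max(
        np.abs(prox.transverse(axis_angle_deg)).max(),
        np.abs(dist.transverse(axis_angle_deg)).max(),
    )
    if axial_peak > noise_floor_um and trans_peak > transverse_frac * axial_peak:
        reasons.append(
            f"transverse motion {trans_peak:.2f} um exceeds "
            f"{transverse_frac:.0%} of axial {axial_peak:.2f} um"
        )
    return QCResult(accepted=not reasons, reasons=tuple(reasons))
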