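"""Fractional-shortening waveforms, beat segmentation and kinetic parameters.

A tracked proximal/distal ROI pair defines an inter-ROI axial length
``L(t)``; fractional shortening is ``fs(t) = (L0 - L(t)) / L0`` with the
resting length ``L0`` estimated from the quiescent baseline.  Beats are
detected as prominent fs peaks, aligned on their upstroke half-maximum
crossing, and merged; kinetic parameters (contraction/relaxation
velocities at 20/50/80% of peak shortening, peak acceleration,
deceleration time, relaxation time, frequency) are extracted from the
merged beat and, for per-beat standard deviations, from every beat.

Velocities are normalized, d(fs)/dt in 1/s, which makes them independent
of bundle geometry; absolute um/s values follow by multiplying with L0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .tracking import DisplacementTrace

KINETICS_COLUMNS = [
    "tissue_id",
    "max_fs",
    "v_con_20",
    "v_con_50",
    "v_con_80",
    "v_rel_80",
    "v_rel_50",
    "v_rel_20",
    "peak_acceleration",
    "deceleration_time",
    "relaxation_time",
    "frequency",
    "n_beats",
    "L0_um",
    "max_fs_sd",
    "v_con_20_sd",
    "v_con_50_sd",
    "v_con_80_sd",
    "v_rel_80_sd",
    "v_rel_50_sd",
    "v_rel_20_sd",
    "peak_acceleration_sd",
    "deceleration_time_sd",
    "relaxation_time_sd",
]

_PARAMS = [
    "max_fs",
    "v_con_20",
    "v_con_50",
    "v_con_80",
    "v_rel_80",
    "v_rel_50",
    "v_rel_20",
    "peak_acceleration",
    "deceleration_time",
    "relaxation_time",
]


@dataclass(frozen=True)
class ShorteningWaveform:
    """Fractional shortening vs. time for one bundle."""

    time: np.ndarray  # s
    fs: np.ndarray  # dimensionless, ~0 at rest
    L0: float  # resting inter-ROI axial separation, um

    def __post_init__(self):
        if len(self.time) != len(self.fs):
            raise ValueError("time and fs must have equal length")
        if not (self.L0 > 0):
            raise ValueError("L0 must be positive")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else math.nan


@dataclass
class BeatSet:
    """Segmented, aligned and merged beats from one waveform."""

    windows: list[tuple[int, int]]  # half-open index windows into the source
    rel_time: np.ndarray  # common time grid relative to alignment point, s
    beats: np.ndarray  # (n_beats, len(rel_time)) aligned fs
    merged: np.ndarray  # pointwise mean across beats
    ci_low: np.ndarray  # mean - 1.96 SEM
    ci_high: np.ndarray
    frequency: float  # Hz; NaN with < 2 beats
    L0: float
    reason: str = ""  # why empty, when n_beats == 0

    @property
    def n_beats(self) -> int:
        return len(self.windows)

    @property
    def dt(self) -> float:
        return float(self.rel_time[1] - self.rel_time[0]) if len(self.rel_time) > 1 else math.nan


@dataclass
class KineticsSummary:
    """Scalar contractile parameters for one bundle (merged-beat values)."""

    tissue_id: str
    max_fs: float
    v_con_20: float
    v_con_50: float
    v_con_80: float
    v_rel_80: float
    v_rel_50: float
    v_rel_20: float
    peak_acceleration: float
    deceleration_time: float
    relaxation_time: float
    frequency: float
    n_beats: int
    L0_um: float
    sd: dict = field(default_factory=dict)  # per-parameter SD across beats

    @property
    def max_fs_pct(self) -> float:
        return 100.0 * self.max_fs

    def absolute(self, name: str) -> float:
        """Velocity/acceleration parameter scaled to um/s (um/s^2)."""
        return getattr(self, name) * self.L0_um

    def as_dict(self) -> dict:
        d = {"tissue_id": self.tissue_id}
        for p in _PARAMS:
            d[p] = getattr(self, p)
        d["frequency"] = self.frequency
        d["n_beats"] = self.n_beats
        d["L0_um"] = self.L0_um
        for p in _PARAMS:
            d[p + "_sd"] = self.sd.get(p, math.nan)
        return d


def build_waveform(
    prox: DisplacementTrace,
    dist: DisplacementTrace,
    axis_angle_deg: float | None = None,
    baseline_percentile: float = 90.0,
) -> ShorteningWaveform:
    """Convert a QC-accepted ROI trace pair into a shortening waveform.

    ``L(t)`` is the centre-to-centre separation plus the difference of the
    axial displacement components.  The resting length ``L0`` is a high
    percentile of ``L(t)`` (the tissue is longest at rest), which is robust
    when the movie never shows a fully quiescent frame.
    """
    if len(prox) != len(dist):
        raise ValueError("traces must have the same length")
    d_px = np.subtract(dist.roi.center, prox.roi.center)
    if axis_angle_deg is None:
        axis_angle_deg = float(np.rad2deg(np.arctan2(d_px[1], d_px[0])))
    a = np.deg2rad(axis_angle_deg)
    sep0 = float((d_px[0] * np.cos(a) + d_px[1] * np.sin(a)) * prox.pixel_size)
    L = sep0 + dist.axial(axis_angle_deg) - prox.axial(axis_angle_deg)
    if np.any(L <= 0):
        raise ValueError("non-positive inter-ROI length; tracking failure")
    L0 = float(np.percentile(L, baseline_percentile))
    fs = (L0 - L) / L0
    return ShorteningWaveform(time=prox.times, fs=fs, L0=L0)


def segment_and_merge(
    waveform: ShorteningWaveform,
    prominence_frac: float = 0.5,
    min_spacing_s: float = 0.3,
    noise_floor: float = 2e-3,
) -> BeatSet:
    """Detect beats, align them on the upstroke half-maximum, and merge.

    Peaks must have prominence of at least ``prominence_frac`` of the
    global fs maximum and be separated by ``min_spacing_s``.  Each beat is
    windowed between the fs minima flanking its peak.  The merged waveform
    is the pointwise mean over beats with a 95% confidence band
    (mean +/- 1.96 SEM).  Beat frequency is ``(n-1) / span of peak times``.
    """
    fs = np.asarray(waveform.fs, float)
    t = np.asarray(waveform.time, float)
    dt = waveform.dt
    empty = BeatSet(
        windows=[],
        rel_time=np.zeros(0),
        beats=np.zeros((0, 0)),
        merged=np.zeros(0),
        ci_low=np.zeros(0),
        ci_high=np.zeros(0),
        frequency=math.nan,
        L0=waveform.L0,
    )
    amp = float(fs.max())
    if amp < noise_floor:
        empty.reason = f"no contraction above noise floor (max fs {amp:.2g})"
        return empty
    distance = max(1, int(round(min_spacing_s / dt)))
    peaks, _ = find_peaks(fs, prominence=prominence_frac * amp, distance=distance)
    if peaks.size == 0:
        empty.reason = "no fs peaks at the requested prominence"
        return empty

    # window each beat between the local minima flanking its peak
    bounds = np.concatenate(([0], peaks, [len(fs) - 1]))
    windows: list[tuple[int, int]] = []
    aligns: list[float] = []
    for i, pk in enumerate(peaks):
        lo = bounds[i] + int(np.argmin(fs[bounds[i] : pk + 1]))
        hi = pk + int(np.argmin(fs[pk : bounds[i + 2] + 1]))
        if hi <= lo:
            continue
        base = fs[lo]
        half = base + 0.5 * (fs[pk] - base)
        seg = fs[lo : pk + 1]
        above = np.flatnonzero(seg >= half)
        if above.size == 0:
            continue
        j = above[0]
        if j == 0:
            t_half = t[lo]
        else:  # linear interpolation of the upstroke crossing
            f0, f1 = seg[j - 1], seg[j]
            t_half = t[lo + j - 1] + dt * (half - f0) / (f1 - f0)
        windows.append((lo, hi + 1))
        aligns.append(t_half)

    if not windows:
        empty.reason = "no well-formed beat windows"
        return empty

    rel_lo = max(t[w[0]] - a for w, a in zip(windows, aligns))
    rel_hi = min(t[w[1] - 1] - a for w, a in zip(windows, aligns))
    n_pts = int(np.floor((rel_hi - rel_lo) / dt)) + 1
    if n_pts < 5:
        empty.reason = "aligned beat overlap too short"
        return empty
    rel_time = rel_lo + np.arange(n_pts) * dt
    beats = np.vstack(
        [
            np.interp(rel_time + a, t[w[0] : w[1]], fs[w[0] : w[1]])
            for w, a in zip(windows, aligns)
        ]
    )
    merged = beats.mean(axis=0)
    if len(windows) > 1:
        sem = beats.std(axis=0, ddof=1) / np.sqrt(len(windows))
        freq = float((len(peaks) - 1) / (t[peaks[-1]] - t[peaks[0]]))
    else:
        sem = np.zeros_like(merged)
        freq = math.nan
    return BeatSet(
        windows=windows,
        rel_time=rel_time,
        beats=beats,
        merged=merged,
        ci_low=merged - 1.96 * sem,
        ci_high=merged + 1.96 * sem,
        frequency=freq,
        L0=waveform.L0,
    )


def _crossing_time(t, y, level, rising_first):
    """First (rising) or last (falling) time y crosses *level*, interpolated."""
    above = y >= level
    if rising_first:
        idx = np.flatnonzero(above)
        if idx.size == 0:
            return math.nan
        j = idx[0]
        if j == 0:
            return float(t[0])
        f0, f1 = y[j - 1], y[j]
    else:
        idx = np.flatnonzero(above)
        if idx.size == 0:
            return math.nan
        j = idx[-1]
        if j == len(y) - 1:
            return float(t[-1])
        f0, f1 = y[j], y[j + 1]
        return float(t[j] + (t[j + 1] - t[j]) * (f0 - level) / (f0 - f1))
    return float(t[j - 1] + (t[j] - t[j - 1]) * (level - f0) / (f1 - f0))


def _extract_single(t, fs, dt, smooth_window, smooth_order, decel_tol, relax_recovery):
    """Kinetic parameters from one (merged or single) aligned beat."""
    if len(fs) < smooth_window:
        raise ValueError(
            f"beat of {len(fs)} samples is shorter than the smoothing window {smooth_window}"
        )
    v = savgol_filter(fs, smooth_window, smooth_order, deriv=1, delta=dt)
    acc = savgol_filter(fs, smooth_window, smooth_order, deriv=2, delta=dt)
    i_pk = int(np.argmax(fs))
    base = float(min(fs[0], fs[-1]))
    amp = float(fs[i_pk] - base)
    out = {"max_fs": amp}

    t_con, fs_con, v_con = t[: i_pk + 1], fs[: i_pk + 1], v[: i_pk + 1]
    t_rel, fs_rel = t[i_pk:], fs[i_pk:]
    speed = np.abs(v)
    for pct, name_c, name_r in (
        (0.2, "v_con_20", "v_rel_20"),
        (0.5, "v_con_50", "v_rel_50"),
        (0.8, "v_con_80", "v_rel_80"),
    ):
        level = base + pct * amp
        tc = _crossing_time(t_con, fs_con, level, rising_first=True)
        out[name_c] = float(np.interp(tc, t, speed)) if np.isfinite(tc) else math.nan
        tr = _crossing_time(t_rel, fs_rel, level, rising_first=False)
        out[name_r] = float(np.interp(tr, t, speed)) if np.isfinite(tr) else math.nan

    out["peak_acceleration"] = float(acc[: i_pk + 1].max()) if i_pk >= 1 else math.nan

    # deceleration time: the contraction-velocity plateau defines the linear
    # contractile slope; onset is where velocity drops below (1 - tol) of it
    if i_pk >= 2:
        v_max = float(v_con.max())
        i_vmax = int(np.argmax(v_con))
        plateau = float(v_con[v_con >= 0.95 * v_max].mean())
        tail = v_con[i_vmax:]
        below = np.flatnonzero(tail < (1.0 - decel_tol) * plateau)
        if below.size:
            j = i_vmax + below[0]
            out["deceleration_time"] = float(t_con[i_pk] - t_con[j])
        else:
            out["deceleration_time"] = float(t_con[i_pk] - t_con[i_vmax])
    else:
        out["deceleration_time"] = math.nan

    # relaxation time: fs peak -> recovery of `relax_recovery` of the amplitude
    level = base + (1.0 - relax_recovery) * amp
    drop = np.flatnonzero(fs_rel <= level)
    if drop.size:
        j = drop[0]
        if j == 0:
            out["relaxation_time"] = 0.0
        else:
            f0, f1 = fs_rel[j - 1], fs_rel[j]
            t_x = t_rel[j - 1] + dt * (f0 - level) / (f0 - f1)
            out["relaxation_time"] = float(t_x - t_rel[0])
    else:
        out["relaxation_time"] = math.nan
    return out


def extract_kinetics(
    beats: BeatSet,
    tissue_id: str = "tissue0",
    smooth_window: int = 5,
    smooth_order: int = 3,
    decel_tol: float = 0.10,
    relax_recovery: float = 0.90,
) -> KineticsSummary:
    """Extract the contractile parameter set from a merged beat.

    Derivatives are taken by Savitzky-Golay filtering (default 5-sample
    window, order 3 at 50 fps — wider windows bias the second derivative
    at the rest-to-contraction corner; the choice is configurable and
    recorded with exported tables).
    Per-beat standard deviations come from applying the same extraction to
    every aligned beat.
    """
    if beats.n_beats < 1:
        raise ValueError(f"no beats to extract from: {beats.reason}")
    t, dt = beats.rel_time, beats.dt
    merged = _extract_single(
        t, beats.merged, dt, smooth_window, smooth_order, decel_tol, relax_recovery
    )
    per_beat: dict[str, list[float]] = {p: [] for p in _PARAMS}
    for row in beats.beats:
        try:
            one = _extract_single(t, row, dt, smooth_window, smooth_order, decel_tol, relax_recovery)
        except ValueError:
            continue
        for p in _PARAMS:
            per_beat[p].append(one[p])
    sd = {
        p: float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else math.nan
        for p, vals in per_beat.items()
    }
    return KineticsSummary(
        tissue_id=tissue_id,
        frequency=beats.frequency,
        n_beats=beats.n_beats,
        L0_um=beats.L0,
        sd=sd,
        **merged,
    )


def kinetics_from_waveform(waveform: ShorteningWaveform, tissue_id: str = "tissue0", **kwargs) -> KineticsSummary:
    """Convenience: segment, merge and extract in one call."""
    seg_keys = {"prominence_frac", "min_spacing_s", "noise_floor"}
    seg_kwargs = {k: v for k, v in kwargs.items() if k in seg_keys}
    ext_kwargs = {k: v for k, v in kwargs.items() if k not in seg_keys}
    beats = segment_and_merge(waveform, **seg_kwargs)
    return extract_kinetics(beats, tissue_id=tissue_id, **ext_kwargs)


def drug_response(before: KineticsSummary, after: KineticsSummary) -> dict:
    """Per-parameter fold change (after/before) for one paired tissue.

    Parameters with a zero or non-finite baseline are reported as NaN and
    listed under ``"undefined"`` rather than silently dropped.
    """
    folds: dict[str, float] = {}
    undefined: list[str] = []
    for p in _PARAMS + ["frequency"]:
        b = getattr(before, p)
        a = getattr(after, p)
        if not np.isfinite(b) or b == 0:
            folds[p] = math.nan
            undefined.append(p)
        else:
            folds[p] = float(a / b)
    folds["undefined"] = undefined  # type: ignore[assignment]
    return folds


def summarize_folds(fold_dicts: list[dict]) -> dict:
    """Batch mean +/- SD of fold changes across paired tissues."""
    params = [k for k in fold_dicts[0] if k != "undefined"]
    out = {}
    for p in params:
        vals = np.array([d[p] for d in fold_dicts], float)
        ok = np.isfinite(vals)
        out[p] = {
            "mean_fold": float(vals[ok].mean()) if ok.any() else math.nan,
            "sd_fold": float(vals[ok].std(ddof=1)) if ok.sum() > 1 else math.nan,
            "n": int(ok.sum()),
        }
    return out
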