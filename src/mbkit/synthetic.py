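"""Seeded generators for contraction movies and structure images.

Every generator is a pure function of its parameters and seed: identical
inputs give bit-identical outputs, and the imposed ground truth (strain
waveform, drawn sarcomere angles, stripe layout) is returned alongside the
pixels so downstream modules can be validated without external data.

The contraction generator emulates brightfield acquisition of a
rectangular bundle contracting uniaxially: a band-limited random texture
confined to the tissue footprint is warped each frame by the uniform
axial-strain displacement field ``u(x, t) = -eps(t) * (x - x_c)`` using
high-order spline resampling, so imposed subpixel shifts are exact and
serve as the reference standard for tracking accuracy.  Optics are not
modelled (no PSF or shot-noise physics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .io import ImageStack, TissueGeometry

DEFAULT_GEOMETRY = TissueGeometry(center=(165.0, 50.0), long_axis_angle=0.0, length=308.0, width=45.0)


# ---------------------------------------------------------------------------
# contraction movies

@dataclass(frozen=True)
class ContractionGroundTruth:
    """Imposed contraction parameters for one synthetic bundle."""

    fs_max: float = 0.05  # peak fractional shortening
    frequency_hz: float = 0.4
    contraction_s: float = 0.5  # upstroke duration
    relaxation_s: float = 0.5
    waveform: str = "raised_cosine"  # or "two_sigmoid"
    noise_sd: float = 0.02  # additive noise, fraction of texture contrast
    drift_um_per_s: float = 0.0
    common_mode_um: float = 0.0  # rigid translation synchronized with the beat
    texture_contrast: float = 30.0
    texture_corr_um: float = 2.0  # texture correlation length

    def __post_init__(self):
        if not (0 <= self.fs_max <= 0.2):
            raise ValueError("fs_max must lie in [0, 0.2]")
        if self.contraction_s <= 0 or self.relaxation_s <= 0:
            raise ValueError("durations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.waveform not in ("raised_cosine", "two_sigmoid"):
            raise ValueError(f"unknown waveform family {self.waveform!r}")


def strain_waveform(truth: ContractionGroundTruth, times: np.ndarray) -> np.ndarray:
    """Imposed fractional shortening eps(t) over the movie, periodic beats."""
    t = np.asarray(times, float)
    if truth.fs_max == 0 or truth.frequency_hz == 0:
        return np.zeros_like(t)
    period = 1.0 / truth.frequency_hz
    s = np.mod(t, period)
    tc, tr = truth.contraction_s, truth.relaxation_s
    eps = np.zeros_like(t)
    if truth.waveform == "raised_cosine":
        con = s < tc
        eps[con] = 0.5 * (1.0 - np.cos(np.pi * s[con] / tc))
        rel = (s >= tc) & (s < tc + tr)
        eps[rel] = 0.5 * (1.0 + np.cos(np.pi * (s[rel] - tc) / tr))
    else:  # two_sigmoid: logistic upstroke times logistic recovery
        k_c, k_r = 10.0 / tc, 10.0 / tr
        up = 1.0 / (1.0 + np.exp(-k_c * (s - 0.5 * tc)))
        down = 1.0 / (1.0 + np.exp(k_r * (s - tc - 0.5 * tr)))
        eps = up * down
        eps -= eps.min()
        eps /= eps.max()
    return truth.fs_max * eps


def _tissue_mask(shape, geometry: TissueGeometry, pixel_size: float) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = cols * pixel_size - geometry.center[0]
    y = rows * pixel_size - geometry.center[1]
    ux, uy = geometry.axis_unit
    a = x * ux + y * uy
    tv = -x * uy + y * ux
    return (np.abs(a) <= geometry.length / 2) & (np.abs(tv) <= geometry.width / 2)


def _base_texture(shape, geometry, pixel_size, truth, rng, background=100.0):
    noise = rng.standard_normal(shape)
    tex = gaussian_filter(noise, truth.texture_corr_um / pixel_size)
    sd = tex.std()
    if sd > 0:
        tex *= truth.texture_contrast / sd
    return background + tex * _tissue_mask(shape, geometry, pixel_size)


def gen_contraction_movie(
    truth: ContractionGroundTruth,
    geometry: TissueGeometry = DEFAULT_GEOMETRY,
    pixel_size: float = 0.1625,
    fps: float = 50.0,
    duration_s: float = 20.0,
    fov_um: tuple[float, float] = (330.0, 100.0),
    seed: int = 0,
) -> tuple[ImageStack, dict]:
    """Render a contracting-bundle movie plus its ground-truth record.

    Returns ``(stack, record)`` where ``record`` carries the imposed
    strain waveform per frame and everything needed to predict any
    material-point displacement analytically.
    """
    shape = (int(round(fov_um[1] / pixel_size)), int(round(fov_um[0] / pixel_size)))
    # tissue must stay inside the field of view even at peak shortening
    half = np.abs(geometry.axis_unit) * geometry.length / 2 + np.abs(
        np.array([-geometry.axis_unit[1], geometry.axis_unit[0]])
    ) * geometry.width / 2
    lo = np.asarray(geometry.center) - half
    hi = np.asarray(geometry.center) + half
    if lo.min() < 0 or hi[0] > fov_um[0] or hi[1] > fov_um[1]:
        raise ValueError("tissue geometry does not fit inside the field of view")

    rng = np.random.default_rng(seed)
    base = _base_texture(shape, geometry, pixel_size, truth, rng)
    n_frames = int(round(duration_s * fps))
    times = np.arange(n_frames) / fps
    eps = strain_waveform(truth, times)

    cx = geometry.center[0] / pixel_size
    cy = geometry.center[1] / pixel_size
    ux, uy = geometry.axis_unit
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    xr = cols - cx
    yr = rows - cy
    a_dst = xr * ux + yr * uy  # axial/transverse px coords about the centre
    t_dst = -xr * uy + yr * ux

    frames = np.empty((n_frames,) + shape, np.float32)
    for k in range(n_frames):
        shift_px = (
            truth.common_mode_um * (eps[k] / truth.fs_max if truth.fs_max else 0.0)
            + truth.drift_um_per_s * times[k]
        ) / pixel_size
        a_src = (a_dst - shift_px) / (1.0 - eps[k])  # exact inverse of the warp
        src_cols = cx + a_src * ux - t_dst * uy
        src_rows = cy + a_src * uy + t_dst * ux
        frame = map_coordinates(base, [src_rows, src_cols], order=3, mode="nearest")
        if truth.noise_sd > 0:
            frame = frame + rng.normal(
                0.0, truth.noise_sd * truth.texture_contrast, size=shape
            )
        frames[k] = frame.astype(np.float32)

    stack = ImageStack(frames, pixel_size=pixel_size, frame_interval=1.0 / fps)
    record = {
        "truth": truth,
        "geometry": geometry,
        "seed": seed,
        "times_s": times,
        "eps": eps,
        "pixel_size": pixel_size,
        "fps": fps,
    }
    return stack, record


def gen_monolayer_movie(
    n_domains: int = 8,
    base_truth: ContractionGroundTruth | None = None,
    fs_jitter_cv: float = 0.4,
    pixel_size: float = 0.1625,
    fps: float = 50.0,
    duration_s: float = 20.0,
    fov_um: tuple[float, float] = (330.0, 100.0),
    seed: int = 0,
) -> tuple[ImageStack, list[dict]]:
    """Nonpatterned-monolayer surrogate: a grid of independently beating domains.

    The field of view is tiled by ``n_domains`` rectangular texture domains,
    each contracting along its own random direction with its own amplitude
    and phase — the disorganized counterpart to an aligned bundle, used to
    demonstrate the heterogeneity contrast between the two preparations.
    Domains tile the field exactly, so they never overlap.
    """
    base_truth = base_truth or ContractionGroundTruth()
    rng = np.random.default_rng(seed)
    # tile: as square a grid as divides n_domains
    nx = int(np.ceil(np.sqrt(n_domains * fov_um[0] / fov_um[1])))
    ny = int(np.ceil(n_domains / nx))
    w, h = fov_um[0] / nx, fov_um[1] / ny
    shape = (int(round(fov_um[1] / pixel_size)), int(round(fov_um[0] / pixel_size)))
    n_frames = int(round(duration_s * fps))
    times = np.arange(n_frames) / fps

    frames = np.full((n_frames,) + shape, 100.0, np.float32)
    records: list[dict] = []
    count = 0
    for iy in range(ny):
        for ix in range(nx):
            if count >= n_domains:
                break
            count += 1
            cx_um, cy_um = (ix + 0.5) * w, (iy + 0.5) * h
            angle = float(rng.uniform(-89.0, 90.0))
            fs = float(
                np.clip(base_truth.fs_max * (1.0 + fs_jitter_cv * rng.standard_normal()), 0.0, 0.2)
            )
            phase = float(rng.uniform(0, 1.0 / base_truth.frequency_hz))
            margin = 4.0  # um gap so neighbouring textures never collide
            # size the rotated domain so its bounding box fits its tile
            aspect = 7.0
            c_, s_ = abs(np.cos(np.deg2rad(angle))), abs(np.sin(np.deg2rad(angle)))
            L = min(
                (w - 2 * margin) / (c_ + s_ / aspect),
                (h - 2 * margin) / (s_ + c_ / aspect),
            )
            geo = TissueGeometry(
                center=(cx_um, cy_um),
                long_axis_angle=angle if -90 < angle <= 90 else 0.0,
                length=L,
                width=L / aspect,
            )
            truth = replace(base_truth, fs_max=fs)
            dom_seed = int(rng.integers(0, 2**31 - 1))
            drng = np.random.default_rng(dom_seed)
            base = _base_texture(shape, geo, pixel_size, truth, drng, background=0.0)
            eps = strain_waveform(truth, times + phase)
            cxp, cyp = cx_um / pixel_size, cy_um / pixel_size
            ux, uy = geo.axis_unit
            rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
            a_dst = (cols - cxp) * ux + (rows - cyp) * uy
            t_dst = -(cols - cxp) * uy + (rows - cyp) * ux
            for k in range(n_frames):
                a_src = a_dst / (1.0 - eps[k])
                sc = cxp + a_src * ux - t_dst * uy
                sr = cyp + a_src * uy + t_dst * ux
                frames[k] += map_coordinates(base, [sr, sc], order=3, mode="nearest").astype(
                    np.float32
                )
            records.append(
                {
                    "truth": truth,
                    "geometry": geo,
                    "seed": dom_seed,
                    "phase_s": phase,
                    "eps": eps,
                    "times_s": times,
                }
            )
    if base_truth.noise_sd > 0:
        frames += rng.normal(
            0.0, base_truth.noise_sd * base_truth.texture_contrast, size=frames.shape
        ).astype(np.float32)
    return ImageStack(frames, pixel_size=pixel_size, frame_interval=1.0 / fps), records


# ---------------------------------------------------------------------------
# structure images

@dataclass(frozen=True)
class StructureGroundTruth:
    """Parameters for synthetic striation / F-actin bundle images."""

    # striation kind
    spacing_um: float = 2.2  # sarcomere period along the myofibril axis
    orientation_mean_deg: float = 0.0  # relative to the tissue long axis
    orientation_sigma_deg: float = 5.0
    myofibril_width_um: float = 1.4
    myofibril_gap_um: float = 0.6
    segment_length_um: float = 15.4  # myofibril chain length (~7 sarcomeres)
    chain_coverage: float = 0.55  # fraction of tissue area covered by chains
    # factin_bundles kind
    stripe_widths_um: tuple | None = None
    stripe_gaps_um: tuple | None = None
    coverage: float | None = None  # draw a layout at this area fraction
    stripe_width_mean_um: float = 4.0
    stripe_width_sd_um: float = 1.0
    # shared
    background: float = 100.0
    amplitude: float = 80.0
    noise_sd: float = 4.0

    def __post_init__(self):
        if not (1.2 <= self.spacing_um <= 3.5):
            raise ValueError("spacing_um must lie in [1.2, 3.5]")
        if self.orientation_sigma_deg < 0:
            raise ValueError("orientation sigma must be >= 0")


def factin_layout(
    width_um: float,
    coverage: float,
    rng: np.random.Generator,
    width_mean_um: float = 4.0,
    width_sd_um: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw alternating stripe widths and gaps summing to the tissue width.

    ``n`` stripe widths are drawn around ``width_mean_um`` and rescaled so
    their total equals ``coverage * width_um``; the ``n + 1`` gaps share the
    remainder.  Used both for controlled-coverage fixtures and for
    realistic bundle layouts.
    """
    if not (0 < coverage < 1):
        raise ValueError("coverage must lie in (0, 1)")
    n = max(1, int(round(width_um * coverage / width_mean_um)))
    widths = np.clip(rng.normal(width_mean_um, width_sd_um, n), 0.3 * width_mean_um, None)
    widths *= coverage * width_um / widths.sum()
    gaps = rng.uniform(0.5, 1.5, n + 1)
    gaps *= (1.0 - coverage) * width_um / gaps.sum()
    return widths, gaps


def gen_structure_image(
    truth: StructureGroundTruth,
    geometry: TissueGeometry = DEFAULT_GEOMETRY,
    pixel_size: float = 0.2,
    kind: str = "striation",
    fov_um: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render a single-frame structure image with stored ground truth.

    ``kind="striation"`` draws per-myofibril striation gratings (period =
    sarcomere spacing) whose axis angles are drawn from
    ``N(orientation_mean, orientation_sigma)`` independently per myofibril
    segment; the realized draws are stored in the record, so recovery can
    be checked against the actually-rendered sample, not just the
    requested population parameters.  ``kind="factin_bundles"`` draws
    smooth-edged axial stripes of known widths and gaps.
    """
    if kind == "striation" and pixel_size * 4 > truth.spacing_um:
        raise ValueError(
            f"pixel size {pixel_size} um cannot resolve a {truth.spacing_um} um period "
            "(need >= 4 px per period)"
        )
    if fov_um is None:
        fov_um = (geometry.length + 22.0, geometry.width + 25.0)
        geometry = TissueGeometry(
            center=(fov_um[0] / 2, fov_um[1] / 2),
            long_axis_angle=geometry.long_axis_angle,
            length=geometry.length,
            width=geometry.width,
        )
    shape = (int(round(fov_um[1] / pixel_size)), int(round(fov_um[0] / pixel_size)))
    rng = np.random.default_rng(seed)

    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    x = cols * pixel_size - geometry.center[0]
    y = rows * pixel_size - geometry.center[1]
    ux, uy = geometry.axis_unit
    a = x * ux + y * uy  # axial um
    tv = -x * uy + y * ux  # transverse um
    inside = (np.abs(a) <= geometry.length / 2) & (np.abs(tv) <= geometry.width / 2)

    record: dict = {"truth": truth, "geometry": geometry, "seed": seed, "kind": kind}
    img = np.full(shape, truth.background)

    if kind == "striation":
        # Myofibrils are rendered as randomly placed short sarcomere
        # chains: each chain is a rotated rectangle carrying an exact
        # striation grating (period = spacing) and one angle draw from
        # N(mean, sigma).  Overlapping chains keep the brighter band, as a
        # maximum-intensity projection would.  Because every chain is
        # statistically identical apart from its angle, occlusion losses
        # are independent of the drawn angle, so the rendered angle sample
        # is an unbiased draw from the requested distribution; the drawn
        # angles are stored as the ground truth.
        p = truth.spacing_um
        n_sarc = max(3, int(round(truth.segment_length_um / p)))
        n_bands = 2 * ((n_sarc - 1) // 2) + 1  # odd band count, grating peak at centre
        half_len = (n_bands / 2) * p  # chain ends fall on grating troughs
        half_w = truth.myofibril_width_um / 2
        area = geometry.length * geometry.width
        n_chains = int(round(truth.chain_coverage * area / (2 * half_len * 2 * half_w)))
        centers_a = rng.uniform(-geometry.length / 2, geometry.length / 2, n_chains)
        centers_t = rng.uniform(-geometry.width / 2, geometry.width / 2, n_chains)
        theta = rng.normal(truth.orientation_mean_deg, truth.orientation_sigma_deg, n_chains)
        # per-chain brightness variation (labeling/focus differences); it
        # also lets one chain dominate where chains overlap, instead of a
        # fine interleaving of equal-brightness bands
        bright = np.clip(rng.normal(1.0, 0.25, n_chains), 0.4, 1.6)
        ramp = 0.3  # um, smooth shoulder standing in for optical blur
        fg = np.zeros(shape)
        for a_m, tau_k, th_deg, br in zip(centers_a, centers_t, theta, bright):
            th = np.deg2rad(th_deg)
            reach_a = half_len * abs(np.cos(th)) + half_w + 2 * ramp
            reach_t = half_len * abs(np.sin(th)) + half_w + 2 * ramp
            sel = (np.abs(a - a_m) <= reach_a) & (np.abs(tv - tau_k) <= reach_t)
            if not sel.any():
                continue
            da, dtv = a[sel] - a_m, tv[sel] - tau_k
            a_loc = da * np.cos(th) + dtv * np.sin(th)
            tv_loc = -da * np.sin(th) + dtv * np.cos(th)
            env = np.clip((half_w - np.abs(tv_loc)) / ramp + 0.5, 0.0, 1.0)
            env *= np.clip((half_len - np.abs(a_loc)) / ramp + 0.5, 0.0, 1.0)
            band = 0.5 * (1.0 + np.cos(2 * np.pi * a_loc / p))
            fg[sel] = np.maximum(fg[sel], br * truth.amplitude * band * env)
        img = img + fg * inside
        record["angles_deg"] = geometry.long_axis_angle + theta
        record["realized_sigma_deg"] = float(np.std(theta, ddof=1)) if theta.size > 1 else 0.0
        record["realized_mean_deg"] = float(geometry.long_axis_angle + theta.mean())
        record["spacing_um"] = truth.spacing_um
        record["n_chains"] = n_chains
    elif kind == "factin_bundles":
        if truth.stripe_widths_um is not None:
            widths = np.asarray(truth.stripe_widths_um, float)
            gaps = (
                np.asarray(truth.stripe_gaps_um, float)
                if truth.stripe_gaps_um is not None
                else np.full(len(widths) + 1, (geometry.width - widths.sum()) / (len(widths) + 1))
            )
        elif truth.coverage is not None:
            widths, gaps = factin_layout(
                geometry.width, truth.coverage, rng, truth.stripe_width_mean_um, truth.stripe_width_sd_um
            )
        else:
            raise ValueError("factin_bundles needs stripe_widths_um or coverage")
        if widths.sum() + gaps.sum() > geometry.width * 1.001:
            raise ValueError("stripe layout exceeds tissue width")
        # transverse indicator profile, smooth edged
        n_t = int(round(geometry.width / (0.25 * pixel_size)))
        tau_grid = np.linspace(-geometry.width / 2, geometry.width / 2, n_t)
        prof = np.zeros(n_t)
        pos = -geometry.width / 2
        edges = []
        for wd, gp in zip(widths, gaps):
            pos += gp
            edges.append((pos, pos + wd))
            prof[(tau_grid >= pos) & (tau_grid < pos + wd)] = 1.0
            pos += wd
        sigma_edge_um = 0.5
        prof = gaussian_filter(prof, sigma_edge_um / (tau_grid[1] - tau_grid[0]))
        img = img + truth.amplitude * np.interp(tv, tau_grid, prof, left=0, right=0) * inside
        record["stripe_widths_um"] = widths
        record["stripe_gaps_um"] = gaps
        record["stripe_edges_um"] = edges
        record["coverage"] = float(widths.sum() / geometry.width)
    else:
        raise ValueError(f"unknown structure kind {kind!r}")

    if truth.noise_sd > 0:
        img = img + rng.normal(0.0, truth.noise_sd, shape)
    return img, record
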