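"""Elastic coupling between a contracting bundle and a finite-thickness substrate.

A quasi-static linear model of a thin contractile tissue strip bonded to
the surface of a soft elastomer layer of thickness ``h`` on rigid glass.
The tissue is a membrane with axial stiffness ``E_tissue * t_tissue``
carrying an imposed contractile eigenstrain; the substrate surface
responds through a layer Green's function, represented here by the scalar
spectral kernel

    G(k) = 2 (1 - nu^2) tanh(k h) / (E k)

which reduces to the Boussinesq half-space response
``u = P (1 - nu^2) / (pi E r)`` as ``h -> inf`` and stiffens as the rigid
base is approached (``G -> 2 (1 - nu^2) h / E`` for ``k h << 1``).  Only
the axial displacement component is carried by this scalar surrogate;
transverse motion of a uniaxially contracting bundle is second order.
Tissue membrane equilibrium and the substrate response are solved
self-consistently as one linear system (matrix-free GMRES with FFT-applied
Green's function).

Units: um, kPa; forces in uN (1 kPa * um^2 = 1e-3 uN).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse.linalg import LinearOperator, lgmres

from .io import TissueGeometry

DEFAULT_TISSUE = TissueGeometry(center=(0.0, 0.0), long_axis_angle=0.0, length=308.0, width=45.0)


@dataclass(frozen=True)
class LayerModel:
    """Substrate + tissue description for the coupled elastic problem."""

    E_substrate: float = 8.0  # kPa (soft PDMS formulation)
    nu_substrate: float = 0.49  # near-incompressible elastomer
    thickness: float = 70.0  # um, elastomer layer on rigid glass
    E_tissue: float = 10.0  # kPa, in the cardiac-muscle range [8, 12]
    t_tissue: float = 8.0  # um, monolayer-scale tissue thickness
    geometry: TissueGeometry = DEFAULT_TISSUE
    eigenstrain: float = 0.05  # imposed axial contractile strain

    def __post_init__(self):
        if self.E_substrate <= 0 or self.E_tissue <= 0:
            raise ValueError("elastic moduli must be positive")
        if not (0 <= self.nu_substrate < 0.5):
            raise ValueError("nu must lie in [0, 0.5)")
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")
        if not (0 <= self.eigenstrain <= 0.2):
            raise ValueError("eigenstrain must lie in [0, 0.2]")


@dataclass
class Grid:
    """Regular surface grid centred on the tissue."""

    spacing: float = 4.0  # um
    margin_x: float = 280.0  # um beyond each tissue end
    margin_y: float = 120.0  # um beyond each tissue side

    def axes(self, geometry: TissueGeometry) -> tuple[np.ndarray, np.ndarray]:
        hx = geometry.length / 2 + self.margin_x
        hy = geometry.width / 2 + self.margin_y
        nx = 2 * int(round(hx / self.spacing)) + 1
        ny = 2 * int(round(hy / self.spacing)) + 1
        x = (np.arange(nx) - nx // 2) * self.spacing
        y = (np.arange(ny) - ny // 2) * self.spacing
        return x, y


@dataclass
class MechanicsSolution:
    x: np.ndarray  # um, axial axis of the grid
    y: np.ndarray
    ux: np.ndarray  # surface axial displacement, um, shape (len(y), len(x))
    uy: np.ndarray  # zero in the scalar surrogate
    traction: np.ndarray  # kPa, axial surface traction
    force_uN: float  # total axial reaction force (one half of the dipole)
    traction_per_width_uN_per_mm: float
    realized_fs: float  # inner-50% fractional shortening of the tissue
    tissue_mask: np.ndarray = field(repr=False, default=None)
    residual: float = 0.0

    def u_at(self, x_um: float, y_um: float = 0.0) -> float:
        """Bilinear interpolation of the axial surface displacement."""
        ix = np.interp(x_um, self.x, np.arange(len(self.x)))
        iy = np.interp(y_um, self.y, np.arange(len(self.y)))
        i0, j0 = int(np.floor(iy)), int(np.floor(ix))
        fy, fx = iy - i0, ix - j0
        i1, j1 = min(i0 + 1, len(self.y) - 1), min(j0 + 1, len(self.x) - 1)
        u = self.ux
        return float(
            u[i0, j0] * (1 - fy) * (1 - fx)
            + u[i0, j1] * (1 - fy) * fx
            + u[i1, j0] * fy * (1 - fx)
            + u[i1, j1] * fy * fx
        )


def write_solution(sol: "MechanicsSolution", path_prefix) -> None:
    """Export a solution: gridded field CSV plus a summary JSON sidecar.

    ``<prefix>_field.csv`` holds one row per grid node (x_um, y_um, ux_um,
    traction_kpa); ``<prefix>_summary.json`` the scalar outputs.
    """
    import json
    from pathlib import Path

    import pandas as pd

    prefix = Path(path_prefix)
    X, Y = np.meshgrid(sol.x, sol.y)
    pd.DataFrame(
        {
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "ux_um": sol.ux.ravel(),
            "traction_kpa": sol.traction.ravel(),
        }
    ).to_csv(prefix.with_name(prefix.name + "_field.csv"), index=False, float_format="%.9g")
    summary = {
        "force_uN": sol.force_uN,
        "traction_per_width_uN_per_mm": sol.traction_per_width_uN_per_mm,
        "realized_fs": sol.realized_fs,
        "residual": sol.residual,
        "grid_shape": list(sol.ux.shape),
    }
    prefix.with_name(prefix.name + "_summary.json").write_text(json.dumps(summary, indent=2))


def layer_kernel_fft(shape, spacing, E, nu, h):
    """Spectral Green's function on a zero-padded FFT grid."""
    ny, nx = shape
    kx = 2 * np.pi * np.fft.rfftfreq(2 * nx, d=spacing)
    ky = 2 * np.pi * np.fft.fftfreq(2 * ny, d=spacing)
    K = np.hypot(ky[:, None], kx[None, :])
    G = np.empty_like(K)
    nz = K > 0
    G[nz] = 2.0 * (1.0 - nu**2) * np.tanh(K[nz] * h) / (E * K[nz])
    G[~nz] = 2.0 * (1.0 - nu**2) * h / E
    return G


def surface_response(traction, spacing, E, nu, h):
    """Surface displacement (um) from a traction field (kPa) via the layer kernel.

    Zero-padded FFT convolution, so the periodic images are pushed one full
    domain away.
    """
    ny, nx = traction.shape
    G = layer_kernel_fft((ny, nx), spacing, E, nu, h)
    pad = np.zeros((2 * ny, 2 * nx))
    pad[:ny, :nx] = traction
    u = np.fft.irfft2(G * np.fft.rfft2(pad), s=(2 * ny, 2 * nx))
    return u[:ny, :nx]


def solve_displacement_field(
    model: LayerModel,
    grid: Grid | None = None,
    tol: float = 1e-9,
    maxiter: int = 400,
) -> MechanicsSolution:
    """Solve the coupled tissue-substrate problem for the surface field.

    The tissue membrane stress is ``N = k_m (du/dx + eps0)`` inside the
    footprint (``k_m = E_tissue * t_tissue``), its divergence is the
    traction passed to the substrate, and ``u`` is the substrate surface
    response to that traction; the fixed point is found as one linear
    system.  Raises if GMRES does not reach the requested residual.
    """
    grid = grid or Grid()
    g = model.geometry
    x, y = grid.axes(g)
    d = grid.spacing
    X, Y = np.meshgrid(x, y)
    chi = ((np.abs(X) <= g.length / 2) & (np.abs(Y) <= g.width / 2)).astype(float)
    chi = gaussian_filter(chi, 4.0 / d)  # ~4 um edge regularization
    k_m = model.E_tissue * model.t_tissue  # kPa um
    eps0 = model.eigenstrain
    shape = chi.shape

    def dx(f):
        return np.gradient(f, d, axis=1)

    def conv(tau):
        return surface_response(tau, d, model.E_substrate, model.nu_substrate, model.thickness)

    def apply(tau_flat):
        tau = tau_flat.reshape(shape)
        u = conv(tau)
        return (tau - dx(chi * k_m * dx(u))).ravel()

    b = (k_m * eps0 * dx(chi)).ravel()
    if eps0 == 0:
        tau = np.zeros(shape)
        u = np.zeros(shape)
        res = 0.0
    else:
        A = LinearOperator((b.size, b.size), matvec=apply)
        tau_flat, info = lgmres(A, b, rtol=tol, atol=0.0, maxiter=maxiter)
        res = float(np.linalg.norm(apply(tau_flat) - b) / np.linalg.norm(b))
        if info != 0:
            raise RuntimeError(
                f"substrate-tissue solve did not converge (info={info}, residual={res:.2e})"
            )
        tau = tau_flat.reshape(shape)
        u = conv(tau)

    # total axial reaction force: traction integrated over the pulling half
    force_kpa_um2 = float(np.abs(tau[:, x < 0].sum()) * d * d)
    force_uN = force_kpa_um2 * 1e-3
    width_mm = g.width / 1000.0
    # realized shortening measured the way the platform measures it: inner 50%
    mid = len(y) // 2
    uL = np.interp(-g.length / 4, x, u[mid])
    uR = np.interp(+g.length / 4, x, u[mid])
    realized = float((uL - uR) / (g.length / 2))
    return MechanicsSolution(
        x=x,
        y=y,
        ux=u,
        uy=np.zeros_like(u),
        traction=tau,
        force_uN=force_uN,
        traction_per_width_uN_per_mm=force_uN / width_mm,
        realized_fs=realized,
        tissue_mask=chi > 0.5,
        residual=res,
    )


def neighbor_coupling(
    model: LayerModel,
    gaps_um: tuple[float, ...] = (80.0, 240.0),
    axis: str = "long",
    solution: MechanicsSolution | None = None,
    grid: Grid | None = None,
) -> dict[float, float]:
    """Coupling metric per buffer-gap distance.

    metric(gap) = max |surface displacement| on the contour one gap beyond
    the tissue edge, divided by max |displacement| under the tissue.  A gap
    of zero gives 1 by construction (the maximum sits at the tissue edge).
    """
    sol = solution or solve_displacement_field(model, grid)
    g = model.geometry
    # max |u| over the geometric tissue footprint; one grid cell of slack
    # so the edge peak is included when L/2 is not a grid point
    dx_grid = float(sol.x[1] - sol.x[0])
    X, Y = np.meshgrid(sol.x, sol.y)
    box = (np.abs(X) <= g.length / 2 + dx_grid) & (np.abs(Y) <= g.width / 2 + dx_grid)
    under = float(np.abs(sol.ux[box]).max())
    out: dict[float, float] = {}
    mid = len(sol.y) // 2
    for gap in gaps_um:
        if axis == "long":
            xq = g.length / 2 + gap
            val = abs(sol.u_at(xq, 0.0))
            val = max(val, abs(sol.u_at(-xq, 0.0)))
        else:
            yq = g.width / 2 + gap
            row = np.interp(yq, sol.y, np.arange(len(sol.y)))
            i = int(round(row))
            sel = np.abs(sol.x) <= g.length / 2
            val = float(np.abs(sol.ux[i, sel]).max())
        out[float(gap)] = val / under if under > 0 else 0.0
    return out


def thickness_decoupling_sweep(
    model: LayerModel,
    h_values: tuple[float, ...] = (10.0, 20.0, 40.0, 70.0, 150.0),
    grid: Grid | None = None,
) -> dict[float, float]:
    """Relative deviation of the surface field from the half-space solution.

    For each thickness ``h``, deviation = max-norm difference of the
    surface displacement versus the ``h -> inf`` field, normalized by the
    half-space peak displacement.  Decreases monotonically with ``h``; the
    full curve is exposed so any decoupling criterion can be applied to it.
    """
    inf_model = replace(model, thickness=1e6)
    u_inf = solve_displacement_field(inf_model, grid).ux
    peak = float(np.abs(u_inf).max())
    out: dict[float, float] = {}
    for h in h_values:
        u_h = solve_displacement_field(replace(model, thickness=float(h)), grid).ux
        out[float(h)] = float(np.abs(u_h - u_inf).max() / peak)
    return out


def fs_force_curve(
    model: LayerModel,
    eigenstrains: tuple[float, ...] = (0.02, 0.05, 0.08, 0.11),
    E_tissue_range: tuple[float, ...] = (8.0, 10.0, 12.0),
    fs_eval: float | None = None,
    grid: Grid | None = None,
) -> dict:
    """Realized-shortening vs. width-normalized-force curve and modulus sensitivity.

    The curve is computed at the model's tissue modulus; the sensitivity is
    the relative spread of the interpolated force at a fixed realized
    shortening across ``E_tissue_range``.  With the default ``fs_eval=None``
    the evaluation point is the midpoint of the realized-shortening range
    that every modulus in the sweep can reach (with passive-scale tissue
    moduli the coupled model realizes only a small fraction of the imposed
    eigenstrain, so a fixed absolute level may be unreachable).
    """
    def curve_for(E_t):
        pts = []
        for e in eigenstrains:
            sol = solve_displacement_field(replace(model, E_tissue=E_t, eigenstrain=e), grid)
            pts.append((sol.realized_fs, sol.traction_per_width_uN_per_mm))
        return np.array(pts)

    curves = {E_t: curve_for(E_t) for E_t in E_tissue_range}
    main = curves.get(model.E_tissue)
    if main is None:
        main = curve_for(model.E_tissue)
    if fs_eval is None:
        fs_eval = 0.5 * min(c[:, 0].max() for c in curves.values())
    forces_at_eval = np.array(
        [float(np.interp(fs_eval, c[:, 0], c[:, 1])) for c in curves.values()]
    )
    sens = float((forces_at_eval.max() - forces_at_eval.min()) / forces_at_eval.mean())
    return {
        "curve": main,  # columns: realized fs, uN/mm
        "fs_eval": float(fs_eval),
        "modulus_sensitivity": sens,
        "force_at_eval_by_modulus": dict(zip(E_tissue_range, forces_at_eval.tolist())),
    }


def fs_from_field(solution_u, x, sep_um: float, offset_um: float = 0.0, L_um: float | None = None):
    """Shortening estimated from an ROI pair read off a displacement profile.

    ``solution_u`` is the axial displacement along the tissue midline as a
    function of ``x``; the estimate is the separation change of two points
    at ``offset +/- sep/2`` divided by their separation.
    """
    uL = np.interp(offset_um - sep_um / 2, x, solution_u)
    uR = np.interp(offset_um + sep_um / 2, x, solution_u)
    return float((uL - uR) / sep_um)


def roi_placement_sensitivity(
    solution: MechanicsSolution,
    geometry: TissueGeometry,
    separations_frac: tuple[float, ...] = (0.5, 0.8, 1.0),
    offset_step_um: float = 5.0,
) -> dict:
    """Error and placement gradient of fs estimates at several ROI spans.

    The reference is the tissue-average strain (end-to-end separation
    change over the full length).  For each ROI span the relative error of
    the estimate and its numerical gradient with respect to a common
    centre offset are reported; small gradients mean robust placement.
    """
    mid = len(solution.y) // 2
    u = solution.ux[mid]
    x = solution.x
    L = geometry.length
    fs_true = fs_from_field(u, x, L)
    if fs_true == 0:
        raise ValueError("zero tissue-average strain; nothing to compare")
    out = {}
    for frac in separations_frac:
        sep = frac * L
        fs0 = fs_from_field(u, x, sep)
        # worst-case placement sensitivity: a symmetric field makes the
        # central difference vanish, so probe both directions separately
        grad = max(
            abs(fs_from_field(u, x, sep, o) - fs0) / abs(o)
            for o in (+offset_step_um, -offset_step_um)
        )
        out[float(frac)] = {
            "rel_error": float(fs0 / fs_true - 1.0),
            "gradient_per_um": float(grad / abs(fs_true)),
        }
    return out
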