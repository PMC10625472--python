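"""Fourier-transform traction cytometry (FTTC).

The surface displacement u(r) of a linear-elastic half-space responds to a
tangential traction field F(r) by the Boussinesq convolution

    u(r) = ∫ G(r - r') F(r') d²r',

where, for an incompressible substrate (Poisson ratio ν = 0.5, appropriate
for hydrogels) with Young's modulus E, the 2×2 Green tensor is

    G(r) = 3 / (4 π E r³) · [[r² + x²,  x y],
                             [x y,      r² + y²]].

In Fourier space the convolution diagonalizes per wavevector k:

    G̃(k) = 3 / (2 E k³) · [[k² + ky²,  -kx ky],
                            [-kx ky,    k² + kx²]]
          = 3/(2 E k) · (P∥ + 2 P⊥),

with P∥ = k̂ k̂ᵀ the longitudinal and P⊥ = I - P∥ the transverse projector,
i.e. eigenvalues 3/(2Ek) along k̂ and 3/(Ek) across it.  Inverting the
convolution is ill-posed at large k, so the traction estimate minimizes the
zeroth-order Tikhonov functional

    J(f) = ‖G f - u‖² + λ² ‖f‖²,

whose per-mode minimizer is f̂(k) = (G̃ᵀG̃ + λ²I)⁻¹ G̃ᵀ û(k).  The
regularization factor λ is selected automatically by a half-interval
(bisection) search for the Morozov discrepancy condition
``residual(λ) = σ·sqrt(2·N)`` given the displacement noise level σ.

Units: displacements µm, E and tractions Pa, wavevectors rad/µm.  The k = 0
mode is excluded (zero-mean traction), which encodes global force balance
and makes the per-mode operator invertible everywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .core import GelSubstrate, Point2D
from .fields import DisplacementField, TractionField

__all__ = [
    "GreenOperator",
    "RegularizationResult",
    "green_tensor_real",
    "build_fourier_kernel",
    "forward_displacement",
    "forward_displacement_direct",
    "invert_traction",
    "tikhonov_functional",
    "auto_lambda",
    "fill_invalid_nodes",
]


def _require_incompressible(substrate: GelSubstrate) -> None:
    if abs(substrate.poisson_ratio - 0.5) > 1e-12:
        raise ValueError(
            "only incompressible substrate supported (ν = 0.5); "
            f"got ν = {substrate.poisson_ratio}"
        )


def green_tensor_real(point: Point2D, substrate: GelSubstrate) -> np.ndarray:
    """Real-space Boussinesq Green tensor at ``point`` for ν = 0.5.

    Returns the 2×2 tensor G (µm per Pa·µm², i.e. 1/(Pa·µm)) such that a
    point traction F (Pa·µm²) at the origin displaces the surface at
    ``point`` by G·F (µm).
    """
    _require_incompressible(substrate)
    x, y = point.x, point.y
    r2 = x * x + y * y
    if r2 == 0.0:
        raise ValueError("Green tensor singular at origin (r = 0)")
    r = np.sqrt(r2)
    pref = 3.0 / (4.0 * np.pi * substrate.young_modulus_Pa * r2 * r)
    return pref * np.array([[r2 + x * x, x * y], [x * y, r2 + y * y]])


@dataclass
class GreenOperator:
    """Discretized Fourier-space Green tensor on a (possibly padded) lattice.

    ``g_par``/``g_perp`` are the longitudinal/transverse eigenvalues of G̃
    per wavevector; ``khx``/``khy`` the unit wavevector components.  The
    k = 0 mode is flagged excluded.  ``pad_factor`` > 1 embeds the working
    grid in a larger lattice before transforming, suppressing periodic-wrap
    bias of the open-plane convolution.
    """

    substrate: GelSubstrate
    n_rows: int
    n_cols: int
    spacing_um: float
    pad_factor: int = 2
    # filled by build_fourier_kernel
    pad_rows: int = 0
    pad_cols: int = 0
    g_par: np.ndarray = field(default=None, repr=False)
    g_perp: np.ndarray = field(default=None, repr=False)
    khx: np.ndarray = field(default=None, repr=False)
    khy: np.ndarray = field(default=None, repr=False)
    kmag: np.ndarray = field(default=None, repr=False)
    nyq_line: np.ndarray = field(default=None, repr=False)

    @property
    def gmax(self) -> float:
        """Largest kernel eigenvalue, ‖G̃‖ (µm/Pa)."""
        return float(self.g_perp.max())

    def apply_forward(self, fx_hat: np.ndarray, fy_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """û = G̃ f̂ per mode (k = 0 forced to zero)."""
        return self._apply(fx_hat, fy_hat, self.g_par, self.g_perp)

    def _apply(self, vx, vy, m_par, m_perp):
        par = self.khx * vx + self.khy * vy
        px, py = par * self.khx, par * self.khy
        ox, oy = vx - px, vy - py
        return m_par * px + m_perp * ox, m_par * py + m_perp * oy


def build_fourier_kernel(
    n_rows: int,
    n_cols: int,
    spacing_um: float,
    substrate: GelSubstrate,
    pad_factor: int = 2,
) -> GreenOperator:
    """Assemble the analytic Fourier-space Green tensor on the discrete lattice.

    The tensor is stored through its eigen-decomposition (longitudinal
    eigenvalue 3/(2Ek), transverse 3/(Ek)).  On Nyquist rows/columns the
    wavevector sign is ambiguous, so the off-diagonal (shear) coupling is
    dropped there (isotropic average of P∥ and P⊥) to keep real transforms
    real to machine precision.
    """
    _require_incompressible(substrate)
    if n_rows < 2 or n_cols < 2:
        raise ValueError("grid must be at least 2x2 nodes")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    pr, pc = n_rows * pad_factor, n_cols * pad_factor
    E = substrate.young_modulus_Pa
    ky = 2.0 * np.pi * np.fft.fftfreq(pr, d=spacing_um)[:, None]
    kx = 2.0 * np.pi * np.fft.fftfreq(pc, d=spacing_um)[None, :]
    kmag = np.hypot(kx, ky)
    with np.errstate(divide="ignore", invalid="ignore"):
        khx = np.where(kmag > 0, kx / np.where(kmag > 0, kmag, 1.0), 0.0)
        khy = np.where(kmag > 0, ky / np.where(kmag > 0, kmag, 1.0), 0.0)
        g_par = np.where(kmag > 0, 3.0 / (2.0 * E * np.where(kmag > 0, kmag, 1.0)), 0.0)
    g_perp = 2.0 * g_par
    # Nyquist lines: k and -k alias to the same mode; zero the anisotropic
    # (off-diagonal) part there so the kernel stays Hermitian-symmetric.
    nyq = np.zeros((pr, pc), dtype=bool)
    if pr % 2 == 0:
        nyq[pr // 2, :] = True
    if pc % 2 == 0:
        nyq[:, pc // 2] = True
    iso = 0.5 * (g_par + g_perp)
    g_par = np.where(nyq, iso, g_par)
    g_perp = np.where(nyq, iso, g_perp)
    khx = np.broadcast_to(khx, (pr, pc)).copy()
    khy = np.broadcast_to(khy, (pr, pc)).copy()
    return GreenOperator(
        substrate=substrate,
        n_rows=n_rows,
        n_cols=n_cols,
        spacing_um=spacing_um,
        pad_factor=pad_factor,
        pad_rows=pr,
        pad_cols=pc,
        g_par=g_par,
        g_perp=g_perp,
        khx=khx,
        khy=khy,
        kmag=kmag,
        nyq_line=nyq,
    )


def _check_grid_match(op: GreenOperator, n_rows: int, n_cols: int, spacing: float) -> None:
    if (op.n_rows, op.n_cols) != (n_rows, n_cols) or abs(op.spacing_um - spacing) > 1e-9:
        raise ValueError(
            f"operator built for {op.n_rows}x{op.n_cols} @ {op.spacing_um} µm, "
            f"field is {n_rows}x{n_cols} @ {spacing} µm"
        )


def forward_displacement(traction: TractionField, op: GreenOperator) -> DisplacementField:
    """Forward elastic model: u = G ⊛ F via per-mode multiplication.

    The traction must be force-balanced (the k = 0 mode of the inverse
    problem is indeterminate, so an unbalanced input cannot round-trip) and
    compactly supported away from the boundary margin; the grid is
    zero-padded by ``op.pad_factor`` before transforming and cropped after.
    """
    _check_grid_match(op, traction.n_rows, traction.n_cols, traction.spacing_um)
    mean_mag = np.mean(traction.magnitude)
    if mean_mag > 0:
        if (
            abs(traction.tx.mean()) > 1e-6 * mean_mag
            or abs(traction.ty.mean()) > 1e-6 * mean_mag
        ):
            raise ValueError("k=0 mode indeterminate: traction field is not force-balanced")
    fx = np.zeros((op.pad_rows, op.pad_cols))
    fy = np.zeros_like(fx)
    fx[: traction.n_rows, : traction.n_cols] = traction.tx
    fy[: traction.n_rows, : traction.n_cols] = traction.ty
    ux_hat, uy_hat = op.apply_forward(np.fft.fft2(fx), np.fft.fft2(fy))
    ux = np.fft.ifft2(ux_hat).real[: traction.n_rows, : traction.n_cols]
    uy = np.fft.ifft2(uy_hat).real[: traction.n_rows, : traction.n_cols]
    return DisplacementField(ux, uy, traction.spacing_um, traction.origin_um)


def forward_displacement_direct(
    traction: TractionField,
    substrate: GelSubstrate,
    near_subsample: int = 16,
    near_radius_cells: float = 6.0,
) -> DisplacementField:
    """Direct O(N²) real-space summation of the Boussinesq convolution.

    Reference implementation for small grids: the traction is treated as
    piecewise constant per h×h cell and u(r_i) = Σ_j K(r_i - r_j)·F_j with
    K the Green tensor integrated over the source cell — by midpoint
    quadrature with ``near_subsample``² points within ``near_radius_cells``
    of the singularity (fewer farther out) and analytically for the
    singular self cell, where the off-diagonal part vanishes by symmetry
    and the diagonal integral is 9 h ln(1+√2) / (2πE).
    """
    _require_incompressible(substrate)
    h = traction.spacing_um
    E = substrate.young_modulus_Pa
    nr, nc = traction.tx.shape
    di = np.arange(-(nr - 1), nr)
    dj = np.arange(-(nc - 1), nc)
    kxx = np.zeros((len(di), len(dj)))
    kxy = np.zeros_like(kxx)
    kyy = np.zeros_like(kxx)
    self_diag = 9.0 * h * np.log(1.0 + np.sqrt(2.0)) / (2.0 * np.pi * E)
    for a, ii in enumerate(di):
        for b, jj in enumerate(dj):
            if ii == 0 and jj == 0:
                kxx[a, b] = self_diag
                kyy[a, b] = self_diag
                continue
            rc = np.hypot(ii, jj)
            if rc <= near_radius_cells:
                s = near_subsample
            elif rc <= 2.0 * near_radius_cells:
                s = 4
            else:
                s = 1
            off = ((np.arange(s) + 0.5) / s - 0.5) * h
            ox, oy = np.meshgrid(off, off)
            x = jj * h - ox
            y = ii * h - oy
            r2 = x * x + y * y
            r = np.sqrt(r2)
            pref = 3.0 / (4.0 * np.pi * E * r2 * r)
            kxx[a, b] = np.mean(pref * (r2 + x * x)) * h * h
            kxy[a, b] = np.mean(pref * (x * y)) * h * h
            kyy[a, b] = np.mean(pref * (r2 + y * y)) * h * h
    fx, fy = traction.tx, traction.ty
    ux = np.zeros((nr, nc))
    uy = np.zeros((nr, nc))
    rows = np.arange(nr)[:, None]
    cols = np.arange(nc)[None, :]
    for i in range(nr):
        for j in range(nc):
            sx = i - rows + (nr - 1)
            sy = j - cols + (nc - 1)
            ux[i, j] = np.sum(kxx[sx, sy] * fx + kxy[sx, sy] * fy)
            uy[i, j] = np.sum(kxy[sx, sy] * fx + kyy[sx, sy] * fy)
    return DisplacementField(ux, uy, h, traction.origin_um)


def fill_invalid_nodes(u: DisplacementField, max_iter: int = 100) -> DisplacementField:
    """Return a copy with invalid nodes in-filled by the median of valid neighbors.

    Iterates so that isolated holes and hole clusters are all filled; the
    validity mask of the result is all-True only in the sense of "finite
    everywhere" — the original mask is preserved on the returned field.
    """
    ux, uy = u.ux.copy(), u.uy.copy()
    known = u.valid_mask.copy()
    if known.all():
        return u.copy()
    if not known.any():
        raise ValueError("displacement field has no valid nodes to in-fill from")
    for _ in range(max_iter):
        if known.all():
            break
        holes = np.argwhere(~known)
        newly = []
        for i, j in holes:
            i0, i1 = max(0, i - 1), min(known.shape[0], i + 2)
            j0, j1 = max(0, j - 1), min(known.shape[1], j + 2)
            nb = known[i0:i1, j0:j1]
            if nb.any():
                ux[i, j] = np.median(ux[i0:i1, j0:j1][nb])
                uy[i, j] = np.median(uy[i0:i1, j0:j1][nb])
                newly.append((i, j))
        if not newly:
            break
        for i, j in newly:
            known[i, j] = True
    return DisplacementField(ux, uy, u.spacing_um, u.origin_um, u.valid_mask.copy())


def _pad_tapered(a: np.ndarray, pad_rows: int, pad_cols: int) -> np.ndarray:
    """Embed ``a`` at the top-left of a larger array, extending the trailing
    edges by edge-replication multiplied by a half-cosine ramp to zero."""
    nr, nc = a.shape
    if (pad_rows, pad_cols) == (nr, nc):
        return a.copy()
    er, ec = pad_rows - nr, pad_cols - nc
    out = np.pad(a, ((0, er), (0, ec)), mode="edge")
    wr = np.ones(pad_rows)
    if er > 0:
        wr[nr:] = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, er + 1) / er))
    wc = np.ones(pad_cols)
    if ec > 0:
        wc[nc:] = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, ec + 1) / ec))
    return out * wr[:, None] * wc[None, :]


@dataclass
class RegularizationResult:
    """Outcome of a regularized inversion.

    ``residual_norm`` = ‖Gf − u‖ and ``solution_norm`` = ‖f‖ are root sums
    of squares over the padded computational lattice (both displacement
    components), so ``J_value = residual_norm² + λ²·solution_norm²`` holds
    exactly and both norms are monotone in λ.
    """

    lambda_opt: float
    residual_norm: float
    solution_norm: float
    J_value: float
    n_iterations: int
    converged: bool
    traction: TractionField | None = None
    noise_sigma_um: float | None = None
    target_residual: float | None = None

    def __post_init__(self) -> None:
        jj = self.residual_norm**2 + self.lambda_opt**2 * self.solution_norm**2
        if self.J_value == 0.0:
            self.J_value = jj


def _prepare_uhat(u: DisplacementField, op: GreenOperator):
    """In-fill invalid nodes, taper-pad, remove the mean, transform.

    The spatial-mean (k = 0) displacement component is an unobservable
    rigid translation — uncorrectable residual drift, not deformation — and
    the zero-mean traction constraint cannot fit it, so it is removed here
    rather than left to pollute the discrepancy residual.
    """
    filled = fill_invalid_nodes(u)
    upx = _pad_tapered(filled.ux, op.pad_rows, op.pad_cols)
    upy = _pad_tapered(filled.uy, op.pad_rows, op.pad_cols)
    upx -= upx.mean()
    upy -= upy.mean()
    return np.fft.fft2(upx), np.fft.fft2(upy)


def _solve_modes(ux_hat, uy_hat, op: GreenOperator, lam: float):
    """Per-mode Tikhonov minimizer in the kernel eigenbasis.

    Decomposes û into longitudinal/transverse channels; in each channel with
    kernel eigenvalue g the minimizer is f̂ = g û / (g² + λ²), the residual
    λ² û / (g² + λ²).  Returns (f̂x, f̂y, residual², solution²) with norms
    already converted to real-space sums via Parseval.
    """
    par = op.khx * ux_hat + op.khy * uy_hat
    px, py = par * op.khx, par * op.khy
    ox, oy = ux_hat - px, uy_hat - py
    l2 = lam * lam
    w_par = op.g_par / (op.g_par**2 + l2) if l2 > 0 else np.where(op.g_par > 0, 1.0 / np.where(op.g_par > 0, op.g_par, 1.0), 0.0)
    w_perp = op.g_perp / (op.g_perp**2 + l2) if l2 > 0 else np.where(op.g_perp > 0, 1.0 / np.where(op.g_perp > 0, op.g_perp, 1.0), 0.0)
    fx_hat = w_par * px + w_perp * ox
    fy_hat = w_par * py + w_perp * oy
    # residual per channel: û - g f̂ = û λ²/(g²+λ²); k=0 channel (g=0): residual = û
    with np.errstate(invalid="ignore", divide="ignore"):
        r_par = np.where(op.g_par > 0, l2 / (op.g_par**2 + l2), 1.0)
        r_perp = np.where(op.g_perp > 0, l2 / (op.g_perp**2 + l2), 1.0)
    ntot = op.pad_rows * op.pad_cols
    par_pow = np.abs(px) ** 2 + np.abs(py) ** 2
    perp_pow = np.abs(ox) ** 2 + np.abs(oy) ** 2
    res2 = float((r_par**2 * par_pow + r_perp**2 * perp_pow).sum() / ntot)
    sol2 = float(((w_par**2) * par_pow + (w_perp**2) * perp_pow).sum() / ntot)
    return fx_hat, fy_hat, res2, sol2


def invert_traction(
    u: DisplacementField,
    op: GreenOperator,
    lambda_: float,
    crop: bool = True,
    full_output: bool = False,
):
    """Tikhonov inversion of the forward model at a fixed λ.

    Returns the traction field on the original grid (or the full padded
    lattice with ``crop=False``); with ``full_output=True`` also a
    :class:`RegularizationResult` carrying the residual and solution norms.
    """
    if lambda_ < 0:
        raise ValueError(f"regularization factor must be >= 0, got {lambda_}")
    _check_grid_match(op, u.n_rows, u.n_cols, u.spacing_um)
    ux_hat, uy_hat = _prepare_uhat(u, op)
    fx_hat, fy_hat, res2, sol2 = _solve_modes(ux_hat, uy_hat, op, lambda_)
    fx = np.fft.ifft2(fx_hat).real
    fy = np.fft.ifft2(fy_hat).real
    if crop:
        fx = fx[: u.n_rows, : u.n_cols]
        fy = fy[: u.n_rows, : u.n_cols]
    traction = TractionField(fx, fy, u.spacing_um, u.origin_um)
    if not full_output:
        return traction
    result = RegularizationResult(
        lambda_opt=lambda_,
        residual_norm=np.sqrt(res2),
        solution_norm=np.sqrt(sol2),
        J_value=res2 + lambda_**2 * sol2,
        n_iterations=0,
        converged=True,
        traction=traction,
    )
    return traction, result


def tikhonov_functional(
    fx_pad: np.ndarray, fy_pad: np.ndarray, u: DisplacementField, op: GreenOperator, lambda_: float
) -> float:
    """Evaluate J(f) = ‖Gf − u‖² + λ²‖f‖² for a traction defined on the
    padded lattice (same norms as the solver uses)."""
    ux_hat, uy_hat = _prepare_uhat(u, op)
    fx_hat, fy_hat = np.fft.fft2(fx_pad), np.fft.fft2(fy_pad)
    gx_hat, gy_hat = op.apply_forward(fx_hat, fy_hat)
    ntot = op.pad_rows * op.pad_cols
    res2 = (np.abs(gx_hat - ux_hat) ** 2 + np.abs(gy_hat - uy_hat) ** 2).sum() / ntot
    sol2 = (np.abs(fx_hat) ** 2 + np.abs(fy_hat) ** 2).sum() / ntot
    return float(res2 + lambda_**2 * sol2)


def estimate_noise_sigma(u: DisplacementField) -> float:
    """Robust displacement-noise estimate: 1.4826 × median absolute deviation
    of (u − 3×3 median-filtered u), pooled over both components at valid nodes."""
    res = []
    for comp in (u.ux, u.uy):
        smooth = median_filter(comp, size=3, mode="nearest")
        res.append((comp - smooth)[u.valid_mask])
    pooled = np.abs(np.concatenate(res))
    return float(1.4826 * np.median(pooled))


def auto_lambda(
    u: DisplacementField,
    op: GreenOperator,
    noise_sigma_um: float | None = None,
    rel_tol: float = 1e-3,
    max_halvings: int = 60,
) -> RegularizationResult:
    """Select λ by half-interval search on the Morozov discrepancy condition.

    Seeks λ* with ``residual(λ*) = noise_sigma_um · sqrt(2 · N_valid)`` —
    the residual a solution fitting everything but the noise should leave.
    The residual is monotone non-decreasing in λ (per-mode Tikhonov), so
    bisection on log₁₀λ over [1e-6, 1e2]·‖G̃‖ is guaranteed to converge
    when the target is attainable.  If the noise level is not supplied it
    is estimated from the field itself (see :func:`estimate_noise_sigma`).
    """
    n_valid = int(u.valid_mask.sum())
    if n_valid < 16:
        raise ValueError(f"need >= 16 valid displacement nodes, got {n_valid}")
    if noise_sigma_um is None:
        noise_sigma_um = estimate_noise_sigma(u)
    target = noise_sigma_um * np.sqrt(2.0 * n_valid)
    ux_hat, uy_hat = _prepare_uhat(u, op)

    def residual(lam: float) -> float:
        return float(np.sqrt(_solve_modes(ux_hat, uy_hat, op, lam)[2]))

    lo = 1e-6 * op.gmax
    hi = 1e2 * op.gmax
    res_lo, res_hi = residual(lo), residual(hi)
    n_iter = 0
    converged = False
    if target >= res_hi:
        warnings.warn(
            "discrepancy target exceeds the residual at the largest λ; "
            "data indistinguishable from noise — returning λmax",
            RuntimeWarning,
        )
        lam = hi
    elif target <= res_lo:
        # noise floor below what the bracket can resolve; λ at the bracket floor
        lam = lo
        converged = abs(res_lo - target) <= rel_tol * max(target, 1e-300)
    else:
        llo, lhi = np.log10(lo), np.log10(hi)
        lam = lo
        for n_iter in range(1, max_halvings + 1):
            lmid = 0.5 * (llo + lhi)
            lam = 10.0**lmid
            r = residual(lam)
            if abs(r - target) <= rel_tol * target:
                converged = True
                break
            if r < target:
                llo = lmid
            else:
                lhi = lmid
    traction, base = invert_traction(u, op, lam, full_output=True)
    return RegularizationResult(
        lambda_opt=lam,
        residual_norm=base.residual_norm,
        solution_norm=base.solution_norm,
        J_value=base.J_value,
        n_iterations=n_iter,
        converged=converged,
        traction=traction,
        noise_sigma_um=noise_sigma_um,
        target_residual=target,
    )
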