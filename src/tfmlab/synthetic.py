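"""Synthetic TFM scenes with exact ground truth.

Emulates what a TFM acquisition produces — diffraction-limited fluorescent
beads in a gel imaged before and after cell detachment, defocused z-stacks,
lateral stage drift, and a cell channel with punctate focal adhesions — all
driven by a known, force-balanced traction field pushed through the elastic
forward model.  Every generator is a pure function of its arguments and
seed, so each downstream stage can be tested against exact truth.

Default scene scale mimics a high-NA TIRF acquisition: 0.108 µm pixels,
bead PSF σ ≈ 1.5 px, ~0.01 beads/px², camera background 100 counts, bead
peak ≈ 2000 counts, Gaussian read noise σ = 5, Poisson shot noise.  The
substrate default is a soft 2 kPa polyacrylamide gel (ν = 0.5), on which a
300 Pa contractile dipole produces multi-pixel bead displacements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import erf

from .core import GelSubstrate, GridImage, Point2D
from .fields import DisplacementField, TractionField
from .fttc import build_fourier_kernel, forward_displacement

__all__ = [
    "NoiseModel",
    "SyntheticScene",
    "make_traction_dipole",
    "render_beads",
    "warp_beads",
    "render_zstack",
    "render_cell_channel",
    "make_scene",
    "write_scene_files",
    "peak_to_total_counts",
]


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: constant background, Poisson shot noise, Gaussian read noise."""

    background: float = 100.0
    read_sigma: float = 5.0
    poisson: bool = True


DEFAULT_NOISE = NoiseModel()


def peak_to_total_counts(peak: float, sigma_px: float) -> float:
    """Total integrated counts of a pixel-integrated Gaussian bead whose
    central pixel (bead centered on it) holds ``peak`` counts."""
    frac = erf(0.5 / (sigma_px * np.sqrt(2.0))) ** 2
    return peak / frac


def make_traction_dipole(
    grid_shape: tuple[int, int],
    pixel_size_um: float,
    magnitude_Pa: float,
    patch_sigma_um: float,
    separation_um: float,
    angle_rad: float = 0.0,
    center_um: tuple[float, float] | None = None,
) -> TractionField:
    """Contractile traction dipole: two Gaussian patches of equal magnitude
    pulling toward each other along the separation axis.

    Stands in for a polarized contractile cell.  The two patches cancel by
    construction, and any residual discretization imbalance is removed by
    subtracting the mean, so the integrated force components are each below
    1e-9 of the total |F| integral (the k=0 mode of the inverse problem is
    indeterminate, so fixtures must be exactly balanced).
    """
    nr, nc = grid_shape
    h = pixel_size_um
    if not separation_um > 2.0 * patch_sigma_um:
        raise ValueError(
            f"separation ({separation_um} µm) must exceed 2·patch_sigma ({2 * patch_sigma_um} µm)"
        )
    if center_um is None:
        center_um = ((nc - 1) * h / 2.0, (nr - 1) * h / 2.0)
    ex, ey = np.cos(angle_rad), np.sin(angle_rad)
    cx1 = center_um[0] + 0.5 * separation_um * ex
    cy1 = center_um[1] + 0.5 * separation_um * ey
    cx2 = center_um[0] - 0.5 * separation_um * ex
    cy2 = center_um[1] - 0.5 * separation_um * ey
    margin = 3.0 * patch_sigma_um
    for cx, cy in ((cx1, cy1), (cx2, cy2)):
        if not (margin <= cx <= (nc - 1) * h - margin and margin <= cy <= (nr - 1) * h - margin):
            raise ValueError(
                f"patch center ({cx:.2f}, {cy:.2f}) µm closer than 3σ = {margin:.2f} µm "
                "to the grid boundary; boundary wrap would corrupt the FFT forward model"
            )
    x = h * np.arange(nc)[None, :]
    y = h * np.arange(nr)[:, None]
    s2 = 2.0 * patch_sigma_um**2
    g1 = np.exp(-((x - cx1) ** 2 + (y - cy1) ** 2) / s2)
    g2 = np.exp(-((x - cx2) ** 2 + (y - cy2) ** 2) / s2)
    # patch 1 sits at +axis and pulls toward the center (-axis), and vice versa
    amp = magnitude_Pa * (g2 - g1)
    tx = amp * ex
    ty = amp * ey
    if magnitude_Pa != 0.0:
        tx = tx - tx.mean()
        ty = ty - ty.mean()
    return TractionField(tx, ty, h)


def _as_xy(positions) -> np.ndarray:
    arr = np.array(
        [(p.x, p.y) if isinstance(p, Point2D) else (p[0], p[1]) for p in positions],
        dtype=np.float64,
    ).reshape(-1, 2)
    return arr


def render_beads(
    positions,
    intensities,
    bead_sigma_um: float,
    grid_shape: tuple[int, int],
    pixel_size_um: float,
    noise_model: NoiseModel | None = None,
    rng_seed: int | np.random.Generator | None = 0,
) -> GridImage:
    """Render fluorescent beads as pixel-integrated 2D Gaussians.

    Each bead deposits ``intensity`` total counts distributed by the erf
    difference over pixel edges (not point-sampled), so sub-pixel centroid
    bias of the fixture itself is negligible.  ``noise_model=None`` renders
    a clean, background-free image.  Deterministic for a fixed seed.
    """
    nr, nc = grid_shape
    h = pixel_size_um
    if bead_sigma_um < 0.5 * h:
        raise ValueError(
            f"bead_sigma_um ({bead_sigma_um}) must be >= half the pixel size ({h}) for sampling"
        )
    pos = _as_xy(positions)
    n = len(pos)
    if n and (
        pos[:, 0].min() < 0
        or pos[:, 1].min() < 0
        or pos[:, 0].max() > (nc - 1) * h
        or pos[:, 1].max() > (nr - 1) * h
    ):
        raise ValueError("bead positions must lie inside the image grid")
    if n / (nr * nc) > 0.05:
        warnings.warn(
            f"bead density {n / (nr * nc):.3f} beads/px² exceeds 0.05: tracking ambiguity regime",
            RuntimeWarning,
        )
    inten = np.broadcast_to(np.asarray(intensities, dtype=np.float64), (n,))
    img = np.zeros((nr, nc))
    sig_px = bead_sigma_um / h
    w = int(np.ceil(4.0 * sig_px)) + 2
    inv = 1.0 / (sig_px * np.sqrt(2.0))
    for (x, y), a in zip(pos, inten):
        cx, cy = x / h, y / h
        j0, j1 = max(0, int(np.floor(cx)) - w), min(nc, int(np.floor(cx)) + w + 1)
        i0, i1 = max(0, int(np.floor(cy)) - w), min(nr, int(np.floor(cy)) + w + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        jj = np.arange(j0, j1)
        ii = np.arange(i0, i1)
        fx = 0.5 * (erf((jj + 0.5 - cx) * inv) - erf((jj - 0.5 - cx) * inv))
        fy = 0.5 * (erf((ii + 0.5 - cy) * inv) - erf((ii - 0.5 - cy) * inv))
        img[i0:i1, j0:j1] += a * fy[:, None] * fx[None, :]
    if noise_model is not None:
        rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
        img = img + noise_model.background
        if noise_model.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if noise_model.read_sigma > 0:
            img = img + rng.normal(0.0, noise_model.read_sigma, img.shape)
    return GridImage(img, pixel_size_um, channel_tag="beads")


def warp_beads(positions, displacement: DisplacementField):
    """Displace bead positions by the field bilinearly interpolated at each bead.

    Returns ``(warped_positions, dropped_indices)``: beads pushed off the
    field's grid are dropped and their original indices reported.  Every
    input position must lie within the field's extent.
    """
    pos = _as_xy(positions)
    x_nodes = displacement.origin_um[0] + displacement.spacing_um * np.arange(displacement.n_cols)
    y_nodes = displacement.origin_um[1] + displacement.spacing_um * np.arange(displacement.n_rows)
    if len(pos) and (
        pos[:, 0].min() < x_nodes[0]
        or pos[:, 0].max() > x_nodes[-1]
        or pos[:, 1].min() < y_nodes[0]
        or pos[:, 1].max() > y_nodes[-1]
    ):
        raise ValueError("displacement field does not cover all bead positions")
    ix = RegularGridInterpolator((y_nodes, x_nodes), displacement.ux, method="linear")
    iy = RegularGridInterpolator((y_nodes, x_nodes), displacement.uy, method="linear")
    pts = pos[:, ::-1]  # (y, x) order
    new = pos + np.stack([ix(pts), iy(pts)], axis=1) if len(pos) else pos
    keep = (
        (new[:, 0] >= x_nodes[0])
        & (new[:, 0] <= x_nodes[-1])
        & (new[:, 1] >= y_nodes[0])
        & (new[:, 1] <= y_nodes[-1])
    )
    warped = [Point2D(float(x), float(y)) for x, y in new[keep]]
    dropped = list(np.nonzero(~keep)[0])
    return warped, dropped


def render_zstack(
    positions,
    intensities,
    bead_sigma_um: float,
    grid_shape: tuple[int, int],
    pixel_size_um: float,
    n_slices: int,
    dz_um: float,
    focus_index: int,
    defocus_rate: float = 1.0,
    noise_model: NoiseModel | None = None,
    rng_seed: int = 0,
) -> list[GridImage]:
    """Render a defocus z-stack of the same bead configuration.

    Slice i is blurred to width sqrt(σ² + (defocus_rate·|i−focus_index|·dz)²),
    so ``focus_index`` is strictly the sharpest slice by construction; total
    counts are conserved across slices (defocus dims the peak, not the sum).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if not (0 <= focus_index < n_slices):
        raise ValueError(f"focus_index {focus_index} outside [0, {n_slices})")
    rng = np.random.default_rng(rng_seed)
    out = []
    for i in range(n_slices):
        blur = defocus_rate * abs(i - focus_index) * dz_um
        sig = float(np.sqrt(bead_sigma_um**2 + blur**2))
        img = render_beads(
            positions, intensities, sig, grid_shape, pixel_size_um, noise_model, rng_seed=rng
        )
        img.z_index = i
        out.append(img)
    return out


def render_cell_channel(
    grid_shape: tuple[int, int],
    pixel_size_um: float,
    cell_center_um: tuple[float, float],
    cell_axes_um: tuple[float, float],
    n_adhesions: int = 0,
    rng_seed: int = 0,
    angle_rad: float = 0.0,
    plateau: float = 500.0,
    adhesion_amp: float = 1500.0,
    adhesion_sigma_um: float = 0.4,
    edge_softness_um: float = 0.3,
    noise_model: NoiseModel | None = None,
):
    """Fluorescent cell channel: smooth elliptical plateau plus bright
    focal-adhesion puncta near the rim.

    Returns ``(image, truth_mask, adhesion_points)``; the mask is the
    analytic ellipse interior, the puncta are placed with enforced minimum
    separation so they are non-overlapping by construction.
    """
    nr, nc = grid_shape
    h = pixel_size_um
    a, b = cell_axes_um
    cx, cy = cell_center_um
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    # ellipse must fit in the grid
    for dx, dy in ((a * ca, a * sa), (-b * sa, b * ca)):
        px, py = cx + dx, cy + dy
        qx, qy = cx - dx, cy - dy
        if not (0 <= px <= (nc - 1) * h and 0 <= py <= (nr - 1) * h and 0 <= qx <= (nc - 1) * h and 0 <= qy <= (nr - 1) * h):
            raise ValueError("cell ellipse does not fit inside the grid")
    x = h * np.arange(nc)[None, :] - cx
    y = h * np.arange(nr)[:, None] - cy
    xr = x * ca + y * sa
    yr = -x * sa + y * ca
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    w = edge_softness_um / min(a, b)
    img = plateau / (1.0 + np.exp((rho - 1.0) / max(w, 1e-6)))
    mask = rho <= 1.0
    rng = np.random.default_rng(rng_seed)
    points: list[Point2D] = []
    min_sep = 5.0 * adhesion_sigma_um
    tries = 0
    while len(points) < n_adhesions and tries < 2000:
        tries += 1
        theta = rng.uniform(0, 2 * np.pi)
        frac = rng.uniform(0.70, 0.92)
        px = cx + frac * a * np.cos(theta) * ca - frac * b * np.sin(theta) * sa
        py = cy + frac * a * np.cos(theta) * sa + frac * b * np.sin(theta) * ca
        if any(np.hypot(px - q.x, py - q.y) < min_sep for q in points):
            continue
        points.append(Point2D(px, py))
    if len(points) < n_adhesions:
        raise ValueError(f"could not place {n_adhesions} non-overlapping adhesions")
    s2 = 2.0 * adhesion_sigma_um**2
    for p in points:
        img += adhesion_amp * np.exp(-((h * np.arange(nc)[None, :] - p.x) ** 2 + (h * np.arange(nr)[:, None] - p.y) ** 2) / s2)
    if noise_model is not None:
        img = img + noise_model.background
        if noise_model.poisson:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if noise_model.read_sigma > 0:
            img = img + rng.normal(0.0, noise_model.read_sigma, img.shape)
    return GridImage(img, pixel_size_um, channel_tag="cell"), mask, points


def write_scene_files(scene: "SyntheticScene", outdir, label: str = "pos0", truth_subsample: int = 8) -> dict:
    """Write a scene as the OME-TIFF layout the pipeline ingests.

    Produces ``<label>_beads.ome.tif`` (stressed z-stack + stressed time
    series), ``<label>_ref.ome.tif`` (equilibrium z-stack),
    ``<label>_cell.ome.tif`` (cell channel), a ground-truth ASCII table
    (``x y ux uy tx ty`` per subsampled grid node) and a JSON sidecar of
    scene parameters.  Returns the path dictionary.
    """
    import json
    from pathlib import Path

    from .io import write_ome_series

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    h = scene.pixel_size_um
    beads_path = outdir / f"{label}_beads.ome.tif"
    ref_path = outdir / f"{label}_ref.ome.tif"
    cell_path = outdir / f"{label}_cell.ome.tif"
    zs = np.stack([im.pixels for im in scene.render_stressed_zstack()])
    ts = np.stack([scene.render_stressed_frame(t).pixels for t in range(scene.n_t)])
    write_ome_series(beads_path, zs, ts, h, channel_tag="beads")
    rz = np.stack([im.pixels for im in scene.render_reference_zstack()])
    write_ome_series(ref_path, rz, None, h, channel_tag="beads_ref")
    cell0, _, _ = scene.render_cell_frame(0)
    cz = cell0.pixels[None]
    ct = np.stack([scene.render_cell_frame(t)[0].pixels for t in range(scene.n_t)])
    write_ome_series(cell_path, cz, ct, h, channel_tag="cell")
    s = truth_subsample
    d, tr = scene.displacement_truth, scene.traction_truth
    rows = np.column_stack(
        [
            d.grid_x[::s, ::s].ravel(),
            d.grid_y[::s, ::s].ravel(),
            d.ux[::s, ::s].ravel(),
            d.uy[::s, ::s].ravel(),
            tr.tx[::s, ::s].ravel(),
            tr.ty[::s, ::s].ravel(),
        ]
    )
    truth_path = outdir / f"{label}_truth.txt"
    np.savetxt(truth_path, rows, fmt="%.6f %.6f %.9e %.9e %.6e %.6e",
               header="x_um y_um ux_um uy_um tx_Pa ty_Pa")
    params = {
        "label": label,
        "rng_seed": scene.rng_seed,
        "pixel_size_um": h,
        "image_shape": list(scene.image_shape),
        "young_modulus_Pa": scene.substrate.young_modulus_Pa,
        "poisson_ratio": scene.substrate.poisson_ratio,
        "bead_sigma_um": scene.bead_sigma_um,
        "n_beads": len(scene.bead_positions),
        "n_t": scene.n_t,
        "n_z": scene.n_z,
        "dz_um": scene.dz_um,
        "focus_truth": scene.focus_truth,
        "drift_truth_um": scene.drift_truth_um.tolist(),
    }
    json_path = outdir / f"{label}_scene.json"
    json_path.write_text(json.dumps(params, indent=2, sort_keys=True))
    return {
        "beads": str(beads_path),
        "ref": str(ref_path),
        "cell": str(cell_path),
        "truth": str(truth_path),
        "params": str(json_path),
    }


@dataclass
class SyntheticScene:
    """A complete ground-truth TFM scene (one stage position)."""

    pixel_size_um: float
    image_shape: tuple[int, int]
    substrate: GelSubstrate
    traction_truth: TractionField
    displacement_truth: DisplacementField
    bead_positions: list[Point2D]          # equilibrium (reference) configuration
    bead_positions_stressed: list[Point2D]
    bead_intensities: np.ndarray
    bead_sigma_um: float
    drift_truth_um: np.ndarray             # (n_t, 2) cumulative (dx, dy) per frame
    focus_truth: int
    n_z: int
    dz_um: float
    defocus_rate: float
    noise_model: NoiseModel | None
    rng_seed: int
    cell_center_um: tuple[float, float] = (0.0, 0.0)
    cell_axes_um: tuple[float, float] = (10.0, 10.0)
    n_adhesions: int = 0

    @property
    def n_t(self) -> int:
        return len(self.drift_truth_um)

    def displacement_at(self, positions) -> np.ndarray:
        """Ground-truth (ux, uy) sampled at arbitrary points, shape (n, 2)."""
        d = self.displacement_truth
        xn = d.origin_um[0] + d.spacing_um * np.arange(d.n_cols)
        yn = d.origin_um[1] + d.spacing_um * np.arange(d.n_rows)
        ix = RegularGridInterpolator((yn, xn), d.ux, bounds_error=False, fill_value=0.0)
        iy = RegularGridInterpolator((yn, xn), d.uy, bounds_error=False, fill_value=0.0)
        pos = _as_xy(positions)[:, ::-1]
        return np.stack([ix(pos), iy(pos)], axis=1)

    # ------------------------------------------------------------------ renders
    def render_reference(self, noise_seed: int = 1000) -> GridImage:
        """Equilibrium (cell-detached) bead image, best focus."""
        return render_beads(
            self.bead_positions, self.bead_intensities, self.bead_sigma_um,
            self.image_shape, self.pixel_size_um, self.noise_model, rng_seed=noise_seed,
        )

    def render_reference_zstack(self, noise_seed: int = 2000) -> list[GridImage]:
        return render_zstack(
            self.bead_positions, self.bead_intensities, self.bead_sigma_um,
            self.image_shape, self.pixel_size_um, self.n_z, self.dz_um,
            self.focus_truth, self.defocus_rate, self.noise_model, rng_seed=noise_seed,
        )

    def render_stressed_frame(self, t: int, noise_seed_base: int = 3000) -> GridImage:
        """Stressed bead frame at time t, including stage drift."""
        dx, dy = self.drift_truth_um[t]
        pos = [Point2D(p.x + dx, p.y + dy) for p in self.bead_positions_stressed]
        keep, inten = self._inside(pos)
        img = render_beads(
            keep, inten, self.bead_sigma_um, self.image_shape,
            self.pixel_size_um, self.noise_model, rng_seed=noise_seed_base + t,
        )
        img.t_index = t
        return img

    def render_stressed_zstack(self, noise_seed: int = 4000) -> list[GridImage]:
        return render_zstack(
            self.bead_positions_stressed, self.bead_intensities, self.bead_sigma_um,
            self.image_shape, self.pixel_size_um, self.n_z, self.dz_um,
            self.focus_truth, self.defocus_rate, self.noise_model, rng_seed=noise_seed,
        )

    def render_cell_frame(self, t: int):
        dx, dy = self.drift_truth_um[t]
        img, mask, pts = render_cell_channel(
            self.image_shape, self.pixel_size_um,
            (self.cell_center_um[0] + dx, self.cell_center_um[1] + dy),
            self.cell_axes_um, self.n_adhesions, rng_seed=self.rng_seed + 77,
            noise_model=self.noise_model,
        )
        img.t_index = t
        return img, mask, pts

    def _inside(self, pos):
        nr, nc = self.image_shape
        h = self.pixel_size_um
        keep, inten = [], []
        for p, a in zip(pos, self.bead_intensities):
            if 0 <= p.x <= (nc - 1) * h and 0 <= p.y <= (nr - 1) * h:
                keep.append(p)
                inten.append(a)
        return keep, np.array(inten)


def make_scene(
    rng_seed: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.108,
    young_modulus_Pa: float = 2000.0,
    magnitude_Pa: float = 300.0,
    patch_sigma_um: float = 3.0,
    separation_um: float = 20.0,
    angle_rad: float = 0.0,
    bead_density_per_px2: float = 0.01,
    bead_sigma_px: float = 1.5,
    bead_peak_counts: float = 2000.0,
    n_t: int = 5,
    drift_step_px: float = 0.5,
    n_z: int = 14,
    dz_um: float = 0.2,
    focus_index: int | None = None,
    defocus_rate: float = 1.0,
    noise_model: NoiseModel | None = DEFAULT_NOISE,
    n_adhesions: int = 8,
) -> SyntheticScene:
    """Build a full ground-truth scene: a contractile dipole on a soft gel,
    its forward-model displacement field, a random bead carpet in both the
    equilibrium and stressed configurations, per-frame stage drift, and the
    z-stack/cell-channel parameters.

    Defaults are the package's standard study conditions (see the methods
    note): 512×512 px at 0.108 µm/px, E = 2 kPa, a 300 Pa dipole with 3 µm
    patches 20 µm apart, 0.01 beads/px², five time frames with a 0.5 px/frame
    drift walk, and a 14-slice z-stack at 200 nm steps.
    """
    rng = np.random.default_rng(rng_seed)
    nr, nc = image_shape
    h = pixel_size_um
    substrate = GelSubstrate(young_modulus_Pa, 0.5)
    traction = make_traction_dipole(
        image_shape, h, magnitude_Pa, patch_sigma_um, separation_um, angle_rad
    )
    op = build_fourier_kernel(nr, nc, h, substrate, pad_factor=2)
    displacement = forward_displacement(traction, op)
    n_beads = int(round(bead_density_per_px2 * nr * nc))
    margin = 3.0 * bead_sigma_px * h
    xs = rng.uniform(margin, (nc - 1) * h - margin, n_beads)
    ys = rng.uniform(margin, (nr - 1) * h - margin, n_beads)
    eq = [Point2D(float(x), float(y)) for x, y in zip(xs, ys)]
    total = peak_to_total_counts(bead_peak_counts, bead_sigma_px)
    inten = total * rng.uniform(0.7, 1.3, n_beads)
    stressed_all, dropped = warp_beads(eq, displacement)
    if dropped:  # keep the two configurations index-aligned
        keep = np.setdiff1d(np.arange(n_beads), np.array(dropped))
        eq = [eq[i] for i in keep]
        inten = inten[keep]
    drift = np.cumsum(rng.normal(0.0, drift_step_px * h, (n_t, 2)), axis=0)
    if focus_index is None:
        focus_index = n_z // 2
    cx, cy = (nc - 1) * h / 2.0, (nr - 1) * h / 2.0
    a = min(separation_um * 0.75 + 3.0 * patch_sigma_um, 0.42 * (nc - 1) * h)
    b = min(0.6 * a, 0.42 * (nr - 1) * h)
    return SyntheticScene(
        pixel_size_um=h,
        image_shape=image_shape,
        substrate=substrate,
        traction_truth=traction,
        displacement_truth=displacement,
        bead_positions=eq,
        bead_positions_stressed=stressed_all,
        bead_intensities=inten,
        bead_sigma_um=bead_sigma_px * h,
        drift_truth_um=drift,
        focus_truth=int(focus_index),
        n_z=n_z,
        dz_um=dz_um,
        defocus_rate=defocus_rate,
        noise_model=noise_model,
        rng_seed=rng_seed,
        cell_center_um=(cx, cy),
        cell_axes_um=(a, b),
        n_adhesions=n_adhesions,
    )
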