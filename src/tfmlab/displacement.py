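"""Bead displacement fields by PIV, PTV, and the PIV-seeded hybrid.

PIV splits the image pair into interrogation windows and assigns each
window the normalized-cross-correlation peak shift — robust but averaging.
PTV detects individual beads and pairs them between the equilibrium
(reference) and stressed images by a cost built from position residual and
intensity moments.  The hybrid seeds each bead's search position with the
PIV field interpolated there, so a very small exploration radius suffices
even when the largest displacement exceeds it — the failure mode of plain
PTV that the seeding removes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .core import GridImage
from .fields import DisplacementField

__all__ = [
    "ParticleSet",
    "MatchSet",
    "HybridResult",
    "piv_displacement",
    "detect_particles",
    "link_particles",
    "reject_match_outliers",
    "interpolate_to_grid",
    "estimate_match_noise",
    "hybrid_displacement",
]


# --------------------------------------------------------------------------- PIV

def _subpixel_1d(cm: float, c0: float, cp: float) -> float:
    """3-point Gaussian peak interpolation, parabolic fallback."""
    if cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = lm - 2.0 * l0 + lp
        if denom < 0:
            return float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5))
    denom = cm - 2.0 * c0 + cp
    if denom < 0:
        return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))
    return 0.0


def piv_displacement(
    stressed: GridImage,
    reference: GridImage,
    window_px: int = 32,
    overlap_fraction: float = 0.5,
    peak_ratio_threshold: float = 1.2,
    outlier_threshold: float = 2.0,
    n_passes: int = 2,
) -> DisplacementField:
    """Windowed normalized cross-correlation displacement field (µm).

    Each window's correlation peak is located with a 3-point Gaussian
    sub-pixel fit per axis.  With ``n_passes > 1``, later passes offset the
    stressed-side window by the previous pass's rounded displacement
    (discrete window offset), which removes the loss-of-correlation bias in
    strong displacement gradients.  Windows whose first/second correlation
    peak ratio falls below ``peak_ratio_threshold`` are marked invalid;
    invalid vectors and normalized-median-test outliers (threshold 2.0 over
    8-neighborhoods, fluctuation floor 0.2 px — the sub-pixel fit noise of
    windows at this bead density) are replaced by the median of their valid
    neighbors and flagged as not-valid in the returned mask — never
    silently overwritten.
    """
    if window_px < 16:
        raise ValueError(f"window_px must be >= 16, got {window_px}")
    if not (0.0 <= overlap_fraction <= 0.75):
        raise ValueError(f"overlap_fraction must be in [0, 0.75], got {overlap_fraction}")
    if stressed.shape != reference.shape:
        raise ValueError(f"image shapes differ: {stressed.shape} vs {reference.shape}")
    h = reference.pixel_size_um
    nr, nc = reference.shape
    w = window_px
    step = max(1, int(round(w * (1.0 - overlap_fraction))))
    rows = list(range(0, nr - w + 1, step))
    cols = list(range(0, nc - w + 1, step))
    if len(rows) * len(cols) < 4:
        raise ValueError("image too small for PIV: fewer than 4 interrogation windows")
    hw = w // 2
    prev_ux = prev_uy = None
    for _pass in range(max(1, n_passes)):
        ux = np.zeros((len(rows), len(cols)))
        uy = np.zeros_like(ux)
        good = np.zeros(ux.shape, dtype=bool)
        for ii, i0 in enumerate(rows):
            for jj, j0 in enumerate(cols):
                oi = oj = 0
                if prev_ux is not None:
                    oj = int(round(prev_ux[ii, jj] / h))
                    oi = int(round(prev_uy[ii, jj] / h))
                    if i0 + oi < 0 or j0 + oj < 0 or i0 + oi + w > nr or j0 + oj + w > nc:
                        oi = oj = 0
                a = reference.pixels[i0 : i0 + w, j0 : j0 + w]
                b = stressed.pixels[i0 + oi : i0 + oi + w, j0 + oj : j0 + oj + w]
                a = a - a.mean()
                b = b - b.mean()
                sa, sb = a.std(), b.std()
                if sa == 0 or sb == 0:
                    continue
                corr = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
                corr = np.fft.fftshift(corr) / (w * w * sa * sb)
                pi, pj = np.unravel_index(np.argmax(corr), corr.shape)
                peak = corr[pi, pj]
                # second peak outside an exclusion zone the size of a bead
                # image around the first (closer maxima are the same peak's
                # shoulder, not a competing displacement)
                masked = corr.copy()
                masked[max(0, pi - 3) : pi + 4, max(0, pj - 3) : pj + 4] = -np.inf
                second = masked.max()
                if second > 0 and peak / second < peak_ratio_threshold:
                    continue
                if pi == 0 or pi == w - 1 or pj == 0 or pj == w - 1:
                    continue  # peak on window edge: displacement out of range
                dy = (pi - hw) + _subpixel_1d(corr[pi - 1, pj], peak, corr[pi + 1, pj])
                dx = (pj - hw) + _subpixel_1d(corr[pi, pj - 1], peak, corr[pi, pj + 1])
                ux[ii, jj] = (dx + oj) * h
                uy[ii, jj] = (dy + oi) * h
                good[ii, jj] = True
        valid = _normalized_median_filter(ux, uy, good, outlier_threshold, eps_um=0.2 * h)
        ux, uy = _replace_flagged(ux, uy, valid)
        prev_ux, prev_uy = ux, uy
    origin = (float((cols[0] + (w - 1) / 2.0) * h), float((rows[0] + (w - 1) / 2.0) * h))
    return DisplacementField(ux, uy, spacing_um=step * h, origin_um=origin, valid_mask=valid)


def _normalized_median_filter(ux, uy, good, threshold, eps_um):
    """Westerweel-style normalized median test over 8-neighborhoods."""
    valid = good.copy()
    nr, nc = ux.shape
    for i in range(nr):
        for j in range(nc):
            if not good[i, j]:
                continue
            i0, i1 = max(0, i - 1), min(nr, i + 2)
            j0, j1 = max(0, j - 1), min(nc, j + 2)
            nb = good[i0:i1, j0:j1].copy()
            nb[i - i0, j - j0] = False
            if nb.sum() < 3:
                continue
            r = 0.0
            for comp in (ux, uy):
                vals = comp[i0:i1, j0:j1][nb]
                med = np.median(vals)
                fluct = np.median(np.abs(vals - med))
                r = max(r, abs(comp[i, j] - med) / (fluct + eps_um))
            if r > threshold:
                valid[i, j] = False
    return valid


def _replace_flagged(ux, uy, valid, max_iter=50):
    """Fill not-valid nodes with the median of valid neighbors (iterative)."""
    ux, uy = ux.copy(), uy.copy()
    known = valid.copy()
    nr, nc = ux.shape
    for _ in range(max_iter):
        if known.all():
            break
        progressed = False
        for i, j in np.argwhere(~known):
            i0, i1 = max(0, i - 1), min(nr, i + 2)
            j0, j1 = max(0, j - 1), min(nc, j + 2)
            nb = known[i0:i1, j0:j1]
            if nb.any():
                ux[i, j] = np.median(ux[i0:i1, j0:j1][nb])
                uy[i, j] = np.median(uy[i0:i1, j0:j1][nb])
                known[i, j] = True
                progressed = True
        if not progressed:
            break
    return ux, uy


# --------------------------------------------------------------------------- PTV

@dataclass
class ParticleSet:
    """Detected bead centroids (µm, sub-pixel) with intensity moments.

    ``m0`` is the integrated background-subtracted intensity of the
    particle neighborhood; ``m2`` the second-order radial intensity moment
    (px²), following the ParticleTracker formulation.
    """

    positions: np.ndarray  # (n, 2) as (x, y) µm
    m0: np.ndarray
    m2: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 2)
        self.m0 = np.asarray(self.m0, dtype=np.float64)
        self.m2 = np.asarray(self.m2, dtype=np.float64)
        if len(self.m0) != len(self.positions) or len(self.m2) != len(self.positions):
            raise ValueError("moment arrays must match the number of particles")
        if np.any(self.m0 <= 0):
            raise ValueError("particle m0 must be > 0")

    def __len__(self) -> int:
        return len(self.positions)


def detect_particles(
    img: GridImage,
    radius_px: int = 3,
    intensity_percentile: float = 90.0,
    noise_floor_k: float = 6.0,
) -> ParticleSet:
    """Detect bead-like particles: boxcar background subtraction, local
    maxima above the given intensity percentile (never below
    ``noise_floor_k`` robust noise sigmas, so sparse images do not admit
    noise peaks), sub-pixel centroid refinement within ``radius_px``, and
    merging of duplicates closer than the radius (the brighter detection
    wins)."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    h = img.pixel_size_um
    nr, nc = img.shape
    bg = ndimage.uniform_filter(img.pixels, size=4 * radius_px + 1, mode="nearest")
    resid = img.pixels - bg
    noise_sig = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    work = np.clip(resid, 0.0, None)
    # floor at a small fraction of the brightest feature so that noise-free
    # images do not admit background-subtraction plateau artifacts
    thr = max(
        np.percentile(work, intensity_percentile),
        noise_floor_k * noise_sig,
        0.02 * work.max(),
    )
    if thr <= 0:
        return ParticleSet(np.empty((0, 2)), np.empty(0), np.empty(0))
    mx = ndimage.maximum_filter(work, size=2 * radius_px + 1, mode="nearest")
    cand = np.argwhere((work >= mx) & (work > thr))
    r = radius_px
    # neighborhood grids for centroid refinement
    oy, ox = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (ox**2 + oy**2) <= r * r
    pos, m0s, m2s = [], [], []
    for ci, cj in cand:
        if ci < r + 1 or ci >= nr - r - 1 or cj < r + 1 or cj >= nc - r - 1:
            continue
        yc, xc = float(ci), float(cj)
        for _ in range(3):  # a few centroid iterations
            i0, j0 = int(round(yc)), int(round(xc))
            if i0 < r or i0 >= nr - r or j0 < r or j0 >= nc - r:
                break
            patch = work[i0 - r : i0 + r + 1, j0 - r : j0 + r + 1] * disk
            m0 = patch.sum()
            if m0 <= 0:
                break
            yc = i0 + float((patch * oy).sum() / m0)
            xc = j0 + float((patch * ox).sum() / m0)
        i0, j0 = int(round(yc)), int(round(xc))
        if i0 < r or i0 >= nr - r or j0 < r or j0 >= nc - r:
            continue
        patch = work[i0 - r : i0 + r + 1, j0 - r : j0 + r + 1] * disk
        m0 = float(patch.sum())
        if m0 <= 0:
            continue
        dy2 = (oy + i0 - yc) ** 2
        dx2 = (ox + j0 - xc) ** 2
        m2 = float((patch * (dx2 + dy2)).sum() / m0)
        pos.append((xc * h, yc * h))
        m0s.append(m0)
        m2s.append(m2)
    if not pos:
        return ParticleSet(np.empty((0, 2)), np.empty(0), np.empty(0))
    pos = np.array(pos)
    m0s = np.array(m0s)
    m2s = np.array(m2s)
    # merge duplicates closer than radius: keep the brighter
    order = np.argsort(-m0s)
    tree = cKDTree(pos[order])
    taken = np.zeros(len(order), dtype=bool)
    keep_idx = []
    for oi in range(len(order)):
        if taken[oi]:
            continue
        keep_idx.append(order[oi])
        for nb in tree.query_ball_point(pos[order[oi]], r * h):
            if nb != oi:
                taken[nb] = True
    keep_idx = np.array(sorted(keep_idx))
    return ParticleSet(pos[keep_idx], m0s[keep_idx], m2s[keep_idx])


@dataclass
class MatchSet:
    """One-to-one pairings between reference and stressed particle sets."""

    pairs: np.ndarray           # (m, 2) as (ref index, stressed index)
    ref_positions: np.ndarray   # (m, 2) µm
    displacements: np.ndarray   # (m, 2) µm, stressed − reference
    n_unmatched_ref: int
    n_unmatched_stressed: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if len(self.pairs):
            for col, name in ((0, "reference"), (1, "stressed")):
                if len(np.unique(self.pairs[:, col])) != len(self.pairs):
                    raise ValueError(f"pairing uses a {name} particle twice")

    def __len__(self) -> int:
        return len(self.pairs)


def _seed_at(seed_field: DisplacementField, pos: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the seed field at (x, y) positions; positions
    outside the grid are clamped-checked by the caller."""
    x0, y0 = seed_field.origin_um
    hs = seed_field.spacing_um
    fx = (pos[:, 0] - x0) / hs
    fy = (pos[:, 1] - y0) / hs
    out = np.empty_like(pos)
    coords = np.vstack([fy, fx])
    out[:, 0] = ndimage.map_coordinates(seed_field.ux, coords, order=1, mode="nearest")
    out[:, 1] = ndimage.map_coordinates(seed_field.uy, coords, order=1, mode="nearest")
    return out


def link_particles(
    ref_set: ParticleSet,
    stressed_set: ParticleSet,
    exploration_radius_um: float,
    seed_field: DisplacementField | None = None,
    w0: float | None = None,
    w2: float | None = None,
    method: str = "greedy",
    seed_coverage_margin_um: float | None = None,
) -> MatchSet:
    """Pair reference and stressed particles one-to-one.

    For each reference particle the search is centered at its position plus
    the seed field interpolated there (zero without a seed); stressed
    candidates within ``exploration_radius_um`` of that center are scored by

        cost = ‖Δposition_residual‖² + w0·(Δm0)² + w2·(Δm2)²,

    where w0, w2 default to the inverse variances of m0 and m2 pooled over
    both sets (making the three terms commensurate).  Assignment minimizes
    the total cost one-to-one: greedily by ascending cost followed by
    pairwise swap relaxation (``method="greedy"``, default) or exactly with
    the Hungarian algorithm (``method="hungarian"``).
    """
    if len(ref_set) == 0 or len(stressed_set) == 0:
        raise ValueError("both particle sets must be non-empty")
    rp = ref_set.positions
    sp = stressed_set.positions
    if seed_field is not None:
        x0, y0 = seed_field.origin_um
        hs = seed_field.spacing_um
        xmax = x0 + hs * (seed_field.n_cols - 1)
        ymax = y0 + hs * (seed_field.n_rows - 1)
        # window-centered PIV grids do not reach the image border; particles
        # within the margin get the clamped (nearest-edge) seed, anything
        # farther out is an error
        margin = 2.0 * hs if seed_coverage_margin_um is None else seed_coverage_margin_um
        outside = (
            (rp[:, 0] < x0 - margin)
            | (rp[:, 0] > xmax + margin)
            | (rp[:, 1] < y0 - margin)
            | (rp[:, 1] > ymax + margin)
        )
        if np.any(outside):
            idx = int(np.nonzero(outside)[0][0])
            raise ValueError(
                f"seed field does not cover reference particle {idx} at "
                f"({rp[idx, 0]:.2f}, {rp[idx, 1]:.2f}) µm"
            )
        centers = rp + _seed_at(seed_field, rp)
    else:
        centers = rp
    pooled_m0 = np.concatenate([ref_set.m0, stressed_set.m0])
    pooled_m2 = np.concatenate([ref_set.m2, stressed_set.m2])
    if w0 is None:
        v = np.var(pooled_m0)
        w0 = 1.0 / v if v > 0 else 0.0
    if w2 is None:
        v = np.var(pooled_m2)
        w2 = 1.0 / v if v > 0 else 0.0
    tree = cKDTree(sp)
    cand_lists = tree.query_ball_point(centers, exploration_radius_um)
    edges = []  # (cost, i, j)
    cand_of = {}
    for i, cands in enumerate(cand_lists):
        for j in cands:
            d2 = np.sum((sp[j] - centers[i]) ** 2)
            cost = (
                d2
                + w0 * (stressed_set.m0[j] - ref_set.m0[i]) ** 2
                + w2 * (stressed_set.m2[j] - ref_set.m2[i]) ** 2
            )
            edges.append((cost, i, j))
            cand_of.setdefault(i, {})[j] = cost
    if method == "hungarian":
        pairs = _assign_hungarian(len(rp), len(sp), edges)
    elif method == "greedy":
        pairs = _assign_greedy(edges, cand_of)
    else:
        raise ValueError(f"unknown assignment method {method!r}")
    if not pairs:
        return MatchSet(np.empty((0, 2), int), np.empty((0, 2)), np.empty((0, 2)),
                        len(rp), len(sp))
    pairs = np.array(sorted(pairs), dtype=int)
    disp = sp[pairs[:, 1]] - rp[pairs[:, 0]]
    return MatchSet(
        pairs=pairs,
        ref_positions=rp[pairs[:, 0]],
        displacements=disp,
        n_unmatched_ref=len(rp) - len(pairs),
        n_unmatched_stressed=len(sp) - len(pairs),
    )


def _assign_greedy(edges, cand_of, swap_passes: int = 5):
    edges = sorted(edges)
    ref_of = {}
    str_of = {}
    for cost, i, j in edges:
        if i not in ref_of and j not in str_of:
            ref_of[i] = j
            str_of[j] = i
    for _ in range(swap_passes):
        improved = False
        for i1, j1 in list(ref_of.items()):
            for j2, c12 in cand_of[i1].items():
                if j2 == j1 or j2 not in str_of:
                    continue
                i2 = str_of[j2]
                c11 = cand_of[i1][j1]
                c22 = cand_of[i2][j2]
                c21 = cand_of[i2].get(j1)
                if c21 is None:
                    continue
                if c12 + c21 < c11 + c22 - 1e-15:
                    ref_of[i1], ref_of[i2] = j2, j1
                    str_of[j1], str_of[j2] = i2, i1
                    j1 = j2
                    improved = True
        if not improved:
            break
    return [(i, j) for i, j in ref_of.items()]


def _assign_hungarian(n_ref, n_str, edges):
    if not edges:
        return []
    big = 1e12
    ris = sorted({i for _, i, _ in edges})
    sjs = sorted({j for _, _, j in edges})
    rmap = {i: a for a, i in enumerate(ris)}
    smap = {j: b for b, j in enumerate(sjs)}
    n = max(len(ris), len(sjs))
    cost = np.full((n, n), big)
    for c, i, j in edges:
        cost[rmap[i], smap[j]] = c
    rows, cols = linear_sum_assignment(cost)
    out = []
    for a, b in zip(rows, cols):
        if a < len(ris) and b < len(sjs) and cost[a, b] < big:
            out.append((ris[a], sjs[b]))
    return out


def reject_match_outliers(
    matches: MatchSet, k_neighbors: int = 8, n_mad: float = 3.0, floor_um: float = 0.02
) -> MatchSet:
    """Drop matches whose displacement deviates from the local consensus.

    Each match is compared with the median displacement of its
    ``k_neighbors`` nearest matches; deviations beyond ``n_mad`` local MADs
    (plus an absolute floor that protects against zero-MAD neighborhoods)
    mark mislinked pairs, which would otherwise contaminate the gridded
    field with bead-spacing-scale spikes.
    """
    n = len(matches)
    if n <= k_neighbors + 1:
        return matches
    tree = cKDTree(matches.ref_positions)
    _, idx = tree.query(matches.ref_positions, k=k_neighbors + 1)
    nbd = matches.displacements[idx[:, 1:]]
    med = np.median(nbd, axis=1)
    dev = np.hypot(
        matches.displacements[:, 0] - med[:, 0], matches.displacements[:, 1] - med[:, 1]
    )
    mad = np.median(np.abs(nbd - med[:, None, :]).reshape(n, -1), axis=1)
    keep = dev <= n_mad * mad + floor_um
    return MatchSet(
        pairs=matches.pairs[keep],
        ref_positions=matches.ref_positions[keep],
        displacements=matches.displacements[keep],
        n_unmatched_ref=matches.n_unmatched_ref + int((~keep).sum()),
        n_unmatched_stressed=matches.n_unmatched_stressed + int((~keep).sum()),
    )


def estimate_match_noise(
    matches: MatchSet,
    origin_um: tuple[float, float],
    spacing_um: float,
    n_rows: int,
    n_cols: int,
    bandwidth_um: float | None = None,
) -> float:
    """Per-node displacement noise (µm) expected after Gaussian-weighted
    gridding: the weighted scatter of member displacements about the node
    mean, scaled by the effective number of contributing beads; the median
    over nodes is returned."""
    if bandwidth_um is None:
        bandwidth_um = spacing_um
    sigma = bandwidth_um / 2.355
    cut = 3.0 * sigma
    gx = origin_um[0] + spacing_um * np.arange(n_cols)
    gy = origin_um[1] + spacing_um * np.arange(n_rows)
    nodes = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)
    p = matches.ref_positions
    d = matches.displacements
    tree = cKDTree(p)
    out = []
    for k, nb in enumerate(tree.query_ball_point(nodes, cut)):
        if len(nb) < 3:
            continue
        nb = np.asarray(nb)
        w = np.exp(-0.5 * np.sum((p[nb] - nodes[k]) ** 2, axis=1) / sigma**2)
        tw = w.sum()
        mu = (w[:, None] * d[nb]).sum(axis=0) / tw
        var = (w[:, None] * (d[nb] - mu) ** 2).sum(axis=0) / tw
        neff = tw**2 / np.sum(w**2)
        out.append(np.sqrt(var.mean() / neff))
    if not out:
        return 0.0
    return float(np.median(out))


# ------------------------------------------------------------------- gridding

def interpolate_to_grid(
    matches: MatchSet,
    origin_um: tuple[float, float],
    spacing_um: float,
    n_rows: int,
    n_cols: int,
    bandwidth_um: float | None = None,
    weight_floor: float = 0.05,
) -> DisplacementField:
    """Grid scattered PTV displacements by Gaussian-weighted averaging.

    The Gaussian bandwidth (FWHM) defaults to the grid spacing; weights are
    truncated at 3σ.  Nodes whose total weight falls below ``weight_floor``
    are marked invalid (they carry the value of their nearest match for
    continuity but are flagged).  Requires at least 3 non-collinear matches.
    """
    if len(matches) < 3:
        raise ValueError(f"need at least 3 matched particles, got {len(matches)}")
    p = matches.ref_positions
    centered = p - p.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("matched particles are collinear; cannot grid a 2D field")
    if bandwidth_um is None:
        bandwidth_um = spacing_um
    sigma = bandwidth_um / 2.355  # FWHM -> σ
    cut = 3.0 * sigma
    gx = origin_um[0] + spacing_um * np.arange(n_cols)
    gy = origin_um[1] + spacing_um * np.arange(n_rows)
    nodes = np.stack(np.meshgrid(gx, gy), axis=-1).reshape(-1, 2)
    tree = cKDTree(p)
    neighbors = tree.query_ball_point(nodes, cut)
    ux = np.zeros(len(nodes))
    uy = np.zeros(len(nodes))
    valid = np.zeros(len(nodes), dtype=bool)
    d = matches.displacements
    for k, idx in enumerate(neighbors):
        if not idx:
            continue
        idx = np.asarray(idx)
        dist2 = np.sum((p[idx] - nodes[k]) ** 2, axis=1)
        wgt = np.exp(-0.5 * dist2 / sigma**2)
        tw = wgt.sum()
        if tw < weight_floor:
            continue
        ux[k] = float((wgt * d[idx, 0]).sum() / tw)
        uy[k] = float((wgt * d[idx, 1]).sum() / tw)
        valid[k] = True
    # carry nearest-match values at invalid nodes for continuity
    if not valid.all():
        _, nearest = tree.query(nodes[~valid])
        ux[~valid] = d[nearest, 0]
        uy[~valid] = d[nearest, 1]
    return DisplacementField(
        ux.reshape(n_rows, n_cols),
        uy.reshape(n_rows, n_cols),
        spacing_um,
        origin_um,
        valid.reshape(n_rows, n_cols),
    )


@dataclass
class HybridResult:
    """Output of the full displacement stage."""

    field: DisplacementField
    matches: MatchSet
    piv: DisplacementField
    noise_sigma_um: float

    def __iter__(self):  # allow field, matches, piv = result
        return iter((self.field, self.matches, self.piv))


def hybrid_displacement(
    stressed: GridImage,
    reference: GridImage,
    window_px: int = 32,
    overlap_fraction: float = 0.75,
    exploration_radius_um: float | None = None,
    radius_px: int = 3,
    intensity_percentile: float = 90.0,
) -> HybridResult:
    """The full displacement stage: PIV, particle detection in both images,
    PIV-seeded linking with a small exploration radius (default 2 px in
    physical units), local-consensus outlier rejection, and gridding onto
    the PIV node lattice.

    The result also carries the expected per-node noise level estimated
    from the bead-displacement scatter, ready to feed the traction solver's
    discrepancy criterion.
    """
    h = reference.pixel_size_um
    if exploration_radius_um is None:
        exploration_radius_um = 2.0 * h
    piv = piv_displacement(stressed, reference, window_px, overlap_fraction)
    ref_parts = detect_particles(reference, radius_px, intensity_percentile)
    str_parts = detect_particles(stressed, radius_px, intensity_percentile)
    # the PIV grid is inset from the image border (window centering plus the
    # leftover of uneven tiling); particles in that border band get the
    # clamped edge seed
    nr, nc = reference.shape
    margin = max(
        piv.origin_um[0],
        piv.origin_um[1],
        (nc - 1) * h - (piv.origin_um[0] + piv.spacing_um * (piv.n_cols - 1)),
        (nr - 1) * h - (piv.origin_um[1] + piv.spacing_um * (piv.n_rows - 1)),
    ) + 1e-9
    matches = link_particles(
        ref_parts, str_parts, exploration_radius_um, seed_field=piv,
        seed_coverage_margin_um=margin,
    )
    matches = reject_match_outliers(matches)
    # Grid the per-bead residuals relative to the PIV baseline: where bead
    # support is locally missing the field falls back to PIV instead of a
    # stale nearest-match vector.
    baseline = _seed_at(piv, matches.ref_positions)
    residuals = MatchSet(
        matches.pairs, matches.ref_positions, matches.displacements - baseline, 0, 0
    )
    fres = interpolate_to_grid(
        residuals, piv.origin_um, piv.spacing_um, piv.n_rows, piv.n_cols
    )
    ux = piv.ux + np.where(fres.valid_mask, fres.ux, 0.0)
    uy = piv.uy + np.where(fres.valid_mask, fres.uy, 0.0)
    field = DisplacementField(
        ux, uy, piv.spacing_um, piv.origin_um, piv.valid_mask | fres.valid_mask
    )
    # Noise model for the traction solver's discrepancy criterion: the RMS
    # disagreement (per component) between the two estimators bounds their
    # combined uncertainty and, unlike a split-half estimate, also sees
    # error components shared by neighboring beads (PSF-overlap bias,
    # window-averaging bias); the split-half estimate serves as a floor.
    disagreement = float(
        np.sqrt(0.5 * np.mean((field.ux - piv.ux) ** 2 + (field.uy - piv.uy) ** 2))
    )
    noise = max(_split_half_noise(residuals, piv), disagreement)
    return HybridResult(field=field, matches=matches, piv=piv, noise_sigma_um=noise)


def _split_half_noise(residuals: MatchSet, piv: DisplacementField) -> float:
    """Per-component node noise of the gridded field by a split-half estimate.

    The matches are split into two interleaved halves (deterministic index
    parity), each half gridded separately; each half carries twice the
    variance of the full field, so the per-component noise of the full
    field is half the standard deviation of the half-field difference.
    """
    n = len(residuals)
    if n < 12:
        return 0.0
    sel = np.arange(n) % 2 == 0
    halves = []
    for s in (sel, ~sel):
        ms = MatchSet(residuals.pairs[s], residuals.ref_positions[s],
                      residuals.displacements[s], 0, 0)
        try:
            halves.append(
                interpolate_to_grid(ms, piv.origin_um, piv.spacing_um, piv.n_rows, piv.n_cols)
            )
        except ValueError:
            return 0.0
    both = halves[0].valid_mask & halves[1].valid_mask
    if both.sum() < 8:
        return 0.0
    dx = (halves[0].ux - halves[1].ux)[both]
    dy = (halves[0].uy - halves[1].uy)[both]
    return float(0.5 * np.sqrt(0.5 * (np.var(dx) + np.var(dy))))
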