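"""Cell/focal-adhesion segmentation and traction integration.

Total force is the integral of the traction magnitude over the segmented
cell area (Pa·µm² = pN); the force ratio divides it by the area, i.e. the
mean stress under the cell.  Focal adhesions (FAs) are segmented by simple
thresholding of a fluorescent marker channel and traction stress sums are
integrated per FA region.  Traction is integrated on its own (coarser) node
grid rather than resampled to pixels, avoiding invented sub-node detail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import disk

from .core import GridImage, Point2D, NN_PER_PA_UM2
from .fields import TractionField

__all__ = [
    "CellMask",
    "ForceRecord",
    "segment_cell",
    "track_cell",
    "segment_adhesions",
    "integrate_force",
]


@dataclass
class CellMask:
    """Binary mask of a single cell on the (cropped) image grid."""

    mask: np.ndarray
    pixel_size_um: float
    t_index: int | None = None
    tracking_flagged: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if label(self.mask).max() > 1:
            raise ValueError("cell mask must be a single connected component")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2

    @property
    def centroid(self) -> Point2D:
        r, c = ndimage.center_of_mass(self.mask)
        return Point2D(x=c * self.pixel_size_um, y=r * self.pixel_size_um)


def segment_cell(
    img: GridImage,
    smoothing_sigma_px: float = 2.0,
    use_variance_map: bool = False,
) -> CellMask:
    """Segment the cell: Gaussian smoothing → Otsu threshold → morphological
    closing (3 px disk) → hole filling → largest connected component.

    Bright-field images lack a bimodal intensity histogram; pass
    ``use_variance_map=True`` to segment a 7-px local-variance map instead
    of raw intensity.
    """
    work = img.pixels
    if use_variance_map:
        mean = ndimage.uniform_filter(work, size=7, mode="nearest")
        sq = ndimage.uniform_filter(work**2, size=7, mode="nearest")
        work = np.clip(sq - mean**2, 0.0, None)
    sm = ndimage.gaussian_filter(work, smoothing_sigma_px, mode="nearest")
    if sm.max() == sm.min():
        raise ValueError("no cell found: image is constant")
    thr = threshold_otsu(sm)
    fg = sm > thr
    fg = ndimage.binary_closing(fg, structure=disk(3))
    fg = ndimage.binary_fill_holes(fg)
    lbl, n = label(fg, return_num=True)
    if n == 0:
        raise ValueError("no cell found: empty foreground after thresholding")
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    biggest = 1 + int(np.argmax(sizes))
    return CellMask(lbl == biggest, img.pixel_size_um, t_index=img.t_index)


def track_cell(images: list[GridImage], **segment_kwargs) -> list[CellMask]:
    """Segment and follow one cell across a time series.

    At each time point all candidate components are extracted and the one
    maximizing pixel overlap with the previous mask is kept (first frame:
    the largest component).  Frames with no overlap fall back to the
    nearest-centroid component and are flagged.
    """
    if len(images) == 0:
        raise ValueError("need at least one time point")
    masks: list[CellMask] = []
    prev: CellMask | None = None
    for img in images:
        work = img.pixels
        if segment_kwargs.get("use_variance_map"):
            mean = ndimage.uniform_filter(work, size=7, mode="nearest")
            sq = ndimage.uniform_filter(work**2, size=7, mode="nearest")
            work = np.clip(sq - mean**2, 0.0, None)
        sm = ndimage.gaussian_filter(work, segment_kwargs.get("smoothing_sigma_px", 2.0), mode="nearest")
        thr = threshold_otsu(sm) if sm.max() > sm.min() else np.inf
        fg = ndimage.binary_fill_holes(ndimage.binary_closing(sm > thr, structure=disk(3)))
        lbl, n = label(fg, return_num=True)
        if n == 0:
            if prev is None:
                raise ValueError("no cell found in the first frame")
            masks.append(CellMask(prev.mask.copy(), img.pixel_size_um, img.t_index, tracking_flagged=True))
            continue
        if prev is None:
            sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
            pick, flagged = 1 + int(np.argmax(sizes)), False
        else:
            overlaps = np.array(
                [np.sum((lbl == k) & prev.mask) for k in range(1, n + 1)]
            )
            if overlaps.max() > 0:
                pick, flagged = 1 + int(np.argmax(overlaps)), False
            else:
                pc = prev.centroid
                dists = []
                for k in range(1, n + 1):
                    r, c = ndimage.center_of_mass(lbl == k)
                    dists.append(np.hypot(c * img.pixel_size_um - pc.x, r * img.pixel_size_um - pc.y))
                pick, flagged = 1 + int(np.argmin(dists)), True
        m = CellMask(lbl == pick, img.pixel_size_um, img.t_index, tracking_flagged=flagged)
        masks.append(m)
        prev = m
    return masks


def segment_adhesions(
    img: GridImage,
    cell_mask: np.ndarray | None = None,
    background_sigma_px: float = 20.0,
    threshold_k: float = 3.0,
    min_size_px: int = 4,
) -> np.ndarray:
    """Label focal adhesions by simple thresholding of the fluorescent
    FA-marker channel.

    A large-σ Gaussian background is subtracted, pixels above
    mean + k·std of the cell interior (whole image if no mask) are kept,
    fragments separated by a 1-px gap are merged (connectivity is taken on
    a 1-px-dilated mask while the labeled pixels keep the original
    support), and components below ``min_size_px`` are discarded.  Returns
    a label image (0 = background); zero adhesions is allowed.
    """
    work = img.pixels - ndimage.gaussian_filter(img.pixels, background_sigma_px, mode="nearest")
    region = work[cell_mask] if cell_mask is not None else work.ravel()
    thr = region.mean() + threshold_k * region.std()
    fg = work > thr
    if cell_mask is not None:
        fg &= cell_mask
    dilated = ndimage.binary_dilation(fg, structure=disk(1))
    lbl_d, n = label(dilated, return_num=True)
    lbl = np.where(fg, lbl_d, 0)
    if n == 0:
        return lbl
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    out = np.zeros_like(lbl)
    nxt = 1
    for k in range(1, n + 1):
        if sizes[k - 1] >= min_size_px:
            out[lbl == k] = nxt
            nxt += 1
    return out


@dataclass
class ForceRecord:
    """Integrated traction metrics for one cell at one time point."""

    t_index: int | None
    total_force_pN: float
    area_um2: float
    n_FA: int
    per_FA_stress_sums: list[float]  # Pa·µm² per focal adhesion

    @property
    def total_force_nN(self) -> float:
        return self.total_force_pN * NN_PER_PA_UM2

    @property
    def force_ratio_Pa(self) -> float:
        """Total force / area: the mean stress magnitude under the cell (Pa)."""
        return self.total_force_pN / self.area_um2 if self.area_um2 > 0 else 0.0


def _nodes_in_mask(traction: TractionField, mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Boolean (n_rows, n_cols) of traction nodes whose nearest pixel is masked."""
    rows = np.clip(np.rint(traction.grid_y[:, 0] / pixel_size_um).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.rint(traction.grid_x[0, :] / pixel_size_um).astype(int), 0, mask.shape[1] - 1)
    return mask[np.ix_(rows, cols)]


def integrate_force(
    traction: TractionField,
    cell: CellMask,
    fa_labels: np.ndarray | None = None,
) -> ForceRecord:
    """Integrate |T| over the cell selection (and per FA region).

    Traction nodes are mapped to mask pixels by nearest-node lookup; the
    total force is Σ |T|·h² over in-mask nodes (Pa·µm² = pN) and the force
    ratio divides by the segmented cell area.  Both grids must live in the
    same (cropped) frame.
    """
    nr_px = cell.mask.shape[0]
    max_y = traction.grid_y[-1, 0]
    if max_y > (nr_px - 1 + 0.5) * cell.pixel_size_um + traction.spacing_um:
        raise ValueError("traction grid extends beyond the mask frame: frame mismatch")
    a = traction.spacing_um**2
    inside = _nodes_in_mask(traction, cell.mask, cell.pixel_size_um)
    mag = traction.magnitude
    total = float(mag[inside].sum() * a)
    per_fa: list[float] = []
    n_fa = 0
    if fa_labels is not None:
        n_fa = int(fa_labels.max())
        for k in range(1, n_fa + 1):
            sel = _nodes_in_mask(traction, fa_labels == k, cell.pixel_size_um)
            per_fa.append(float(mag[sel].sum() * a))
    return ForceRecord(
        t_index=cell.t_index,
        total_force_pN=total,
        area_um2=cell.area_um2,
        n_FA=n_fa,
        per_FA_stress_sums=per_fa,
    )
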