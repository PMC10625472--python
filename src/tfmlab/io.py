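"""Readers and writers for the pipeline's interchange formats.

Images move as TIFF (32-bit float for maps), tables as plain ASCII/CSV, and
microscope input as OME-TIFF.  The input convention is one file per stage
position and channel holding a z-stack followed by the time-series frames;
files written here store them as two OME series (series 0 = z-stack,
series 1 = time series) with the pixel size in the OME metadata, and the
reader also accepts single-series files split by an explicit ``n_z``.

All tables are written with fixed numeric formats so that repeated runs on
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import tifffile

from .core import GridImage
from .fields import DisplacementField, TractionField
from .registration import DriftTrace

__all__ = [
    "write_field_ascii",
    "read_field_meta",
    "read_displacement_ascii",
    "write_traction_ascii",
    "read_traction_ascii",
    "write_drift_ascii",
    "read_drift_ascii",
    "write_focus_scores",
    "write_tiff",
    "read_tiff_stack",
    "write_ome_series",
    "read_ome_series",
    "overlay_beads_jpeg",
    "quiver_overlay_jpeg",
]


# ------------------------------------------------------------------ ASCII tables

def write_field_ascii(field: DisplacementField, path, extra_meta: dict | None = None) -> None:
    """Displacement table: one row per node, ``x_um y_um ux_um uy_um valid``.

    Coordinates are µm in the image frame (row = +y, col = +x, origin at
    the center of pixel [0, 0] of the frame the field was computed on).
    ``extra_meta`` key=value pairs (e.g. the estimated noise level) go into
    the header comment.
    """
    rows = np.column_stack(
        [
            field.grid_x.ravel(),
            field.grid_y.ravel(),
            field.ux.ravel(),
            field.uy.ravel(),
            field.valid_mask.ravel().astype(float),
        ]
    )
    header = (
        f"x_um y_um ux_um uy_um valid\n"
        f"n_rows={field.n_rows} n_cols={field.n_cols} spacing_um={field.spacing_um:.9g} "
        f"origin_x_um={field.origin_um[0]:.9g} origin_y_um={field.origin_um[1]:.9g}"
    )
    if extra_meta:
        header += "\n" + " ".join(f"{k}={v:.9g}" for k, v in extra_meta.items())
    np.savetxt(path, rows, fmt="%.6f %.6f %.9e %.9e %d", header=header)


def _parse_grid_header(path):
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for m in re.finditer(r"(\w+)=([-\d.eE+]+)", line):
                meta[m.group(1)] = float(m.group(2))
    return meta


def read_field_meta(path) -> dict:
    """Numeric key=value metadata from a field table's header comments."""
    return _parse_grid_header(path)


def read_displacement_ascii(path) -> DisplacementField:
    meta = _parse_grid_header(path)
    data = np.loadtxt(path)
    nr, nc = int(meta["n_rows"]), int(meta["n_cols"])
    return DisplacementField(
        data[:, 2].reshape(nr, nc),
        data[:, 3].reshape(nr, nc),
        meta["spacing_um"],
        (meta["origin_x_um"], meta["origin_y_um"]),
        data[:, 4].reshape(nr, nc) > 0.5,
    )


def write_traction_ascii(traction: TractionField, path) -> None:
    """Traction table: ``x_um y_um tx_Pa ty_Pa t_mag_Pa`` per node (same frame
    convention as the displacement writer)."""
    rows = np.column_stack(
        [
            traction.grid_x.ravel(),
            traction.grid_y.ravel(),
            traction.tx.ravel(),
            traction.ty.ravel(),
            traction.magnitude.ravel(),
        ]
    )
    header = (
        f"x_um y_um tx_Pa ty_Pa t_mag_Pa\n"
        f"n_rows={traction.n_rows} n_cols={traction.n_cols} spacing_um={traction.spacing_um:.9g} "
        f"origin_x_um={traction.origin_um[0]:.9g} origin_y_um={traction.origin_um[1]:.9g}"
    )
    np.savetxt(path, rows, fmt="%.6f %.6f %.6e %.6e %.6e", header=header)


def read_traction_ascii(path) -> TractionField:
    meta = _parse_grid_header(path)
    data = np.loadtxt(path)
    nr, nc = int(meta["n_rows"]), int(meta["n_cols"])
    return TractionField(
        data[:, 2].reshape(nr, nc),
        data[:, 3].reshape(nr, nc),
        meta["spacing_um"],
        (meta["origin_x_um"], meta["origin_y_um"]),
    )


def write_drift_ascii(trace: DriftTrace, path) -> None:
    r0, r1, c0, c1 = trace.crop_box
    t = np.arange(len(trace.shifts_px))
    rows = np.column_stack([t, trace.shifts_px])
    np.savetxt(
        path,
        rows,
        fmt="%d %.6f %.6f",
        header=f"t dx_px dy_px\ncrop_box={r0},{r1},{c0},{c1}",
    )


def read_drift_ascii(path) -> DriftTrace:
    crop = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "crop_box=" in line:
                crop = tuple(int(v) for v in line.split("crop_box=")[1].strip().split(","))
    data = np.loadtxt(path).reshape(-1, 3)
    return DriftTrace(shifts_px=data[:, 1:3], crop_box=crop)


def write_focus_scores(report, path) -> None:
    rows = np.column_stack([np.arange(len(report.scores)), report.scores])
    np.savetxt(
        path,
        rows,
        fmt="%d %.9e",
        header=f"slice_index score\nmetric={report.metric_name} best_index={report.best_index}",
    )


# ---------------------------------------------------------------------- TIFF

def write_tiff(images, path, pixel_size_um: float | None = None) -> None:
    """Write an image or stack as 32-bit float TIFF (no timestamps, so output
    is byte-reproducible)."""
    if isinstance(images, GridImage):
        arr = images.pixels[None].astype(np.float32)
        pixel_size_um = pixel_size_um or images.pixel_size_um
    elif isinstance(images, np.ndarray):
        arr = (images[None] if images.ndim == 2 else images).astype(np.float32)
    else:
        arr = np.stack([im.pixels for im in images]).astype(np.float32)
        pixel_size_um = pixel_size_um or images[0].pixel_size_um
    res = None
    if pixel_size_um:
        res = (1.0 / pixel_size_um, 1.0 / pixel_size_um)
    tifffile.imwrite(path, arr, photometric="minisblack", resolution=res)


def read_tiff_stack(path, pixel_size_um: float) -> list[GridImage]:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return [GridImage(a, pixel_size_um, t_index=i) for i, a in enumerate(arr)]


# ------------------------------------------------------------------ OME-TIFF

def write_ome_series(
    path,
    zstack: np.ndarray | None,
    tseries: np.ndarray | None,
    pixel_size_um: float,
    channel_tag: str = "",
) -> None:
    """Write the z-stack-then-time-series layout of one position/channel.

    The z-stack is stored as OME series 0 (axes ZYX) and the time series as
    series 1 (axes TYX); pages therefore appear in the file as the z-stack
    followed by the time-series frames.  Pixel size goes into the OME
    PhysicalSize fields.
    """
    meta_common = {
        "PhysicalSizeX": pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": pixel_size_um,
        "PhysicalSizeYUnit": "µm",
    }
    with tifffile.TiffWriter(path, ome=True) as tw:
        if zstack is not None and len(zstack):
            tw.write(
                np.asarray(zstack, dtype=np.float32),
                photometric="minisblack",
                metadata={"axes": "ZYX", "Name": f"{channel_tag}_zstack", **meta_common},
            )
        if tseries is not None and len(tseries):
            tw.write(
                np.asarray(tseries, dtype=np.float32),
                photometric="minisblack",
                metadata={"axes": "TYX", "Name": f"{channel_tag}_tseries", **meta_common},
            )


def _pixel_size_from_ome(xml: str | None) -> float | None:
    if not xml:
        return None
    m = re.search(r'PhysicalSizeX="([\d.eE+-]+)"', xml)
    return float(m.group(1)) if m else None


def read_ome_series(
    path,
    n_z: int | None = None,
    pixel_size_um: float | None = None,
    channel_tag: str = "",
):
    """Read one position/channel file into (z-stack, time series, pixel size).

    Two-series OME files (as written by :func:`write_ome_series`) split
    unambiguously; single-series plain TIFFs fall back to the page-count
    convention — the first ``n_z`` pages are the z-stack, the rest the time
    series.  The pixel size comes from the OME metadata, else from the
    ``pixel_size_um`` argument, else an error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        px = _pixel_size_from_ome(tif.ome_metadata) or pixel_size_um
        if px is None:
            raise ValueError(
                f"{path}: pixel size missing from OME metadata and no fallback configured"
            )
        series = tif.series
        if len(series) >= 2:
            zarr_ = series[0].asarray()
            tarr = series[1].asarray()
            if zarr_.ndim == 2:
                zarr_ = zarr_[None]
            if tarr.ndim == 2:
                tarr = tarr[None]
        else:
            arr = series[0].asarray()
            if arr.ndim == 2:
                arr = arr[None]
            if n_z is None:
                zarr_, tarr = arr, arr[:0]
            else:
                if len(arr) < n_z:
                    raise ValueError(
                        f"{path}: expected at least n_z={n_z} pages, found {len(arr)}"
                    )
                zarr_, tarr = arr[:n_z], arr[n_z:]
    zimgs = [
        GridImage(a, px, channel_tag=channel_tag, z_index=i) for i, a in enumerate(zarr_)
    ]
    timgs = [
        GridImage(a, px, channel_tag=channel_tag, t_index=i) for i, a in enumerate(tarr)
    ]
    return zimgs, timgs, px


# ------------------------------------------------------------------ overlays

def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(img, (1, 99.8))
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def overlay_beads_jpeg(reference: GridImage, stressed: GridImage, path) -> None:
    """Green/red superposition of the reference and stressed bead images —
    displaced bead pairs appear as green/red doublets."""
    from PIL import Image

    g = _normalize(reference.pixels)
    r = _normalize(stressed.pixels)
    rgb = np.stack([r, g, np.zeros_like(g)], axis=-1)
    Image.fromarray((rgb * 255).astype(np.uint8)).save(path, quality=90)


def quiver_overlay_jpeg(
    background: GridImage,
    field,
    path,
    subsample: int = 1,
    scale: float | None = None,
    color: str = "yellow",
) -> None:
    """Vector arrows (displacement or traction) over an image, saved as JPEG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h = background.pixel_size_um
    fig, ax = plt.subplots(figsize=(6, 6 * background.shape[0] / background.shape[1]), dpi=110)
    ax.imshow(_normalize(background.pixels), cmap="gray", origin="upper",
              extent=[-0.5 * h, (background.shape[1] - 0.5) * h,
                      (background.shape[0] - 0.5) * h, -0.5 * h])
    s = slice(None, None, subsample)
    if hasattr(field, "tx"):
        vx, vy = field.tx, field.ty
    else:
        vx, vy = field.ux, field.uy
    ax.quiver(
        field.grid_x[s, s], field.grid_y[s, s], vx[s, s], -vy[s, s],
        color=color, scale=scale, width=0.003,
    )
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0, format="jpg")
    plt.close(fig)
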