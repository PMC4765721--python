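"""Running-window smoothing and 2D density rendering with exact geometry.

Depths and minor fractions are smoothed along the genome (per chromosome,
in positional order) with a running median or mean; the window shrinks
symmetrically at chromosome ends so every locus keeps an output.  The
smoothed observations are then binned into a 2D (depth x fraction)
density raster and written as a PNG whose axis geometry is recorded in a
plain-text sidecar, so that overlays can map data coordinates to pixels
exactly — the same affine mapping is shared by density rendering and node
overlay.

The window size trades noise against resolution: with many loci a window
of ~51 suppresses sampling noise while clonal states remain separate
clusters; with few loci the same window spans several states and merges
their clusters, so a smaller window (e.g. 11) is preferable.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from matplotlib import colormaps
from scipy import ndimage

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 51
SMOOTHED_COLUMNS = ["chrom", "pos", "smoothed_depth", "smoothed_fraction"]


def _running_1d(values: np.ndarray, window: int, statistic: str) -> np.ndarray:
    n = len(values)
    half = window // 2
    out = np.empty(n, dtype=float)
    fn = np.median if statistic == "median" else np.mean
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = fn(values[i - k : i + k + 1])
    return out


def running_smooth(
    observations: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    statistic: str = "median",
) -> pd.DataFrame:
    """Smooth depth and minor fraction along each chromosome.

    Parameters
    ----------
    observations
        Frame with chrom, pos, depth, minor_fraction (one row per locus).
    window
        Odd window length in loci; 1 is the identity.  At chromosome ends
        the window shrinks symmetrically (position i uses i +/- k with
        k = min(half, i, n-1-i)), so no locus is dropped.
    statistic
        "median" (default) or "mean".

    Returns one SmoothedObservation row per input row, same order within
    chromosome; smoothing never crosses a chromosome boundary.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    frames = []
    for chrom, grp in observations.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="stable")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": grp["pos"].to_numpy(),
                    "smoothed_depth": _running_1d(
                        grp["depth"].to_numpy(float), window, statistic
                    ),
                    "smoothed_fraction": _running_1d(
                        grp["minor_fraction"].to_numpy(float), window, statistic
                    ),
                }
            )
        )
    if not frames:
        raise ValueError("no observations to smooth")
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class PlotMetadata:
    """Axis limits and pixel geometry of a density image.

    The data area (plot region) is inset from the full image by a margin;
    depth runs along x in [depth_min, depth_max], minor fraction along y
    in [fraction_min, fraction_max] (0 to 0.5 by convention, with 0 at
    the bottom of the plot).
    """

    depth_min: float = 0.0
    depth_max: float = 100.0
    fraction_min: float = 0.0
    fraction_max: float = 0.5
    image_width_px: int = 800
    image_height_px: int = 800
    margin_px: int = 60

    def __post_init__(self) -> None:
        if not self.depth_min < self.depth_max:
            raise ValueError("depth_min must be < depth_max")
        if not self.fraction_min < self.fraction_max:
            raise ValueError("fraction_min must be < fraction_max")
        left, right, top, bottom = self.plot_region
        if not (0 < left < right < self.image_width_px
                and 0 < top < bottom < self.image_height_px):
            raise ValueError("plot region must lie strictly inside the image")

    @property
    def plot_region(self) -> tuple[int, int, int, int]:
        """(left, right, top, bottom) pixel bounds of the data area."""
        return (
            self.margin_px,
            self.image_width_px - self.margin_px,
            self.margin_px,
            self.image_height_px - self.margin_px,
        )

    def write_sidecar(self, path: str) -> None:
        with open(path, "w") as fh:
            for key in (
                "depth_min", "depth_max", "fraction_min", "fraction_max",
                "image_width_px", "image_height_px", "margin_px",
            ):
                fh.write(f"{key}={getattr(self, key)}\n")

    @classmethod
    def read_sidecar(cls, path: str) -> "PlotMetadata":
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, value = line.split("=", 1)
                key = key.strip()
                if key.endswith("_px"):
                    kwargs[key] = int(float(value))
                else:
                    kwargs[key] = float(value)
        return cls(**kwargs)


def sidecar_path(image_path: str) -> str:
    """`sample.png` -> `sample.meta`, next to the image."""
    return os.path.splitext(str(image_path))[0] + ".meta"


def data_to_pixel(meta: PlotMetadata, depth, fraction):
    """Affine map from data coordinates to (float) pixel coordinates."""
    left, right, top, bottom = meta.plot_region
    depth = np.asarray(depth, dtype=float)
    fraction = np.asarray(fraction, dtype=float)
    px = left + (depth - meta.depth_min) / (meta.depth_max - meta.depth_min) * (right - left)
    py = bottom - (fraction - meta.fraction_min) / (meta.fraction_max - meta.fraction_min) * (bottom - top)
    return px, py


def pixel_to_data(meta: PlotMetadata, px, py):
    """Inverse of :func:`data_to_pixel` within the plot region."""
    left, right, top, bottom = meta.plot_region
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    depth = meta.depth_min + (px - left) / (right - left) * (meta.depth_max - meta.depth_min)
    fraction = meta.fraction_min + (bottom - py) / (bottom - top) * (meta.fraction_max - meta.fraction_min)
    return depth, fraction


@dataclass
class DensityImage:
    """A density raster at plot-region resolution plus its geometry.

    ``raster[row, col]`` has row 0 at the top of the plot region
    (fraction_max) and col 0 at the left (depth_min); its shape equals
    the plot-region pixel dimensions.  ``histogram_mass`` is the total
    count before any kernel smoothing; ``n_clipped`` the observations
    outside the axis limits.
    """

    raster: np.ndarray
    metadata: PlotMetadata
    histogram_mass: float
    n_clipped: int

    def to_pil(self, cmap_name: str = "Greys") -> Image.Image:
        """Render to a PIL image (white canvas, colormapped data area)."""
        meta = self.metadata
        left, right, top, bottom = meta.plot_region
        norm = self.raster / self.raster.max() if self.raster.max() > 0 else self.raster
        cmap = colormaps[cmap_name]
        rgba = (cmap(norm) * 255).astype(np.uint8)
        canvas = Image.new("RGB", (meta.image_width_px, meta.image_height_px),
                           (255, 255, 255))
        canvas.paste(Image.fromarray(rgba[:, :, :3]), (left, top))
        # 1-px frame around the data area
        frame = np.array(canvas)
        frame[top - 1, left - 1 : right + 1] = 0
        frame[bottom, left - 1 : right + 1] = 0
        frame[top - 1 : bottom + 1, left - 1] = 0
        frame[top - 1 : bottom + 1, right] = 0
        return Image.fromarray(frame)

    def save(self, png_path: str, cmap_name: str = "Greys") -> None:
        """Write the PNG and its `.meta` sidecar."""
        self.to_pil(cmap_name).save(png_path, format="PNG")
        self.metadata.write_sidecar(sidecar_path(png_path))


def _xy_columns(observations: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Prefer smoothed columns; fall back to raw observation columns."""
    if "smoothed_depth" in observations.columns:
        return (observations["smoothed_depth"].to_numpy(float),
                observations["smoothed_fraction"].to_numpy(float))
    return (observations["depth"].to_numpy(float),
            observations["minor_fraction"].to_numpy(float))


def render_density(
    observations: pd.DataFrame,
    metadata: PlotMetadata = PlotMetadata(),
    n_depth_bins: int | None = None,
    n_fraction_bins: int | None = None,
    kernel_smooth_sigma: float = 0.0,
) -> DensityImage:
    """Bin (smoothed) observations into a density raster.

    Bins default to the plot-region pixel dimensions, in which case the
    raster's total mass equals the number of in-range observations;
    coarser binnings are up-sampled (nearest) to region resolution.
    Out-of-range observations are dropped with a logged count; an empty
    or fully out-of-range input raises.
    """
    if observations.empty:
        raise ValueError("no observations to render")
    depth, fraction = _xy_columns(observations)
    meta = metadata
    in_range = (
        (depth >= meta.depth_min) & (depth <= meta.depth_max)
        & (fraction >= meta.fraction_min) & (fraction <= meta.fraction_max)
    )
    n_clipped = int((~in_range).sum())
    if n_clipped:
        logger.info("clipped %d observations outside axis limits", n_clipped)
    if not in_range.any():
        raise ValueError(
            f"all observations outside depth [{meta.depth_min}, {meta.depth_max}] "
            f"x fraction [{meta.fraction_min}, {meta.fraction_max}]"
        )
    left, right, top, bottom = meta.plot_region
    width, height = right - left, bottom - top
    nd = n_depth_bins or width
    nf = n_fraction_bins or height
    hist, _, _ = np.histogram2d(
        depth[in_range], fraction[in_range],
        bins=[nd, nf],
        range=[[meta.depth_min, meta.depth_max],
               [meta.fraction_min, meta.fraction_max]],
    )
    raster = np.flipud(hist.T)  # row 0 = fraction_max, col 0 = depth_min
    if raster.shape != (height, width):
        rows = np.floor(np.arange(height) * raster.shape[0] / height).astype(int)
        cols = np.floor(np.arange(width) * raster.shape[1] / width).astype(int)
        raster = raster[np.ix_(rows, cols)]
    mass = float(in_range.sum())
    if kernel_smooth_sigma > 0:
        raster = ndimage.gaussian_filter(raster, kernel_smooth_sigma)
    return DensityImage(raster, meta, mass, n_clipped)


def write_smoothed(df: pd.DataFrame, path: str) -> None:
    """Write a smoothed-observation TSV."""
    df[SMOOTHED_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")
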