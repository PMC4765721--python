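"""Superimpose predicted copy-number grids on a density image.

Given a density PNG with its geometry sidecar, a candidate
(cellularity, single-copy depth) solution is rendered as a lattice of
markers at each copy-number state's predicted (depth, folded fraction)
position, using the same affine data-to-pixel mapping the density
renderer used.  A good solution places markers on the density modes; a
wrong one leaves modes uncovered, which is the visual basis for
adjudicating between competing purity/ploidy estimates.

:class:`OverlaySession` wraps the same rendering in a matplotlib figure
with two sliders (cellularity and single-copy depth) and editable axis
metadata; all computation stays in the library functions, the session is
a thin interactive view.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace

import numpy as np
from PIL import Image, ImageDraw

from .grid import (
    DEFAULT_MAX_TOTAL_COPY,
    GridSolution,
    build_grid,
)
from .smooth import PlotMetadata, data_to_pixel, sidecar_path

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlayStyle:
    """Marker and label styling for grid overlays."""

    marker_radius: int = 6
    colour: tuple[int, int, int] = (220, 30, 30)
    label_format: str = "total"  # "total" -> "4"; "pair" -> "(2,2)"; "none"
    show_fold: bool = True
    contour_quantile: float | None = None

    def __post_init__(self) -> None:
        if self.marker_radius <= 0:
            raise ValueError("marker_radius must be positive")
        if self.label_format not in ("total", "pair", "none"):
            raise ValueError(f"unknown label_format {self.label_format!r}")


def load_metadata_for(image_path: str) -> PlotMetadata:
    """The image's sidecar metadata, or defaults sized to the image.

    Externally produced PNGs without a sidecar get the default axis
    limits and margin (with a warning) but keep their own pixel size.
    """
    side = sidecar_path(image_path)
    if os.path.exists(side):
        return PlotMetadata.read_sidecar(side)
    with Image.open(image_path) as im:
        width, height = im.size
    logger.warning(
        "no sidecar %s; assuming default axis limits for a %dx%d image",
        side, width, height,
    )
    return PlotMetadata(image_width_px=width, image_height_px=height)


def node_pixel_positions(
    solution: GridSolution,
    meta: PlotMetadata,
    max_total_copy: int = DEFAULT_MAX_TOTAL_COPY,
    show_fold: bool = True,
):
    """Pixel coordinates of each in-range grid node.

    Returns (nodes, px, py, n_skipped) where nodes are the in-range
    :class:`~bafgrid.grid.GridNode` objects and n_skipped counts nodes
    outside the axis limits.
    """
    nodes = build_grid(solution, max_total_copy, fold=show_fold)
    depths = np.array([n.predicted_depth for n in nodes])
    fracs = np.array(
        [n.folded_fraction if show_fold else n.predicted_fraction for n in nodes]
    )
    in_range = (
        (depths >= meta.depth_min) & (depths <= meta.depth_max)
        & (fracs >= meta.fraction_min) & (fracs <= meta.fraction_max)
    )
    n_skipped = int((~in_range).sum())
    if n_skipped:
        logger.info("%d grid nodes outside axis limits not drawn", n_skipped)
    kept = [n for n, ok in zip(nodes, in_range) if ok]
    px, py = data_to_pixel(meta, depths[in_range], fracs[in_range])
    return kept, px, py, n_skipped


def _draw_contour(draw: ImageDraw.ImageDraw, image: Image.Image,
                  meta: PlotMetadata, quantile: float,
                  colour: tuple[int, int, int]) -> None:
    """Outline the densest region of the data area at a luminance quantile."""
    left, right, top, bottom = meta.plot_region
    grey = np.asarray(image.convert("L"), dtype=float)[top:bottom, left:right]
    density = grey.max() - grey  # our density PNGs map darker = denser
    nonzero = density[density > 0]
    if nonzero.size == 0:
        return
    level = np.quantile(nonzero, quantile)
    mask = density >= level
    interior = (
        mask
        & np.roll(mask, 1, 0) & np.roll(mask, -1, 0)
        & np.roll(mask, 1, 1) & np.roll(mask, -1, 1)
    )
    edge = mask & ~interior
    ys, xs = np.nonzero(edge)
    for y, x in zip(ys, xs):
        draw.point((left + x, top + y), fill=colour)


def render_overlay(
    image_path: str,
    solution: GridSolution,
    max_total_copy: int = DEFAULT_MAX_TOTAL_COPY,
    style: OverlayStyle = OverlayStyle(),
    out_path: str | None = None,
) -> Image.Image:
    """Compose grid markers over a density image (source left untouched).

    Each non-degenerate state is drawn as a ring at its predicted pixel
    position, optionally labelled with its copy number.  A pure function
    of its inputs: identical inputs give identical output bytes.
    """
    meta = load_metadata_for(image_path)
    with Image.open(image_path) as im:
        composed = im.convert("RGB").copy()
    draw = ImageDraw.Draw(composed)
    if style.contour_quantile is not None:
        _draw_contour(draw, composed, meta, style.contour_quantile, style.colour)
    nodes, px, py, _ = node_pixel_positions(
        solution, meta, max_total_copy, style.show_fold
    )
    r = style.marker_radius
    for node, x, y in zip(nodes, px, py):
        draw.ellipse([x - r, y - r, x + r, y + r], outline=style.colour, width=2)
        if style.label_format == "total":
            label = str(node.state.total)
        elif style.label_format == "pair":
            label = f"({node.state.n1},{node.state.n2})"
        else:
            label = None
        if label:
            draw.text((x + r + 2, y - r - 2), label, fill=style.colour)
    if out_path:
        composed.save(out_path, format="PNG")
    return composed


class OverlaySession:
    """Interactive two-slider exploration of (C, D) over a density image.

    Sliders set cellularity in [0, 1] and single-copy depth in
    (0, depth_max / 2]; text boxes edit the depth axis range.  The current
    solution is always available via :attr:`solution` and can be written
    out with :meth:`export`.  Construction does not require a display
    (any matplotlib backend works); call :meth:`show` to run it.
    """

    def __init__(
        self,
        image_path: str,
        max_total_copy: int = DEFAULT_MAX_TOTAL_COPY,
        style: OverlayStyle = OverlayStyle(),
        initial: GridSolution | None = None,
    ) -> None:
        import matplotlib.pyplot as plt
        from matplotlib.widgets import Slider, TextBox

        self.image_path = str(image_path)
        self.max_total_copy = max_total_copy
        self.style = style
        self.metadata = load_metadata_for(image_path)
        d_max = self.metadata.depth_max / 2.0
        if initial is None:
            initial = GridSolution(0.5, d_max / 2.0)
        self._solution = initial

        with Image.open(image_path) as im:
            self._base = np.asarray(im.convert("RGB"))
        self.fig, self.ax = plt.subplots(figsize=(7, 7))
        self.fig.subplots_adjust(bottom=0.22)
        self.ax.imshow(self._base)
        self.ax.set_axis_off()
        (self._markers,) = self.ax.plot(
            [], [], "o", mfc="none", mec=np.array(style.colour) / 255.0,
            mew=2, ms=style.marker_radius * 2,
        )
        ax_c = self.fig.add_axes([0.15, 0.10, 0.55, 0.03])
        ax_d = self.fig.add_axes([0.15, 0.05, 0.55, 0.03])
        self._slider_c = Slider(ax_c, "cellularity", 0.0, 1.0,
                                valinit=initial.cellularity)
        self._slider_d = Slider(ax_d, "single-copy depth", 1e-6, d_max,
                                valinit=initial.single_copy_depth)
        self._slider_c.on_changed(self._on_slider)
        self._slider_d.on_changed(self._on_slider)
        ax_lo = self.fig.add_axes([0.80, 0.10, 0.12, 0.04])
        ax_hi = self.fig.add_axes([0.80, 0.04, 0.12, 0.04])
        self._box_lo = TextBox(ax_lo, "depth min ",
                               initial=str(self.metadata.depth_min))
        self._box_hi = TextBox(ax_hi, "depth max ",
                               initial=str(self.metadata.depth_max))
        self._box_lo.on_submit(self._on_depth_range)
        self._box_hi.on_submit(self._on_depth_range)
        self._redraw()

    @property
    def solution(self) -> GridSolution:
        """The currently selected (cellularity, single-copy depth)."""
        return self._solution

    def set_solution(self, cellularity: float, single_copy_depth: float) -> None:
        self._solution = GridSolution(cellularity, single_copy_depth)
        self._redraw()

    def set_depth_range(self, depth_min: float, depth_max: float) -> None:
        self.metadata = replace(self.metadata,
                                depth_min=depth_min, depth_max=depth_max)
        self._redraw()

    def _on_slider(self, _value) -> None:
        self._solution = GridSolution(self._slider_c.val, self._slider_d.val)
        self._redraw()

    def _on_depth_range(self, _text) -> None:
        try:
            self.set_depth_range(float(self._box_lo.text), float(self._box_hi.text))
        except ValueError as exc:
            logger.warning("ignoring bad depth range: %s", exc)

    def _redraw(self) -> None:
        _, px, py, _ = node_pixel_positions(
            self._solution, self.metadata, self.max_total_copy,
            self.style.show_fold,
        )
        self._markers.set_data(px, py)
        self.fig.canvas.draw_idle()

    def export(self, path: str) -> None:
        """Write the current solution as a two-line key=value text file."""
        with open(path, "w") as fh:
            fh.write(f"cellularity={self._solution.cellularity}\n")
            fh.write(f"single_copy_depth={self._solution.single_copy_depth}\n")

    def show(self) -> None:
        import matplotlib.pyplot as plt

        plt.show()


def interactive_session(image_path: str, **kwargs) -> OverlaySession:
    """Construct (but do not block on) an :class:`OverlaySession`."""
    return OverlaySession(image_path, **kwargs)
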