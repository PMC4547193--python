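"""Static renderers for the two coordinated views.

The tabular view draws one row per visible record — parameter columns left,
measure columns right — encoding each value as a bar (when the row height
exceeds the bar/line threshold) or as a point on a per-column polyline.  The
image-browser view lays out the input images on top and, below them, one row
per selected record of output images alpha-blended onto their inputs, with an
optional rectangular region of interest, nearest-neighbour magnification, and
a side panel of domain-coverage strips.

Everything is composed directly into uint8 arrays with round-half-up
quantisation, so renders are deterministic and the blend endpoints
(alpha = 0 or 1) reproduce the source images bit for bit.  PNG is the primary
format; the tabular view can also be written as structural SVG.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .core import ResultTable, SweepManifest
from .tableops import domain_coverage

__all__ = [
    "RenderSpec",
    "TableRender",
    "GridRender",
    "TABLE_CHROME_HEIGHT",
    "render_table",
    "render_image_grid",
    "render_single_record",
]

WHITE = np.array([255, 255, 255], dtype=np.uint8)
PARAM_COLOR = np.array([70, 110, 160], dtype=np.uint8)
MEASURE_COLOR = np.array([205, 120, 50], dtype=np.uint8)
SELECT_COLOR = np.array([200, 40, 40], dtype=np.uint8)
STRIP_BG = np.array([228, 228, 228], dtype=np.uint8)
STRIP_FG = np.array([60, 60, 60], dtype=np.uint8)

CELL_W = 48      # px per table column
CELL_GAP = 4
MARGIN_L = 10    # selection-marker margin
MARGIN_R = 4
HEADER_H = 8     # colour band distinguishing parameter vs measure columns
STRIP_H = 5      # filter/coverage strip under each column
SEP = 2
TABLE_CHROME_HEIGHT = HEADER_H + SEP + SEP + STRIP_H
GRID_PAD = 4
PANEL_W = 90     # coverage side panel of the image grid


@dataclass(frozen=True)
class RenderSpec:
    """Rendering knobs shared by the table and image-grid views."""

    row_height: int = 8
    bar_line_threshold: int = 4
    blend_alpha: float = 0.5
    roi: tuple[int, int, int, int] | None = None  # (x, y, w, h) in input-image px
    magnification: float = 1.0
    fmt: str = "png"

    def __post_init__(self) -> None:
        if self.row_height < 1:
            raise ValueError("row_height must be >= 1")
        if not 0.0 <= self.blend_alpha <= 1.0:
            raise ValueError("blend_alpha must be in [0, 1]")
        if self.magnification <= 0:
            raise ValueError("magnification must be > 0")
        if self.fmt not in ("png", "svg"):
            raise ValueError(f"unsupported output format {self.fmt!r}")


@dataclass(frozen=True)
class TableRender:
    path: Path
    width: int
    height: int
    mode: str            # "bar" or "line"
    n_rows: int


@dataclass(frozen=True)
class GridRender:
    path: Path
    cell_shape: tuple[int, int]   # (h, w) of one grid cell
    n_rows: int
    n_cols: int
    row_width: int                # width of the image-row area (excl. panel)
    row_y: tuple[int, ...]        # y offset of each selected-record row


# ---------------------------------------------------------------------------
# tabular view


def _column_fraction(values: np.ndarray, v: float) -> float:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return 0.5  # degenerate domain renders mid-scale
    return (v - lo) / (hi - lo)


def render_table(table: ResultTable, spec: RenderSpec, path: str | Path) -> TableRender:
    """Render the tabular view of *table* to *path*.

    One row per visible record in the current display order; bar encoding iff
    ``row_height > bar_line_threshold``, else one polyline per column through
    the per-row value positions.  Selected rows get a marker in the left
    margin and each column gets a coverage strip of the visible records'
    domain underneath.
    """
    order = table.visible_ordering()
    if not order:
        raise ValueError("no visible records to render")
    columns = table.columns
    n_rows = len(order)
    mode = "bar" if spec.row_height > spec.bar_line_threshold else "line"

    width = MARGIN_L + len(columns) * (CELL_W + CELL_GAP) + MARGIN_R
    height = n_rows * spec.row_height + TABLE_CHROME_HEIGHT
    if spec.fmt == "svg":
        _render_table_svg(table, spec, path, order, mode, width, height)
        return TableRender(Path(path), width, height, mode, n_rows)

    canvas = np.broadcast_to(WHITE, (height, width, 3)).copy()
    col_x = {c: MARGIN_L + j * (CELL_W + CELL_GAP) for j, c in enumerate(columns)}
    body_y0 = HEADER_H + SEP

    domains = {c: table.column_values(c) for c in columns}
    for c in columns:
        x0 = col_x[c]
        color = PARAM_COLOR if c in table.param_columns else MEASURE_COLOR
        canvas[0:HEADER_H, x0 : x0 + CELL_W] = color

        fracs = [_column_fraction(domains[c], table.records[i].value(c)) for i in order]
        xs = [x0 + int(round(f * (CELL_W - 1))) for f in fracs]
        if mode == "bar":
            gap = 1 if spec.row_height >= 3 else 0
            for r, x in enumerate(xs):
                y0 = body_y0 + r * spec.row_height
                canvas[y0 : y0 + spec.row_height - gap, x0 : x + 1] = color
        else:
            ys = [body_y0 + r * spec.row_height + spec.row_height // 2 for r in range(n_rows)]
            for r in range(n_rows):
                canvas[ys[r], xs[r]] = color
                if r + 1 < n_rows:  # connect the polyline
                    for y in range(ys[r], ys[r + 1] + 1):
                        t = (y - ys[r]) / max(ys[r + 1] - ys[r], 1)
                        x = int(round(xs[r] + t * (xs[r + 1] - xs[r])))
                        canvas[y, x] = color

        # coverage strip for the visible records, under the column
        strip_y = body_y0 + n_rows * spec.row_height + SEP
        canvas[strip_y : strip_y + STRIP_H, x0 : x0 + CELL_W] = STRIP_BG
        lo, hi = float(domains[c].min()), float(domains[c].max())
        vis_vals = domains[c][list(order)]
        if hi == lo:
            canvas[strip_y : strip_y + STRIP_H, x0 : x0 + CELL_W] = STRIP_FG
        else:
            for v in vis_vals:
                x = x0 + int(round((v - lo) / (hi - lo) * (CELL_W - 2)))
                canvas[strip_y : strip_y + STRIP_H, x : x + 2] = STRIP_FG

    for r, i in enumerate(order):
        if i in table.selection:
            y0 = body_y0 + r * spec.row_height
            canvas[y0 : y0 + spec.row_height, 2 : MARGIN_L - 2] = SELECT_COLOR

    iio.imwrite(Path(path), canvas)
    return TableRender(Path(path), width, height, mode, n_rows)


def _render_table_svg(table, spec, path, order, mode, width, height) -> None:
    # structural SVG: one rect (bar mode) or circle (line mode) per cell value
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    body_y0 = HEADER_H + SEP
    for j, c in enumerate(table.columns):
        x0 = MARGIN_L + j * (CELL_W + CELL_GAP)
        color = "#466ea0" if c in table.param_columns else "#cd7832"
        parts.append(f'<rect x="{x0}" y="0" width="{CELL_W}" height="{HEADER_H}" fill="{color}"/>')
        values = table.column_values(c)
        for r, i in enumerate(order):
            f = _column_fraction(values, table.records[i].value(c))
            y0 = body_y0 + r * spec.row_height
            if mode == "bar":
                w = max(f * CELL_W, 1)
                parts.append(
                    f'<rect class="cell" x="{x0}" y="{y0}" width="{w:.2f}" '
                    f'height="{max(spec.row_height - 1, 1)}" fill="{color}"/>'
                )
            else:
                cx = x0 + f * (CELL_W - 1)
                cy = y0 + spec.row_height / 2
                parts.append(f'<circle class="cell" cx="{cx:.2f}" cy="{cy:.2f}" r="1" fill="{color}"/>')
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")


# ---------------------------------------------------------------------------
# image browser


def _to_rgb_uint8(image: np.ndarray) -> np.ndarray:
    """Coerce an image to (H, W, 3) uint8 with round-half-up quantisation."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.dtype != np.uint8:
        arr = np.clip(np.floor(arr.astype(float) + 0.5), 0, 255).astype(np.uint8)
    return arr


def _apply_roi_zoom(image: np.ndarray, spec: RenderSpec) -> np.ndarray:
    out = image
    if spec.roi is not None:
        x, y, w, h = spec.roi
        if x < 0 or y < 0 or w < 1 or h < 1 or y + h > image.shape[0] or x + w > image.shape[1]:
            raise ValueError(f"roi {spec.roi} outside image bounds {image.shape[:2]}")
        out = out[y : y + h, x : x + w]
    if spec.magnification != 1.0:
        m = spec.magnification
        new_h = max(int(round(out.shape[0] * m)), 1)
        new_w = max(int(round(out.shape[1] * m)), 1)
        rows = np.minimum((np.arange(new_h) / m).astype(int), out.shape[0] - 1)
        cols = np.minimum((np.arange(new_w) / m).astype(int), out.shape[1] - 1)
        out = out[np.ix_(rows, cols)]
    return out


def _blend(output: np.ndarray, input_: np.ndarray, alpha: float) -> np.ndarray:
    """Linear alpha compositing, round half up: ``alpha*out + (1-alpha)*in``."""
    if alpha == 1.0:
        return output.copy()
    if alpha == 0.0:
        return input_.copy()
    mix = alpha * output.astype(float) + (1.0 - alpha) * input_.astype(float)
    return np.clip(np.floor(mix + 0.5), 0, 255).astype(np.uint8)


def _record_row_cells(
    manifest: SweepManifest,
    record_index: int,
    input_cells: Sequence[np.ndarray],
    spec: RenderSpec,
    sweep_dir: Path,
) -> list[np.ndarray]:
    rec = manifest.records[record_index]
    n_ch = max(k for _, k in rec.output_image_refs) + 1 if rec.output_image_refs else 0
    cells = []
    for i in range(len(manifest.input_image_paths)):
        for k in range(n_ch):
            ref = rec.output_image_refs.get((i, k))
            if ref is None:
                raise ValueError(f"record {rec.record_id} has no output image for ({i},{k})")
            img_path = sweep_dir / ref
            if not img_path.is_file():
                raise FileNotFoundError(f"missing output image: {img_path}")
            out = _apply_roi_zoom(_to_rgb_uint8(iio.imread(img_path)), spec)
            cells.append(_blend(out, input_cells[i], spec.blend_alpha))
    return cells


def _compose_row(cells: Sequence[np.ndarray], cell_shape: tuple[int, int]) -> np.ndarray:
    h, w = cell_shape
    width = GRID_PAD + len(cells) * (w + GRID_PAD)
    row = np.broadcast_to(WHITE, (h, width, 3)).copy()
    for c, cell in enumerate(cells):
        if cell.shape[:2] != cell_shape:
            raise ValueError(f"cell shape {cell.shape[:2]} != expected {cell_shape}")
        x0 = GRID_PAD + c * (w + GRID_PAD)
        row[:, x0 : x0 + w] = cell
    return row


def _load_inputs(
    manifest: SweepManifest,
    sweep_dir: Path,
    input_images: Sequence[np.ndarray] | None,
    spec: RenderSpec,
) -> list[np.ndarray]:
    if input_images is None:
        input_images = []
        for ref in manifest.input_image_paths:
            p = Path(ref)
            if not p.is_absolute() and (sweep_dir / ref).is_file():
                p = sweep_dir / ref  # inputs persisted inside the sweep dir
            if not p.is_file():
                raise FileNotFoundError(f"missing input image: {p}")
            input_images.append(iio.imread(p))
    return [_apply_roi_zoom(_to_rgb_uint8(img), spec) for img in input_images]


def render_image_grid(
    manifest: SweepManifest,
    selection: Sequence[int],
    spec: RenderSpec,
    path: str | Path,
    sweep_dir: str | Path,
    input_images: Sequence[np.ndarray] | None = None,
) -> GridRender:
    """Render the image-browser grid for *selection* (ordered record indices).

    The top strip shows each input image above its block of output-channel
    columns; below it, one row per selected record (top-to-bottom = selection
    order) of output images blended onto their inputs.  A side panel draws the
    selection's domain-coverage strips for every table column.
    """
    if not selection:
        raise ValueError("selection is empty")
    sweep_dir = Path(sweep_dir)
    input_cells = _load_inputs(manifest, sweep_dir, input_images, spec)
    cell_shape = input_cells[0].shape[:2]

    rows = []
    for idx in selection:
        cells = _record_row_cells(manifest, idx, input_cells, spec, sweep_dir)
        rows.append(_compose_row(cells, cell_shape))
    n_cols = len(rows[0][0]) and (rows[0].shape[1] - GRID_PAD) // (cell_shape[1] + GRID_PAD)
    n_ch = n_cols // len(input_cells)
    # input strip: each input image repeated over its block of channel columns
    top_cells = [input_cells[i] for i in range(len(input_cells)) for _ in range(n_ch)]
    top_row = _compose_row(top_cells, cell_shape)

    row_width = top_row.shape[1]
    h, w = cell_shape
    height = GRID_PAD + (len(selection) + 1) * (h + GRID_PAD) + SEP
    width = row_width + PANEL_W
    canvas = np.broadcast_to(WHITE, (height, width, 3)).copy()
    canvas[GRID_PAD : GRID_PAD + h, :row_width] = top_row
    row_y = []
    for j, row in enumerate(rows):
        y0 = GRID_PAD + (j + 1) * (h + GRID_PAD) + SEP
        row_y.append(y0)
        canvas[y0 : y0 + h, :row_width] = row

    _draw_coverage_panel(canvas, manifest, selection, row_width)
    iio.imwrite(Path(path), canvas)
    return GridRender(
        Path(path), cell_shape, len(selection), n_cols, row_width, tuple(row_y)
    )


def _draw_coverage_panel(
    canvas: np.ndarray, manifest: SweepManifest, selection: Sequence[int], x_panel: int
) -> None:
    table = ResultTable.from_manifest(manifest)
    strips = domain_coverage(table, tuple(selection))
    y = GRID_PAD
    strip_w = PANEL_W - 2 * GRID_PAD
    for strip in strips:
        if y + STRIP_H > canvas.shape[0]:
            break
        x0 = x_panel + GRID_PAD
        canvas[y : y + STRIP_H, x0 : x0 + strip_w] = STRIP_BG
        lo, hi = strip.domain
        for a, b in strip.covered:
            if hi == lo:
                xa, xb = 0, strip_w
            else:
                xa = int(round((a - lo) / (hi - lo) * (strip_w - 1)))
                xb = int(round((b - lo) / (hi - lo) * (strip_w - 1))) + 1
            canvas[y : y + STRIP_H, x0 + xa : x0 + xb] = STRIP_FG
        y += STRIP_H + SEP


def render_single_record(
    manifest: SweepManifest,
    record_index: int,
    spec: RenderSpec,
    path: str | Path,
    sweep_dir: str | Path,
    input_images: Sequence[np.ndarray] | None = None,
) -> GridRender:
    """Render one record's output images as a single blended strip.

    The strip is composed exactly like the corresponding row of
    :func:`render_image_grid`, so it serves as the static analogue of a
    hover preview of a single run.
    """
    if not 0 <= record_index < len(manifest.records):
        raise IndexError(f"record index {record_index} out of range")
    sweep_dir = Path(sweep_dir)
    input_cells = _load_inputs(manifest, sweep_dir, input_images, spec)
    cell_shape = input_cells[0].shape[:2]
    cells = _record_row_cells(manifest, record_index, input_cells, spec, sweep_dir)
    row = _compose_row(cells, cell_shape)
    iio.imwrite(Path(path), row)
    return GridRender(Path(path), cell_shape, 1, len(cells), row.shape[1], (0,))
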