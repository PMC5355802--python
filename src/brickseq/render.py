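"""Render per-strand incorporation values on the structure geometry.

Strand segments become axis-aligned boxes in nanometres on the square
lattice: x runs along the helix axis (base index × 0.34 nm), y and z across
helices (column/row × 2 nm).  SRI values are painted on a linear colour scale
from blue (0) to yellow (1); strands flagged by the filters (too few product
reads, excluded roles) are grey and never contribute to projection means.
3D structures are summarized as projections along each major axis and as
ordered slices of configurable thickness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.colors import LinearSegmentedColormap  # noqa: E402

from .design import Design
from .incorporation import FLAG_OK, SRITable

logger = logging.getLogger(__name__)

BLUE = (0.0, 0.0, 1.0)
YELLOW = (1.0, 1.0, 0.0)
GREY = (0.6, 0.6, 0.6)

INCORPORATION_CMAP = LinearSegmentedColormap.from_list(
    "incorporation", [BLUE, YELLOW]
)
INCORPORATION_CMAP.set_bad(alpha=0.0)

AXES = ("X", "Y", "Z")


class RenderError(ValueError):
    pass


def value_to_rgb(v: float) -> tuple[float, float, float]:
    """Linear RGB interpolation between blue (0) and yellow (1)."""
    if not 0 <= v <= 1:
        raise RenderError(f"value {v} outside [0, 1]")
    return (v, v, 1.0 - v)


@dataclass(frozen=True)
class Box:
    """One strand segment as an axis-aligned box (nm)."""

    strand_id: str
    x0: float
    x1: float
    y: float       # lower corner; extent inter_helix_nm
    z: float
    row: int
    col: int
    base_start: int
    base_end: int
    value: float   # NaN when flagged
    flag: str


@dataclass
class Scene:
    boxes: list[Box]
    inter_helix_nm: float
    axial_rise_nm: float

    @property
    def is_3d(self) -> bool:
        xs = {(b.base_start, b.base_end) for b in self.boxes}
        rows = {b.row for b in self.boxes}
        cols = {b.col for b in self.boxes}
        spans_x = len({b.base_start for b in self.boxes}) > 1 or any(
            b.base_end - b.base_start > 1 for b in self.boxes
        )
        return spans_x and len(rows) > 1 and len(cols) > 1 and len(xs) >= 1

    def extent(self, axis: str) -> tuple[float, float]:
        if axis == "X":
            return (min(b.x0 for b in self.boxes), max(b.x1 for b in self.boxes))
        if axis == "Y":
            return (min(b.y for b in self.boxes),
                    max(b.y for b in self.boxes) + self.inter_helix_nm)
        if axis == "Z":
            return (min(b.z for b in self.boxes),
                    max(b.z for b in self.boxes) + self.inter_helix_nm)
        raise RenderError(f"unknown axis {axis!r}")

    def dump(self, path) -> None:
        """Plain TSV of the scene for downstream plotting."""
        with open(path, "w") as fh:
            fh.write("strand_id\tx0\tx1\ty\tz\tvalue\tflag\n")
            for b in self.boxes:
                fh.write(
                    f"{b.strand_id}\t{b.x0:.4f}\t{b.x1:.4f}\t{b.y:.4f}\t"
                    f"{b.z:.4f}\t{b.value:.6g}\t{b.flag}\n"
                )


def layout(design: Design, values: SRITable | frozenset | set) -> Scene:
    """Place one box per strand segment, carrying the strand's value and flag.

    ``values`` is an :class:`SRITable` (SRI colouring) or a set of present
    strand ids (presence colouring: 1 for present, 0 for absent).  Strands
    with a value but no lattice segments are skipped with a warning.
    """
    geom = design.geometry
    if isinstance(values, SRITable):
        lookup = {
            row["strand_id"]: (row["sri"], row["flag"])
            for _, row in values.data.iterrows()
        }
    else:
        lookup = {
            s.strand_id: (1.0 if s.strand_id in values else 0.0, FLAG_OK)
            for s in design.countable_strands()
        }

    boxes = []
    for s in design:
        if s.strand_id not in lookup:
            continue
        value, flag = lookup[s.strand_id]
        if not s.segments:
            logger.warning("strand %s has a value but no coordinates; skipped",
                           s.strand_id)
            continue
        v = float(value) if flag == FLAG_OK else float("nan")
        for seg in s.segments:
            boxes.append(Box(
                strand_id=s.strand_id,
                x0=seg.base_start * geom.axial_rise_nm,
                x1=seg.base_end * geom.axial_rise_nm,
                y=seg.helix_col * geom.inter_helix_nm,
                z=seg.helix_row * geom.inter_helix_nm,
                row=seg.helix_row,
                col=seg.helix_col,
                base_start=seg.base_start,
                base_end=seg.base_end,
                value=v,
                flag=str(flag),
            ))
    return Scene(boxes=boxes, inter_helix_nm=geom.inter_helix_nm,
                 axial_rise_nm=geom.axial_rise_nm)


# ---------------------------------------------------------------------------
# Projections and slices
# ---------------------------------------------------------------------------

def _project(boxes: list[Box], axis: str, aggregate: str = "mean"
             ) -> np.ndarray:
    """Project boxes along ``axis`` onto a cell grid of the two other axes.

    Cells are one helix across (Y/Z axes) and one base along the helix axis
    (X).  Each cell holds the mean (or max) of the values of all unflagged
    boxes intersecting it; cells no box touches are NaN.
    """
    if axis not in AXES:
        raise RenderError(f"axis must be one of {AXES}")
    contributing = [b for b in boxes if b.flag == FLAG_OK
                    and not math.isnan(b.value)]
    cells: dict[tuple[int, int], list[float]] = {}

    def add(key, v):
        cells.setdefault(key, []).append(v)

    for b in contributing:
        if axis == "X":
            add((b.row, b.col), b.value)
        elif axis == "Z":  # collapse rows: image over (col, base)
            for base in range(b.base_start, b.base_end):
                add((b.col, base), b.value)
        else:  # axis == "Y": collapse cols: image over (row, base)
            for base in range(b.base_start, b.base_end):
                add((b.row, base), b.value)

    # grid extents come from all boxes so empty cells stay visible as NaN
    if axis == "X":
        keys = [(b.row, b.col) for b in boxes]
    elif axis == "Z":
        keys = [(b.col, base) for b in boxes
                for base in (b.base_start, b.base_end - 1)]
    else:
        keys = [(b.row, base) for b in boxes
                for base in (b.base_start, b.base_end - 1)]
    if not keys:
        return np.full((0, 0), np.nan)
    i_lo = min(k[0] for k in keys)
    i_hi = max(k[0] for k in keys)
    j_lo = min(k[1] for k in keys)
    j_hi = max(k[1] for k in keys)
    img = np.full((i_hi - i_lo + 1, j_hi - j_lo + 1), np.nan)
    for (i, j), vals in cells.items():
        img[i - i_lo, j - j_lo] = (np.mean(vals) if aggregate == "mean"
                                   else np.max(vals))
    return img


def project_3d(scene: Scene, axis: str, aggregate: str = "mean") -> np.ndarray:
    """Mean-value (or max) projection of a 3D scene along one major axis."""
    if not scene.is_3d:
        raise RenderError("3D projection requested for a non-3D scene")
    return _project(scene.boxes, axis, aggregate)


def slices(scene: Scene, axis: str, thickness_nm: float
           ) -> list[tuple[float, float, np.ndarray]]:
    """Contiguous slabs of ``thickness_nm`` along ``axis``, each projected.

    Returns (slab_lo_nm, slab_hi_nm, image) in increasing position order; a
    thickness larger than the extent yields one slice.
    """
    if thickness_nm <= 0:
        raise RenderError("thickness must be positive")
    if not scene.boxes:
        return []
    lo, hi = scene.extent(axis)
    n = max(1, math.ceil((hi - lo) / thickness_nm - 1e-9))
    out = []
    for i in range(n):
        s_lo = lo + i * thickness_nm
        s_hi = min(lo + (i + 1) * thickness_nm, hi)
        sub = [b for b in scene.boxes if _intersects(b, axis, s_lo, s_hi, scene)]
        out.append((s_lo, s_hi, _project(sub, axis)))
    return out


def _intersects(b: Box, axis: str, lo: float, hi: float, scene: Scene) -> bool:
    if axis == "X":
        b_lo, b_hi = b.x0, b.x1
    elif axis == "Y":
        b_lo, b_hi = b.y, b.y + scene.inter_helix_nm
    else:
        b_lo, b_hi = b.z, b.z + scene.inter_helix_nm
    return b_lo < hi and b_hi > lo


def thresholded_shape_image(present: set | frozenset, canvas: Design
                            ) -> np.ndarray:
    """Binary (row, col) occupancy map of the present strands on the canvas."""
    cells = [(seg.helix_row, seg.helix_col)
             for s in canvas if s.segments for seg in s.segments]
    if not cells:
        raise RenderError("canvas has no lattice coordinates")
    r_lo = min(r for r, _ in cells)
    r_hi = max(r for r, _ in cells)
    c_lo = min(c for _, c in cells)
    c_hi = max(c for _, c in cells)
    img = np.zeros((r_hi - r_lo + 1, c_hi - c_lo + 1), dtype=bool)
    for s in canvas:
        if s.strand_id in present:
            for seg in s.segments:
                img[seg.helix_row - r_lo, seg.helix_col - c_lo] = True
    return img


def grid_value_image(design: Design, table: SRITable
                     ) -> tuple[np.ndarray, np.ndarray]:
    """2D (row, col) value map plus a grey mask of flagged strands."""
    scene = layout(design, table)
    img = _project(scene.boxes, "X")
    flagged = np.zeros_like(img, dtype=bool)
    if scene.boxes:
        i_lo = min(b.row for b in scene.boxes)
        j_lo = min(b.col for b in scene.boxes)
        for b in scene.boxes:
            if b.flag != FLAG_OK:
                flagged[b.row - i_lo, b.col - j_lo] = True
    return img, flagged


# ---------------------------------------------------------------------------
# Image files
# ---------------------------------------------------------------------------

def render_image(image: np.ndarray, path, fmt: str = "PNG",
                 flagged: np.ndarray | None = None,
                 title: str | None = None) -> None:
    """Write a value image as PNG or SVG with the incorporation colour bar.

    NaN cells are transparent; cells in ``flagged`` are drawn grey.  Output
    bytes are deterministic for identical input.
    """
    fmt = fmt.upper()
    if fmt not in ("PNG", "SVG"):
        raise RenderError(f"unsupported format {fmt!r}; use PNG or SVG")
    with matplotlib.rc_context({"svg.hashsalt": "brickseq"}):
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(image, cmap=INCORPORATION_CMAP, vmin=0.0, vmax=1.0,
                       origin="lower", interpolation="nearest")
        if flagged is not None and flagged.any():
            grey = np.full(image.shape + (4,), 0.0)
            grey[flagged] = (*GREY, 1.0)
            ax.imshow(grey, origin="lower", interpolation="nearest")
        fig.colorbar(im, ax=ax, label="SRI (0 = blue, 1 = yellow)")
        if title:
            ax.set_title(title)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(path, format=fmt.lower(), metadata=_metadata(fmt), dpi=100)
        plt.close(fig)


def _metadata(fmt: str) -> dict:
    if fmt == "SVG":
        return {"Date": None}
    return {"Software": "brickseq"}
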