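"""Micropatterned island layouts, raster masks, and perimeter-cell geometry.

Cardiomyocytes grown on micro-contact-printed fibronectin islands form
square (or more elaborate multi-region) patches of known physical size.
This module describes such layouts in micrometres, rasterizes them to
labeled mask images at a given pixel size, computes the fraction of cells
on an island's perimeter, and tiles a large island into synthetic small
islands for analysis-bias controls.

Conventions: coordinates are in micrometres, the image origin is the
top-left corner, x increases rightward (columns), y increases downward
(rows).  Rasterization includes a pixel when its centre falls inside the
shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
import yaml
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "Square",
    "LabeledRegions",
    "IslandLayout",
    "CellGrid",
    "perimeter_fraction",
    "make_masks",
    "subdivide_mask",
    "crab_layout",
    "load_layout",
    "save_layout",
    "write_masks",
]

DEFAULT_CELL_DIAMETER_UM = 50.0


class LayoutError(ValueError):
    """Raised for invalid or overlapping island layouts."""


@dataclass(frozen=True)
class Square:
    """Axis-aligned square island: ``origin_um`` is the top-left corner."""

    shape_id: int
    edge_um: float
    origin_um: tuple[float, float]

    @property
    def kind(self) -> str:
        return "square"

    def bounds(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin_um
        return (x0, y0, x0 + self.edge_um, y0 + self.edge_um)

    def polygons(self) -> list[tuple[int, np.ndarray]]:
        x0, y0, x1, y1 = self.bounds()
        poly = np.array([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
        return [(0, poly)]


@dataclass(frozen=True)
class LabeledRegions:
    """Multi-region shape: list of (region_label, polygon) in µm.

    Region labels index functionally distinct zones of one contiguous
    pattern (e.g. an isolated island vs. a bridge-coupled satellite of a
    large syncytium).
    """

    shape_id: int
    regions: tuple[tuple[int, np.ndarray], ...]

    @property
    def kind(self) -> str:
        return "labeled_regions"

    def bounds(self) -> tuple[float, float, float, float]:
        pts = np.vstack([np.asarray(p) for _, p in self.regions])
        return (pts[:, 0].min(), pts[:, 1].min(), pts[:, 0].max(), pts[:, 1].max())

    def polygons(self) -> list[tuple[int, np.ndarray]]:
        return [(lab, np.asarray(p, dtype=float)) for lab, p in self.regions]


@dataclass
class IslandLayout:
    """A set of disjoint island shapes within a rectangular field of view."""

    shapes: list = field(default_factory=list)
    pixel_size_um: float = 3.25
    field_um: tuple[float, float] = (1200.0, 3300.0)

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise LayoutError("pixel_size_um must be positive")
        w, h = self.field_um
        if w <= 0 or h <= 0:
            raise LayoutError("field_um must be positive")
        for s in self.shapes:
            if isinstance(s, Square) and s.edge_um <= 0:
                raise LayoutError(f"shape {s.shape_id}: edge_um must be positive")
            x0, y0, x1, y1 = s.bounds()
            if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
                raise LayoutError(f"shape {s.shape_id} lies outside the field")

    @property
    def shape_px(self) -> tuple[int, int]:
        """(rows, cols) of the rasterized field."""
        w, h = self.field_um
        return (int(round(h / self.pixel_size_um)), int(round(w / self.pixel_size_um)))


@dataclass(frozen=True)
class CellGrid:
    """Cells tiled on a square island: ``n_side`` cells along each edge."""

    cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM
    n_side: int = 1

    @classmethod
    def for_island(cls, edge_um: float, cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM) -> "CellGrid":
        if edge_um <= 0 or cell_diameter_um <= 0:
            raise ValueError("edge_um and cell_diameter_um must be positive")
        n = max(1, int(round(edge_um / cell_diameter_um)))
        return cls(cell_diameter_um=cell_diameter_um, n_side=n)


def perimeter_fraction(edge_um: float, cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM) -> float:
    """Fraction of cells on the perimeter of a square island.

    An island of edge ``edge_um`` holds an ``n × n`` grid of cells with
    ``n = round(edge_um / cell_diameter_um)``.  The perimeter cells are
    those with at least one missing neighbour, ``n² − (n−2)²`` of them;
    for ``n ≤ 2`` every cell is on the perimeter.

    >>> perimeter_fraction(250, 50)
    0.64
    """
    if edge_um <= 0 or cell_diameter_um <= 0:
        raise ValueError("edge_um and cell_diameter_um must be positive")
    if edge_um < cell_diameter_um:
        raise ValueError("edge_um must be at least one cell diameter")
    n = max(1, int(round(edge_um / cell_diameter_um)))
    if n <= 2:
        return 1.0
    return (n * n - (n - 2) * (n - 2)) / (n * n)


def _raster_polygon(poly_um: np.ndarray, pixel_size_um: float, shape_px: tuple[int, int]):
    """Row/col indices of pixels whose centres lie inside the polygon."""
    # pixel centre of (r, c) is at ((c+0.5)*px, (r+0.5)*px) in µm; shift the
    # polygon into pixel-centre coordinates for skimage's polygon rasterizer.
    rows_v = np.asarray(poly_um)[:, 1] / pixel_size_um - 0.5
    cols_v = np.asarray(poly_um)[:, 0] / pixel_size_um - 0.5
    return _sk_polygon(rows_v, cols_v, shape=shape_px)


def make_masks(layout: IslandLayout) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a layout into a labeled island mask.

    Returns ``(labels, region_labels)``: ``labels`` is 0 for background and
    ``k`` for the ``k``-th shape (labels contiguous from 1 in shape order);
    ``region_labels`` carries the per-region label of ``labeled_regions``
    shapes (0 elsewhere).

    Raises :class:`LayoutError` if shapes overlap once rasterized.
    """
    shape_px = layout.shape_px
    labels = np.zeros(shape_px, dtype=np.uint16)
    region_labels = np.zeros(shape_px, dtype=np.uint16)
    for k, s in enumerate(layout.shapes, start=1):
        for reg_lab, poly in s.polygons():
            rr, cc = _raster_polygon(poly, layout.pixel_size_um, shape_px)
            if np.any(labels[rr, cc] != 0) and np.any(labels[rr, cc] != k):
                raise LayoutError(f"shape {s.shape_id} overlaps another shape")
            labels[rr, cc] = k
            if s.kind == "labeled_regions":
                region_labels[rr, cc] = reg_lab
    return labels, region_labels


def subdivide_mask(mask: np.ndarray, sub_edge_um: float, pixel_size_um: float) -> list[np.ndarray]:
    """Tile the bounding box of a single-island mask into square sub-masks.

    Emulates the analysis control of numerically cutting a large island
    into synthetic small islands.  Returns ``floor(edge/sub_edge)²``
    boolean masks, each the intersection of one tile with the parent mask.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("mask is empty")
    if sub_edge_um <= 0 or pixel_size_um <= 0:
        raise ValueError("sub_edge_um and pixel_size_um must be positive")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    edge_px = max(r1 - r0, c1 - c0)
    edge_um = edge_px * pixel_size_um
    if sub_edge_um > edge_um * (1 + 1e-9):
        raise ValueError("sub_edge_um exceeds the island edge")
    n_sub = int(np.floor(edge_um / sub_edge_um + 1e-9))
    r_edges = np.round(np.linspace(r0, r1, n_sub + 1)).astype(int)
    c_edges = np.round(np.linspace(c0, c1, n_sub + 1)).astype(int)
    subs = []
    for i in range(n_sub):
        for j in range(n_sub):
            tile = np.zeros_like(mask)
            tile[r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]] = True
            subs.append(tile & mask)
    return subs


def crab_layout(
    core_edge_um: float = 500.0,
    satellite_edge_um: float = 100.0,
    bridge_um: tuple[float, float] = (20.0, 50.0),
    gap_um: float = 20.0,
    isolated_offset_um: float = 300.0,
    pixel_size_um: float = 3.25,
) -> IslandLayout:
    """Multi-region pattern probing modes of intercellular influence.

    Five labeled regions around a large core syncytium: (1) an isolated
    small island, (2) a small island joined to the core by a thin cell
    bridge (electrical + paracrine coupling), (3) a small island separated
    from the core by a thin gap (paracrine only), (4) a small island with
    both a bridge and proximity, and (5) the core itself, whose interior
    cells have neighbours on all sides.  The printed pattern's exact bridge
    and gap dimensions are not published; the defaults here are
    illustrative and every dimension is a parameter.
    """
    bw, bl = bridge_um
    e, s = core_edge_um, satellite_edge_um
    margin = 40.0
    x_core = isolated_offset_um + s + margin + gap_um + bl
    y_core = margin
    mid_y = y_core + e / 2

    def sq(x0, y0, edge):
        return np.array([(x0, y0), (x0 + edge, y0), (x0 + edge, y0 + edge), (x0, y0 + edge)])

    regions = []
    # 5: core syncytium
    regions.append((5, sq(x_core, y_core, e)))
    # 1: isolated satellite, far from everything
    regions.append((1, sq(margin, mid_y - s / 2, s)))
    # 3: satellite across a thin gap from the core's left face
    regions.append((3, sq(x_core - gap_um - s, mid_y - s / 2, s)))
    # 2: satellite bridged to the core's right face
    x2 = x_core + e + bl
    regions.append((2, sq(x2, mid_y - s / 2, s)))
    regions.append((2, np.array([
        (x_core + e, mid_y - bw / 2), (x2, mid_y - bw / 2),
        (x2, mid_y + bw / 2), (x_core + e, mid_y + bw / 2)])))
    # 4: satellite below the core, bridged, hence close and coupled
    y4 = y_core + e + bl
    regions.append((4, sq(x_core + e / 2 - s / 2, y4, s)))
    regions.append((4, np.array([
        (x_core + e / 2 - bw / 2, y_core + e), (x_core + e / 2 + bw / 2, y_core + e),
        (x_core + e / 2 + bw / 2, y4), (x_core + e / 2 - bw / 2, y4)])))

    shape = LabeledRegions(shape_id=1, regions=tuple(regions))
    x0, y0, x1, y1 = shape.bounds()
    field = (x1 + margin, y1 + margin)
    return IslandLayout(shapes=[shape], pixel_size_um=pixel_size_um, field_um=field)


# ---------------------------------------------------------------------------
# serialization

def save_layout(layout: IslandLayout, path) -> None:
    doc = {
        "pixel_size_um": float(layout.pixel_size_um),
        "field_um": [float(x) for x in layout.field_um],
        "shapes": [],
    }
    for s in layout.shapes:
        if isinstance(s, Square):
            doc["shapes"].append({
                "shape_id": int(s.shape_id), "kind": "square",
                "edge_um": float(s.edge_um),
                "origin_um": [float(x) for x in s.origin_um],
            })
        else:
            doc["shapes"].append({
                "shape_id": int(s.shape_id), "kind": "labeled_regions",
                "regions": [{"label": int(lab), "polygon_um": np.asarray(p, dtype=float).tolist()}
                            for lab, p in s.polygons()],
            })
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_layout(path) -> IslandLayout:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    shapes = []
    for sd in doc.get("shapes", []):
        if sd["kind"] == "square":
            shapes.append(Square(sd["shape_id"], float(sd["edge_um"]),
                                 tuple(float(x) for x in sd["origin_um"])))
        elif sd["kind"] == "labeled_regions":
            regions = tuple((int(r["label"]), np.asarray(r["polygon_um"], dtype=float))
                            for r in sd["regions"])
            shapes.append(LabeledRegions(sd["shape_id"], regions))
        else:
            raise LayoutError(f"unknown shape kind {sd['kind']!r}")
    return IslandLayout(shapes=shapes, pixel_size_um=float(doc["pixel_size_um"]),
                        field_um=tuple(float(x) for x in doc["field_um"]))


def write_masks(layout: IslandLayout, path) -> None:
    """Write the island-label mask (and region labels, if any) as 16-bit TIFF."""
    labels, region_labels = make_masks(layout)
    if region_labels.any():
        tifffile.imwrite(path, np.stack([labels, region_labels]))
    else:
        tifffile.imwrite(path, labels)
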