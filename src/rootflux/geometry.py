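"""Multicellular root-tip templates.

A template is a 2D longitudinal section of the Arabidopsis root tip built
from rectangular cells arranged in vertical tissue files, with an explicit
apoplast: every stretch of cell wall shared between two cells (or forming
the outer surface) is a :class:`Wall`, and every (cell, wall) incidence is a
:class:`MembraneSegment` carrying a face label used to place polar carriers.

Coordinates are in micrometres with the origin at the quiescent centre (QC)
and the +y axis pointing shootward, so rootward faces have the smaller y
coordinate.  Templates are bilaterally symmetric about the stele midline
(x = 0): lateral-root-cap (LRC) files flank the outside and columella tiers
sit below the QC.

The generator here is the synthetic stand-in for confocal root-tip templates
segmented with tools such as CellSeT; real segmented geometries are out of
scope and only the package's own JSON schema is read and written.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import Polygon

SCHEMA = "rootflux-template/1"

#: Cell types that belong to the root cap and therefore carry no MZ/EZ zone.
CAP_TYPES_PREFIX = ("columella_tier_",)
CAP_TYPES = ("LRC_inner", "LRC_outer")

#: Non-cap tissue identifiers accepted by the generator, ordered outer -> inner.
BODY_TISSUES = ("epidermis", "cortex", "endodermis", "pericycle", "stele")

FACES = ("rootward", "shootward", "inner_lateral", "outer_lateral")

_ROUND = 6  # coordinate rounding (decimal places) used to key shared geometry


class TemplateError(ValueError):
    """Raised for invalid template specifications or schema violations."""


def is_cap_type(cell_type: str) -> bool:
    return cell_type in CAP_TYPES or cell_type.startswith(CAP_TYPES_PREFIX[0])


@dataclass
class Cell:
    id: int
    cell_type: str
    vertices: np.ndarray  # (n, 2) closed polygon, not repeating first vertex
    zone: str | None = None  # "MZ" / "EZ"; None for cap cells

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


@dataclass
class Wall:
    id: int
    cell_ids: tuple[int, ...]  # 1 id => outer boundary wall
    p1: np.ndarray
    p2: np.ndarray
    thickness: float = 0.2
    pd_permeability: float = 0.0

    @property
    def length(self) -> float:
        return float(np.hypot(*(self.p2 - self.p1)))

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.p1 + self.p2)

    @property
    def is_boundary(self) -> bool:
        return len(self.cell_ids) == 1


@dataclass
class MembraneSegment:
    cell_id: int
    wall_id: int
    face: str
    length: float

    @property
    def key(self) -> tuple[int, int]:
        return (self.cell_id, self.wall_id)


@dataclass
class RootTemplate:
    cells: dict[int, Cell]
    walls: dict[int, Wall]
    membrane_segments: list[MembraneSegment]
    axis: np.ndarray  # unit vector pointing shootward
    qc_position: np.ndarray
    shoot_boundary_cells: frozenset[int] = frozenset()
    apex_cells: frozenset[int] = frozenset()

    def segments_of_cell(self, cell_id: int) -> list[MembraneSegment]:
        return [s for s in self.membrane_segments if s.cell_id == cell_id]

    def axial_distance(self, cell: Cell) -> float:
        """Signed shootward distance of the cell centroid from the QC."""
        return float(np.dot(cell.centroid - self.qc_position, self.axis))

    def cells_of_type(self, *cell_types: str) -> list[Cell]:
        return [c for c in self.cells.values() if c.cell_type in cell_types]

    @property
    def adjacency(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.cells)
        for w in self.walls.values():
            if len(w.cell_ids) == 2:
                g.add_edge(*w.cell_ids, wall=w.id)
        return g


# ---------------------------------------------------------------------------
# Regular template specification
# ---------------------------------------------------------------------------


@dataclass
class FileSpec:
    """One vertical tissue file of equal-width rectangular cells."""

    tissue: str
    width: float  # um
    cell_length: float  # um along the root axis


@dataclass
class TemplateSpec:
    """Parameters of the geometrically regular root-tip template.

    Defaults give a root tip with a 210 um meristematic zone (MZ) and a
    590 um elongation zone (EZ), two stele files, three columella tiers and
    LRC files flanking the meristem; cell sizes are typical of segmented
    Arabidopsis root tips.  All values are configuration, not constants.
    """

    files: Sequence[FileSpec] = field(
        default_factory=lambda: [
            FileSpec("epidermis", 18.0, 20.0),
            FileSpec("cortex", 22.0, 25.0),
            FileSpec("endodermis", 14.0, 20.0),
            FileSpec("pericycle", 12.0, 20.0),
            FileSpec("stele", 20.0, 25.0),
        ]
    )
    n_stele_files: int = 2  # total central stele files (width from files spec)
    mz_length: float = 210.0
    ez_length: float = 590.0
    lrc_inner_width: float = 12.0
    lrc_outer_width: float = 12.0
    lrc_cell_length: float = 15.0
    lrc_shootward_extent: float = 120.0  # LRC tip ends within the meristem
    n_columella_tiers: int = 3
    columella_tier_height: float = 20.0
    columella_cells_per_tier: int = 4
    qc_height: float = 15.0
    include_cap: bool = True
    include_qc: bool = True
    wall_thickness: float = 0.2

    @property
    def total_length(self) -> float:
        return self.mz_length + self.ez_length


def _rect(x0: float, x1: float, y0: float, y1: float) -> np.ndarray:
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float)


def _check_tiling(tissue: str, span: float, cell_length: float) -> int:
    n = span / cell_length
    if cell_length <= 0 or abs(n - round(n)) > 1e-9 or round(n) < 1:
        raise TemplateError(
            f"tissue '{tissue}': file length {span} um cannot be tiled by "
            f"cells of length {cell_length} um"
        )
    return int(round(n))


def generate_regular_template(spec: TemplateSpec | None = None) -> RootTemplate:
    """Build a bilaterally symmetric, geometrically regular root-tip template.

    Raises :class:`TemplateError` if a tissue file cannot be tiled exactly by
    its cell length, naming the offending tissue.
    """
    spec = spec or TemplateSpec()
    for fs in spec.files:
        if fs.width <= 0 or fs.cell_length <= 0:
            raise TemplateError(f"tissue '{fs.tissue}': sizes must be > 0")

    rects: list[tuple[str, np.ndarray]] = []  # (cell_type, rect vertices)
    L = spec.total_length

    # inner body files, mirrored about x=0. Build the half-width layout:
    # stele files centred, then pericycle..epidermis moving outward.
    by_tissue = {fs.tissue: fs for fs in spec.files}
    for t in BODY_TISSUES:
        if t not in by_tissue:
            raise TemplateError(f"missing file spec for tissue '{t}'")
    stele = by_tissue["stele"]
    if spec.n_stele_files < 1:
        raise TemplateError("tissue 'stele': need at least one file")
    half_stele = 0.5 * spec.n_stele_files * stele.width

    # x-intervals for each file on the right flank (mirrored for the left)
    flank_order = ["pericycle", "endodermis", "cortex", "epidermis"]
    intervals: list[tuple[str, float, float]] = []
    # stele files span the centre
    for i in range(spec.n_stele_files):
        x0 = -half_stele + i * stele.width
        intervals.append(("stele", x0, x0 + stele.width))
    x = half_stele
    for t in flank_order:
        w = by_tissue[t].width
        intervals.append((t, x, x + w))
        intervals.append((t, -x - w, -x))
        x += w
    body_half_width = x  # |x| of the outer epidermis edge

    for tissue, x0, x1 in intervals:
        h = by_tissue[tissue].cell_length
        n = _check_tiling(tissue, L, h)
        for k in range(n):
            rects.append((tissue, _rect(x0, x1, k * h, (k + 1) * h)))

    cap_bottom = 0.0
    if spec.include_qc:
        cap_bottom = -spec.qc_height
        rects.append(("QC", _rect(-body_half_width, body_half_width, -spec.qc_height, 0.0)))
    if spec.include_cap:
        # columella tiers below the QC; tier 1 adjacent to the QC, the
        # highest-numbered tier is the outermost (most rootward).
        for k in range(1, spec.n_columella_tiers + 1):
            y1 = cap_bottom - (k - 1) * spec.columella_tier_height
            y0 = y1 - spec.columella_tier_height
            wcol = 2 * body_half_width / spec.columella_cells_per_tier
            for j in range(spec.columella_cells_per_tier):
                x0 = -body_half_width + j * wcol
                rects.append((f"columella_tier_{k}", _rect(x0, x0 + wcol, y0, y1)))
        col_bottom = cap_bottom - spec.n_columella_tiers * spec.columella_tier_height

        # LRC files flank everything from the columella bottom to the MZ/EZ
        # boundary (inner file first, outer file outside it).
        lrc_span = spec.lrc_shootward_extent - col_bottom
        n_lrc = _check_tiling("LRC", lrc_span, spec.lrc_cell_length)
        for tissue, w, xin in (
            ("LRC_inner", spec.lrc_inner_width, body_half_width),
            ("LRC_outer", spec.lrc_outer_width, body_half_width + spec.lrc_inner_width),
        ):
            for k in range(n_lrc):
                y0 = col_bottom + k * spec.lrc_cell_length
                y1 = y0 + spec.lrc_cell_length
                rects.append((tissue, _rect(xin, xin + w, y0, y1)))
                rects.append((tissue, _rect(-xin - w, -xin, y0, y1)))

    template = build_template_from_rectangles(rects, wall_thickness=spec.wall_thickness)
    template = assign_zones(template, spec.mz_length)
    validate_template(template)
    return template


# ---------------------------------------------------------------------------
# Wall extraction from rectangle tilings
# ---------------------------------------------------------------------------


def _edges_of_rect(v: np.ndarray):
    """Yield (orientation, coord, lo, hi) for the 4 axis-aligned edges."""
    x0, y0 = v.min(axis=0)
    x1, y1 = v.max(axis=0)
    yield ("v", x0, y0, y1)
    yield ("v", x1, y0, y1)
    yield ("h", y0, x0, x1)
    yield ("h", y1, x0, x1)


def build_template_from_rectangles(
    rects: Iterable[tuple[str, np.ndarray]], wall_thickness: float = 0.2
) -> RootTemplate:
    """Assemble cells, walls and membrane segments from axis-aligned rectangles.

    Shared walls are the pairwise overlaps of collinear cell edges; the
    uncovered remainder of each edge becomes outer boundary walls.  Two cells
    sharing an edge stretch reference the same single wall.
    """
    cells: dict[int, Cell] = {}
    for cid, (ctype, verts) in enumerate(rects):
        cells[cid] = Cell(id=cid, cell_type=ctype, vertices=np.asarray(verts, float))

    # index edges: key (orientation, coord) -> list of (cell_id, lo, hi)
    edge_index: dict[tuple[str, float], list[tuple[int, float, float]]] = {}
    for cid, c in cells.items():
        for ori, coord, lo, hi in _edges_of_rect(c.vertices):
            edge_index.setdefault((ori, round(coord, _ROUND)), []).append((cid, lo, hi))

    walls: dict[int, Wall] = {}
    segs: list[MembraneSegment] = []
    wid = 0

    def add_wall(cids, ori, coord, lo, hi):
        nonlocal wid
        if ori == "v":
            p1, p2 = np.array([coord, lo]), np.array([coord, hi])
        else:
            p1, p2 = np.array([lo, coord]), np.array([hi, coord])
        w = Wall(id=wid, cell_ids=tuple(cids), p1=p1, p2=p2, thickness=wall_thickness)
        walls[wid] = w
        for cid in cids:
            segs.append(
                MembraneSegment(cell_id=cid, wall_id=wid, face="", length=w.length)
            )
        wid += 1

    for (ori, coord), entries in edge_index.items():
        for i, (ci, lo_i, hi_i) in enumerate(entries):
            # overlaps with other cells' collinear edges
            covered: list[tuple[float, float]] = []
            for j, (cj, lo_j, hi_j) in enumerate(entries):
                if ci == cj:
                    continue
                lo, hi = max(lo_i, lo_j), min(hi_i, hi_j)
                if hi - lo > 10 ** (-_ROUND):
                    covered.append((lo, hi))
                    if ci < cj:  # create the shared wall once
                        add_wall((ci, cj), ori, coord, lo, hi)
            # boundary remainder of this edge
            covered.sort()
            cursor = lo_i
            for lo, hi in covered:
                if lo - cursor > 10 ** (-_ROUND):
                    add_wall((ci,), ori, coord, cursor, lo)
                cursor = max(cursor, hi)
            if hi_i - cursor > 10 ** (-_ROUND):
                add_wall((ci,), ori, coord, cursor, hi_i)

    template = RootTemplate(
        cells=cells,
        walls=walls,
        membrane_segments=segs,
        axis=np.array([0.0, 1.0]),
        qc_position=np.array([0.0, 0.0]),
    )
    _assign_faces(template)
    _mark_boundary_cells(template)
    return template


def _assign_faces(template: RootTemplate) -> None:
    for seg in template.membrane_segments:
        w = template.walls[seg.wall_id]
        c = template.cells[seg.cell_id]
        mid = w.midpoint
        cen = c.centroid
        d = mid - cen
        ax, ay = template.axis
        axial, lateral = d[0] * ax + d[1] * ay, d[0] * ay - d[1] * ax
        if abs(axial) > abs(lateral):
            seg.face = "shootward" if axial > 0 else "rootward"
        else:
            # lateral: inner if the wall lies closer to the midline than the
            # centroid does (cells straddling the midline count both as outer)
            seg.face = (
                "inner_lateral" if abs(mid[0]) < abs(cen[0]) - 1e-12 else "outer_lateral"
            )


def _mark_boundary_cells(template: RootTemplate) -> None:
    # shootward cut = boundary walls at the global maximum axial coordinate;
    # apex = boundary walls at the global minimum (compare wall positions,
    # not cell centroids: files with taller cells must not be excluded)
    wall_ax = {
        w.id: float(np.dot(w.midpoint - template.qc_position, template.axis))
        for w in template.walls.values()
    }
    y_max = max(wall_ax.values())
    y_min = min(wall_ax.values())
    shoot, apex = set(), set()
    for seg in template.membrane_segments:
        w = template.walls[seg.wall_id]
        if not w.is_boundary:
            continue
        if seg.face == "shootward" and wall_ax[w.id] > y_max - 1e-6:
            shoot.add(seg.cell_id)
        if seg.face == "rootward" and wall_ax[w.id] < y_min + 1e-6:
            apex.add(seg.cell_id)
    template.shoot_boundary_cells = frozenset(shoot)
    template.apex_cells = frozenset(apex)


# ---------------------------------------------------------------------------
# Zones
# ---------------------------------------------------------------------------


def assign_zones(template: RootTemplate, mz_length: float = 210.0) -> RootTemplate:
    """Label every non-cap cell MZ or EZ by shootward centroid distance from
    the QC (MZ iff distance <= ``mz_length``).  Cap cells keep ``zone=None``.
    """
    if mz_length < 0:
        raise TemplateError("mz_length must be >= 0")
    if template.axis is None or template.qc_position is None:
        raise TemplateError("template lacks axis or QC position")
    for c in template.cells.values():
        if is_cap_type(c.cell_type):
            c.zone = None
        else:
            c.zone = "MZ" if template.axial_distance(c) <= mz_length else "EZ"
    return template


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_template(template: RootTemplate) -> None:
    """Check geometric and topological invariants; raise TemplateError."""
    problems: list[str] = []
    for c in template.cells.values():
        poly = c.polygon
        if not poly.is_valid or poly.area <= 0:
            problems.append(f"cell {c.id}: invalid polygon or nonpositive area")
        if not is_cap_type(c.cell_type) and c.zone not in ("MZ", "EZ", None):
            problems.append(f"cell {c.id}: bad zone {c.zone!r}")
    seen_pairs = set()
    for w in template.walls.values():
        if w.length <= 0:
            problems.append(f"wall {w.id}: nonpositive length")
        if not (1 <= len(w.cell_ids) <= 2):
            problems.append(f"wall {w.id}: must reference 1 or 2 cells")
        for cid in w.cell_ids:
            if cid not in template.cells:
                problems.append(f"wall {w.id}: references unknown cell {cid}")
        seen_pairs.add((w.id, w.cell_ids))
    keys = [(s.cell_id, s.wall_id) for s in template.membrane_segments]
    if len(keys) != len(set(keys)):
        problems.append("duplicate (cell, wall) membrane segments")
    expected = {(cid, w.id) for w in template.walls.values() for cid in w.cell_ids}
    if set(keys) != expected:
        problems.append("membrane segments do not cover the (cell, wall) incidences")
    if len(template.cells) > 1 and not nx.is_connected(template.adjacency):
        problems.append("cell adjacency graph is not connected")
    if problems:
        raise TemplateError("; ".join(problems))


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------


def write_template(template: RootTemplate, path: str | Path) -> None:
    doc = {
        "schema": SCHEMA,
        "axis": template.axis.tolist(),
        "qc": template.qc_position.tolist(),
        "cells": [
            {
                "id": c.id,
                "cell_type": c.cell_type,
                "zone": c.zone,
                "vertices": np.asarray(c.vertices, float).tolist(),
            }
            for c in template.cells.values()
        ],
        "walls": [
            {
                "id": w.id,
                "cell_ids": list(w.cell_ids),
                "p1": w.p1.tolist(),
                "p2": w.p2.tolist(),
                "thickness": w.thickness,
                "pd_permeability": w.pd_permeability,
            }
            for w in template.walls.values()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_template(path: str | Path) -> RootTemplate:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise TemplateError(f"not valid JSON: {e}") from e
    missing = [k for k in ("schema", "axis", "qc", "cells", "walls") if k not in doc]
    if missing:
        raise TemplateError(f"missing top-level keys: {missing}")
    if doc["schema"] != SCHEMA:
        raise TemplateError(f"unsupported schema {doc['schema']!r} (expected {SCHEMA!r})")

    cells: dict[int, Cell] = {}
    for entry in doc["cells"]:
        try:
            cells[int(entry["id"])] = Cell(
                id=int(entry["id"]),
                cell_type=str(entry["cell_type"]),
                vertices=np.asarray(entry["vertices"], float),
                zone=entry.get("zone"),
            )
        except (KeyError, TypeError, ValueError) as e:
            raise TemplateError(f"invalid cell entry {entry!r}: {e}") from e
    walls: dict[int, Wall] = {}
    segs: list[MembraneSegment] = []
    for entry in doc["walls"]:
        try:
            w = Wall(
                id=int(entry["id"]),
                cell_ids=tuple(int(i) for i in entry["cell_ids"]),
                p1=np.asarray(entry["p1"], float),
                p2=np.asarray(entry["p2"], float),
                thickness=float(entry.get("thickness", 0.2)),
                pd_permeability=float(entry.get("pd_permeability", 0.0)),
            )
        except (KeyError, TypeError, ValueError) as e:
            raise TemplateError(f"invalid wall entry {entry!r}: {e}") from e
        for cid in w.cell_ids:
            if cid not in cells:
                raise TemplateError(f"wall {w.id} references nonexistent cell {cid}")
        walls[w.id] = w
        for cid in w.cell_ids:
            segs.append(MembraneSegment(cell_id=cid, wall_id=w.id, face="", length=w.length))

    template = RootTemplate(
        cells=cells,
        walls=walls,
        membrane_segments=segs,
        axis=np.asarray(doc["axis"], float),
        qc_position=np.asarray(doc["qc"], float),
    )
    _assign_faces(template)
    _mark_boundary_cells(template)
    validate_template(template)
    return template
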