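"""Parametric chamber/pillar geometry and structured-grid rasterization.

The chamber is a circular perfusion disc (radius ``R``) with rectangular
access channels on opposite sides and an optional array of herringbone
micropillars suspended from the lid.  Each pillar is a chevron made of a
long and a short rectangular segment joined at a bend angle, leaving a
thin gap between the pillar underside and the culture surface (the floor).

Three stock designs are provided:

* Model 1 — flat chamber, no pillars (control),
* Model 2 — large chevrons (l=1.6, s=0.8, w=0.8 mm),
* Model 3 — small chevrons (l=1.0, s=0.5, w=0.5 mm),

all with chamber radius 4 mm, fluid height 1 mm, pillar height 0.5 mm and
a 60 degree bend.  Lengths are millimetres throughout this module.

Coordinate convention: origin at the chamber centre, +x toward the outlet,
z up from the culture surface.  Grid indices are 0-based; cell ``i`` spans
the half-open interval ``[x0 + i*d, x0 + (i+1)*d)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from shapely.geometry import LineString, Point, Polygon, box
from shapely.geometry.polygon import orient
from shapely.ops import unary_union
from shapely import affinity

__all__ = [
    "PillarSpec",
    "ChamberSpec",
    "DomainGrid",
    "build_model",
    "herringbone_polygon",
    "rasterize_plan",
    "rasterize_section",
    "channel_grid",
    "strip_grid",
    "MODEL_PILLAR_DIMS",
]

# Chevron segment dimensions (long, short, width) per stock model, mm.
MODEL_PILLAR_DIMS = {2: (1.6, 0.8, 0.8), 3: (1.0, 0.5, 0.5)}

_CHAMBER_RADIUS = 4.0
_FLUID_HEIGHT = 1.0
_PILLAR_HEIGHT = 0.5
_BEND_ANGLE = 60.0
_CHANNEL_WIDTH = 1.0
_CHANNEL_LENGTH = 2.0


@dataclass(frozen=True)
class PillarSpec:
    """One herringbone pillar: two rectangular segments joined at a bend.

    ``anchor_position`` is the apex (the junction point of the two segment
    centrelines); ``orientation`` rotates the chevron about the apex,
    counter-clockwise, degrees.  At orientation 0 the chevron bisector
    points along +x with the arms opening toward -x.
    """

    long_segment_length: float
    short_segment_length: float
    segment_width: float
    bend_angle: float = _BEND_ANGLE
    height: float = _PILLAR_HEIGHT
    anchor_position: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        for name in ("long_segment_length", "short_segment_length",
                     "segment_width", "height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.bend_angle < 180.0:
            raise ValueError("bend_angle must lie strictly between 0 and 180 degrees")


@dataclass(frozen=True)
class ChamberSpec:
    """Parametric description of one chip."""

    chamber_radius: float = _CHAMBER_RADIUS
    fluid_height: float = _FLUID_HEIGHT
    inlet_width: float = _CHANNEL_WIDTH
    outlet_width: float = _CHANNEL_WIDTH
    access_channel_length: float = _CHANNEL_LENGTH
    pillars: tuple[PillarSpec, ...] = ()
    culture_surface_radius: float | None = None

    def __post_init__(self) -> None:
        if self.chamber_radius <= 0 or self.fluid_height <= 0:
            raise ValueError("chamber_radius and fluid_height must be positive")
        if self.culture_surface_radius is None:
            object.__setattr__(self, "culture_surface_radius", self.chamber_radius)
        if self.culture_surface_radius > self.chamber_radius + 1e-12:
            raise ValueError("culture_surface_radius cannot exceed chamber_radius")
        disc = Point(0.0, 0.0).buffer(self.chamber_radius, quad_segs=256)
        polys = [Polygon(herringbone_polygon(p)) for p in self.pillars]
        for p, poly in zip(self.pillars, polys):
            if p.height >= self.fluid_height:
                raise ValueError("pillar height must be below the fluid height")
            if not poly.within(disc):
                raise ValueError("pillar footprint extends outside the chamber disc")
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                if polys[i].intersects(polys[j]):
                    raise ValueError("pillar footprints overlap")

    # -- derived outline ---------------------------------------------------

    def planform(self) -> Polygon:
        """Union of the chamber disc and the two access channels."""
        disc = Point(0.0, 0.0).buffer(self.chamber_radius, quad_segs=256)
        L = self.chamber_radius + self.access_channel_length
        inlet = box(-L, -self.inlet_width / 2, -self.chamber_radius + 0.5,
                    self.inlet_width / 2)
        outlet = box(self.chamber_radius - 0.5, -self.outlet_width / 2, L,
                     self.outlet_width / 2)
        return unary_union([disc, inlet, outlet])

    def pillar_polygons(self) -> list[np.ndarray]:
        return [herringbone_polygon(p) for p in self.pillars]

    def total_pillar_area(self) -> float:
        return float(sum(Polygon(v).area for v in self.pillar_polygons()))


def herringbone_polygon(pillar: PillarSpec) -> np.ndarray:
    """Chevron outline as an (N, 2) array of CCW vertices, mm.

    The outline is the boolean union of two flat-capped rectangles whose
    centrelines start at the apex and run at ``±bend_angle/2`` about the
    local -x axis (so the included angle between segments equals
    ``bend_angle``), then rotated by ``orientation`` and translated to the
    anchor.
    """
    th = np.radians(pillar.bend_angle) / 2.0
    w = pillar.segment_width
    if min(pillar.long_segment_length, pillar.short_segment_length) <= w / 2:
        raise ValueError("segment lengths must exceed half the segment width")
    # Arms open toward -x; long arm above the bisector, short arm below.
    # Each rectangle spans its full segment length starting w/2 behind the
    # apex, so the two segments share a corner block at the joint (at a 90
    # degree bend with l = s = w the union is the classic L of area
    # l w + s w - w^2).
    e_long = np.array([-np.cos(th), np.sin(th)])
    e_short = np.array([-np.cos(th), -np.sin(th)])
    rects = []
    for e, L in ((e_long, pillar.long_segment_length),
                 (e_short, pillar.short_segment_length)):
        line = LineString([-(w / 2.0) * e, (L - w / 2.0) * e])
        rects.append(line.buffer(w / 2.0, cap_style="flat"))
    poly = unary_union(rects)
    if poly.geom_type != "Polygon":  # pragma: no cover - guarded by angle check
        raise ValueError("degenerate bend angle produced a disconnected outline")
    poly = affinity.rotate(poly, pillar.orientation, origin=(0.0, 0.0))
    poly = affinity.translate(poly, *pillar.anchor_position)
    poly = orient(poly.simplify(0.0), sign=1.0)
    verts = np.asarray(poly.exterior.coords)[:-1]
    return verts


# ---------------------------------------------------------------------------
# Stock layouts


def _default_layout(model_id: int, chamber_radius: float) -> list[PillarSpec]:
    """Staggered chevron rows spanning the chamber, alternating apex direction.

    Rows run across the flow axis; the row pitch scales with the projected
    chevron depth and the in-row pitch with the chevron span, so smaller
    pillars pack proportionally denser.  Candidates that would leave the
    chamber disc (0.15 mm clearance) or touch a neighbour (0.1 mm gap) are
    dropped, which trims the array to the circular planform.
    """
    l, s, w = MODEL_PILLAR_DIMS[model_id]
    th = np.radians(_BEND_ANGLE) / 2.0
    span = (l + s) * np.sin(th) + w * np.cos(th)  # cross-flow extent
    # row pitch: 1.5 x the projected chevron length, so consecutive rows
    # interlock like the dense herringbone-mixer arrays this adapts
    px = 1.5 * (l + s) * np.sin(th)
    py = 1.3 * span + 0.2
    margin = 0.10
    gap = 0.10

    disc = Point(0.0, 0.0).buffer(chamber_radius - margin, quad_segs=256)
    nx = int(np.ceil(chamber_radius / px)) + 1
    ny = int(np.ceil(chamber_radius / py)) + 1

    kept: list[PillarSpec] = []
    kept_polys: list[Polygon] = []
    for i in range(-nx, nx + 1):
        xc = i * px
        orientation = 0.0 if i % 2 == 0 else 180.0
        y_offset = 0.0 if i % 2 == 0 else py / 2.0
        for j in range(-ny, ny + 1):
            yc = j * py + y_offset
            probe = PillarSpec(l, s, w, _BEND_ANGLE, _PILLAR_HEIGHT,
                               (0.0, 0.0), orientation)
            base = Polygon(herringbone_polygon(probe))
            cx, cy = base.centroid.x, base.centroid.y
            anchor = (xc - cx, yc - cy)
            cand = affinity.translate(base, xc - cx, yc - cy)
            if not cand.within(disc):
                continue
            if any(cand.distance(kp) < gap for kp in kept_polys):
                continue
            kept.append(replace(probe, anchor_position=anchor))
            kept_polys.append(cand)
    return kept


def build_model(model_id: int,
                pillars: list[PillarSpec] | None = None) -> ChamberSpec:
    """Build the chamber specification for one of the three stock designs.

    ``pillars`` overrides the default staggered-row layout (layouts are
    data, not geometry: any list of valid, disjoint, in-disc pillars is
    accepted).
    """
    if model_id not in (1, 2, 3):
        raise ValueError(f"unknown model_id {model_id!r}; expected 1, 2 or 3")
    if model_id == 1:
        layout: tuple[PillarSpec, ...] = ()
    elif pillars is not None:
        layout = tuple(pillars)
    else:
        layout = tuple(_default_layout(model_id, _CHAMBER_RADIUS))
    return ChamberSpec(pillars=layout)


# ---------------------------------------------------------------------------
# Rasterization


@dataclass
class DomainGrid:
    """Uniform Cartesian rasterization of a chamber (plan or section mode).

    ``solid_mask[j, i]`` is True for cells outside the fluid;
    ``height_map`` (plan mode, mm) is the local gap between floor and
    lid/pillar underside.  ``boundary_labels`` marks inlet/outlet cells.
    In plan mode axes are (y, x); in section mode (z, x).
    """

    cell_size: float
    x0: float
    y0: float
    n_x: int
    n_y: int
    solid_mask: np.ndarray
    height_map: np.ndarray | None
    inlet_cells: np.ndarray      # boolean, shape (n_y, n_x)
    outlet_cells: np.ndarray
    mode: Literal["plan", "section"]
    fluid_height: float
    culture_mask: np.ndarray = field(default=None)  # floor cells of interest

    def __post_init__(self) -> None:
        if not self.inlet_cells.any() or not self.outlet_cells.any():
            raise ValueError("inlet and outlet label sets must be non-empty")
        if (self.inlet_cells & self.outlet_cells).any():
            raise ValueError("inlet and outlet labels overlap")
        if not self._single_fluid_component():
            raise ValueError("fluid cells do not form a single connected "
                             "component joining inlet and outlet")

    # cell-centre coordinate helpers
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_x) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.n_y) + 0.5) * self.cell_size

    @property
    def fluid_mask(self) -> np.ndarray:
        return ~self.solid_mask

    def _single_fluid_component(self) -> bool:
        from scipy.ndimage import label

        lab, n = label(self.fluid_mask)
        if n == 0:
            return False
        inlet_ids = set(np.unique(lab[self.inlet_cells])) - {0}
        outlet_ids = set(np.unique(lab[self.outlet_cells])) - {0}
        if len(inlet_ids) != 1 or inlet_ids != outlet_ids:
            return False
        main = inlet_ids.pop()
        return bool(((lab == main) == self.fluid_mask).all())


def _min_cell_size(spec: ChamberSpec) -> float:
    if spec.pillars:
        return min(p.segment_width for p in spec.pillars) / 4.0
    return spec.inlet_width / 2.0


def _check_resolution(spec: ChamberSpec, cell_size: float) -> None:
    limit = _min_cell_size(spec)
    if cell_size > limit + 1e-12:
        raise ValueError(
            f"cell_size {cell_size} mm too coarse; the narrowest pillar "
            f"segment must span >= 4 cells (maximum admissible {limit} mm)")


def rasterize_plan(spec: ChamberSpec, cell_size: float) -> DomainGrid:
    """Rasterize the chamber planform onto a uniform (y, x) grid.

    Cell-centre point-in-polygon rule (no partial volumes): a cell is fluid
    iff its centre lies inside the planform; its gap height is
    ``fluid_height`` in the open region and ``fluid_height - pillar.height``
    beneath a pillar footprint.
    """
    _check_resolution(spec, cell_size)
    L = spec.chamber_radius + spec.access_channel_length
    half_w = max(spec.chamber_radius, spec.inlet_width, spec.outlet_width) / 2
    ymax = spec.chamber_radius + cell_size
    n_x = int(np.ceil(2 * L / cell_size))
    n_y = int(np.ceil(2 * ymax / cell_size))
    x0, y0 = -L, -ymax

    xc = x0 + (np.arange(n_x) + 0.5) * cell_size
    yc = y0 + (np.arange(n_y) + 0.5) * cell_size
    XX, YY = np.meshgrid(xc, yc)

    from shapely import contains_xy

    planform = spec.planform()
    fluid = contains_xy(planform, XX.ravel(), YY.ravel()).reshape(n_y, n_x)

    height = np.where(fluid, spec.fluid_height, 0.0)
    for p in spec.pillars:
        poly = Polygon(herringbone_polygon(p))
        hit = contains_xy(poly, XX.ravel(), YY.ravel()).reshape(n_y, n_x)
        height[hit & fluid] = spec.fluid_height - p.height

    solid = ~fluid
    inlet = np.zeros_like(fluid)
    outlet = np.zeros_like(fluid)
    first = fluid.argmax(axis=1)
    # inlet/outlet are the fluid cells on the leftmost/rightmost open column
    left_cols = np.where(fluid.any(axis=0))[0]
    inlet[:, left_cols[0]] = fluid[:, left_cols[0]]
    outlet[:, left_cols[-1]] = fluid[:, left_cols[-1]]
    del first

    rr = np.hypot(XX, YY)
    culture = fluid & (rr <= spec.culture_surface_radius)

    return DomainGrid(cell_size=cell_size, x0=x0, y0=y0, n_x=n_x, n_y=n_y,
                      solid_mask=solid, height_map=height,
                      inlet_cells=inlet, outlet_cells=outlet, mode="plan",
                      fluid_height=spec.fluid_height, culture_mask=culture)


def rasterize_section(spec: ChamberSpec, cell_size: float) -> DomainGrid:
    """Rasterize the longitudinal mid-plane (x-z) section through y=0.

    The floor is at z=0, the lid at z=fluid_height; wherever the mid-plane
    line crosses a pillar footprint, a solid block of the pillar height
    hangs from the lid.
    """
    _check_resolution(spec, cell_size)
    L = spec.chamber_radius + spec.access_channel_length
    n_x = int(np.ceil(2 * L / cell_size))
    n_z = max(int(round(spec.fluid_height / cell_size)), 4)
    x0, z0 = -L, 0.0

    xc = x0 + (np.arange(n_x) + 0.5) * cell_size
    zc = z0 + (np.arange(n_z) + 0.5) * cell_size
    solid = np.zeros((n_z, n_x), dtype=bool)

    from shapely import contains_xy

    planform = spec.planform()
    on_line = contains_xy(planform, xc, np.zeros_like(xc))
    solid[:, ~on_line] = True

    for p in spec.pillars:
        poly = Polygon(herringbone_polygon(p))
        hit = contains_xy(poly, xc, np.zeros_like(xc))
        if not hit.any():
            continue
        under = zc > (spec.fluid_height - p.height)
        solid[np.ix_(under, hit)] = True

    fluid = ~solid
    inlet = np.zeros_like(fluid)
    outlet = np.zeros_like(fluid)
    cols = np.where(fluid.any(axis=0))[0]
    inlet[:, cols[0]] = fluid[:, cols[0]]
    outlet[:, cols[-1]] = fluid[:, cols[-1]]

    culture = np.zeros_like(fluid)
    culture[0, :] = fluid[0, :] & (np.abs(xc) <= spec.culture_surface_radius)

    return DomainGrid(cell_size=cell_size, x0=x0, y0=z0, n_x=n_x, n_y=n_z,
                      solid_mask=solid, height_map=None,
                      inlet_cells=inlet, outlet_cells=outlet, mode="section",
                      fluid_height=spec.fluid_height, culture_mask=culture)


# ---------------------------------------------------------------------------
# Benchmark grids (plain channels/strips, used by the verification fixtures)


def channel_grid(length: float, height: float, cell_size: float) -> DomainGrid:
    """Section-mode rectangular channel: floor z=0, lid z=height, flow in +x."""
    n_x = int(round(length / cell_size))
    n_z = int(round(height / cell_size))
    solid = np.zeros((n_z, n_x), dtype=bool)
    inlet = np.zeros_like(solid)
    outlet = np.zeros_like(solid)
    inlet[:, 0] = True
    outlet[:, -1] = True
    culture = np.zeros_like(solid)
    culture[0, :] = True
    return DomainGrid(cell_size=cell_size, x0=0.0, y0=0.0, n_x=n_x, n_y=n_z,
                      solid_mask=solid, height_map=None,
                      inlet_cells=inlet, outlet_cells=outlet, mode="section",
                      fluid_height=height, culture_mask=culture)


def strip_grid(length: float, width: float, gap_height: float,
               cell_size: float) -> DomainGrid:
    """Plan-mode straight strip of uniform gap height (Hele-Shaw benchmark)."""
    n_x = int(round(length / cell_size))
    n_y = int(round(width / cell_size))
    solid = np.zeros((n_y, n_x), dtype=bool)
    height = np.full((n_y, n_x), gap_height)
    inlet = np.zeros_like(solid)
    outlet = np.zeros_like(solid)
    inlet[:, 0] = True
    outlet[:, -1] = True
    culture = np.ones_like(solid)
    return DomainGrid(cell_size=cell_size, x0=0.0, y0=-width / 2,
                      n_x=n_x, n_y=n_y, solid_mask=solid, height_map=height,
                      inlet_cells=inlet, outlet_cells=outlet, mode="plan",
                      fluid_height=gap_height, culture_mask=culture)
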