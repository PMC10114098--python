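"""Deterministic synthetic substrates for isthmus/reentry analysis.

Real post-infarction ventricles carry a non-conducting scar transcended by
narrow surviving corridors of myocardium (isthmuses) — the anatomical
substrate of scar-related ventricular tachycardia. The generators here build
idealized versions of that anatomy on structured tetrahedral meshes:

* a slab of conducting tissue with an embedded transmural scar block crossed
  by one or more conducting channels (optionally rimmed by slow border zone);
* an annular prism ("ring") whose unique reentrant loop has a closed-form
  mid-radius circumference, used to validate round-trip times.

All generators are pure functions of their parameters — no randomness — so
every downstream stage can be tested against constructed ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .mesh import BZ, HEALTHY, SCAR, TetMesh, element_components

__all__ = [
    "Box",
    "ScarSpec",
    "FixtureReport",
    "make_slab",
    "embed_scar",
    "make_ring",
    "make_preset",
    "count_corridors",
    "PRESETS",
]

# Kuhn split of the unit cube into 6 tets sharing the (0,0,0)-(1,1,1)
# diagonal; vertex ids are bitmasks b = x + 2y + 4z. Face diagonals match
# between neighbouring cells, so the global mesh is conforming.
_KUHN_TETS = np.array(
    [
        (0, 1, 3, 7),
        (0, 3, 2, 7),
        (0, 2, 6, 7),
        (0, 6, 4, 7),
        (0, 4, 5, 7),
        (0, 5, 1, 7),
    ]
)


@dataclass(frozen=True)
class Box:
    """Axis-aligned box given by min/max corners (mm)."""

    lo: tuple
    hi: tuple

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        return np.all((pts >= lo) & (pts <= hi), axis=1)

    def expand(self, margin: float) -> "Box":
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        return Box(tuple(lo - margin), tuple(hi + margin))


@dataclass
class ScarSpec:
    """A scar block with conducting channel corridors through it.

    Each channel box must fully traverse the scar along its long axis and the
    channels must be pairwise disjoint. ``bz_rim_thickness`` > 0 adds a
    border-zone rim around the scar (and lines the channels with BZ when
    ``channel_label`` is BZ).
    """

    scar: Box
    channels: list = dc_field(default_factory=list)
    bz_rim_thickness: float = 0.0
    channel_label: int = HEALTHY

    def __post_init__(self):
        if self.bz_rim_thickness < 0:
            raise ValueError("bz_rim_thickness must be >= 0")
        slo, shi = np.asarray(self.scar.lo), np.asarray(self.scar.hi)
        for ch in self.channels:
            clo, chi = np.asarray(ch.lo), np.asarray(ch.hi)
            if not np.any((clo <= slo) & (chi >= shi)):
                raise ValueError("channel does not traverse the scar box")
        for i, a in enumerate(self.channels):
            for b in self.channels[i + 1 :]:
                alo, ahi = np.asarray(a.lo), np.asarray(a.hi)
                blo, bhi = np.asarray(b.lo), np.asarray(b.hi)
                if np.all((alo < bhi) & (blo < ahi)):
                    raise ValueError("channels overlap")


@dataclass
class FixtureReport:
    """Constructed ground truth for a fixture.

    ``channel_loop_lengths`` holds, per channel, the length (mm) of the
    shortest reentrant path through that channel, computed by a Dijkstra
    oracle on the conducting edge graph with the channel mid-section cut.
    """

    n_channels: int
    channel_loop_lengths: list
    pacing_sites: list


def make_slab(
    dimensions_mm, target_edge_mm: float, fiber_direction=(1.0, 0.0, 0.0)
) -> TetMesh:
    """Structured slab of cube cells, each split into 6 tets.

    Cell counts are ``round(dimension / target_edge)`` per axis (at least 1),
    so the realized spacing can differ slightly from ``target_edge_mm``.
    All elements are HEALTHY with the given (normalized) fiber direction.
    """
    dims = np.asarray(dimensions_mm, dtype=float)
    if np.any(dims <= 0) or target_edge_mm <= 0:
        raise ValueError("dimensions and target edge must be positive")
    fib = np.asarray(fiber_direction, dtype=float)
    nrm = np.linalg.norm(fib)
    if nrm < 1e-12:
        raise ValueError("fiber direction must be normalizable")
    fib = fib / nrm

    nc = np.maximum(1, np.round(dims / target_edge_mm).astype(int))
    nx, ny, nz = nc
    xs = [np.linspace(0.0, dims[i], nc[i] + 1) for i in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    points = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    # cube corner ids for every cell, indexed by bitmask b = x + 2y + 4z
    corners = np.stack(
        [nid(ii + (b & 1), jj + ((b >> 1) & 1), kk + ((b >> 2) & 1)) for b in range(8)],
        axis=1,
    )
    tets = corners[:, _KUHN_TETS].reshape(-1, 4)
    m = len(tets)
    fibers = np.tile(fib, (m, 1))
    labels = np.full(m, HEALTHY, dtype=np.int64)
    return TetMesh(points, tets, fibers, labels)


def embed_scar(mesh: TetMesh, spec: ScarSpec) -> TetMesh:
    """Label elements of ``mesh`` according to a :class:`ScarSpec`.

    Membership is decided by the element centroid: inside a channel box ->
    channel label; inside the scar box -> SCAR; within the BZ rim of the scar
    boundary -> BZ; otherwise unchanged. Centroid classification gives
    staircase boundaries, which is acceptable at fixture scale.
    """
    cen = mesh.centroids()
    labels = mesh.labels.copy()
    in_scar = spec.scar.contains(cen)
    in_channel = np.zeros(mesh.n_tets, dtype=bool)
    for ch in spec.channels:
        in_channel |= ch.contains(cen)
    labels[in_scar & ~in_channel] = SCAR
    if spec.bz_rim_thickness > 0:
        rim = spec.scar.expand(spec.bz_rim_thickness).contains(cen) & ~in_scar
        labels[rim & ~in_channel] = BZ
    labels[in_scar & in_channel] = spec.channel_label

    out = TetMesh(mesh.points, mesh.tets, mesh.fibers, labels)
    _warn_on_degenerate(out, spec)
    return out


def _warn_on_degenerate(mesh: TetMesh, spec: ScarSpec):
    edge = float(np.min(mesh.edge_lengths))  # ~ the grid spacing
    for ch in spec.channels:
        widths = np.asarray(ch.hi) - np.asarray(ch.lo)
        if np.sort(widths)[0] < 2 * edge:
            warnings.warn("channel may pinch off (narrower than 2 edge lengths)")
    # a return path around the scar must exist for reentry
    lo, hi = np.asarray(spec.scar.lo), np.asarray(spec.scar.hi)
    pmin, pmax = mesh.points.min(axis=0), mesh.points.max(axis=0)
    spans = (lo <= pmin + 1e-9) & (hi >= pmax - 1e-9)
    if spans.sum() >= 2:
        ncorr = count_corridors(mesh, spec)
        if ncorr == 0 and len(spec.channels) == 0:
            warnings.warn("no reentrant return path: scar spans the cross-section")


def count_corridors(mesh: TetMesh, spec: ScarSpec) -> int:
    """Number of face-connected conducting corridors through the scar box.

    Flood-fills conducting elements whose centroid lies inside the scar box;
    each component that touches both opposing scar faces counts as one
    corridor.
    """
    cen = mesh.centroids()
    inside = spec.scar.contains(cen) & (mesh.labels != SCAR)
    ncomp, comp = element_components(mesh, inside)
    if ncomp == 0:
        return 0
    # long axis = axis along which every channel traverses the scar
    slo, shi = np.asarray(spec.scar.lo), np.asarray(spec.scar.hi)
    edge = float(np.median(mesh.edge_lengths))
    count = 0
    for c in range(ncomp):
        pts = cen[comp == c]
        # touches both opposing faces along some axis
        touches = (pts.min(axis=0) < slo + edge) & (pts.max(axis=0) > shi - edge)
        if np.any(touches):
            count += 1
    return count


def make_ring(
    inner_radius: float,
    outer_radius: float,
    height: float,
    target_edge_mm: float,
) -> TetMesh:
    """Annular prism with circumferential fibers; all elements HEALTHY.

    The only non-contractible loop runs around the annulus; its mid-radius
    circumference is ``2*pi*(inner+outer)/2``.
    """
    if not (0 < inner_radius < outer_radius) or height <= 0:
        raise ValueError("need 0 < inner_radius < outer_radius and height > 0")
    if target_edge_mm <= 0:
        raise ValueError("target edge must be positive")
    rmid = 0.5 * (inner_radius + outer_radius)
    ntheta = max(8, int(round(2 * np.pi * rmid / target_edge_mm)))
    nr = max(1, int(round((outer_radius - inner_radius) / target_edge_mm)))
    nz = max(1, int(round(height / target_edge_mm)))

    thetas = np.linspace(0.0, 2 * np.pi, ntheta, endpoint=False)
    rs = np.linspace(inner_radius, outer_radius, nr + 1)
    zs = np.linspace(0.0, height, nz + 1)
    # node id (it, ir, iz), theta periodic
    T, R, Z = np.meshgrid(np.arange(ntheta), np.arange(nr + 1), np.arange(nz + 1),
                          indexing="ij")
    points = np.column_stack(
        [
            (rs[R] * np.cos(thetas[T])).ravel(),
            (rs[R] * np.sin(thetas[T])).ravel(),
            zs[Z].ravel(),
        ]
    )

    def nid(it, ir, iz):
        return ((it % ntheta) * (nr + 1) + ir) * (nz + 1) + iz

    ii, jj, kk = np.meshgrid(
        np.arange(ntheta), np.arange(nr), np.arange(nz), indexing="ij"
    )
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    corners = np.stack(
        [nid(ii + (b & 1), jj + ((b >> 1) & 1), kk + ((b >> 2) & 1)) for b in range(8)],
        axis=1,
    )
    tets = corners[:, _KUHN_TETS].reshape(-1, 4)
    mesh_pts = points
    cen = mesh_pts[tets].mean(axis=1)
    # circumferential fiber at each element centroid
    phi = np.arctan2(cen[:, 1], cen[:, 0])
    fibers = np.column_stack([-np.sin(phi), np.cos(phi), np.zeros_like(phi)])
    labels = np.full(len(tets), HEALTHY, dtype=np.int64)
    return TetMesh(mesh_pts, tets, fibers, labels)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Preset geometry is commensurate with the default 0.8 mm grid so that every
# box face falls on a cell boundary: the scar wall is then watertight under
# per-element centroid classification instead of a porous staircase.
_SLAB_DIMS = (40.0, 9.6, 4.8)
_SCAR_BOX = Box((12.0, 1.6, 0.0), (28.0, 8.0, 4.8))
_CH_MID = Box((12.0, 4.0, 0.0), (28.0, 5.6, 4.8))
_CH_LOW = Box((12.0, 2.4, 0.0), (28.0, 4.0, 4.8))
_CH_HIGH = Box((12.0, 5.6, 0.0), (28.0, 7.2, 4.8))

PRESETS = {
    "slab": None,
    "slab1ch": ScarSpec(_SCAR_BOX, [_CH_MID]),
    "slab2ch": ScarSpec(_SCAR_BOX, [_CH_LOW, _CH_HIGH]),
    "slab1ch-bz": ScarSpec(_SCAR_BOX, [_CH_MID], bz_rim_thickness=0.8,
                           channel_label=BZ),
    "ring": None,
}

#: four pacing sites at the slab corners (center, radius in mm)
SLAB_CORNER_SITES = [
    ((0.0, 0.0, 2.4), 2.0),
    ((40.0, 0.0, 2.4), 2.0),
    ((0.0, 9.6, 2.4), 2.0),
    ((40.0, 9.6, 2.4), 2.0),
]


def make_preset(name: str, edge: float = 0.8) -> TetMesh:
    """Build one of the named fixtures at the given target edge length."""
    if name == "ring":
        return make_ring(9.0, 11.0, 2.0, min(edge, 0.6))
    if name not in PRESETS:
        raise KeyError(f"unknown preset '{name}' (have {sorted(PRESETS)})")
    slab = make_slab(_SLAB_DIMS, edge)
    spec = PRESETS[name]
    if spec is None:
        return slab
    return embed_scar(slab, spec)


def fixture_report(mesh: TetMesh, spec: ScarSpec) -> FixtureReport:
    """Ground-truth report: corridor count and per-channel loop lengths.

    Loop lengths come from a Dijkstra oracle: cut the conducting edges that
    cross the channel's mid-plane inside the channel, then measure the
    shortest remaining path between the two sides of the cut.
    """
    n = count_corridors(mesh, spec)
    lengths = []
    for ch in spec.channels:
        clo, chi = np.asarray(ch.lo), np.asarray(ch.hi)
        slo, shi = np.asarray(spec.scar.lo), np.asarray(spec.scar.hi)
        axis = int(np.argmax((clo <= slo) & (chi >= shi)))
        midplane = 0.5 * (slo[axis] + shi[axis])
        edges = mesh.conducting_edges()
        pa, pb = mesh.points[edges[:, 0]], mesh.points[edges[:, 1]]
        # epsilon-expanded: lattice coordinates can sit 1 ulp off a box face
        in_ch = ch.expand(1e-6).contains(0.5 * (pa + pb))
        crosses = (
            np.minimum(pa[:, axis], pb[:, axis]) < midplane
        ) & (np.maximum(pa[:, axis], pb[:, axis]) >= midplane)
        cut = in_ch & crosses
        if not np.any(cut):
            lengths.append(np.inf)
            continue
        keep = mesh.adjacency(edges[~cut])
        src = np.unique(edges[cut][:, 0])
        dst = np.unique(edges[cut][:, 1])
        # orient: src on the low side of the plane
        low = mesh.points[src][:, axis] < midplane
        src, dst = (
            np.concatenate([src[low], dst[mesh.points[dst][:, axis] < midplane]]),
            np.concatenate([src[~low], dst[mesh.points[dst][:, axis] >= midplane]]),
        )
        d = dijkstra(keep, indices=src, min_only=True)
        lengths.append(float(np.min(d[dst])))
    return FixtureReport(
        n_channels=n, channel_loop_lengths=lengths, pacing_sites=SLAB_CORNER_SITES
    )
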