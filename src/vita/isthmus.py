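"""Isosurface split detection and isthmus exit-site classification.

A distance field paced from outside a scar wraps around it; inside a
conducting channel (isthmus) the wavefront is laterally confined, so level
sets of the field split into multiple connected components there. Tracking
the non-largest ("split") fragments level by level samples the isthmus
structure; a split fragment with no downstream neighbour marks the point
where the confined front terminates — by re-merging with the bulk front or
colliding with an opposing front — and is classified as an exit site, the
location where the reentrant wavefront would re-enter bulk myocardium.

Level sets are triangulated by marching tetrahedra over conducting elements;
fragments are edge-connected triangle components; downstream/upstream
neighbourhood is established by steepest ascent/descent walks of the field
along the mesh edge graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .mesh import NodeField, TetMesh

__all__ = [
    "SurfaceFragment",
    "IsthmusGraph",
    "ExitSite",
    "extract_level_sets",
    "split_fragments",
    "combine_micro_fragments",
    "link_isthmus_graph",
    "detect_exit_sites",
]

DEFAULT_D_ISO = 1.0  # mm between consecutive levels

# Marching-tetrahedra case table. Local edges: 0:(0,1) 1:(0,2) 2:(0,3)
# 3:(1,2) 4:(1,3) 5:(2,3). Key: bitmask of vertices with field < level.
_EDGE_VERTS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_MT_TABLE = {
    1: [(0, 1, 2)],
    2: [(0, 3, 4)],
    4: [(1, 3, 5)],
    8: [(2, 4, 5)],
    3: [(1, 2, 4), (1, 4, 3)],
    12: [(1, 2, 4), (1, 4, 3)],
    5: [(0, 2, 5), (0, 5, 3)],
    10: [(0, 2, 5), (0, 5, 3)],
    9: [(0, 1, 5), (0, 5, 4)],
    6: [(0, 1, 5), (0, 5, 4)],
    7: [(2, 4, 5)],
    11: [(1, 3, 5)],
    13: [(0, 3, 4)],
    14: [(0, 1, 2)],
}


@dataclass
class SurfaceFragment:
    """One edge-connected component of a level set.

    ``support`` holds the straddling node pairs of the tet edges the fragment
    cuts: column 0 the proximal endpoint (field < level), column 1 the distal
    endpoint (field >= level).
    """

    id: int
    level: float
    triangles: np.ndarray  # (T, 3, 3) vertex coordinates
    area: float
    support: np.ndarray  # (K, 2) [proximal, distal] node indices
    members: tuple = ()  # non-empty for combined candidates

    @property
    def proximal_nodes(self) -> np.ndarray:
        return np.unique(self.support[:, 0])

    @property
    def distal_nodes(self) -> np.ndarray:
        return np.unique(self.support[:, 1])

    @property
    def is_combined(self) -> bool:
        return len(self.members) > 0


@dataclass
class IsthmusGraph:
    """Split-fragment candidates per level with up/downstream linkage."""

    d_iso: float
    candidates: dict  # level -> list of SurfaceFragment
    downstream: dict = dc_field(default_factory=dict)  # frag id -> set of ids
    upstream: dict = dc_field(default_factory=dict)
    fragments_by_id: dict = dc_field(default_factory=dict)

    def all_candidates(self):
        for level in sorted(self.candidates):
            for frag in self.candidates[level]:
                yield frag


@dataclass
class ExitSite:
    """Terminal split fragment: where a confined wavefront ends."""

    fragment: SurfaceFragment
    is_entrance: bool = False

    @property
    def id(self) -> int:
        return self.fragment.id

    @property
    def level(self) -> float:
        return self.fragment.level

    @property
    def proximal_nodes(self) -> np.ndarray:
        return self.fragment.proximal_nodes

    @property
    def distal_nodes(self) -> np.ndarray:
        return self.fragment.distal_nodes


# ---------------------------------------------------------------------------
# level-set extraction
# ---------------------------------------------------------------------------


def _triangulate_level(mesh, values, elems, level):
    """Marching tetrahedra at one level over the given elements.

    Returns (tri_keys, tri_pts): per triangle the canonical ids of its three
    cut vertices (encoding the straddling mesh edge) and their coordinates.
    """
    tets = mesh.tets[elems]
    f = values[tets]
    below = f < level
    masks = (below * np.array([1, 2, 4, 8])).sum(axis=1)
    n = mesh.n_points
    keys_out, pts_out = [], []
    for mm, tris in _MT_TABLE.items():
        sel = masks == mm
        if not np.any(sel):
            continue
        t4 = tets[sel]
        f4 = f[sel]
        for tri in tris:
            k3 = np.empty((sel.sum(), 3), dtype=np.int64)
            p3 = np.empty((sel.sum(), 3, 3))
            for c, eid in enumerate(tri):
                i, j = _EDGE_VERTS[eid]
                A, B = t4[:, i], t4[:, j]
                fa, fb = f4[:, i], f4[:, j]
                # orient: lo has field < level
                lo_is_a = fa < level
                lo = np.where(lo_is_a, A, B)
                hi = np.where(lo_is_a, B, A)
                flo = np.where(lo_is_a, fa, fb)
                fhi = np.where(lo_is_a, fb, fa)
                w = (level - flo) / (fhi - flo)
                p3[:, c] = mesh.points[lo] + w[:, None] * (
                    mesh.points[hi] - mesh.points[lo]
                )
                k3[:, c] = np.minimum(A, B) * n + np.maximum(A, B)
            keys_out.append(k3)
            pts_out.append(p3)
    if not keys_out:
        return np.empty((0, 3), dtype=np.int64), np.empty((0, 3, 3))
    return np.concatenate(keys_out), np.concatenate(pts_out)


def _triangle_areas(tri_pts):
    a = tri_pts[:, 1] - tri_pts[:, 0]
    b = tri_pts[:, 2] - tri_pts[:, 0]
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)


def _fragment_components(tri_keys):
    """Group triangles into edge-connected components via shared cut edges."""
    T = len(tri_keys)
    # triangle edges as sorted pairs of cut-vertex keys
    pairs = np.stack(
        [tri_keys[:, (0, 1)], tri_keys[:, (1, 2)], tri_keys[:, (0, 2)]], axis=1
    ).reshape(-1, 2)
    pairs = np.sort(pairs, axis=1)
    _, grp = np.unique(pairs, axis=0, return_inverse=True)
    tri_ids = np.repeat(np.arange(T), 3)
    order = np.argsort(grp, kind="stable")
    grp_s, tri_s = grp[order], tri_ids[order]
    same = grp_s[1:] == grp_s[:-1]
    i, j = tri_s[:-1][same], tri_s[1:][same]
    adj = sparse.coo_matrix(
        (np.ones(2 * len(i)), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(T, T),
    ).tocsr()
    ncomp, lab = connected_components(adj, directed=False)
    return ncomp, lab


def extract_level_sets(
    field: NodeField | np.ndarray,
    mesh: TetMesh,
    d_iso: float = DEFAULT_D_ISO,
    excluded_elements: np.ndarray | None = None,
) -> dict:
    """Marching-tetrahedra fragments of {field = k*d_iso} per level.

    Returns ``{level: [SurfaceFragment, ...]}`` with fragments numbered in
    construction order (levels ascending, components by discovery). Only
    conducting elements with all-finite nodal values are triangulated.
    """
    if d_iso <= 0:
        raise ValueError("d_iso must be > 0")
    values = field.values if isinstance(field, NodeField) else np.asarray(field)
    finite = np.isfinite(values)
    if not np.any(finite):
        raise ValueError("field is undefined everywhere")
    cond = mesh.conducting_elements(excluded_elements)
    cond &= np.all(finite[mesh.tets], axis=1)
    elems_all = np.where(cond)[0]
    vmax = values[finite].max()
    n_levels = int(np.floor(vmax / d_iso))
    n = mesh.n_points

    out = {}
    next_id = 0
    fvals = values[mesh.tets[elems_all]]
    fmin, fmax = fvals.min(axis=1), fvals.max(axis=1)
    for k in range(1, n_levels + 1):
        level = k * d_iso
        elems = elems_all[(fmin < level) & (fmax >= level)]
        if not len(elems):
            continue
        tri_keys, tri_pts = _triangulate_level(mesh, values, elems, level)
        if not len(tri_keys):
            continue
        areas = _triangle_areas(tri_pts)
        ncomp, lab = _fragment_components(tri_keys)
        frags = []
        for c in range(ncomp):
            sel = lab == c
            keys = np.unique(tri_keys[sel])
            sup = np.column_stack([keys // n, keys % n])
            # orient support pairs: proximal = field < level
            swap = values[sup[:, 0]] >= level
            sup[swap] = sup[swap][:, ::-1]
            frags.append(
                SurfaceFragment(
                    id=next_id,
                    level=level,
                    triangles=tri_pts[sel],
                    area=float(areas[sel].sum()),
                    support=sup,
                )
            )
            next_id += 1
        out[level] = frags
    return out


# ---------------------------------------------------------------------------
# split candidates
# ---------------------------------------------------------------------------


def split_fragments(level_sets: dict) -> dict:
    """Drop the largest fragment at each level; the rest are split candidates.

    The largest fragment is the part of the wavefront wrapping around the
    bulk of the tissue; levels with a single fragment yield no candidates.
    Area ties break toward the lowest fragment id.
    """
    out = {}
    for level, frags in level_sets.items():
        if len(frags) < 2:
            continue
        largest = max(frags, key=lambda fr: (fr.area, -fr.id))
        cands = [fr for fr in frags if fr.id != largest.id]
        if cands:
            out[level] = cands
    return out


def combine_micro_fragments(candidates: dict) -> dict:
    """At levels with >= 2 candidates, add their union as an extra candidate.

    Fibrosis inside an isthmus shatters the confined front into several
    micro-fragments; insulating any single one would not block the channel,
    so the union is tested as well. Combined candidates get fresh ids above
    all member ids and record their members.
    """
    next_id = 1 + max(
        (fr.id for frs in candidates.values() for fr in frs), default=-1
    )
    out = {}
    for level, frags in sorted(candidates.items()):
        frags = list(frags)
        if len(frags) >= 2:
            union = SurfaceFragment(
                id=next_id,
                level=level,
                triangles=np.concatenate([fr.triangles for fr in frags]),
                area=float(sum(fr.area for fr in frags)),
                support=np.concatenate([fr.support for fr in frags]),
                members=tuple(fr.id for fr in frags),
            )
            next_id += 1
            frags.append(union)
        out[level] = frags
    return out


# ---------------------------------------------------------------------------
# linkage
# ---------------------------------------------------------------------------


def _steepest_walk(start, values, nb_ptr, nb_idx, targets, sign, step_cap):
    """Walk the edge graph by steepest ascent (sign=+1) or descent (-1).

    Returns the target fragment id if a walk node is a supporting node of a
    target fragment, else -1. ``targets`` maps node -> fragment id.
    """
    v = start
    for _ in range(step_cap):
        tid = targets.get(v, -1)
        if tid >= 0:
            return tid
        best = -1
        best_val = sign * values[v]
        for p in range(nb_ptr[v], nb_ptr[v + 1]):
            nb = nb_idx[p]
            val = sign * values[nb]
            if np.isfinite(val) and val > best_val:
                best_val = val
                best = nb
            # plateau/tie: keep the first (lowest-index) neighbour
        if best < 0:
            return -1
        v = best
    return -1


def link_isthmus_graph(
    candidates: dict,
    field: NodeField | np.ndarray,
    mesh: TetMesh,
    d_iso: float = DEFAULT_D_ISO,
    excluded_elements: np.ndarray | None = None,
) -> IsthmusGraph:
    """Link split candidates of consecutive levels into an isthmus graph.

    From every distal supporting node of a candidate at level d, a steepest
    ascent of the field along the conducting edge graph is launched; if it
    reaches a supporting node of a candidate at level d + d_iso, a downstream
    link is recorded. Upstream links use steepest descent to d - d_iso.
    Combined candidates inherit the union of their members' links. Walks end
    at local extrema or after a step cap of the node count.
    """
    values = field.values if isinstance(field, NodeField) else np.asarray(field)
    pairs = mesh.conducting_edges(excluded_elements)
    n = mesh.n_points
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.argsort(src, kind="stable")
    counts = np.bincount(src, minlength=n)
    nb_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    nb_idx = dst[order]

    graph = IsthmusGraph(d_iso=d_iso, candidates=candidates)
    levels = sorted(candidates)
    # node -> candidate id maps per level (individual candidates only;
    # combined candidates share their members' supports)
    support_map = {}
    for level in levels:
        m = {}
        for fr in candidates[level]:
            if fr.is_combined:
                continue
            for nd in np.unique(fr.support):
                m.setdefault(int(nd), fr.id)
        support_map[level] = m
    for level in levels:
        for fr in candidates[level]:
            graph.fragments_by_id[fr.id] = fr
            graph.downstream.setdefault(fr.id, set())
            graph.upstream.setdefault(fr.id, set())

    step_cap = n
    for level in levels:
        for fr in candidates[level]:
            if fr.is_combined:
                continue
            nxt = round(level + d_iso, 9)
            if nxt in support_map:
                for nd in fr.distal_nodes:
                    tid = _steepest_walk(
                        int(nd), values, nb_ptr, nb_idx, support_map[nxt], 1.0,
                        step_cap,
                    )
                    if tid >= 0:
                        graph.downstream[fr.id].add(tid)
                        graph.upstream[tid].add(fr.id)
            prv = round(level - d_iso, 9)
            if prv in support_map:
                for nd in fr.proximal_nodes:
                    tid = _steepest_walk(
                        int(nd), values, nb_ptr, nb_idx, support_map[prv], -1.0,
                        step_cap,
                    )
                    if tid >= 0:
                        graph.upstream[fr.id].add(tid)
                        graph.downstream[tid].add(fr.id)

    # combined candidates inherit the union of their members' links
    for level in levels:
        for fr in candidates[level]:
            if fr.is_combined:
                down = set().union(*(graph.downstream[m] for m in fr.members))
                up = set().union(*(graph.upstream[m] for m in fr.members))
                graph.downstream[fr.id] = down
                graph.upstream[fr.id] = up
    return graph


def detect_exit_sites(graph: IsthmusGraph) -> list:
    """Exit sites: candidates with no downstream link, ordered by (level, id).

    Candidates with no upstream link are additionally reported as entrances
    (flagged, not targeted for ablation).
    """
    exits = []
    for fr in graph.all_candidates():
        if not graph.downstream.get(fr.id):
            exits.append(
                ExitSite(fr, is_entrance=not graph.upstream.get(fr.id))
            )
    exits.sort(key=lambda e: (e.level, e.id))
    return exits
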