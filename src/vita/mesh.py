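"""Tetrahedral mesh data model, CARP-format I/O and derived connectivity.

Meshes are labelled tetrahedral volumes: node coordinates in mm, one fiber
(longitudinal) direction and one region tag per element. Region tags
distinguish healthy myocardium, slow-conducting border zone (BZ) and
non-conducting scar. Transverse isotropy is assumed throughout, so only the
longitudinal direction ``l`` is stored; any unit vector orthogonal to ``l``
serves as the transverse direction.

All indices are 0-based internally and in the text files written here
(a ``one_based`` flag on the readers/writers handles 1-based dialects).
Units: coordinates mm, times ms; 1 m/s == 1 mm/ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

__all__ = [
    "HEALTHY",
    "BZ",
    "SCAR",
    "TetMesh",
    "NodeField",
    "ElementSet",
    "read_mesh",
    "write_mesh",
    "read_node_field",
    "write_node_field",
    "build_edge_graph",
]

#: Region tags (per element).
HEALTHY = 1
BZ = 2
SCAR = 3

_FIBER_TOL = 1e-6

# local vertex pairs forming the 6 edges of a tetrahedron
TET_EDGES = np.array([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
# local vertex triples forming the 4 faces of a tetrahedron
TET_FACES = np.array([(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)])


class MeshFormatError(ValueError):
    """Raised for malformed mesh files (bad counts, headers or element types)."""


@dataclass
class TetMesh:
    """Labelled tetrahedral volume mesh with per-element fibers.

    Parameters
    ----------
    points : (n, 3) float array
        Node coordinates in mm.
    tets : (m, 4) int array
        Node indices of each tetrahedron.
    fibers : (m, 3) float array
        Unit longitudinal fiber direction per element.
    labels : (m,) int array
        Region tag per element (HEALTHY, BZ or SCAR).
    """

    points: np.ndarray
    tets: np.ndarray
    fibers: np.ndarray
    labels: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.fibers = np.ascontiguousarray(self.fibers, dtype=np.float64)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self):
        n = self.n_points
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise MeshFormatError("points must be (n, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshFormatError("tets must be (m, 4)")
        if len(self.fibers) != self.n_tets or len(self.labels) != self.n_tets:
            raise MeshFormatError(
                f"fiber/label count ({len(self.fibers)}/{len(self.labels)}) "
                f"does not match element count ({self.n_tets})"
            )
        if self.n_tets and (self.tets.min() < 0 or self.tets.max() >= n):
            bad = int(np.abs(self.tets).max())
            raise IndexError(f"tet node index {bad} out of range for {n} points")
        norms = np.linalg.norm(self.fibers, axis=1)
        if self.n_tets and np.any(np.abs(norms - 1.0) > 1e-4):
            # tolerate text-file rounding; renormalize, reject degenerate
            if np.any(norms < _FIBER_TOL):
                raise ValueError("zero-length fiber vector")
            self.fibers = self.fibers / norms[:, None]
        self._fix_orientation()

    def _fix_orientation(self):
        """Swap two nodes of any negatively oriented tet; reject degenerate."""
        if not self.n_tets:
            return
        vol = self.signed_volumes()
        if np.any(vol == 0.0):
            raise MeshFormatError("degenerate (zero-volume) tetrahedron")
        neg = vol < 0
        if np.any(neg):
            t = self.tets.copy()
            t[neg, 0], t[neg, 1] = self.tets[neg, 1], self.tets[neg, 0]
            self.tets = t

    # -- basic properties ---------------------------------------------------

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def signed_volumes(self) -> np.ndarray:
        p = self.points[self.tets]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def centroids(self) -> np.ndarray:
        return self.points[self.tets].mean(axis=1)

    # -- derived connectivity (cached) --------------------------------------

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) sorted unique node pairs; every tet contributes its 6 edges."""
        if "edges" not in self._cache:
            pairs = self.tets[:, TET_EDGES].reshape(-1, 2)
            pairs = np.sort(pairs, axis=1)
            self._cache["edges"] = np.unique(pairs, axis=0)
        return self._cache["edges"]

    @property
    def edge_lengths(self) -> np.ndarray:
        if "edge_lengths" not in self._cache:
            e = self.edges
            self._cache["edge_lengths"] = np.linalg.norm(
                self.points[e[:, 1]] - self.points[e[:, 0]], axis=1
            )
        return self._cache["edge_lengths"]

    def adjacency(self, edges: np.ndarray | None = None) -> sparse.csr_matrix:
        """Symmetric node adjacency with Euclidean edge lengths as weights."""
        if edges is None:
            if "adjacency" in self._cache:
                return self._cache["adjacency"]
            edges = self.edges
            lengths = self.edge_lengths
        else:
            lengths = np.linalg.norm(
                self.points[edges[:, 1]] - self.points[edges[:, 0]], axis=1
            )
        n = self.n_points
        a = sparse.coo_matrix(
            (
                np.concatenate([lengths, lengths]),
                (
                    np.concatenate([edges[:, 0], edges[:, 1]]),
                    np.concatenate([edges[:, 1], edges[:, 0]]),
                ),
            ),
            shape=(n, n),
        ).tocsr()
        if edges is self.edges:
            self._cache["adjacency"] = a
        return a

    @property
    def node_tets(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (indptr, tet_indices) of elements incident to each node."""
        if "node_tets" not in self._cache:
            nodes = self.tets.ravel()
            tet_ids = np.repeat(np.arange(self.n_tets), 4)
            order = np.argsort(nodes, kind="stable")
            counts = np.bincount(nodes, minlength=self.n_points)
            indptr = np.concatenate([[0], np.cumsum(counts)])
            self._cache["node_tets"] = (indptr.astype(np.int64), tet_ids[order])
        return self._cache["node_tets"]

    def face_adjacency(self) -> sparse.csr_matrix:
        """Element adjacency across shared triangular faces."""
        if "face_adjacency" not in self._cache:
            faces = np.sort(self.tets[:, TET_FACES].reshape(-1, 3), axis=1)
            tet_ids = np.repeat(np.arange(self.n_tets), 4)
            order = np.lexsort(faces.T)
            faces, tet_ids = faces[order], tet_ids[order]
            same = np.all(faces[1:] == faces[:-1], axis=1)
            i, j = tet_ids[:-1][same], tet_ids[1:][same]
            m = self.n_tets
            a = sparse.coo_matrix(
                (np.ones(2 * len(i)), (np.concatenate([i, j]), np.concatenate([j, i]))),
                shape=(m, m),
            ).tocsr()
            self._cache["face_adjacency"] = a
        return self._cache["face_adjacency"]

    # -- conduction helpers --------------------------------------------------

    def conducting_elements(self, excluded: np.ndarray | None = None) -> np.ndarray:
        """Boolean mask of elements that conduct (not scar, not excluded)."""
        mask = self.labels != SCAR
        if excluded is not None and len(excluded):
            mask = mask.copy()
            mask[np.asarray(excluded, dtype=np.int64)] = False
        return mask

    def conducting_nodes(self, excluded: np.ndarray | None = None) -> np.ndarray:
        """Nodes incident to at least one conducting element.

        A node is "scar-only" iff all incident elements are SCAR; such nodes
        are not part of the solve domain.
        """
        mask = np.zeros(self.n_points, dtype=bool)
        cond = self.conducting_elements(excluded)
        mask[self.tets[cond].ravel()] = True
        return mask

    def conducting_edges(self, excluded: np.ndarray | None = None) -> np.ndarray:
        """Unique edges contributed by conducting elements only."""
        cond = self.conducting_elements(excluded)
        pairs = self.tets[cond][:, TET_EDGES].reshape(-1, 2)
        if not len(pairs):
            return np.empty((0, 2), dtype=np.int64)
        return np.unique(np.sort(pairs, axis=1), axis=0)

    def relabel(self, element_ids: np.ndarray, label: int) -> "TetMesh":
        """Return a copy with the given elements assigned a new region tag."""
        element_ids = np.asarray(element_ids, dtype=np.int64)
        if len(element_ids) and (
            element_ids.min() < 0 or element_ids.max() >= self.n_tets
        ):
            raise IndexError("element index out of range")
        labels = self.labels.copy()
        labels[element_ids] = label
        return TetMesh(self.points, self.tets, self.fibers, labels)


@dataclass
class NodeField:
    """Per-node scalar carrier (activation times in ms or distances in mm).

    Undefined entries (e.g. scar-only nodes) hold ``+inf``; ``mask`` reads
    True where the value is defined.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ElementSet:
    """A tagged set of element indices (scar, ablation lesion, insulated...)."""

    indices: np.ndarray
    tag: str = ""

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        if len(idx) and idx.min() < 0:
            raise IndexError("negative element index")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# CARP plain-text I/O
# ---------------------------------------------------------------------------


def _read_count_header(line: str, path, what: str) -> int:
    try:
        return int(line.split()[0])
    except (ValueError, IndexError):
        raise MeshFormatError(f"{path}: line 1: expected {what} count header")


def read_mesh(
    points_path,
    elements_path,
    fibers_path=None,
    labels_path=None,
    one_based: bool = False,
) -> TetMesh:
    """Read a CARP plain-text mesh (.pts/.elem/.lon [+ per-element labels]).

    The region tag is taken from the 6th column of the ``.elem`` file unless a
    separate one-tag-per-line ``labels_path`` is given. Missing fibers default
    to (1, 0, 0).
    """
    points_path, elements_path = Path(points_path), Path(elements_path)
    with open(points_path) as f:
        lines = f.read().split("\n")
    n = _read_count_header(lines[0], points_path, "point")
    try:
        pts = np.array(
            [[float(v) for v in lines[1 + i].split()[:3]] for i in range(n)]
        )
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"{points_path}: malformed point record: {exc}")

    with open(elements_path) as f:
        lines = f.read().split("\n")
    m = _read_count_header(lines[0], elements_path, "element")
    tets = np.empty((m, 4), dtype=np.int64)
    tags = np.full(m, HEALTHY, dtype=np.int64)
    for i in range(m):
        parts = lines[1 + i].split()
        if not parts:
            raise MeshFormatError(f"{elements_path}: line {i + 2}: empty record")
        if parts[0] != "Tt":
            raise MeshFormatError(
                f"{elements_path}: line {i + 2}: unsupported element type "
                f"'{parts[0]}' (only tetrahedra 'Tt' are supported)"
            )
        try:
            tets[i] = [int(v) for v in parts[1:5]]
        except ValueError as exc:
            raise MeshFormatError(f"{elements_path}: line {i + 2}: {exc}")
        if len(parts) > 5:
            tags[i] = int(parts[5])
    if one_based:
        tets -= 1

    if fibers_path is not None:
        fibers = np.loadtxt(fibers_path, ndmin=2)
        if fibers.shape != (m, 3):
            raise MeshFormatError(
                f"{fibers_path}: expected {m} fiber vectors, got {fibers.shape}"
            )
    else:
        fibers = np.tile([1.0, 0.0, 0.0], (m, 1))

    if labels_path is not None:
        tags = np.loadtxt(labels_path, dtype=np.int64, ndmin=1)
        if len(tags) != m:
            raise MeshFormatError(
                f"{labels_path}: expected {m} labels, got {len(tags)}"
            )
    return TetMesh(pts, tets, fibers, tags)


def write_mesh(mesh: TetMesh, basename, one_based: bool = False) -> None:
    """Write .pts/.elem/.lon files with ``basename`` as path prefix.

    Floats carry 9+ significant digits so a read/write round trip is lossless
    at that precision.
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    with open(base.with_suffix(".pts"), "w") as f:
        f.write(f"{mesh.n_points}\n")
        for x, y, z in mesh.points:
            f.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
    off = 1 if one_based else 0
    with open(base.with_suffix(".elem"), "w") as f:
        f.write(f"{mesh.n_tets}\n")
        for (a, b, c, d), tag in zip(mesh.tets, mesh.labels):
            f.write(f"Tt {a + off} {b + off} {c + off} {d + off} {tag}\n")
    with open(base.with_suffix(".lon"), "w") as f:
        for x, y, z in mesh.fibers:
            f.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


_DAT_SENTINEL = -1.0


def write_node_field(fieldv, path, sentinel: float = _DAT_SENTINEL) -> None:
    """Write a per-node scalar as a .dat file, one value per line.

    ``+inf`` (undefined) entries are written as the sentinel value, flagged in
    a leading comment header.
    """
    values = fieldv.values if isinstance(fieldv, NodeField) else np.asarray(fieldv)
    with open(path, "w") as f:
        f.write(f"# vita-dat n={len(values)} inf_sentinel={sentinel:g}\n")
        for v in values:
            if np.isfinite(v):
                f.write(f"{float(v)}\n")
            else:
                f.write(f"{sentinel:g}\n")


def read_node_field(path) -> NodeField:
    """Read a .dat written by :func:`write_node_field`; sentinel -> +inf."""
    sentinel = _DAT_SENTINEL
    values = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for part in line.split():
                    if part.startswith("inf_sentinel="):
                        sentinel = float(part.split("=", 1)[1])
                continue
            values.append(float(line))
    values = np.array(values)
    values[values == sentinel] = np.inf
    return NodeField(values)


def build_edge_graph(mesh: TetMesh) -> sparse.csr_matrix:
    """Undirected node adjacency with edge lengths (mm) as weights."""
    return mesh.adjacency()


def element_components(mesh: TetMesh, element_mask: np.ndarray) -> tuple[int, np.ndarray]:
    """Connected components of the selected elements under face adjacency.

    Returns ``(n_components, labels)`` where ``labels[i]`` is the component id
    of element ``i`` (-1 outside the mask). Used as the flood-fill primitive
    for corridor counting and post-ablation checks.
    """
    adj = mesh.face_adjacency()
    sel = np.where(element_mask)[0]
    if not len(sel):
        return 0, np.full(mesh.n_tets, -1, dtype=np.int64)
    sub = adj[sel][:, sel]
    ncomp, lab = connected_components(sub, directed=False)
    out = np.full(mesh.n_tets, -1, dtype=np.int64)
    out[sel] = lab
    return ncomp, out
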