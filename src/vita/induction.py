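"""Reentry induction by unidirectional block at an exit site.

A temporary conduction block is imposed across the exit-site isosurface by
decoupling the tissue the surface cuts: every tetrahedron containing a
straddling support pair of the surface is excluded from the solve domain (no
flux can cross the surface). Activation is then initiated at t0 = 0 ms on
one face of the block; if a reentrant path exists, the wavefront travels the
full circuit and re-arrives at the opposite face. The earliest such arrival
is the round-trip time (RTT), the vulnerability metric: circuits with RTT
below a threshold (default 50 ms) are considered too short to sustain
ventricular tachycardia and are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .eikonal import (
    ActivationField,
    SourceSet,
    VelocityModel,
    build_velocity_tensors,
    solve_activation,
)
from .isthmus import ExitSite
from .mesh import TetMesh

__all__ = [
    "InsulatedMesh",
    "VTCircuit",
    "insulate",
    "induce",
    "filter_sustained",
]

DEFAULT_RTT_MIN = 50.0  # ms


@dataclass
class InsulatedMesh:
    """A mesh with a temporary block across an exit-site surface.

    ``cut_elements`` are the tets the surface passes through (excluded from
    the solve); ``removed_edges`` are the straddling node pairs themselves.
    With the default orientation the distal face is stimulated and the
    proximal face is where the returning wavefront is measured; ``flipped``
    swaps the two, yielding the opposite-chirality circuit.
    """

    mesh: TetMesh
    exit_id: int
    removed_edges: np.ndarray  # (K, 2) [proximal, distal]
    cut_elements: np.ndarray
    stimulated_nodes: np.ndarray
    measurement_nodes: np.ndarray
    flipped: bool = False
    extra_excluded: np.ndarray = dc_field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    @property
    def excluded_elements(self) -> np.ndarray:
        return np.union1d(self.cut_elements, self.extra_excluded)


@dataclass
class VTCircuit:
    """An induced reentrant circuit: activation map and round-trip time."""

    exit_id: int
    at_map: ActivationField
    rtt: float
    #: globally unique id assigned when circuits from several pacing sites
    #: are pooled (exit ids are only unique within one distance field)
    circuit_id: int = -1
    chirality: str = "forward"  # which face was stimulated
    pacing_site: int | None = None
    exit_site: ExitSite | None = None
    cut_elements: np.ndarray | None = None
    #: nodes on either face of the block; their phase (0 vs one full cycle)
    #: is an artifact of where the block was imposed, not of the circuit
    block_nodes: np.ndarray | None = None

    @property
    def inducible(self) -> bool:
        return np.isfinite(self.rtt)


def _cut_elements_of(mesh: TetMesh, support: np.ndarray) -> np.ndarray:
    """Elements containing at least one straddling support pair."""
    n = mesh.n_points
    pair_keys = set(
        (np.minimum(support[:, 0], support[:, 1]) * n
         + np.maximum(support[:, 0], support[:, 1])).tolist()
    )
    nt_ptr, nt_idx = mesh.node_tets
    cand_tets = np.unique(
        np.concatenate(
            [nt_idx[nt_ptr[v]:nt_ptr[v + 1]] for v in np.unique(support[:, 0])]
        )
    )
    cut = []
    tets = mesh.tets
    from .mesh import TET_EDGES

    for e in cand_tets:
        tn = tets[e]
        for i, j in TET_EDGES:
            a, b = tn[i], tn[j]
            key = min(a, b) * n + max(a, b)
            if key in pair_keys:
                cut.append(e)
                break
    return np.asarray(cut, dtype=np.int64)


def insulate(
    mesh: TetMesh,
    exit_site: ExitSite,
    flip: bool = False,
    extra_excluded: np.ndarray | None = None,
) -> InsulatedMesh:
    """Impose a temporary block across an exit-site surface.

    Raises a degenerate-surface error if, after the cut, either face of the
    block has no node left in the conducting domain.
    """
    support = exit_site.fragment.support
    if not len(support):
        raise ValueError("exit surface has empty support (degenerate)")
    cut = _cut_elements_of(mesh, support)
    extra = (
        np.asarray(extra_excluded, dtype=np.int64)
        if extra_excluded is not None
        else np.empty(0, dtype=np.int64)
    )
    excluded = np.union1d(cut, extra)
    conducting = mesh.conducting_nodes(excluded)
    distal = exit_site.distal_nodes[conducting[exit_site.distal_nodes]]
    proximal = exit_site.proximal_nodes[conducting[exit_site.proximal_nodes]]
    stim, meas = (proximal, distal) if flip else (distal, proximal)
    if not len(stim) or not len(meas):
        raise ValueError(
            "degenerate surface: one side of the block has no conducting node"
        )
    return InsulatedMesh(
        mesh=mesh,
        exit_id=exit_site.id,
        removed_edges=support,
        cut_elements=cut,
        stimulated_nodes=stim,
        measurement_nodes=meas,
        flipped=flip,
        extra_excluded=extra,
    )


def induce(
    insulated: InsulatedMesh,
    velocity_model: VelocityModel | None = None,
    tensors: np.ndarray | None = None,
) -> VTCircuit:
    """Simulate the would-be reentry and measure the round-trip time.

    Sources are the stimulated face at t0 = 0; RTT is the minimum arrival
    over the measurement face (+inf when no return path exists, in which
    case the circuit is marked non-inducible).
    """
    mesh = insulated.mesh
    if tensors is None:
        tensors = build_velocity_tensors(mesh, velocity_model or VelocityModel())
    at = solve_activation(
        mesh,
        tensors,
        SourceSet(insulated.stimulated_nodes),
        excluded_elements=insulated.excluded_elements,
    )
    arrivals = at.values[insulated.measurement_nodes]
    rtt = float(np.min(arrivals)) if np.any(np.isfinite(arrivals)) else np.inf
    return VTCircuit(
        exit_id=insulated.exit_id,
        at_map=at,
        rtt=rtt,
        chirality="reverse" if insulated.flipped else "forward",
        cut_elements=insulated.cut_elements,
        block_nodes=np.union1d(
            insulated.stimulated_nodes, insulated.measurement_nodes
        ),
    )


def filter_sustained(circuits, rtt_min: float = DEFAULT_RTT_MIN):
    """Keep circuits with finite RTT >= rtt_min (order preserved)."""
    if rtt_min < 0:
        raise ValueError("rtt_min must be >= 0")
    return [c for c in circuits if np.isfinite(c.rtt) and c.rtt >= rtt_min]
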