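"""Unidirectional block, reentry induction and the RTT filter."""

from collections import deque

import numpy as np
import pytest
from scipy.sparse.csgraph import dijkstra

import vita
from vita.induction import VTCircuit, filter_sustained, induce, insulate
from vita.isthmus import ExitSite, SurfaceFragment

from conftest import ISO_HALF, make_ring_exit


@pytest.fixture(scope="module")
def ring_block(ring_mesh):
    site = make_ring_exit(ring_mesh)
    return site, insulate(ring_mesh, site)


def graph_hops(mesh, removed_pairs, start_nodes, target_nodes, max_hops):
    """BFS hop count from start to target avoiding removed edges."""
    removed = {tuple(sorted(p)) for p in removed_pairs}
    e = mesh.conducting_edges()
    adj = {}
    for a, b in e:
        if tuple(sorted((a, b))) in removed:
            continue
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    targets = set(int(t) for t in target_nodes)
    seen = set(int(s) for s in start_nodes)
    frontier = list(seen)
    for hop in range(1, max_hops + 1):
        nxt = []
        for v in frontier:
            for nb in adj.get(v, ()):
                if nb in targets:
                    return hop
                if nb not in seen:
                    seen.add(nb)
                    nxt.append(nb)
        frontier = nxt
        if not frontier:
            break
    return None


def test_block_severs_local_path(ring_mesh, ring_block):
    """Flood fill from the stimulated face reaches the measurement face only
    the long way around the ring, never in a few hops across the cut."""
    site, ins = ring_block
    hops = graph_hops(
        ring_mesh, ins.removed_edges, ins.stimulated_nodes,
        ins.measurement_nodes, max_hops=10,
    )
    assert hops is None
    # without the cut the two faces are adjacent
    hops_open = graph_hops(
        ring_mesh, [], ins.stimulated_nodes, ins.measurement_nodes, max_hops=3
    )
    assert hops_open is not None


def test_full_cut_splits_scar_free_slab():
    m = vita.make_slab((20, 6, 3), 1.0)
    e = m.conducting_edges()
    pa, pb = m.points[e[:, 0]], m.points[e[:, 1]]
    crosses = (pa[:, 0] < 10.0) != (pb[:, 0] < 10.0)
    sup = e[crosses].copy()
    swap = pa[crosses][:, 0] >= 10.0
    sup[swap] = sup[swap][:, ::-1]
    site = ExitSite(SurfaceFragment(0, 0.0, np.zeros((1, 3, 3)), 1.0, sup))
    ins = insulate(m, site)
    circ = induce(ins, velocity_model=ISO_HALF)
    assert np.isinf(circ.rtt)  # no way around a full transmural cut
    assert not circ.inducible


def test_empty_support_rejected(ring_mesh):
    frag = SurfaceFragment(0, 0.0, np.zeros((1, 3, 3)), 1.0,
                           np.empty((0, 2), dtype=int))
    with pytest.raises(ValueError, match="empty support|degenerate"):
        insulate(ring_mesh, ExitSite(frag))


def test_ring_rtt_matches_dijkstra_loop(ring_mesh, ring_block):
    site, ins = ring_block
    circ = induce(ins, velocity_model=ISO_HALF)
    # oracle: shortest loop over the edge graph with the cut edges removed
    e = ring_mesh.conducting_edges()
    removed = {tuple(sorted(p)) for p in ins.removed_edges}
    keep = np.array([tuple(sorted(p)) not in removed for p in e])
    g = ring_mesh.adjacency(e[keep])
    d = dijkstra(g, indices=ins.stimulated_nodes, min_only=True)
    loop_time = np.min(d[ins.measurement_nodes]) / 0.5
    assert circ.rtt == pytest.approx(loop_time, rel=0.05)
    # the loop is the ring circumference: between inner and outer bounds
    assert 2 * np.pi * 9.0 / 0.5 * 0.95 < circ.rtt < 2 * np.pi * 11.0 / 0.5


def test_swapped_faces_give_same_rtt(ring_mesh, ring_block):
    site, _ = ring_block
    fwd = induce(insulate(ring_mesh, site), velocity_model=ISO_HALF)
    rev = induce(insulate(ring_mesh, site, flip=True), velocity_model=ISO_HALF)
    assert rev.chirality == "reverse"
    assert fwd.rtt == pytest.approx(rev.rtt, rel=0.02)


def test_rtt_scales_inversely_with_velocity(ring_mesh, ring_block):
    site, ins = ring_block
    c1 = induce(ins, velocity_model=ISO_HALF)
    c2 = induce(ins, velocity_model=ISO_HALF.scaled(2.0))
    assert c1.rtt == 2.0 * c2.rtt


def test_slower_tissue_never_shortens_rtt(ring_mesh, ring_block):
    site, ins = ring_block
    base = induce(ins, velocity_model=ISO_HALF)
    slow = induce(ins, velocity_model=ISO_HALF.scaled(0.8))
    assert slow.rtt >= base.rtt


def _circ(rtt, exit_id=0):
    return VTCircuit(exit_id=exit_id, at_map=vita.ActivationField([0.0]), rtt=rtt)


def test_filter_sustained_semantics():
    circuits = [_circ(125.7), _circ(40.0), _circ(np.inf)]
    kept = filter_sustained(circuits, 50.0)
    assert [c.rtt for c in kept] == [125.7]
    assert [c.rtt for c in filter_sustained(circuits, 0.0)] == [125.7, 40.0]


def test_raising_rtt_min_gives_subset(slab1ch_report):
    base = filter_sustained(slab1ch_report.circuits, 50.0)
    strict = filter_sustained(slab1ch_report.circuits, 200.0)
    assert set(id(c) for c in strict) <= set(id(c) for c in base)


def test_no_bypass_means_no_reentry():
    """Scar spanning the full cross-section: block is never reentrant."""
    m = vita.make_slab((40, 10, 5), 1.0)
    spec = vita.ScarSpec(
        vita.Box((15.0, 0.0, 0.0), (25.0, 10.0, 5.0)),
        [vita.Box((15.0, 4.5, 0.0), (25.0, 5.5, 5.0))],
    )
    scarred = vita.embed_scar(m, spec)
    # cut the channel mid-section
    e = scarred.conducting_edges()
    pa, pb = scarred.points[e[:, 0]], scarred.points[e[:, 1]]
    mid = 0.5 * (pa + pb)
    crosses = ((pa[:, 0] < 20.0) != (pb[:, 0] < 20.0)) & (mid[:, 1] > 3.5) & (
        mid[:, 1] < 6.5
    )
    sup = e[crosses].copy()
    swap = pa[crosses][:, 0] >= 20.0
    sup[swap] = sup[swap][:, ::-1]
    site = ExitSite(SurfaceFragment(0, 0.0, np.zeros((1, 3, 3)), 1.0, sup))
    circ = induce(insulate(scarred, site), velocity_model=vita.VelocityModel())
    assert np.isinf(circ.rtt)
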