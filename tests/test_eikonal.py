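"""Eikonal solver: speed recovery, closed forms, Dijkstra bounds, scaling."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

import vita
from vita.eikonal import VelocityModel


def plane_nodes(mesh, axis, value=0.0):
    return np.where(np.abs(mesh.points[:, axis] - value) < 1e-9)[0]


def fitted_speed(mesh, field, axis, lo=None, hi=None):
    x = mesh.points[:, axis]
    sel = np.isfinite(field.values)
    if lo is not None:
        sel &= (x >= lo) & (x <= hi)
    slope = np.polyfit(x[sel], field.values[sel], 1)[0]
    return 1.0 / slope


def test_velocity_tensor_values():
    m = vita.make_slab((2, 2, 2), 1.0)
    V = vita.build_velocity_tensors(m, VelocityModel())
    np.testing.assert_allclose(V[0], np.diag([0.25, 0.0256, 0.0256]), atol=1e-12)
    bz = m.relabel(np.arange(m.n_tets), vita.BZ)
    Vbz = vita.build_velocity_tensors(bz, VelocityModel())
    np.testing.assert_allclose(Vbz[0], 0.0256 * np.eye(3), atol=1e-12)
    Vunit = vita.build_velocity_tensors(m, VelocityModel(1.0, 1.0, 1.0))
    np.testing.assert_allclose(Vunit[0], np.eye(3), atol=1e-12)


def test_planar_wave_recovers_longitudinal_speed(slab_plain):
    V = vita.build_velocity_tensors(slab_plain, VelocityModel())
    ta = vita.solve_activation(
        slab_plain, V, vita.SourceSet(plane_nodes(slab_plain, 0))
    )
    assert fitted_speed(slab_plain, ta, 0) == pytest.approx(0.50, rel=0.02)


def test_planar_wave_recovers_transverse_speed(slab_plain):
    V = vita.build_velocity_tensors(slab_plain, VelocityModel())
    ta = vita.solve_activation(
        slab_plain, V, vita.SourceSet(plane_nodes(slab_plain, 1))
    )
    assert fitted_speed(slab_plain, ta, 1) == pytest.approx(0.16, rel=0.02)


def point_source_error(edge):
    """L-inf relative error vs the closed form sqrt(x^T V^-1 x).

    The source ball is initialized with the exact solution (source
    factoring) so the measured error is the bulk discretization error.
    """
    m = vita.make_slab((16, 16, 8), edge)
    V = vita.build_velocity_tensors(m, VelocityModel())
    c = np.array([8.0, 8.0, 4.0])
    Vinv = np.linalg.inv(V[0])
    d = m.points - c
    exact = np.sqrt(np.einsum("ij,jk,ik->i", d, Vinv, d))
    ball = np.where(np.linalg.norm(d, axis=1) <= 2.0)[0]
    ta = vita.solve_activation(m, V, vita.SourceSet(ball, exact[ball]))
    sel = np.ones(m.n_points, bool)
    sel[ball] = False
    rel = np.abs(ta.values - exact)[sel] / exact[sel]
    return rel.max(), ta, exact


def test_point_source_matches_closed_form_under_refinement():
    coarse, *_ = point_source_error(1.6)
    fine, *_ = point_source_error(0.8)
    assert fine < coarse  # converging
    assert fine < 0.16  # mesh-dependent tolerance at 0.8 mm


def dijkstra_oracle(mesh, tensors, src_nodes):
    """Edge-graph arrival upper bound.

    Travel time along a straight edge u through tissue with squared-velocity
    tensor V is sqrt(u^T V^-1 u); any edge path is an admissible front
    trajectory, so the shortest-path time bounds the Eikonal arrival from
    above. The fixtures used here are homogeneous (element 0's tensor
    applies everywhere).
    """
    e = mesh.conducting_edges()
    u = mesh.points[e[:, 1]] - mesh.points[e[:, 0]]
    Minv = np.linalg.inv(tensors[0])
    cost = np.sqrt(np.einsum("ij,jk,ik->i", u, Minv, u))
    n = mesh.n_points
    g = coo_matrix(
        (
            np.concatenate([cost, cost]),
            (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]])),
        ),
        shape=(n, n),
    ).tocsr()
    return dijkstra(g, indices=src_nodes, min_only=True)


def test_arrival_bounded_by_edge_graph_dijkstra():
    m = vita.make_slab((16, 16, 8), 1.0)
    V = vita.build_velocity_tensors(m, VelocityModel())
    i0 = int(np.argmin(np.linalg.norm(m.points - [8, 8, 4], axis=1)))
    ta = vita.solve_activation(m, V, vita.SourceSet([i0]))
    ub = dijkstra_oracle(m, V, [i0])
    assert np.all(ta.values <= ub + 1e-6)


def test_velocity_scaling_is_exact(slab_plain):
    src = vita.SourceSet(plane_nodes(slab_plain, 0))
    vm = VelocityModel()
    ta1 = vita.solve_activation(
        slab_plain, vita.build_velocity_tensors(slab_plain, vm), src
    )
    ta2 = vita.solve_activation(
        slab_plain, vita.build_velocity_tensors(slab_plain, vm.scaled(2.0)), src
    )
    fin = np.isfinite(ta1.values)
    np.testing.assert_array_equal(ta1.values[fin], 2.0 * ta2.values[fin])


def test_adding_a_source_never_increases_arrival(slab_plain):
    V = vita.build_velocity_tensors(slab_plain, VelocityModel())
    src1 = plane_nodes(slab_plain, 0)
    far = plane_nodes(slab_plain, 0, 40.0)
    ta1 = vita.solve_activation(slab_plain, V, vita.SourceSet(src1))
    ta2 = vita.solve_activation(
        slab_plain, V, vita.SourceSet(np.concatenate([src1, far]))
    )
    assert np.all(ta2.values <= ta1.values + 1e-9)


def test_distance_mode_on_convex_slab(slab_plain):
    """Convexity: the geodesic is the straight line. A factored source ball
    (exact distances planted within 2 mm) isolates the bulk discretization
    error, first order in the edge length."""
    i0 = int(np.argmin(np.linalg.norm(slab_plain.points - [20, 5, 2.5], axis=1)))
    eu = np.linalg.norm(slab_plain.points - slab_plain.points[i0], axis=1)
    ball = np.where(eu <= 2.0)[0]
    d = vita.solve_distance(slab_plain, vita.SourceSet(ball, eu[ball]))
    assert d.values[i0] == 0.0
    far = eu > 8.0  # away from the source ball
    assert np.all(d.values[far] >= eu[far] - 1e-9)
    assert np.max(np.abs(d.values[far] - eu[far]) / eu[far]) < 0.08


def test_distance_behind_obstacle_exceeds_euclidean(slab1ch):
    nodes = vita.resolve_pacing_site(slab1ch, (0.0, 0.0, 2.5), 2.0)
    d = vita.solve_distance(slab1ch, vita.SourceSet(nodes))
    # a probe point straight behind the scar block: geodesic must exceed the
    # Euclidean distance to the nearest source node
    probe = int(np.argmin(np.linalg.norm(slab1ch.points - [30, 3, 2.5], axis=1)))
    eu_min = np.linalg.norm(slab1ch.points[nodes] - slab1ch.points[probe],
                            axis=1).min()
    assert d.values[probe] > eu_min
    # bounded above by unit-speed edge-graph Dijkstra through conducting edges
    e = slab1ch.conducting_edges()
    L = np.linalg.norm(slab1ch.points[e[:, 1]] - slab1ch.points[e[:, 0]], axis=1)
    n = slab1ch.n_points
    g = coo_matrix(
        (
            np.concatenate([L, L]),
            (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]])),
        ),
        shape=(n, n),
    ).tocsr()
    ub = dijkstra(g, indices=nodes, min_only=True)
    fin = np.isfinite(d.values)
    assert np.all(d.values[fin] <= ub[fin] + 1e-6)


def test_scar_only_sources_rejected(slab1ch):
    scar_only = ~slab1ch.conducting_nodes()
    nodes = np.where(scar_only)[0][:3]
    assert len(nodes)
    with pytest.raises(ValueError, match="conducting"):
        vita.solve_distance(slab1ch, vita.SourceSet(nodes))


def test_pacing_ball_in_scar_rejected(slab2ch):
    with pytest.raises(ValueError, match="no conducting node"):
        vita.resolve_pacing_site(slab2ch, (20.0, 5.0, 2.5), 0.5)
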