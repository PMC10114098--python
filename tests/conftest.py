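"""Shared fixtures: synthetic substrates and (expensive) pipeline runs."""

import warnings

import numpy as np
import pytest

import vita
from vita.fixtures import SLAB_CORNER_SITES
from vita.induction import induce, insulate
from vita.isthmus import ExitSite, SurfaceFragment

warnings.filterwarnings("ignore", message="channel may pinch off")


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------


@pytest.fixture(scope="session")
def slab_plain():
    """Scar-free 40x10x5 mm slab, fibers along x, 1 mm edge."""
    return vita.make_slab((40.0, 10.0, 5.0), 1.0)


@pytest.fixture(scope="session")
def slab1ch():
    return vita.make_preset("slab1ch", edge=0.8)


@pytest.fixture(scope="session")
def slab2ch():
    return vita.make_preset("slab2ch", edge=0.8)


@pytest.fixture(scope="session")
def ring_mesh():
    return vita.make_ring(9.0, 11.0, 2.0, 0.5)


def make_ring_exit(mesh, xmin=5.0):
    """Synthetic exit site cutting the ring at the cross-section y=0, x>0.

    Stands in for a detected exit surface: its support pairs are exactly the
    conducting edges straddling the half-plane (half-open: y >= 0 is distal).
    """
    e = mesh.conducting_edges()
    pa, pb = mesh.points[e[:, 0]], mesh.points[e[:, 1]]
    neg_a, neg_b = pa[:, 1] < 0, pb[:, 1] < 0
    crosses = (neg_a != neg_b) & (np.minimum(pa[:, 0], pb[:, 0]) > xmin)
    sup = e[crosses].copy()
    swap = ~neg_a[crosses]  # proximal = y < 0 side
    sup[swap] = sup[swap][:, ::-1]
    frag = SurfaceFragment(
        id=0, level=0.0, triangles=np.zeros((1, 3, 3)), area=1.0, support=sup
    )
    return ExitSite(frag)


ISO_HALF = vita.VelocityModel(0.5, 0.5, 0.5)


@pytest.fixture(scope="session")
def ring_circuit_pair():
    """Opposite-chirality circuits on a thin ring (radial spread ~0.4 mm)."""
    m = vita.make_ring(9.8, 10.2, 0.8, 0.4)
    site = make_ring_exit(m)
    fwd = induce(insulate(m, site), velocity_model=ISO_HALF)
    rev = induce(insulate(m, site, flip=True), velocity_model=ISO_HALF)
    return m, fwd, rev


# --------------------------------------------------------------------------
# pipeline runs (shared across modules; each takes seconds to a minute)
# --------------------------------------------------------------------------


def corner_config(**kw):
    return vita.VitaConfig(pacing_sites=list(SLAB_CORNER_SITES), **kw)


@pytest.fixture(scope="session")
def slab1ch_report(slab1ch):
    return vita.run_vita(slab1ch, corner_config())


@pytest.fixture(scope="session")
def slab2ch_report_both(slab2ch):
    return vita.run_vita(slab2ch, corner_config(chirality="both"))
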