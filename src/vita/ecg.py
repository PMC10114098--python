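"""Reaction-Eikonal surrogate ECG: activation map -> Einthoven limb leads.

Eikonal arrival times carry no electrogram by themselves. The
reaction-Eikonal idea recovers one by assigning every node a stereotyped
action-potential waveform shifted by its local activation time, yielding a
time-resolved transmembrane-voltage field Vm(x, t). Far-field extracellular
potentials then follow from the infinite-homogeneous-volume-conductor
approximation: each element acts as a current dipole proportional to its
volume times the local Vm gradient,

    phi_e(e, t) = -k * sum_el  V_el * grad(Vm)_el . grad(1 / |e - c_el|),

sampled at electrode positions approximating the limb electrodes; lead
traces are the Einthoven differences I = LA - RA, II = LL - RA,
III = LL - LA (so I + III = II identically). Amplitudes are in arbitrary
units — the single scale constant k is not calibrated.

The action potential is a smooth parametric template (tanh upstroke, plateau,
sigmoidal repolarization) with the action-potential duration defaulting to
201.5 ms; no ionic model is solved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import NodeField, TetMesh

__all__ = [
    "APTemplate",
    "ElectrodeSet",
    "ECGTrace",
    "vm_from_activation",
    "recover_phi_e",
    "einthoven_leads",
    "default_electrodes",
    "simulate_vt_ecg",
]

DEFAULT_APD = 201.5  # ms


@dataclass(frozen=True)
class APTemplate:
    """Parametric action-potential waveform Vm(t) in mV.

    ``t < 0`` returns the resting potential exactly; the upstroke is a
    monotone tanh over ``upstroke_ms``; repolarization is a sigmoid centred
    at ``apd_ms`` with width ``repol_ms`` (back within 1 mV of rest by
    ``apd_ms + repol_ms``).
    """

    v_rest: float = -85.0
    v_peak: float = 30.0
    upstroke_ms: float = 1.5
    apd_ms: float = DEFAULT_APD
    repol_ms: float = 40.0

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        amp = self.v_peak - self.v_rest
        up = 0.5 * (1.0 + np.tanh((t - 0.5 * self.upstroke_ms)
                                  / (self.upstroke_ms / 6.0)))
        rep = 0.5 * (1.0 - np.tanh((t - self.apd_ms) / (self.repol_ms / 7.0)))
        v = self.v_rest + amp * up * rep
        return np.where(t < 0, self.v_rest, v)


@dataclass(frozen=True)
class ElectrodeSet:
    """Named electrode positions (mm) outside the conducting volume."""

    LA: tuple
    RA: tuple
    LL: tuple
    scale: float = 1.0  # bath-conductivity scale k (arbitrary units)

    def positions(self):
        return {
            "LA": np.asarray(self.LA, dtype=float),
            "RA": np.asarray(self.RA, dtype=float),
            "LL": np.asarray(self.LL, dtype=float),
        }


@dataclass
class ECGTrace:
    """Uniformly sampled lead traces; I + III == II by construction."""

    time_ms: np.ndarray
    leads: dict  # name -> array

    def normalized(self) -> "ECGTrace":
        peak = np.max(np.abs(self.leads["II"]))
        if peak == 0:
            return self
        return ECGTrace(self.time_ms, {k: v / peak for k, v in self.leads.items()})


def default_electrodes(mesh: TetMesh) -> ElectrodeSet:
    """Einthoven triangle vertices on a sphere of 3x the bounding-box diagonal."""
    lo, hi = mesh.points.min(axis=0), mesh.points.max(axis=0)
    center = 0.5 * (lo + hi)
    r = 3.0 * np.linalg.norm(hi - lo)
    # equilateral triangle in the x-y plane: RA upper-left, LA upper-right,
    # LL at the bottom (roughly anatomical orientation)
    angles = {"LA": np.deg2rad(30.0), "RA": np.deg2rad(150.0),
              "LL": np.deg2rad(270.0)}
    pos = {
        k: tuple(center + r * np.array([np.cos(a), np.sin(a), 0.0]))
        for k, a in angles.items()
    }
    return ElectrodeSet(**pos)


def vm_from_activation(
    at_map: NodeField | np.ndarray,
    template: APTemplate,
    time_axis: np.ndarray,
    rtt: float | None = None,
) -> np.ndarray:
    """Per-node Vm time series, (n_nodes, n_times) in mV.

    ``Vm(node, t) = template(t - ta(node))``; with ``rtt`` given, local time
    is evaluated modulo RTT (one cycle of cyclic reentry). Nodes with
    undefined activation stay at rest.
    """
    time_axis = np.asarray(time_axis, dtype=float)
    if len(time_axis) > 1 and np.any(np.diff(time_axis) <= 0):
        raise ValueError("time axis must be strictly increasing")
    at = at_map.values if isinstance(at_map, NodeField) else np.asarray(at_map)
    local = time_axis[None, :] - at[:, None]
    if rtt is not None:
        local = np.mod(local, rtt)
    vm = template(local)
    vm[~np.isfinite(at)] = template.v_rest
    return vm


def _dipole_weights(mesh: TetMesh, electrode: np.ndarray) -> np.ndarray:
    """Per-element vector w with phi_e = -k * sum grad(Vm) . w.

    w = V_el * grad(1/|e - c|) evaluated at the element centroid c, i.e.
    V_el * (e - c) / |e - c|^3.
    """
    cen = mesh.centroids()
    vol = np.abs(mesh.signed_volumes())
    d = electrode[None, :] - cen
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("electrode coincides with an element centroid")
    return vol[:, None] * d / r[:, None] ** 3


def _shape_gradients(mesh: TetMesh) -> np.ndarray:
    """(m, 4, 3) gradients of the linear nodal shape functions per tet."""
    p = mesh.points[mesh.tets]
    e = p[:, 1:] - p[:, 0:1]  # (m, 3, 3) rows are edge vectors
    einv = np.linalg.inv(e)  # columns give grads of N1..N3
    g123 = np.transpose(einv, (0, 2, 1))
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1)


def recover_phi_e(
    vm_series: np.ndarray,
    mesh: TetMesh,
    electrodes: ElectrodeSet,
    conducting_only: bool = True,
) -> dict:
    """Extracellular potential time series at each electrode (arbitrary units).

    ``vm_series`` is (n_nodes, n_times). Electrodes must lie outside the
    conducting volume (checked against the mesh bounding box).
    """
    lo, hi = mesh.points.min(axis=0), mesh.points.max(axis=0)
    for name, pos in electrodes.positions().items():
        if np.all(pos >= lo - 1e-9) and np.all(pos <= hi + 1e-9):
            raise ValueError(f"electrode {name} lies inside the tissue volume")
    sel = np.where(mesh.conducting_elements())[0] if conducting_only else \
        np.arange(mesh.n_tets)
    grads = _shape_gradients(mesh)[sel]  # (m, 4, 3)
    vm_el = vm_series[mesh.tets[sel]]  # (m, 4, nt)
    grad_vm = np.einsum("mkd,mkt->mdt", grads, vm_el)  # (m, 3, nt)
    out = {}
    k = electrodes.scale
    for name, pos in electrodes.positions().items():
        w = _dipole_weights(mesh, pos)[sel]  # (m, 3)
        out[name] = -k * np.einsum("md,mdt->t", w, grad_vm)
    return out


def einthoven_leads(phi_LA, phi_RA, phi_LL) -> dict:
    """Limb leads I = LA - RA, II = LL - RA, III = LL - LA.

    II is assembled as I + III so the Einthoven identity I + III = II holds
    exactly in floating point, not just in exact arithmetic.
    """
    phi_LA, phi_RA, phi_LL = map(np.asarray, (phi_LA, phi_RA, phi_LL))
    if not (len(phi_LA) == len(phi_RA) == len(phi_LL)):
        raise ValueError("electrode series length mismatch")
    lead_i = phi_LA - phi_RA
    lead_iii = phi_LL - phi_LA
    return {"I": lead_i, "II": lead_i + lead_iii, "III": lead_iii}


def simulate_vt_ecg(
    mesh: TetMesh,
    at_map,
    rtt: float,
    template: APTemplate | None = None,
    electrodes: ElectrodeSet | None = None,
    dt_ms: float = 1.0,
    normalize: bool = True,
) -> ECGTrace:
    """One VT cycle of Einthoven leads from an activation map."""
    template = template or APTemplate()
    electrodes = electrodes or default_electrodes(mesh)
    time_axis = np.arange(0.0, rtt, dt_ms)
    vm = vm_from_activation(at_map, template, time_axis, rtt=rtt)
    phi = recover_phi_e(vm, mesh, electrodes)
    leads = einthoven_leads(phi["LA"], phi["RA"], phi["LL"])
    trace = ECGTrace(time_axis, leads)
    return trace.normalized() if normalize else trace
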