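"""Ablation targeting: make blocks permanent until nothing is inducible.

Exit sites are visited in descending order of the round-trip time measured
during induction (longer circuits sustain clinically relevant VT more
readily). For each site a temporary block is imposed on the *current*
substrate — original scar plus lesions accumulated so far — and the exit is
stimulated. If the wavefront returns to the opposite face of the block, a
circuit still exists and the block is made permanent: the thin transmural
sheet of elements the exit surface cuts becomes a lesion. Sites whose
circuit is already interrupted by earlier lesions are skipped, keeping the
lesion set minimal in the sense that every lesion answered a demonstrated
circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .eikonal import VelocityModel, build_velocity_tensors
from .induction import induce, insulate
from .mesh import SCAR, ElementSet, TetMesh

__all__ = ["AblationPlan", "plan_ablation", "apply_ablation", "verify_noninducibility"]


@dataclass
class PlanEntry:
    exit_id: int
    decision: str  # "ablated" | "skipped"
    rtt_at_test: float
    planning_rtt: float
    circuit_id: int = -1


@dataclass
class AblationPlan:
    """Ordered ablation decisions and the cumulative lesion element set."""

    entries: list = dc_field(default_factory=list)
    lesion: ElementSet = dc_field(
        default_factory=lambda: ElementSet(np.empty(0, dtype=np.int64), "ablation lesion")
    )

    @property
    def ablated_ids(self):
        return [e.exit_id for e in self.entries if e.decision == "ablated"]


def plan_ablation(
    mesh: TetMesh,
    velocity_model: VelocityModel,
    circuits,
    rtt_min: float | None = None,
) -> AblationPlan:
    """Iterate exit sites by descending RTT, ablating while still inducible.

    ``circuits`` are induced VTCircuits carrying their exit sites. The
    arrival test is "any finite arrival at the opposite face"; passing
    ``rtt_min`` additionally requires the re-tested RTT to reach that value
    before ablating (exposed because very short circuits reflect
    non-sustained reentry). One forward pass: skipped sites are not
    re-tested after later lesions alter the substrate.
    """
    tensors = build_velocity_tensors(mesh, velocity_model)
    order = sorted(circuits, key=lambda c: (-c.rtt, c.circuit_id, c.exit_id))
    plan = AblationPlan()
    lesions = np.empty(0, dtype=np.int64)
    for circ in order:
        if circ.exit_site is None:
            raise ValueError("circuit carries no exit site")
        try:
            ins = insulate(
                mesh, circ.exit_site,
                flip=(circ.chirality == "reverse"),
                extra_excluded=lesions,
            )
        except ValueError:
            # surface fully swallowed by earlier lesions: nothing to test
            plan.entries.append(
                PlanEntry(circ.exit_id, "skipped", np.inf, circ.rtt,
                          circ.circuit_id)
            )
            continue
        test = induce(ins, tensors=tensors)
        inducible = np.isfinite(test.rtt)
        if inducible and rtt_min is not None:
            inducible = test.rtt >= rtt_min
        if inducible:
            plan.entries.append(
                PlanEntry(circ.exit_id, "ablated", test.rtt, circ.rtt,
                          circ.circuit_id)
            )
            lesions = np.union1d(lesions, ins.cut_elements)
        else:
            plan.entries.append(
                PlanEntry(circ.exit_id, "skipped", test.rtt, circ.rtt,
                          circ.circuit_id)
            )
    plan.lesion = ElementSet(lesions, "ablation lesion")
    return plan


def apply_ablation(mesh: TetMesh, plan: AblationPlan) -> TetMesh:
    """Render the plan's lesion elements non-conducting (relabel as scar)."""
    if not len(plan.lesion):
        return mesh
    return mesh.relabel(plan.lesion.indices, SCAR)


def verify_noninducibility(
    ablated_mesh: TetMesh,
    velocity_model: VelocityModel,
    pacing_sites,
    config=None,
):
    """Re-run the full pipeline on the ablated mesh; success = no sustained VT.

    Returns a report object with ``success`` and the list of surviving
    sustained circuits. ``config`` defaults to the pipeline defaults with the
    given velocities and pacing sites.
    """
    from .pipeline import VitaConfig, run_vita

    if config is None:
        config = VitaConfig(pacing_sites=list(pacing_sites), velocities=velocity_model)
    else:
        from dataclasses import replace

        config = replace(
            config, pacing_sites=list(pacing_sites), velocities=velocity_model
        )
    report = run_vita(ablated_mesh, config, plan_and_verify=False)
    surviving = report.sustained_circuits
    return VerificationReport(success=not surviving, surviving=surviving)


@dataclass
class VerificationReport:
    success: bool
    surviving: list
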