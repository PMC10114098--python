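"""Full workflow orchestration: pacing -> exits -> induction -> ablation.

For every pacing site a distance field is solved, its level sets are
extracted and split candidates linked into an isthmus graph; every exit site
is tested for reentry by temporary unidirectional block. Sustained circuits
(RTT >= rtt_min) pooled over all pacing sites are reduced to a unique-VT set
by aligned activation-map correlation; exit sites are then ablated in
descending-RTT order while inducible, and non-inducibility of the ablated
substrate is verified by a complete re-run. The whole pipeline is
deterministic: identical inputs give identical reports.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from . import __version__
from .ablation import AblationPlan, apply_ablation, plan_ablation
from .discrimination import UniqueVTSet, select_unique
from .eikonal import (
    SourceSet,
    VelocityModel,
    build_velocity_tensors,
    resolve_pacing_site,
    solve_distance,
)
from .induction import filter_sustained, induce, insulate
from .isthmus import (
    combine_micro_fragments,
    detect_exit_sites,
    extract_level_sets,
    link_isthmus_graph,
    split_fragments,
)
from .mesh import TetMesh, write_node_field

__all__ = ["PacingSite", "VitaConfig", "VitaReport", "run_vita", "multi_site_pacing"]


@dataclass(frozen=True)
class PacingSite:
    """A stimulus location: ball (center, radius) or explicit node list."""

    center: tuple | None = None
    radius: float = 2.0
    nodes: tuple | None = None
    name: str = ""

    def resolve(self, mesh: TetMesh) -> np.ndarray:
        if self.nodes is not None:
            return np.asarray(self.nodes, dtype=np.int64)
        return resolve_pacing_site(mesh, self.center, self.radius)


def _as_site(s) -> PacingSite:
    if isinstance(s, PacingSite):
        return s
    center, radius = s
    return PacingSite(center=tuple(center), radius=float(radius))


@dataclass
class VitaConfig:
    """Run configuration; defaults follow the method's standard settings."""

    d_iso: float = 1.0  # mm between isosurface levels
    rtt_min: float = 50.0  # ms, sustained-VT filter
    correlation_threshold: float = 0.8
    velocities: VelocityModel = dc_field(default_factory=VelocityModel)
    pacing_sites: list = dc_field(default_factory=list)
    chirality: str = "default"  # "default" | "both"
    out_dir: str | None = None
    seed: int | None = None  # reserved: the pipeline is deterministic

    def __post_init__(self):
        if self.d_iso <= 0 or self.rtt_min < 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.correlation_threshold <= 1):
            raise ValueError("correlation threshold must be in (0, 1]")
        if self.chirality not in ("default", "both"):
            raise ValueError("chirality policy must be 'default' or 'both'")


@dataclass
class SiteResult:
    site_index: int
    n_levels: int
    split_levels: int
    n_candidates: int
    n_exits: int
    exits: list
    distance_field: object


@dataclass
class VitaReport:
    config: VitaConfig
    site_results: list
    circuits: list  # all induced circuits (finite or not)
    sustained_circuits: list
    unique_vts: UniqueVTSet | None
    ablation_plan: AblationPlan | None
    verification_success: bool | None
    timings: dict = dc_field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "version": __version__,
            "config": {
                "d_iso": self.config.d_iso,
                "rtt_min": self.config.rtt_min,
                "correlation_threshold": self.config.correlation_threshold,
                "velocities": {
                    "vl_healthy": self.config.velocities.vl_healthy,
                    "vt_healthy": self.config.velocities.vt_healthy,
                    "v_bz": self.config.velocities.v_bz,
                },
                "chirality": self.config.chirality,
                "n_pacing_sites": len(self.config.pacing_sites),
                "seed": self.config.seed,
            },
            "per_site": [
                {
                    "site": s.site_index,
                    "levels": s.n_levels,
                    "split_levels": s.split_levels,
                    "candidates": s.n_candidates,
                    "exits": s.n_exits,
                }
                for s in self.site_results
            ],
            "induced_vts": len(self.sustained_circuits),
            "all_rtts_ms": [
                round(c.rtt, 3) for c in self.sustained_circuits
            ],
            "unique_vts": len(self.unique_vts.kept) if self.unique_vts else None,
            "ablated_sites": (
                self.ablation_plan.ablated_ids if self.ablation_plan else None
            ),
            "n_lesion_elements": (
                int(len(self.ablation_plan.lesion)) if self.ablation_plan else None
            ),
            "verification_success": self.verification_success,
            "timings_s": {k: round(v, 3) for k, v in self.timings.items()},
        }


def multi_site_pacing(mesh: TetMesh, sites, excluded_elements=None) -> list:
    """One distance field per pacing site (cached by the caller, reusable)."""
    fields = []
    for s in sites:
        site = _as_site(s)
        nodes = site.resolve(mesh)
        fields.append(
            solve_distance(mesh, SourceSet(nodes), excluded_elements)
        )
    return fields


def _detect_and_induce(mesh, config, tensors, pooled, site_results):
    """Stages distance -> splits -> exits -> induction, per pacing site."""
    sites = [_as_site(s) for s in config.pacing_sites]
    flips = (False,) if config.chirality == "default" else (False, True)
    for si, site in enumerate(sites):
        nodes = site.resolve(mesh)
        dist = solve_distance(mesh, SourceSet(nodes))
        levels = extract_level_sets(dist, mesh, config.d_iso)
        cands = combine_micro_fragments(split_fragments(levels))
        graph = link_isthmus_graph(cands, dist, mesh, config.d_iso)
        exits = detect_exit_sites(graph)
        site_results.append(
            SiteResult(
                site_index=si,
                n_levels=len(levels),
                split_levels=len([l for l in cands if cands[l]]),
                n_candidates=sum(len(v) for v in cands.values()),
                n_exits=len(exits),
                exits=exits,
                distance_field=dist,
            )
        )
        for ex in exits:
            for flip in flips:
                try:
                    ins = insulate(mesh, ex, flip=flip)
                except ValueError:
                    continue  # degenerate surface at the mesh boundary
                circ = induce(ins, tensors=tensors)
                circ.pacing_site = si
                circ.exit_site = ex
                circ.circuit_id = len(pooled)
                pooled.append(circ)


def run_vita(
    mesh: TetMesh, config: VitaConfig, plan_and_verify: bool = True
) -> VitaReport:
    """Execute the complete pipeline and return a machine-readable report."""
    if not config.pacing_sites:
        raise ValueError("config needs at least one pacing site")
    t0 = time.perf_counter()
    timings = {}
    tensors = build_velocity_tensors(mesh, config.velocities)
    site_results: list = []
    pooled: list = []
    _detect_and_induce(mesh, config, tensors, pooled, site_results)
    timings["detect_and_induce"] = time.perf_counter() - t0

    sustained = filter_sustained(pooled, config.rtt_min)
    t1 = time.perf_counter()
    unique = select_unique(sustained, config.correlation_threshold)
    timings["discriminate"] = time.perf_counter() - t1

    plan = None
    verified = None
    if plan_and_verify:
        t2 = time.perf_counter()
        plan = plan_ablation(mesh, config.velocities, sustained)
        ablated = apply_ablation(mesh, plan)
        timings["ablate"] = time.perf_counter() - t2
        t3 = time.perf_counter()
        re_report = run_vita(ablated, config, plan_and_verify=False)
        verified = len(re_report.sustained_circuits) == 0
        timings["verify"] = time.perf_counter() - t3

    report = VitaReport(
        config=config,
        site_results=site_results,
        circuits=pooled,
        sustained_circuits=sustained,
        unique_vts=unique,
        ablation_plan=plan,
        verification_success=verified,
        timings=timings,
    )
    if config.out_dir:
        _write_artifacts(report, mesh)
    return report


def _write_artifacts(report: VitaReport, mesh: TetMesh):
    from pathlib import Path

    out = Path(report.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as f:
        json.dump(report.summary(), f, indent=2)
    for i, circ in enumerate(report.sustained_circuits):
        write_node_field(circ.at_map, out / f"vt{i:03d}_at.dat")
    for s in report.site_results:
        write_node_field(s.distance_field, out / f"site{s.site_index}_dist.dat")
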