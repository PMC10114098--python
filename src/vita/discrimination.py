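"""Unique-VT discrimination by cyclically aligned activation-map correlation.

Different pacing sites (and different exit surfaces of the same channel)
often induce the same reentrant circuit. Two circuits are compared by
converting each activation map to a cyclic phase — ``(AT mod RTT)/RTT`` —
aligning the second map so both start (phase 0) at the same location, and
computing the Pearson product-moment correlation over the nodes both maps
cover. Circuits correlating above a threshold (default 0.8) are redundant;
the rest are unique. Same-path opposite-direction circuits correlate
strongly negatively and are therefore kept as distinct VTs.

QRS-complex correlation of simulated ECG leads is available as an advisory
alternative; its power to separate subtly different circuits is limited.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

from .induction import VTCircuit

__all__ = [
    "UniqueVTSet",
    "cyclic_align",
    "at_map_correlation",
    "select_unique",
    "qrs_correlation",
]

DEFAULT_THRESHOLD = 0.8
MIN_COMMON_NODES = 10


class AlignmentError(ValueError):
    """Raised when two circuits cannot be compared (overlap/variance)."""


@dataclass
class UniqueVTSet:
    """Kept circuits plus a map discarded-index -> (kept-index, correlation)."""

    kept: list
    redundant: dict = dc_field(default_factory=dict)
    threshold: float = DEFAULT_THRESHOLD


def cyclic_align(a: VTCircuit, b: VTCircuit):
    """Per-node phase arrays of both circuits on their common nodes.

    Each activation time is reduced to a phase in [0, 1) by its own circuit's
    RTT; both arrays are then shifted (mod 1) so the node where ``a``
    activates earliest has phase 0 in both.
    """
    if not (np.isfinite(a.rtt) and np.isfinite(b.rtt)):
        raise AlignmentError("both circuits need a finite RTT")
    common = a.at_map.mask & b.at_map.mask
    # at the line of block the induced AT jumps from 0 to one full cycle; in
    # the steady reentry it is continuous there, so those nodes' phase is an
    # artifact of where the block was placed and they are left out
    for c in (a, b):
        if c.block_nodes is not None:
            common[c.block_nodes] = False
    idx = np.where(common)[0]
    if len(idx) < MIN_COMMON_NODES:
        raise AlignmentError(
            f"only {len(idx)} common finite-AT nodes (< {MIN_COMMON_NODES})"
        )
    pa = np.mod(a.at_map.values[idx], a.rtt) / a.rtt
    pb = np.mod(b.at_map.values[idx], b.rtt) / b.rtt
    anchor = int(np.argmin(a.at_map.values[idx]))  # ties -> lowest node index
    pa = np.mod(pa - pa[anchor], 1.0)
    pb = np.mod(pb - pb[anchor], 1.0)
    return pa, pb


def at_map_correlation(a: VTCircuit, b: VTCircuit) -> float:
    """Pearson correlation of the cyclically aligned phase maps."""
    pa, pb = cyclic_align(a, b)
    if np.std(pa) < 1e-12 or np.std(pb) < 1e-12:
        raise AlignmentError("zero variance in a phase array")
    r = stats.pearsonr(pa, pb).statistic
    return float(r)


def select_unique(circuits, threshold: float = DEFAULT_THRESHOLD) -> UniqueVTSet:
    """Greedy uniqueness filter in descending-RTT order.

    A circuit is kept iff its correlation with every already-kept circuit is
    <= threshold; otherwise it is recorded as redundant to the kept circuit
    it correlates with most. Incomparable pairs (alignment errors) are
    treated as non-redundant.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(
        range(len(circuits)),
        key=lambda i: (-circuits[i].rtt, circuits[i].circuit_id,
                       circuits[i].exit_id),
    )
    kept, kept_idx = [], []
    redundant = {}
    for i in order:
        best_r, best_j = -np.inf, None
        for j, kc in zip(kept_idx, kept):
            try:
                r = at_map_correlation(circuits[i], kc)
            except AlignmentError:
                continue
            if r > best_r:
                best_r, best_j = r, j
        if best_j is not None and best_r > threshold:
            redundant[i] = (best_j, best_r)
        else:
            kept.append(circuits[i])
            kept_idx.append(i)
    return UniqueVTSet(kept=kept, redundant=redundant, threshold=threshold)


def qrs_correlation(trace_a: np.ndarray, trace_b: np.ndarray) -> float:
    """Mean per-lead Pearson correlation of two equal-length lead traces.

    Traces are (n_leads, n_samples) (a single lead may be 1-D). Advisory
    only — activation-map correlation is the primary discriminator.
    """
    ta, tb = np.atleast_2d(trace_a), np.atleast_2d(trace_b)
    if ta.shape != tb.shape:
        raise ValueError(f"trace shape mismatch: {ta.shape} vs {tb.shape}")
    rs = [stats.pearsonr(x, y).statistic for x, y in zip(ta, tb)]
    return float(np.mean(rs))
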