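"""Scoring an inference against the expert electrodes of interest (EOI).

An inference is *successful* when strictly more than 50% of the inferred
nodes fall inside the protected set — the EOI together with the grid nodes
strictly adjacent to it (8-neighbourhood by default).  The false-positive
detection rate V_p divides the inferred nodes outside the protected set by
the number of grid nodes outside it.  Both depend only on set memberships,
never on score magnitudes.

This module also hosts the baseline ranker used for comparisons: net-flow
(outgoing minus incoming total weight).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recordings import GridLayout

__all__ = [
    "EvaluationResult",
    "adjacent_set",
    "success",
    "false_positive_rate",
    "evaluate",
    "netflow_scores",
    "cohort_summary",
]


@dataclass
class EvaluationResult:
    success: bool
    vp: float
    protected_set: set[str]
    inferred: set[str]


def _check_labels(grid: GridLayout, labels, what: str) -> set[str]:
    labels = set(labels)
    unknown = labels - set(grid.labels)
    if unknown:
        raise ValueError(f"unknown {what} label(s): {sorted(unknown)}")
    return labels


def adjacent_set(grid: GridLayout, eoi, connectivity: int = 8) -> set[str]:
    """Grid nodes strictly adjacent to the EOI, excluding the EOI itself."""
    eoi = _check_labels(grid, eoi, "EOI")
    if not eoi:
        raise ValueError("EOI set is empty")
    if connectivity == 8:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    elif connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    out: set[str] = set()
    for lab in eoi:
        r, c = grid.position_of(lab)
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.n_rows and 0 <= cc < grid.n_cols:
                out.add(grid.label_of(rr, cc))
    return out - eoi


def _protected(grid: GridLayout, eoi, connectivity: int) -> set[str]:
    eoi = _check_labels(grid, eoi, "EOI")
    return eoi | adjacent_set(grid, eoi, connectivity)


def success(inferred, eoi, grid: GridLayout, connectivity: int = 8) -> bool:
    """True iff strictly more than half the inferred nodes are protected.

    An exactly-50% overlap is *not* successful, and an empty inference is
    never successful.
    """
    inferred = _check_labels(grid, inferred, "inferred")
    if not inferred:
        return False
    protected = _protected(grid, eoi, connectivity)
    return len(inferred & protected) / len(inferred) > 0.5


def false_positive_rate(inferred, eoi, grid: GridLayout, connectivity: int = 8) -> float:
    """V_p = |inferred \\ protected| / |grid \\ protected|."""
    inferred = _check_labels(grid, inferred, "inferred")
    protected = _protected(grid, eoi, connectivity)
    denom = grid.n_nodes - len(protected)
    if denom == 0:
        raise ValueError("protected set covers the whole grid; V_p undefined")
    return len(inferred - protected) / denom


def evaluate(inferred, eoi, grid: GridLayout, connectivity: int = 8) -> EvaluationResult:
    inferred = _check_labels(grid, inferred, "inferred")
    return EvaluationResult(
        success=success(inferred, eoi, grid, connectivity),
        vp=false_positive_rate(inferred, eoi, grid, connectivity),
        protected_set=_protected(grid, eoi, connectivity),
        inferred=inferred,
    )


def netflow_scores(g: np.ndarray) -> np.ndarray:
    """Baseline ranking: total outgoing weight minus total incoming weight."""
    g = np.asarray(g, dtype=float)
    return g.sum(axis=1) - g.sum(axis=0)


def cohort_summary(results: list[EvaluationResult]) -> tuple[float, float]:
    """(success rate, mean V_p) over a cohort of per-patient evaluations."""
    if not results:
        raise ValueError("empty cohort")
    rate = sum(r.success for r in results) / len(results)
    mean_vp = float(np.mean([r.vp for r in results]))
    return rate, mean_vp
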