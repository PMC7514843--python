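"""Shared test utilities: independent oracles and tiny dataset builders."""

import numpy as np
import pandas as pd

from irnv.criteria import ProbabilityIntervals, _plogp
from irnv.schema import AccidentDataset, CategoricalVariableSpec


def tiny_dataset(columns: dict, severity: list, weights=None) -> AccidentDataset:
    """Build a small AccidentDataset from literal columns (None = missing)."""
    variables = [
        CategoricalVariableSpec(
            name=k,
            values=tuple(sorted({int(v) for v in col if v is not None})) or (0,),
            missing_allowed=True,
        )
        for k, col in columns.items()
    ]
    frame = pd.DataFrame({k: pd.array(v, dtype="Int64") for k, v in columns.items()})
    return AccidentDataset(
        variables=variables,
        frame=frame,
        severity=np.asarray(severity),
        weights=np.ones(len(severity)) if weights is None else np.asarray(weights, float),
    )


def random_interval_system(rng, k: int, max_width: float = 0.3):
    """A random non-empty probability-interval system around a Dirichlet draw.

    Returns the system and the (feasible) generating distribution.
    """
    p0 = rng.dirichlet(np.ones(k))
    widths = rng.uniform(0.0, max_width, size=k)
    lower = np.maximum(0.0, p0 - widths)
    upper = np.minimum(1.0, p0 + widths)
    return ProbabilityIntervals(tuple(lower), tuple(upper)), p0


def bruteforce_max_entropy(
    intervals: ProbabilityIntervals,
    feasible_start,
    grid: int = 11,
    max_iters: int = 200,
    min_width: float = 1e-9,
) -> float:
    """Maximum entropy over a credal set by grid-based pattern search.

    Pure search (no optimality conditions): the first k-1 coordinates are
    enumerated on a window around the best feasible point found so far,
    the last coordinate is the simplex remainder.  On improvement the
    window recenters at the same scale (so the search can travel along
    thin feasible slabs); on a stall it shrinks.  Entropy is concave and
    the feasible set convex, so this converges to the global maximum.
    Independent of the water-filling solver it is used to check.
    """
    lo = np.asarray(intervals.lower)
    up = np.asarray(intervals.upper)
    k = len(lo)
    best = np.asarray(feasible_start, dtype=float)
    best_h = float(_plogp(best).sum())
    width = 1.0
    for _ in range(max_iters):
        axes = [
            np.linspace(
                max(lo[j], best[j] - width), min(up[j], best[j] + width), grid
            )
            for j in range(k - 1)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        firsts = np.stack([m.ravel() for m in mesh], axis=1)
        last = 1.0 - firsts.sum(axis=1)
        ok = (last >= lo[k - 1] - 1e-12) & (last <= up[k - 1] + 1e-12)
        improved = False
        if ok.any():
            pts = np.column_stack([firsts[ok], np.clip(last[ok], 0.0, 1.0)])
            h = _plogp(pts).sum(axis=1)
            i = int(np.argmax(h))
            if h[i] > best_h + 1e-15:
                best_h = float(h[i])
                best = pts[i]
                improved = True
        if not improved:
            width /= 2.5
            if width < min_width:
                break
    return best_h
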