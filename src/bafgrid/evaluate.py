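"""Quantitative goodness-of-fit of (C, D) solutions to observations.

Formalises the visual judgement "this solution's grid sits on the
density modes": each smoothed observation is assigned its distance to
the nearest predicted grid node in normalised coordinates,

    dist = sqrt((d_obs - d_node)^2 / depth_scale^2
                + (f_obs - f_node)^2 / fraction_scale^2)

and a solution is summarised by a trimmed mean of those distances plus
the share of observations within unit distance of some node
(``fraction_explained``).  :func:`grid_search` ranks an exhaustive grid
of candidate solutions; by design near-ties are reported, not collapsed,
because purity/ploidy aliasing (notably genome-doubled solutions) is a
real identifiability limit the user must adjudicate, not an error to
hide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import DEFAULT_MAX_TOTAL_COPY, GridSolution, solution_node_arrays
from .smooth import _xy_columns


@dataclass(frozen=True)
class FitScore:
    """Summary of how well one solution explains the observations."""

    solution: GridSolution
    mean_distance: float
    fraction_explained: float
    n_observations: int


def _distances(
    depth: np.ndarray,
    fraction: np.ndarray,
    solution: GridSolution,
    max_total_copy: int,
    depth_scale: float,
    fraction_scale: float,
    fold: bool,
) -> np.ndarray:
    _, _, node_d, node_f = solution_node_arrays(solution, max_total_copy, fold)
    dd = (depth[:, None] - node_d[None, :]) / depth_scale
    df = (fraction[:, None] - node_f[None, :]) / fraction_scale
    return np.sqrt(dd * dd + df * df).min(axis=1)


def _trimmed_mean_upper(values: np.ndarray, trim: float) -> float:
    """Mean after discarding the largest `trim` share of values.

    Distances are bounded below by zero and inflated only by off-grid
    (e.g. sub-clonal) mass, so the trim is applied to the upper tail
    alone; the discarded share is still visible through
    ``fraction_explained``.
    """
    if trim <= 0:
        return float(values.mean())
    n_drop = int(np.ceil(trim * len(values)))
    if n_drop >= len(values):
        return float(values.mean())
    kept = np.sort(values)[: len(values) - n_drop]
    return float(kept.mean())


def fit_score(
    observations: pd.DataFrame,
    solution: GridSolution,
    max_total_copy: int = DEFAULT_MAX_TOTAL_COPY,
    depth_scale: float | None = None,
    fraction_scale: float = 0.05,
    trim: float = 0.05,
    fold: bool = True,
) -> FitScore:
    """Score one candidate solution against (smoothed) observations.

    ``depth_scale`` defaults to half the candidate's single-copy depth,
    putting half a copy of depth and 5 percentage points of fraction on
    an equal footing.  Invariant to observation order.
    """
    if observations.empty:
        raise ValueError("no observations to score")
    if depth_scale is None:
        depth_scale = solution.single_copy_depth / 2.0
    if depth_scale <= 0 or fraction_scale <= 0:
        raise ValueError("scales must be positive")
    depth, fraction = _xy_columns(observations)
    dists = _distances(depth, fraction, solution, max_total_copy,
                       depth_scale, fraction_scale, fold)
    return FitScore(
        solution=solution,
        mean_distance=_trimmed_mean_upper(dists, trim),
        fraction_explained=float((dists <= 1.0).mean()),
        n_observations=len(dists),
    )


def grid_search(
    observations: pd.DataFrame,
    c_grid: Sequence[float] | Iterable[float],
    d_grid: Sequence[float] | Iterable[float],
    max_total_copy: int = DEFAULT_MAX_TOTAL_COPY,
    **score_kwargs,
) -> list[FitScore]:
    """Exhaustively score every (C, D) combination, best first.

    Ranked by mean distance ascending with a deterministic tie-break on
    (lower cellularity, lower depth).  The full ranked list is returned
    so aliased near-ties remain visible.
    """
    c_values = sorted(set(float(c) for c in c_grid))
    d_values = sorted(set(float(d) for d in d_grid))
    if not c_values or not d_values:
        raise ValueError("candidate grids must be nonempty")
    scores = [
        fit_score(observations, GridSolution(c, d), max_total_copy, **score_kwargs)
        for c in c_values
        for d in d_values
    ]
    return sorted(
        scores,
        key=lambda s: (s.mean_distance,
                       s.solution.cellularity, s.solution.single_copy_depth),
    )


def scores_frame(scores: Sequence[FitScore]) -> pd.DataFrame:
    """Ranked scores as a table (for TSV export)."""
    return pd.DataFrame(
        {
            "cellularity": [s.solution.cellularity for s in scores],
            "single_copy_depth": [s.solution.single_copy_depth for s in scores],
            "mean_distance": [s.mean_distance for s in scores],
            "fraction_explained": [s.fraction_explained for s in scores],
            "n_observations": [s.n_observations for s in scores],
        }
    )


def parse_grid_spec(spec: str) -> np.ndarray:
    """Parse "start:stop:step" (inclusive of stop within half a step)."""
    parts = spec.split(":")
    if len(parts) != 3:
        raise ValueError(f"grid spec must be start:stop:step, got {spec!r}")
    start, stop, step = (float(p) for p in parts)
    if step <= 0 or stop < start:
        raise ValueError(f"bad grid spec {spec!r}")
    n = int(np.floor((stop - start) / step + 0.5)) + 1
    return start + step * np.arange(n)
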