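"""Copy-number grid predictions for tumour purity / ploidy exploration.

A tumour sample is modelled as a mixture of tumour cells (fraction ``C``,
the *cellularity*) and contaminating normal diploid cells.  For a genomic
region carrying ``n1`` copies of one parental allele and ``n2`` copies of
the other (``n2 <= n1`` by the minor-allele convention), the expected
sequencing depth is

    depth = D * (2 * (1 - C) + (n1 + n2) * C)

where ``D`` is the *single-copy depth*: the depth contributed by one
chromosomal copy present in every cell (half the depth of a diploid region
in a pure sample).  At a germline-heterozygous locus the predicted
minor-allele fraction is

    f = (1 + C * (n2 - 1)) / (2 + C * (n1 + n2 - 2))

which lies in [0, 0.5] under the minor-allele convention.

Because the minor allele is chosen *per locus after observation*, any
sampled fraction above 0.5 is reflected ("folds") below it, so the mean
recorded fraction sits below the prediction — most strongly at low depth
and near allelic balance.  :func:`folded_expected_fraction` computes the
exact folded expectation ``E[min(X, d - X)] / d`` for
``X ~ Binomial(d, f)`` by enumeration, and :func:`build_grid` assembles the
lattice of (depth, fraction) nodes that a candidate ``(C, D)`` solution
predicts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_MAX_TOTAL_COPY = 8


class DegenerateStateError(ValueError):
    """Raised for states with no defined allele fraction.

    The only such state is a homozygous deletion (n1 = n2 = 0) in a pure
    tumour (C = 1): no reads carry either allele, so the fraction is 0/0.
    """


@dataclass(frozen=True)
class GridSolution:
    """A candidate (cellularity, single-copy depth) pair.

    Parameters
    ----------
    cellularity
        Fraction of cells in the sample that are tumour cells, in [0, 1].
    single_copy_depth
        Sequencing depth contributed by a single chromosomal copy present
        in every cell; strictly positive, in read units.
    """

    cellularity: float
    single_copy_depth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cellularity <= 1.0:
            raise ValueError(f"cellularity must be in [0, 1], got {self.cellularity}")
        if not self.single_copy_depth > 0:
            raise ValueError(
                f"single_copy_depth must be > 0, got {self.single_copy_depth}"
            )


@dataclass(frozen=True, order=True)
class CopyState:
    """An allele-specific copy-number state (n1 major, n2 minor copies)."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError(f"copy numbers must be non-negative: ({self.n1},{self.n2})")
        if self.n2 > self.n1:
            raise ValueError(
                f"minor-allele convention requires n2 <= n1, got ({self.n1},{self.n2})"
            )

    @property
    def total(self) -> int:
        return self.n1 + self.n2


@dataclass(frozen=True)
class GridNode:
    """One copy-number state with its predicted plot coordinates."""

    state: CopyState
    predicted_depth: float
    predicted_fraction: float
    folded_fraction: float


def predicted_depth(solution: GridSolution, state: CopyState) -> float:
    """Expected total depth for `state` under `solution`.

    Linear in ``single_copy_depth`` and continuous in cellularity; equals
    ``2 D`` for any state at C = 0 (pure normal is diploid) and
    ``D (n1 + n2)`` at C = 1.
    """
    c = solution.cellularity
    return solution.single_copy_depth * (2.0 * (1.0 - c) + state.total * c)


def predicted_minor_fraction(solution: GridSolution, state: CopyState) -> float:
    """Predicted (unfolded) minor-allele fraction for `state` under `solution`.

    Raises
    ------
    DegenerateStateError
        For the homozygous deletion (0, 0) in a pure tumour (C = 1), where
        the fraction is undefined.
    """
    c = solution.cellularity
    denom = 2.0 + c * (state.total - 2)
    if denom <= 0.0:
        raise DegenerateStateError(
            f"allele fraction undefined for state ({state.n1},{state.n2}) "
            f"at cellularity {c}"
        )
    return (1.0 + c * (state.n2 - 1)) / denom


def folded_expected_fraction(true_fraction: float, depth: float) -> float:
    """Exact expected *observed* minor fraction at a locus.

    Reads are modelled as ``X ~ Binomial(d, true_fraction)`` draws of the
    true minor allele among ``d = round(depth)`` reads; the recorded value
    is ``min(X, d - X) / d`` because the minor allele is identified after
    observation.  The expectation is computed by enumerating k = 0..d.

    Always ``<= true_fraction``; converges to it as depth grows (for
    fractions below 0.5).
    """
    if not 0.0 <= true_fraction <= 0.5:
        raise ValueError(f"true_fraction must be in [0, 0.5], got {true_fraction}")
    d = int(round(depth))
    if d < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    k = np.arange(d + 1)
    pmf = stats.binom.pmf(k, d, true_fraction)
    return float(np.sum(pmf * np.minimum(k, d - k)) / d)


def folded_expected_fractions(
    true_fractions: np.ndarray, depths: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`folded_expected_fraction` over paired arrays.

    Depths are rounded to integer trial counts and clamped to >= 1.
    """
    p = np.atleast_1d(np.asarray(true_fractions, dtype=float))
    d = np.maximum(np.rint(np.atleast_1d(depths)).astype(int), 1)
    k = np.arange(int(d.max()) + 1)
    pmf = stats.binom.pmf(k[None, :], d[:, None], p[:, None])
    # min(k, d-k) clipped at 0 zeroes the k > d tail regardless of pmf
    folded = np.minimum(k[None, :], np.clip(d[:, None] - k[None, :], 0, None))
    return (pmf * folded).sum(axis=1) / d


def enumerate_states(max_total_copy: int) -> list[CopyState]:
    """All states with n2 <= n1 and n1 + n2 <= max_total_copy."""
    if max_total_copy < 1:
        raise ValueError(f"max_total_copy must be >= 1, got {max_total_copy}")
    return [
        CopyState(n1, n2)
        for n1 in range(max_total_copy + 1)
        for n2 in range(min(n1, max_total_copy - n1) + 1)
    ]


def build_grid(
    solution: GridSolution,
    max_total_copy: int = DEFAULT_MAX_TOTAL_COPY,
    fold: bool = True,
) -> list[GridNode]:
    """Predicted (depth, fraction) node per copy-number state.

    The folded fraction is evaluated with the binomial trial count set to
    the node's predicted depth rounded to the nearest integer (clamped to
    >= 1); with ``fold=False`` it equals the raw prediction.  Degenerate
    states (no defined fraction) are omitted with a log notice.
    """
    nodes: list[GridNode] = []
    for state in enumerate_states(max_total_copy):
        dep = predicted_depth(solution, state)
        try:
            frac = predicted_minor_fraction(solution, state)
        except DegenerateStateError:
            logger.info(
                "omitting degenerate state (%d,%d) at cellularity %g",
                state.n1, state.n2, solution.cellularity,
            )
            continue
        folded = folded_expected_fraction(frac, max(round(dep), 1)) if fold else frac
        nodes.append(GridNode(state, dep, frac, folded))
    return nodes


@lru_cache(maxsize=8192)
def _node_arrays_cached(
    c: float, d: float, max_total_copy: int, fold: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    states = enumerate_states(max_total_copy)
    if c == 1.0:  # drop the degenerate homozygous deletion
        states = [s for s in states if s.total > 0]
    n1 = np.array([s.n1 for s in states])
    n2 = np.array([s.n2 for s in states])
    total = n1 + n2
    depths = d * (2.0 * (1.0 - c) + total * c)
    fracs = (1.0 + c * (n2 - 1)) / (2.0 + c * (total - 2))
    out_fracs = folded_expected_fractions(fracs, depths) if fold else fracs
    for arr in (n1, n2, depths, out_fracs):
        arr.flags.writeable = False
    return n1, n2, depths, out_fracs


def solution_node_arrays(
    solution: GridSolution,
    max_total_copy: int = DEFAULT_MAX_TOTAL_COPY,
    fold: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fast array view of :func:`build_grid`: (n1, n2, depths, fractions).

    Fractions are folded when ``fold`` is true.  Results are cached per
    (C, D, max_total_copy, fold), which makes exhaustive grid searches
    over many samples cheap.  Returned arrays are read-only.
    """
    return _node_arrays_cached(
        round(float(solution.cellularity), 12),
        round(float(solution.single_copy_depth), 12),
        int(max_total_copy),
        bool(fold),
    )


def grid_frame(nodes: list[GridNode]) -> pd.DataFrame:
    """Tabular form of a node list (n1, n2, depth, raw and folded fraction)."""
    return pd.DataFrame(
        {
            "n1": [n.state.n1 for n in nodes],
            "n2": [n.state.n2 for n in nodes],
            "predicted_depth": [n.predicted_depth for n in nodes],
            "predicted_fraction": [n.predicted_fraction for n in nodes],
            "folded_fraction": [n.folded_fraction for n in nodes],
        }
    )


def write_grid(nodes: list[GridNode], path: str) -> None:
    """Export a grid as TSV."""
    grid_frame(nodes).to_csv(path, sep="\t", index=False, float_format="%.6f")
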