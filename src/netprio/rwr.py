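"""Random walk with restart on the weighted interaction network.

The walker starts on the seed genes and, at each step, either moves along an
edge with probability 1 - r (choosing a neighbor proportionally to the edge
weight) or teleports back to the seed distribution with probability r.  The
update is

    p_{i+1} = (1 - r) * W @ p_i + r * p_0,

where W is the column-stochastic transition operator, W[i, j] =
w(j, i) / weighted_degree(j).  This propagation conserves probability mass
(each column of W sums to 1) and converges geometrically at rate 1 - r to
the unique fixed point of p = (1 - r) W p + r p_0.  Iteration stops when the
L1 distance between successive iterates falls below the tolerance.

Components of the converged vector rank genes by network proximity to the
seeds; genes scoring above a probability threshold become "RWR genes" for
the downstream filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .network_io import SeedSet, WeightedNetwork

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Power iteration did not converge within max_iterations."""

    def __init__(self, iterations: int, last_delta: float, tolerance: float):
        self.iterations = iterations
        self.last_delta = last_delta
        super().__init__(
            f"RWR did not converge in {iterations} iterations "
            f"(last L1 delta {last_delta:.3e} >= tolerance {tolerance:.3e})"
        )


@dataclass(frozen=True)
class RwrConfig:
    """Tunable parameters of the walk.

    restart_probability
        Teleport-to-seed probability r in (0, 1]; 0.8 by default, which keeps
        the walk local to the seed neighborhood.
    convergence_tolerance
        L1 stopping threshold on successive iterates (default 1e-6).
    max_iterations
        Safety valve; with r = 0.8 convergence takes ~10 iterations.
    score_threshold
        Probability cutoff selecting RWR genes (strictly larger than;
        default 1e-5).
    """

    restart_probability: float = 0.8
    convergence_tolerance: float = 1e-6
    max_iterations: int = 1000
    score_threshold: float = 1e-5

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_probability <= 1.0:
            raise ValueError("restart_probability must be in (0, 1]")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.score_threshold < 0:
            raise ValueError("score_threshold must be non-negative")


@dataclass(frozen=True)
class TransitionOperator:
    """Column-stochastic transition matrix over an ordered node index."""

    nodes: tuple[str, ...]
    matrix: sp.csr_matrix
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", {g: i for i, g in enumerate(self.nodes)})

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()


@dataclass(frozen=True)
class ProbabilityVector:
    """Per-node probability mass aligned with a TransitionOperator index."""

    nodes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.nodes),):
            raise ValueError("values length does not match node index")
        if values.min(initial=0.0) < -1e-12:
            raise ValueError("probability vector has negative components")
        total = values.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probability vector sums to {total!r}, not 1")
        object.__setattr__(self, "values", values)

    def __getitem__(self, gene: str) -> float:
        return float(self.values[self.nodes.index(gene)])

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values, index=list(self.nodes), name="probability")


@dataclass
class RwrInfo:
    """Diagnostics from one run: per-iteration L1 deltas and mass totals."""

    iterations: int
    deltas: list[float]
    masses: list[float]


def build_transition(network: WeightedNetwork) -> TransitionOperator:
    """Build the column-stochastic operator W with W[i, j] = w(j, i) / wdeg(j).

    Column j distributes the walker at node j across its neighbors
    proportionally to edge weight; every node has degree >= 1 by the
    WeightedNetwork invariant so no column is empty.
    """
    nodes = network.nodes
    if not nodes:
        raise ValueError("network is empty")
    index = {g: i for i, g in enumerate(nodes)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    wdeg = np.array([network.weighted_degree(g) for g in nodes], dtype=float)
    for a, b, w in network.edges():
        ia, ib = index[a], index[b]
        # move b -> a and a -> b, each normalized by the source column
        rows.append(ia); cols.append(ib); vals.append(w / wdeg[ib])
        rows.append(ib); cols.append(ia); vals.append(w / wdeg[ia])
    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))
    return TransitionOperator(nodes=nodes, matrix=matrix)


def initial_vector(seeds: SeedSet, operator: TransitionOperator) -> ProbabilityVector:
    """Uniform mass 1/|seeds| on each seed component, zero elsewhere."""
    if not len(seeds):
        raise ValueError("empty seed set")
    values = np.zeros(operator.n_nodes)
    for gene in seeds:
        try:
            values[operator.index[gene]] = 1.0
        except KeyError:
            raise ValueError(f"seed {gene!r} not in operator index") from None
    values /= len(seeds)
    return ProbabilityVector(nodes=operator.nodes, values=values)


def run_rwr(
    operator: TransitionOperator,
    p0: ProbabilityVector,
    config: RwrConfig = RwrConfig(),
    return_info: bool = False,
) -> ProbabilityVector | tuple[ProbabilityVector, RwrInfo]:
    """Iterate p <- (1 - r) W p + r p0 until the L1 delta drops below tolerance.

    Raises ConvergenceError if max_iterations is exhausted first.  With
    r = 1 the fixed point is p0 itself and the walk returns immediately.
    """
    if p0.nodes != operator.nodes:
        raise ValueError("initial vector index does not match operator index")
    r = config.restart_probability
    W = operator.matrix
    restart = r * p0.values
    p = p0.values.copy()
    deltas: list[float] = []
    masses: list[float] = []
    converged = False
    for iteration in range(1, config.max_iterations + 1):
        p_next = (1.0 - r) * (W @ p) + restart
        delta = float(np.abs(p_next - p).sum())
        p = p_next
        deltas.append(delta)
        masses.append(float(p.sum()))
        if delta < config.convergence_tolerance:
            converged = True
            break
    if not converged:
        raise ConvergenceError(config.max_iterations, deltas[-1], config.convergence_tolerance)
    logger.debug("RWR converged in %d iterations (last delta %.3e)", iteration, deltas[-1])
    result = ProbabilityVector(nodes=operator.nodes, values=p)
    if return_info:
        return result, RwrInfo(iterations=iteration, deltas=deltas, masses=masses)
    return result


def expected_iterations(config: RwrConfig) -> int:
    """Upper bound on iterations from the (1 - r) contraction rate.

    The first delta is at most 2(1 - r), and each further step contracts by
    at least (1 - r), so the count is bounded by
    1 + ceil(log(tol / (2(1-r))) / log(1-r)) for r < 1.
    """
    r = config.restart_probability
    if r >= 1.0:
        return 1
    first = 2.0 * (1.0 - r)
    if first < config.convergence_tolerance:
        return 1
    return 1 + math.ceil(math.log(config.convergence_tolerance / first) / math.log(1.0 - r))


def select_rwr_genes(
    prob: ProbabilityVector,
    seeds: SeedSet,
    config: RwrConfig = RwrConfig(),
    include_seeds: bool = False,
) -> list[tuple[str, float]]:
    """Rank non-seed genes with probability strictly above the threshold.

    Sorted by descending probability, ties broken lexicographically so the
    ranking is reproducible.  Seeds are excluded by default (they are known
    disease genes, not discoveries); pass include_seeds=True for diagnostics.
    """
    seed_genes = set(seeds.genes)
    out = [
        (gene, float(p))
        for gene, p in zip(prob.nodes, prob.values)
        if p > config.score_threshold and (include_seeds or gene not in seed_genes)
    ]
    out.sort(key=lambda item: (-item[1], item[0]))
    return out
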