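"""Permutation-test FDR for RWR genes.

High-degree hubs can score well under the walk regardless of the seed set.
To control for this, the walk is re-run on many random seed sets of the same
size and, for each RWR gene g, the empirical false discovery rate is the
fraction of random runs in which g scores strictly higher than it did with
the real seeds:

    FDR(g) = theta(g) / n_permutations.

Genes with FDR below the threshold (default 0.05, strict) survive as
candidate genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network_io import SeedSet, WeightedNetwork
from .rwr import ProbabilityVector, RwrConfig, TransitionOperator, initial_vector, run_rwr

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationResult:
    """Exceedance counts theta and the derived per-gene FDR.

    FDR values are exact multiples of 1/n_permutations by construction.
    """

    theta: pd.Series  # int counts, indexed by gene
    n_permutations: int

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if (self.theta < 0).any() or (self.theta > self.n_permutations).any():
            raise ValueError("theta outside [0, n_permutations]")

    @property
    def fdr(self) -> pd.Series:
        return (self.theta / self.n_permutations).rename("fdr")


def sample_seed_sets(
    network: WeightedNetwork, size: int, n_sets: int, rng_seed: int
) -> list[SeedSet]:
    """Draw n_sets seed sets of `size` distinct nodes, uniformly at random.

    Nodes are drawn without replacement from all network nodes (random sets
    may overlap the true seeds).  Fully reproducible from rng_seed.
    """
    nodes = np.array(network.nodes)
    if size > len(nodes):
        raise ValueError(f"seed-set size {size} exceeds node count {len(nodes)}")
    rng = np.random.default_rng(rng_seed)
    sets = []
    for _ in range(n_sets):
        draw = rng.choice(nodes, size=size, replace=False)
        sets.append(SeedSet(genes=tuple(str(g) for g in draw), dropped=0))
    return sets


def null_probability_runs(
    operator: TransitionOperator,
    seed_sets: Iterable[SeedSet],
    config: RwrConfig = RwrConfig(),
) -> list[ProbabilityVector]:
    """Run the walk once per random seed set, with the same RwrConfig as the real run."""
    runs = []
    for i, seeds in enumerate(seed_sets, 1):
        runs.append(run_rwr(operator, initial_vector(seeds, operator), config))
        if i % 100 == 0:
            logger.info("permutation runs: %d done", i)
    return runs


def permutation_fdr(
    real_scores: pd.Series,
    null_runs: Sequence[ProbabilityVector | pd.Series],
) -> PermutationResult:
    """Count, per gene, the null runs scoring strictly above the real score.

    real_scores is indexed by the RWR genes (scores from the real seed run);
    every null run must cover that index.  Ties do not count as exceedances.
    """
    if len(null_runs) == 0:
        raise ValueError("null_runs is empty")
    genes = real_scores.index
    rows = []
    for k, run in enumerate(null_runs):
        series = run.as_series() if isinstance(run, ProbabilityVector) else run
        aligned = series.reindex(genes)
        if aligned.isna().any():
            missing = list(aligned.index[aligned.isna()][:5])
            raise ValueError(f"null run {k} missing genes {missing}")
        rows.append(aligned.to_numpy())
    null_matrix = np.vstack(rows)
    theta = (null_matrix > real_scores.to_numpy()).sum(axis=0)
    return PermutationResult(
        theta=pd.Series(theta, index=genes, name="theta"),
        n_permutations=len(null_runs),
    )


def filter_candidates(
    records: Sequence[tuple[str, float, float]], fdr_threshold: float = 0.05
) -> list[tuple[str, float, float]]:
    """Keep (gene, probability, fdr) records with fdr strictly below the threshold."""
    return [rec for rec in records if rec[2] < fdr_threshold]
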