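"""Functional-association filters: MIS and MFS.

Two scores judge whether a candidate gene is functionally tied to the seed
genes:

* MIS (maximum interaction score): the candidate's largest edge weight to
  any seed gene.  MIS >= 900 means a direct highest-confidence STRING
  interaction with at least one seed.
* MFS (maximum function score): for each gene g, the neighborhood H(g)
  (g plus its direct neighbors) is scored against every annotation term with
  the upper-tail hypergeometric probability

      p = sum_{k=m}^{min(n, M)} C(M, k) C(N-M, n-k) / C(N, n),

  where N is the background universe, M the term size, n = |H(g)| and m the
  overlap.  The per-term enrichment score is -log10(p), collected into the
  vector ES(g); MFS(g) is the maximal cosine similarity between ES(g) and
  any seed's ES vector.  MFS > 0.9 marks strong functional agreement.

Core candidate genes pass FDR, MIS and MFS filters simultaneously.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .network_io import AnnotationCatalog, SeedSet, WeightedNetwork

logger = logging.getLogger(__name__)

#: Tail probabilities below this floor are capped (score cap 300) so that
#: extreme enrichment cannot overflow the -log10 scale.
P_FLOOR = 1e-300
SCORE_CAP = -math.log10(P_FLOOR)


@dataclass(frozen=True)
class NeighborhoodSet:
    """A gene together with its direct network neighbors, H(g)."""

    gene: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.gene not in self.members:
            raise ValueError("gene must belong to its own neighborhood")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentVector:
    """Per-term -log10 hypergeometric tail values, fixed term ordering."""

    terms: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.terms),):
            raise ValueError("values length does not match term index")
        if (values < 0).any():
            raise ValueError("enrichment scores must be non-negative")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class GeneRecord:
    """One row of the final report: a candidate gene with all its scores."""

    symbol: str
    identifier: str
    probability: float
    fdr: float
    mis: int
    mfs: float
    theta: int | None = None
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        if not (self.mis == 0 or 150 <= self.mis <= 999):
            raise ValueError(f"MIS {self.mis} outside {{0}} u [150, 999]")
        if not 0.0 <= self.mfs <= 1.0 + 1e-12:
            raise ValueError(f"MFS {self.mfs} outside [0, 1]")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"FDR {self.fdr} outside [0, 1]")


# -- MIS -------------------------------------------------------------------


def max_interaction_score(gene: str, seeds: SeedSet, network: WeightedNetwork) -> int:
    """Largest interaction score between `gene` and any seed; 0 with no seed edge."""
    if gene not in network:
        raise ValueError(f"gene {gene!r} not in network")
    neighbors = network.neighbors(gene)
    return max((neighbors[s] for s in seeds if s in neighbors), default=0)


# -- neighborhood enrichment ----------------------------------------------


def neighborhood(gene: str, network: WeightedNetwork) -> NeighborhoodSet:
    """H(g): the gene plus all directly adjacent nodes."""
    if gene not in network:
        raise ValueError(f"gene {gene!r} not in network")
    return NeighborhoodSet(gene=gene, members=frozenset(network.neighbors(gene)) | {gene})


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


@lru_cache(maxsize=1 << 20)
def hypergeometric_enrichment(m: int, n: int, M: int, N: int) -> float:
    """-log10 of the hypergeometric upper tail P[overlap >= m].

    Parameters are the observed overlap m, neighborhood size n, term size M
    and background size N.  Computed with exact log-binomials summed via
    logsumexp so the tail stays accurate down to the 1e-300 floor, where the
    score is capped at 300.  m = 0 gives a tail of 1 and score 0.
    """
    if n > N or M > N:
        raise ValueError(f"invalid hypergeometric parameters: n={n}, M={M}, N={N}")
    if m < 0 or m > min(n, M):
        raise ValueError(f"overlap m={m} outside [0, min(n, M)]")
    if m == 0:
        return 0.0
    log_den = _log_binom(N, n)
    log_terms = [
        _log_binom(M, k) + _log_binom(N - M, n - k) - log_den
        for k in range(m, min(n, M) + 1)
        if n - k <= N - M  # terms with C(N-M, n-k) = 0 vanish
    ]
    if not log_terms:
        return SCORE_CAP
    log_p = float(logsumexp(log_terms))
    score = -log_p / math.log(10.0)
    # rounding can push the full-support tail a hair past p = 1
    return float(min(max(score, 0.0), SCORE_CAP))


def enrichment_score(hood: NeighborhoodSet, term: str, catalog: AnnotationCatalog) -> float:
    """Enrichment of the neighborhood against one term (see module docstring)."""
    term_genes = catalog.terms[term]
    m = len(hood.members & term_genes)
    return hypergeometric_enrichment(m, len(hood.members), len(term_genes), catalog.background_size)


def enrichment_vector(
    gene: str, network: WeightedNetwork, catalog: AnnotationCatalog
) -> EnrichmentVector:
    """ES(g): one enrichment score per catalog term, shared sorted term order."""
    hood = neighborhood(gene, network)
    values = np.array([enrichment_score(hood, t, catalog) for t in catalog.term_ids])
    return EnrichmentVector(terms=catalog.term_ids, values=values)


def enrichment_vectors(
    genes: Iterable[str], network: WeightedNetwork, catalog: AnnotationCatalog
) -> dict[str, EnrichmentVector]:
    """Compute and cache ES vectors for many genes at once."""
    return {g: enrichment_vector(g, network, catalog) for g in dict.fromkeys(genes)}


# -- MFS -------------------------------------------------------------------


def functional_similarity(v1: EnrichmentVector, v2: EnrichmentVector) -> float:
    """Cosine similarity of two ES vectors; 0 if either vector is all-zero."""
    if v1.terms != v2.terms:
        raise ValueError("enrichment vectors use different term orderings")
    n1 = float(np.linalg.norm(v1.values))
    n2 = float(np.linalg.norm(v2.values))
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return float(np.dot(v1.values, v2.values) / (n1 * n2))


def max_function_score(
    gene: str, seeds: SeedSet, vectors: Mapping[str, EnrichmentVector]
) -> float:
    """MFS(g): maximal cosine similarity between ES(g) and any seed's ES vector."""
    try:
        own = vectors[gene]
        return max(functional_similarity(own, vectors[s]) for s in seeds)
    except KeyError as exc:
        raise ValueError(f"missing enrichment vector for {exc.args[0]!r}") from None


def max_function_scores(
    genes: Sequence[str],
    seeds: SeedSet,
    network: WeightedNetwork,
    catalog: AnnotationCatalog,
) -> dict[str, float]:
    """Vectorized MFS for many candidates against a shared seed-vector cache."""
    vectors = enrichment_vectors(list(genes) + list(seeds), network, catalog)
    return {g: max_function_score(g, seeds, vectors) for g in genes}


# -- core-candidate filter -------------------------------------------------


def select_core_candidates(
    records: Sequence[GeneRecord],
    mis_threshold: int = 900,
    mfs_threshold: float = 0.9,
) -> list[GeneRecord]:
    """Keep records with MIS >= mis_threshold and MFS above mfs_threshold.

    MFS is compared at the reported 3-decimal precision, so a value that
    rounds to exactly the threshold (e.g. 0.900 vs 0.9) passes; input order
    is preserved.
    """
    out = []
    for rec in records:
        if rec.mis < mis_threshold:
            continue
        if round(rec.mfs, 3) + 1e-9 < mfs_threshold:
            continue
        out.append(rec)
    return out
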