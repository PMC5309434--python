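"""Readers and validators for weighted PPI networks, seed lists and GMT catalogs.

The on-disk formats are the ones practitioners already have on hand: a
STRING ``protein.links``-style edge list (``protein1 protein2
combined_score``, whitespace separated, optional header), plain
one-identifier-per-line seed files (``#`` comments allowed), and
tab-separated GMT gene-set catalogs for GO terms and KEGG pathways.

Identifiers are treated as opaque strings throughout: whether they are
Ensembl protein IDs, gene symbols or anything else is up to the input files,
which keeps the method decoupled from any one annotation release.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

#: STRING combined scores live on this integer scale.
STRING_MIN_SCORE = 150
STRING_MAX_SCORE = 999


class EdgeListParseError(ValueError):
    """A row of the edge list could not be parsed."""


class NetworkValidationError(ValueError):
    """An input violates a structural invariant (score range, self-loop, ...)."""


class GmtParseError(ValueError):
    """A GMT line could not be parsed."""


class WeightedNetwork:
    """Undirected protein-interaction graph with integer confidence weights.

    Edges are stored once and looked up symmetrically, ``score(a, b) ==
    score(b, a)``.  Every node participates in at least one edge; self-loops
    and scores outside [150, 999] are rejected at construction.
    """

    __slots__ = ("_adj", "_nodes", "_n_edges")

    def __init__(self, edges: Iterable[tuple[str, str, int]]):
        adj: dict[str, dict[str, int]] = {}
        n_edges = 0
        for a, b, w in edges:
            if a == b:
                raise NetworkValidationError(f"self-loop on node {a!r}")
            w = int(w)
            if not STRING_MIN_SCORE <= w <= STRING_MAX_SCORE:
                raise NetworkValidationError(
                    f"score {w} for edge ({a!r}, {b!r}) outside "
                    f"[{STRING_MIN_SCORE}, {STRING_MAX_SCORE}]"
                )
            existing = adj.get(a, {}).get(b)
            if existing is not None:
                if existing != w:
                    raise NetworkValidationError(
                        f"conflicting scores for edge ({a!r}, {b!r}): "
                        f"{existing} vs {w}"
                    )
                continue
            adj.setdefault(a, {})[b] = w
            adj.setdefault(b, {})[a] = w
            n_edges += 1
        self._adj = adj
        self._nodes: tuple[str, ...] = tuple(sorted(adj))
        self._n_edges = n_edges

    # -- basic queries -----------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """All node identifiers, sorted."""
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._n_edges

    def __contains__(self, gene: str) -> bool:
        return gene in self._adj

    def neighbors(self, gene: str) -> Mapping[str, int]:
        """Mapping neighbor -> interaction score (do not mutate)."""
        try:
            return self._adj[gene]
        except KeyError:
            raise NetworkValidationError(f"node {gene!r} not in network") from None

    def score(self, a: str, b: str, default: int = 0) -> int:
        """Symmetric interaction score S(a, b); `default` if no edge."""
        return self._adj.get(a, {}).get(b, default)

    def degree(self, gene: str) -> int:
        return len(self.neighbors(gene))

    def weighted_degree(self, gene: str) -> int:
        return sum(self.neighbors(gene).values())

    def edges(self) -> Iterator[tuple[str, str, int]]:
        """Yield each undirected edge once as (a, b, w) with a < b."""
        for a in self._nodes:
            for b, w in sorted(self._adj[a].items()):
                if a < b:
                    yield a, b, w

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:
        return f"WeightedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass(frozen=True)
class SeedSet:
    """Validated disease genes used to seed the walk.

    ``genes`` is an ordered, duplicate-free tuple of node identifiers all of
    which are present in the network; ``dropped`` counts input identifiers
    that were absent and therefore excluded.
    """

    genes: tuple[str, ...]
    dropped: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise NetworkValidationError("seed set is empty")
        if len(set(self.genes)) != len(self.genes):
            raise NetworkValidationError("seed set contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class AnnotationCatalog:
    """Term -> gene-set mapping with a background-universe size N.

    N is the total number of genes in the background universe used by the
    hypergeometric enrichment test; when built with ``background_size="auto"``
    it is the size of the union of all annotated genes.
    """

    terms: dict[str, frozenset[str]]
    background_size: int
    term_ids: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        union: set[str] = set()
        for term, genes in self.terms.items():
            if not genes:
                raise NetworkValidationError(f"term {term!r} has no genes")
            union |= genes
        if self.background_size < len(union):
            raise NetworkValidationError(
                f"background_size {self.background_size} smaller than the "
                f"union of annotated genes ({len(union)})"
            )
        object.__setattr__(self, "term_ids", tuple(sorted(self.terms)))

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def annotated_union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)


# -- loaders ---------------------------------------------------------------


def load_edge_list(path: str | Path, min_score: int = STRING_MIN_SCORE) -> WeightedNetwork:
    """Read a STRING ``protein.links``-dialect edge list.

    Parameters
    ----------
    path
        Whitespace-separated file with rows ``protein1 protein2 score``; a
        single header line (non-integer third field) is tolerated and skipped.
    min_score
        Keep only edges with score >= ``min_score`` (default 150, i.e. keep
        everything on the STRING scale).

    Symmetric duplicate rows (``a b s`` and ``b a s``) collapse into one
    undirected edge; duplicates with conflicting scores are an error.
    """
    path = Path(path)
    edges: dict[tuple[str, str], int] = {}
    seen_lines: dict[tuple[str, str], int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise EdgeListParseError(
                    f"{path.name}:{lineno}: expected 3 fields, got {len(fields)}"
                )
            a, b, raw = fields
            try:
                w = int(raw)
            except ValueError:
                if lineno == 1:  # header row (e.g. "protein1 protein2 combined_score")
                    continue
                raise EdgeListParseError(
                    f"{path.name}:{lineno}: non-integer score {raw!r}"
                ) from None
            if a == b:
                raise NetworkValidationError(f"{path.name}:{lineno}: self-loop on {a!r}")
            if not STRING_MIN_SCORE <= w <= STRING_MAX_SCORE:
                raise NetworkValidationError(
                    f"{path.name}:{lineno}: score {w} outside "
                    f"[{STRING_MIN_SCORE}, {STRING_MAX_SCORE}]"
                )
            key = (a, b) if a < b else (b, a)
            if key in edges:
                if edges[key] != w:
                    raise NetworkValidationError(
                        f"{path.name}:{lineno}: conflicting score for edge {key}: "
                        f"{edges[key]} (line {seen_lines[key]}) vs {w}"
                    )
                continue
            edges[key] = w
            seen_lines[key] = lineno
    kept = [(a, b, w) for (a, b), w in edges.items() if w >= min_score]
    if not kept:
        raise NetworkValidationError(f"{path.name}: no edges with score >= {min_score}")
    network = WeightedNetwork(kept)
    logger.info(
        "loaded network from %s: %d nodes, %d edges (min_score=%d)",
        path, network.n_nodes, network.n_edges, min_score,
    )
    return network


def write_edge_list(network: WeightedNetwork, path: str | Path, header: bool = True) -> None:
    """Write a network back to the STRING edge-list dialect (one row per edge)."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write("protein1 protein2 combined_score\n")
        for a, b, w in network.edges():
            fh.write(f"{a} {b} {w}\n")


def load_seed_set(path: str | Path, network: WeightedNetwork) -> SeedSet:
    """Read a seed gene list, dropping identifiers absent from the network.

    One identifier per line; blank lines and ``#`` comments are ignored;
    duplicates are de-duplicated (first occurrence kept).  Raises if no
    identifier survives.
    """
    path = Path(path)
    raw: list[str] = []
    with path.open() as fh:
        for line in fh:
            token = line.split("#", 1)[0].strip()
            if token:
                raw.append(token)
    unique = list(dict.fromkeys(raw))
    kept = [g for g in unique if g in network]
    dropped = len(unique) - len(kept)
    if not kept:
        raise NetworkValidationError(f"{path.name}: no seeds in network")
    if dropped:
        logger.warning("%s: dropped %d seed(s) absent from the network", path.name, dropped)
    logger.info("loaded %d seeds from %s (%d dropped)", len(kept), path, dropped)
    return SeedSet(genes=tuple(kept), dropped=dropped)


def load_annotations(path: str | Path, background_size: int | str = "auto") -> AnnotationCatalog:
    """Read a GMT gene-set catalog (term TAB description TAB gene TAB gene ...).

    Terms with zero genes are skipped with a warning.  ``background_size``
    may be an explicit universe size N or ``"auto"`` (union of all annotated
    genes).
    """
    path = Path(path)
    terms: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            term = fields[0].strip()
            if not term:
                raise GmtParseError(f"{path.name}:{lineno}: missing term identifier")
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                logger.warning("%s:%d: term %r has no genes, skipped", path.name, lineno, term)
                continue
            if term in terms:
                raise GmtParseError(f"{path.name}:{lineno}: duplicate term {term!r}")
            terms[term] = genes
    if not terms:
        raise GmtParseError(f"{path.name}: no usable terms")
    if background_size == "auto":
        union: set[str] = set()
        for genes in terms.values():
            union |= genes
        n = len(union)
    else:
        n = int(background_size)
    catalog = AnnotationCatalog(terms=terms, background_size=n)
    logger.info("loaded %d terms from %s (background N=%d)", catalog.n_terms, path, n)
    return catalog
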