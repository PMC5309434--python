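"""Desk-scale benchmark generator with a planted disease module.

Real runs of this tool use a genome-scale STRING network, a curated seed
list and GO/KEGG annotations — none of which fit in a test suite.  The
generator builds a small stand-in with known ground truth: an Erdos-Renyi
background graph containing one denser, higher-scored planted module, a
seed/held-out split inside that module, and annotation terms enriched in
module members.  Held-out module genes play the role of the "novel disease
genes" the pipeline should recover, which makes ranking quality (AUROC) and
filter behaviour measurable without any external download.

Everything is reproducible from a single rng_seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .network_io import AnnotationCatalog, SeedSet, WeightedNetwork, write_edge_list

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the planted-module benchmark.

    Defaults are the package's reference study conditions: a 600-node
    background (edge probability 0.02, scores 150-700) with a 30-gene module
    (edge probability 0.6, scores 800-999), 10 of whose members are seeds;
    40 annotation terms of 10-30 genes, half of them "disease" terms drawing
    50% of their members from the module.
    """

    n_nodes: int = 600
    planted_module_size: int = 30
    n_seeds: int = 10
    intra_module_edge_prob: float = 0.6
    background_edge_prob: float = 0.02
    intra_score_range: tuple[int, int] = (800, 999)
    background_score_range: tuple[int, int] = (150, 700)
    n_terms: int = 40
    n_disease_terms: int | None = None  # default: half of n_terms
    term_size_range: tuple[int, int] = (10, 30)
    term_module_enrichment: float = 0.5
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if not self.n_seeds < self.planted_module_size:
            raise ValueError("n_seeds must be smaller than planted_module_size")
        if self.planted_module_size > self.n_nodes:
            raise ValueError("module larger than the network")
        for p in (self.intra_module_edge_prob, self.background_edge_prob):
            if not 0.0 < p <= 1.0:
                raise ValueError("edge probabilities must be in (0, 1]")
        for lo, hi in (self.intra_score_range, self.background_score_range):
            if not (150 <= lo <= hi <= 999):
                raise ValueError("score ranges must lie within [150, 999]")
        if not 0.0 <= self.term_module_enrichment <= 1.0:
            raise ValueError("term_module_enrichment must be in [0, 1]")

    @property
    def disease_terms(self) -> int:
        return self.n_terms // 2 if self.n_disease_terms is None else self.n_disease_terms


@dataclass(frozen=True)
class BenchmarkTruth:
    """Ground truth of one generated benchmark."""

    module: tuple[str, ...]
    seeds: tuple[str, ...]
    held_out: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.seeds) | set(self.held_out) != set(self.module):
            raise ValueError("seeds and held_out must partition the module")
        if set(self.seeds) & set(self.held_out):
            raise ValueError("seeds and held_out overlap")


def generate_benchmark(
    spec: BenchmarkSpec = BenchmarkSpec(),
) -> tuple[WeightedNetwork, SeedSet, AnnotationCatalog, BenchmarkTruth]:
    """Generate (network, seeds, annotations, truth) from one rng_seed.

    The planted module is made internally connected (a spanning chain across
    its components is added if the random draw left it split) so that walk
    probability can reach every held-out member; isolated background nodes
    are dropped.
    """
    rng = np.random.default_rng(spec.rng_seed)
    width = len(str(spec.n_nodes - 1))
    names = np.array([f"g{i:0{width}d}" for i in range(spec.n_nodes)])
    module_idx = rng.choice(spec.n_nodes, size=spec.planted_module_size, replace=False)
    module = set(names[module_idx])
    seeds = set(rng.choice(sorted(module), size=spec.n_seeds, replace=False))
    held_out = module - seeds

    iu, ju = np.triu_indices(spec.n_nodes, k=1)
    in_module = np.isin(np.arange(spec.n_nodes), module_idx)
    intra_pair = in_module[iu] & in_module[ju]
    prob = np.where(intra_pair, spec.intra_module_edge_prob, spec.background_edge_prob)
    keep = rng.random(iu.size) < prob
    lo_i, hi_i = spec.intra_score_range
    lo_b, hi_b = spec.background_score_range
    scores = np.where(
        intra_pair,
        rng.integers(lo_i, hi_i + 1, size=iu.size),
        rng.integers(lo_b, hi_b + 1, size=iu.size),
    )
    edges = [
        (str(names[i]), str(names[j]), int(s))
        for i, j, s in zip(iu[keep], ju[keep], scores[keep])
    ]

    # enforce module connectivity with a spanning chain across components
    sub = nx.Graph()
    sub.add_nodes_from(sorted(module))
    sub.add_edges_from((a, b) for a, b, _ in edges if a in module and b in module)
    components = [sorted(c) for c in nx.connected_components(sub)]
    components.sort(key=lambda c: c[0])
    for left, right in zip(components, components[1:]):
        a = left[int(rng.integers(len(left)))]
        b = right[int(rng.integers(len(right)))]
        edges.append((a, b, int(rng.integers(lo_i, hi_i + 1))))

    network = WeightedNetwork(edges)  # nodes with no edge drop out here
    present = set(network.nodes)
    if not module <= present:
        raise AssertionError("planted module lost nodes despite connectivity fix")

    catalog = _generate_annotations(spec, rng, sorted(present), sorted(module))
    truth = BenchmarkTruth(
        module=tuple(sorted(module)),
        seeds=tuple(sorted(seeds)),
        held_out=tuple(sorted(held_out)),
    )
    seed_set = SeedSet(genes=truth.seeds, dropped=0)
    logger.info(
        "benchmark: %d nodes, %d edges, module %d (seeds %d / held-out %d), %d terms",
        network.n_nodes, network.n_edges, len(module), len(seeds), len(held_out),
        catalog.n_terms,
    )
    return network, seed_set, catalog, truth


def _generate_annotations(
    spec: BenchmarkSpec, rng: np.random.Generator,
    nodes: Sequence[str], module: Sequence[str],
) -> AnnotationCatalog:
    terms: dict[str, frozenset[str]] = {}
    non_module = sorted(set(nodes) - set(module))
    lo, hi = spec.term_size_range
    for t in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        if t < spec.disease_terms:
            n_mod = min(round(spec.term_module_enrichment * size), len(module))
            mod_part = rng.choice(module, size=n_mod, replace=False)
            rest = rng.choice(non_module, size=size - n_mod, replace=False)
            genes = frozenset(map(str, mod_part)) | frozenset(map(str, rest))
            terms[f"DISEASE_TERM_{t:03d}"] = genes
        else:
            genes = rng.choice(nodes, size=size, replace=False)
            terms[f"BG_TERM_{t:03d}"] = frozenset(map(str, genes))
    return AnnotationCatalog(terms=terms, background_size=len(nodes))


# -- file output (formats that network_io reads back) ----------------------


def write_benchmark(
    network: WeightedNetwork,
    seed_set: SeedSet,
    catalog: AnnotationCatalog,
    truth: BenchmarkTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write edge list, seed list, GMT catalog and truth JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "seeds": out / "seeds.txt",
        "annotations": out / "annotations.gmt",
        "truth": out / "truth.json",
    }
    write_edge_list(network, paths["network"])
    paths["seeds"].write_text("".join(f"{g}\n" for g in seed_set.genes))
    with paths["annotations"].open("w") as fh:
        for term in catalog.term_ids:
            genes = "\t".join(sorted(catalog.terms[term]))
            fh.write(f"{term}\tsynthetic gene set\t{genes}\n")
    with paths["truth"].open("w") as fh:
        json.dump(
            {"module": list(truth.module), "seeds": list(truth.seeds),
             "held_out": list(truth.held_out)},
            fh, indent=2,
        )
        fh.write("\n")
    return paths


def load_truth(path: str | Path) -> BenchmarkTruth:
    with Path(path).open() as fh:
        raw = json.load(fh)
    return BenchmarkTruth(
        module=tuple(raw["module"]), seeds=tuple(raw["seeds"]),
        held_out=tuple(raw["held_out"]),
    )


# -- recovery metrics ------------------------------------------------------


def evaluate_recovery(
    probabilities: pd.Series | "object",
    truth: BenchmarkTruth,
    core_genes: Sequence[str] = (),
) -> dict[str, float]:
    """Rank metrics for one pipeline run against the planted truth.

    probabilities may be a pandas Series over network nodes or a
    ProbabilityVector (anything with .as_series()).  Returns the AUROC of
    held-out module members versus background genes under the probability
    ranking, and the fraction of held-out members recovered in core_genes.
    """
    if hasattr(probabilities, "as_series"):
        probabilities = probabilities.as_series()
    missing = [g for g in truth.held_out if g not in probabilities.index]
    if missing:
        raise ValueError(f"held-out genes missing from probabilities: {missing[:5]}")
    non_seed = probabilities.drop(index=list(truth.seeds), errors="ignore")
    labels = non_seed.index.isin(truth.held_out).astype(int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("need both held-out and background genes for AUROC")
    auroc = float(roc_auc_score(labels, non_seed.to_numpy()))
    recall = len(set(core_genes) & set(truth.held_out)) / len(truth.held_out)
    return {
        "auroc": auroc,
        "held_out_core_recall": recall,
        "n_held_out": float(len(truth.held_out)),
        "n_background": float(len(labels) - labels.sum()),
    }
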