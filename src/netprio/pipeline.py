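"""End-to-end orchestration: load -> RWR -> FDR -> MIS/MFS -> core table.

One configuration object drives the whole cascade and every stage's output
is written alongside a manifest recording the resolved parameters, the RNG
seed and input checksums, so a run is fully reproducible: identical config
plus identical inputs yields byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import functional, network_io, permutation, rwr
from .functional import GeneRecord
from .network_io import AnnotationCatalog, SeedSet, WeightedNetwork
from .rwr import ProbabilityVector, RwrConfig

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    logger.info("stage '%s' done in %.2fs", name, time.perf_counter() - t0)


@dataclass(frozen=True)
class PipelineConfig:
    """Paths plus every threshold of the cascade (defaults = published values).

    background_size is an explicit universe size N for the hypergeometric
    test or "auto" (union of all annotated genes).
    """

    network: str
    seeds: str
    annotations: str
    out_dir: str = "results"
    min_score: int = 150
    restart_probability: float = 0.8
    convergence_tolerance: float = 1e-6
    max_iterations: int = 1000
    score_threshold: float = 1e-5
    n_permutations: int = 1000
    fdr_threshold: float = 0.05
    mis_threshold: int = 900
    mfs_threshold: float = 0.9
    rng_seed: int = 1
    background_size: int | str = "auto"

    def __post_init__(self) -> None:
        self.rwr_config()  # validates the RWR block
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr_threshold must be in (0, 1]")
        if not 0 <= self.mis_threshold <= 999:
            raise ValueError("mis_threshold must be in [0, 999]")

    def rwr_config(self) -> RwrConfig:
        return RwrConfig(
            restart_probability=self.restart_probability,
            convergence_tolerance=self.convergence_tolerance,
            max_iterations=self.max_iterations,
            score_threshold=self.score_threshold,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat key-value YAML document; unknown keys are an error."""
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    probabilities: ProbabilityVector
    rwr_genes: list[tuple[str, float]]
    candidates: list[GeneRecord]
    core: list[GeneRecord]
    stage_counts: dict[str, int]
    manifest: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline_from_objects(
    network: WeightedNetwork,
    seed_set: SeedSet,
    catalog: AnnotationCatalog,
    config: PipelineConfig,
) -> PipelineResult:
    """Run the cascade on in-memory inputs (no file I/O)."""
    rwr_config = config.rwr_config()

    with _stage("consistency"):
        overlap = catalog.annotated_union() & set(network.nodes)
        if not overlap:
            examples = sorted(catalog.annotated_union())[:5]
            raise ValueError(
                f"no annotated gene occurs in the network; catalog examples: {examples}"
            )

    with _stage("rwr"):
        operator = rwr.build_transition(network)
        p0 = rwr.initial_vector(seed_set, operator)
        prob = rwr.run_rwr(operator, p0, rwr_config)
        rwr_genes = rwr.select_rwr_genes(prob, seed_set, rwr_config)

    with _stage("permutation"):
        seed_sets = permutation.sample_seed_sets(
            network, size=len(seed_set), n_sets=config.n_permutations,
            rng_seed=config.rng_seed,
        )
        null_runs = permutation.null_probability_runs(operator, seed_sets, rwr_config)
        real_scores = pd.Series(dict(rwr_genes), name="probability").sort_index()
        perm = permutation.permutation_fdr(real_scores, null_runs)
        ranked = [(g, p) for g, p in rwr_genes]  # keep RWR ranking order
        triples = [(g, p, float(perm.fdr[g])) for g, p in ranked]
        candidate_triples = permutation.filter_candidates(triples, config.fdr_threshold)

    with _stage("functional"):
        cand_genes = [g for g, _, _ in candidate_triples]
        mfs = functional.max_function_scores(cand_genes, seed_set, network, catalog)
        candidates = [
            GeneRecord(
                symbol=g,
                identifier=g,
                probability=p,
                fdr=f,
                mis=functional.max_interaction_score(g, seed_set, network),
                mfs=mfs[g],
                theta=int(perm.theta[g]),
                n_permutations=config.n_permutations,
            )
            for g, p, f in candidate_triples
        ]
        core = functional.select_core_candidates(
            candidates, config.mis_threshold, config.mfs_threshold
        )
        core = sorted(core, key=lambda r: (-r.mfs, r.symbol))  # report ordering

    stage_counts = {
        "nodes": network.n_nodes,
        "edges": network.n_edges,
        "seeds": len(seed_set),
        "seeds_dropped": seed_set.dropped,
        "rwr_genes": len(rwr_genes),
        "candidates": len(candidates),
        "core_candidates": len(core),
    }
    logger.info("cascade counts: %s", stage_counts)
    return PipelineResult(
        probabilities=prob,
        rwr_genes=rwr_genes,
        candidates=candidates,
        core=core,
        stage_counts=stage_counts,
    )


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Load the three inputs, run the cascade and (optionally) write reports.

    Outputs under config.out_dir: rwr_genes.tsv, candidates.tsv,
    core_candidates.tsv and manifest.json.
    """
    with _stage("load"):
        network = network_io.load_edge_list(config.network, min_score=config.min_score)
        seed_set = network_io.load_seed_set(config.seeds, network)
        catalog = network_io.load_annotations(
            config.annotations, background_size=config.background_size
        )

    result = run_pipeline_from_objects(network, seed_set, catalog, config)

    result.manifest = {
        "config": config.to_dict(),
        "inputs": {
            "network": {"path": str(config.network), "sha256": _sha256(config.network)},
            "seeds": {"path": str(config.seeds), "sha256": _sha256(config.seeds)},
            "annotations": {
                "path": str(config.annotations),
                "sha256": _sha256(config.annotations),
            },
        },
        "stage_counts": result.stage_counts,
    }

    if write_outputs:
        with _stage("write"):
            out_dir = Path(config.out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_rwr_genes(result.rwr_genes, out_dir / "rwr_genes.tsv")
            write_candidates(result.candidates, out_dir / "candidates.tsv")
            write_report(result.core, out_dir / "core_candidates.tsv")
            with (out_dir / "manifest.json").open("w") as fh:
                json.dump(result.manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
    return result


# -- writers ---------------------------------------------------------------


def write_rwr_genes(genes: Sequence[tuple[str, float]], path: str | Path) -> None:
    """TSV of (gene, probability), probability in 6-significant-digit scientific form."""
    with Path(path).open("w") as fh:
        fh.write("gene\tprobability\n")
        for gene, p in genes:
            fh.write(f"{gene}\t{p:.5e}\n")


def write_candidates(records: Sequence[GeneRecord], path: str | Path) -> None:
    """TSV of candidate genes with exceedance counts and FDR."""
    with Path(path).open("w") as fh:
        fh.write("gene\tprobability\ttheta\tfdr\n")
        for rec in records:
            theta = "" if rec.theta is None else rec.theta
            fh.write(f"{rec.identifier}\t{rec.probability:.5e}\t{theta}\t{rec.fdr:.6g}\n")


def _format_fdr(rec: GeneRecord) -> str:
    n = rec.n_permutations
    if n and (rec.theta == 0 or rec.fdr == 0.0):
        return f"<{1.0 / n:g}"  # below the resolution of the permutation test
    return f"{rec.fdr:.3f}"


def write_report(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Final six-column report: symbol, ID, probability, FDR, MIS, MFS.

    Probability uses 3-significant-digit scientific notation, FDR and MFS
    three decimals (FDR below the permutation resolution is written as a
    "<1/n" bound), MIS is an integer.
    """
    with Path(path).open("w") as fh:
        fh.write("Gene symbol\tEnsembl ID\tProbability\tPermutation FDR\tMIS\tMFS\n")
        for rec in records:
            fh.write(
                f"{rec.symbol}\t{rec.identifier}\t{rec.probability:.2e}\t"
                f"{_format_fdr(rec)}\t{rec.mis}\t{rec.mfs:.3f}\n"
            )
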