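"""End-to-end orchestration: counts → fitness → interaction calls.

One call runs the whole chain on either real input TSVs or a synthetic
screen configuration, logs per-stage row counts, and returns the gene
results together with a manifest capturing everything needed to reproduce
the run (resolved config, input digests, seed, version, stage counts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version

import pandas as pd

from .errors import CrisprGiError
from .fitness import PipelineConfig, compute_fitness
from .io import (
    CountTable,
    GeneInteraction,
    GuideAnnotation,
    read_count_table,
    read_guide_annotation,
    read_sample_meta,
    write_gene_results,
)
from .scoring import guide_delta, score_genes
from .sim import SimConfig, simulate_paired_screens

logger = logging.getLogger("crispri_gi")

try:
    _VERSION = version("crispri-gi")
except PackageNotFoundError:  # running from a source tree
    _VERSION = "unknown"


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    seed: int | None = None
    version: str = _VERSION
    counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        c = self.counts
        if not (
            c["guides_ranked"] <= c["guides_read"]
            and c["genes_tested"] <= c["genes_annotated"]
            and c["hits_tier2"] <= c["hits_tier1_or_better"] <= c["genes_tested"]
        ):
            raise CrisprGiError(f"inconsistent manifest counts: {c}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except CrisprGiError as e:
            raise type(e)(f"[{name}] {e}") from e

    return wrap


def run_pipeline(
    config: PipelineConfig | None = None,
    *,
    counts_path=None,
    samples_path=None,
    guides_path=None,
    sim_config: SimConfig | None = None,
) -> tuple[list[GeneInteraction], RunManifest]:
    """Run the full analysis on file inputs or on a simulated screen.

    Exactly one input mode must be given: either the three TSV paths
    (counts, sample metadata, guide annotation) or a :class:`SimConfig`.
    """
    config = config or PipelineConfig()
    manifest = RunManifest(config={"pipeline": dataclasses.asdict(config)})

    if sim_config is not None:
        if counts_path or samples_path or guides_path:
            raise CrisprGiError("give either file inputs or sim_config, not both")
        annotation, raw, _truth = _stage("simulate")(
            simulate_paired_screens, sim_config
        )
        sim_dict = dataclasses.asdict(sim_config)
        manifest.config["sim"] = sim_dict
        manifest.seed = sim_config.seed
        logger.info(
            "simulate: %d guides, %d samples", len(annotation), len(raw.samples)
        )
    else:
        if not (counts_path and samples_path and guides_path):
            raise CrisprGiError(
                "need counts, sample-metadata and guide-annotation paths"
            )
        annotation = _stage("read_guides")(read_guide_annotation, guides_path)
        meta = _stage("read_samples")(read_sample_meta, samples_path)
        raw, warnings = _stage("read_counts")(
            read_count_table, counts_path, meta, annotation
        )
        for w in warnings:
            logger.warning("read_counts: %s", w)
        manifest.input_digests = {
            "counts": _sha256(counts_path),
            "samples": _sha256(samples_path),
            "guides": _sha256(guides_path),
        }

    fitness = _stage("fitness")(compute_fitness, raw, annotation, config)
    n_guides = raw.counts.shape[0]
    passed = (
        fitness.groupby("background")["passed_filter"].sum().astype(int).to_dict()
    )
    logger.info("fitness: %d guides read, passed filter per background: %s",
                n_guides, passed)

    delta, excluded = _stage("delta")(guide_delta, fitness)
    logger.info("delta: %d guides ranked, %d excluded", len(delta), len(excluded))

    results = _stage("score")(score_genes, delta, annotation, config)
    tested = [r for r in results if r.tested]
    tier2 = sum(r.tier == "tier2" for r in results)
    tier1p = sum(r.tier in ("tier1", "tier2") for r in results)
    logger.info(
        "score: %d genes tested, %d tier1-or-better, %d tier2",
        len(tested), tier1p, tier2,
    )

    manifest.counts = {
        "guides_read": int(n_guides),
        **{f"guides_passed_{bg}": int(n) for bg, n in passed.items()},
        "guides_ranked": int(len(delta)),
        "guides_excluded": int(len(excluded)),
        "genes_annotated": len(annotation.genes),
        "genes_tested": len(tested),
        "hits_tier1_or_better": int(tier1p),
        "hits_tier2": int(tier2),
    }
    manifest.validate()
    return results, manifest


def run_and_write(
    out_results,
    out_manifest=None,
    **kwargs,
) -> tuple[list[GeneInteraction], RunManifest]:
    """Convenience wrapper: run the pipeline and write results/manifest."""
    results, manifest = run_pipeline(**kwargs)
    write_gene_results(results, out_results)
    if out_manifest is not None:
        manifest.write(out_manifest)
    return results, manifest
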