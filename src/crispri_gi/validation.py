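"""Screen-scale validation scenarios for the scoring pipeline.

These functions run the full pipeline on simulated paired screens under
fixed study conditions — a genome-scale library of five guides per gene
plus non-targeting controls, ~17 generations of growth, two replicates —
and summarise how the statistics behave: false-positive calibration when
nothing is planted, and recovery when synthetic-sick interactions are.
They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .fitness import PipelineConfig, compute_fitness
from .io import REFERENCE, MUTANT
from .scoring import guide_delta, score_genes
from .sim import SimConfig, simulate_paired_screens


def _run_screen(sim: SimConfig, config: PipelineConfig | None = None):
    annotation, counts, truth = simulate_paired_screens(sim)
    fitness = compute_fitness(counts, annotation, config)
    delta, _ = guide_delta(fitness)
    results = score_genes(delta, annotation, config)
    return annotation, truth, fitness, results


def null_calibration(
    seed: int,
    n_genes: int = 2000,
    n_controls: int = 100,
    depth_per_guide: int = 10_000,
) -> dict:
    """Type-I-error check: a paired screen with no planted interactions.

    Gene fitness effects still differ between genes (neutral majority,
    half-normal defects) but are identical across backgrounds, so every
    gene is null for interaction.  Reports the fraction of tested genes
    with p < 0.05 and the number of stringent-tier hits (should be ~0.05
    and 0).
    """
    sim = SimConfig(
        n_genes=n_genes,
        n_controls=n_controls,
        depth_per_guide=depth_per_guide,
        frac_interacting=0.0,
        seed=seed,
    )
    _, _, _, results = _run_screen(sim)
    pv = np.array([r.pvalue for r in results if r.tested])
    return {
        "n_genes_tested": int(len(pv)),
        "positive_rate": float((pv < 0.05).mean()),
        "tier2_hits": int(sum(r.tier == "tier2" for r in results)),
    }


def interaction_recovery(
    seed: int,
    n_genes: int = 2000,
    n_controls: int = 100,
    depth_per_guide: int = 10_000,
    frac_interacting: float = 0.02,
    delta_effect: float = -0.15,
) -> dict:
    """Power check: planted synthetic-sick interactions of |GI| ≈ 2+.

    With a per-generation interaction effect of −0.15 and efficacies in
    [0.6, 1], planted genes carry median Δlog2FC around −2 to −2.5 after 17
    generations.  Reports the fraction of planted genes called at q < 0.05
    with negative direction, and the q < 0.05 rate among unplanted genes.
    """
    sim = SimConfig(
        n_genes=n_genes,
        n_controls=n_controls,
        depth_per_guide=depth_per_guide,
        frac_interacting=frac_interacting,
        delta_effect=delta_effect,
        efficacy_range=(0.6, 1.0),
        seed=seed,
    )
    _, truth, _, results = _run_screen(sim)
    by_gene = {r.gene: r for r in results}
    planted = truth.genes.loc[truth.genes.interacting, "gene"]
    unplanted = truth.genes.loc[~truth.genes.interacting, "gene"]
    recovered = [
        by_gene[g].tested
        and by_gene[g].qvalue < 0.05
        and by_gene[g].direction == "negative"
        for g in planted
    ]
    false_pos = [
        by_gene[g].tested and by_gene[g].qvalue < 0.05 for g in unplanted
    ]
    return {
        "n_interacting": int(len(planted)),
        "recovery_rate": float(np.mean(recovered)),
        "false_positive_rate": float(np.mean(false_pos)),
        "median_gi_planted": float(
            np.median([by_gene[g].gi_score for g in planted])
        ),
    }


def depth_limit_error(
    seed: int,
    n_genes: int = 50,
    n_controls: int = 20,
    depth_per_guide: int = 100_000,
) -> dict:
    """Growth-law consistency at high sequencing depth.

    At ~10^5 reads per guide sampling noise is negligible, so each guide's
    centered log2FC should match the closed form G · s · efficacy.  Reports
    the worst absolute deviation over all guides and both backgrounds.
    """
    sim = SimConfig(
        n_genes=n_genes,
        n_controls=n_controls,
        depth_per_guide=depth_per_guide,
        fitness_sd=0.05,
        frac_neutral=0.5,
        seed=seed,
    )
    annotation, counts, truth = simulate_paired_screens(sim)
    fitness = compute_fitness(counts, annotation)
    worst = 0.0
    n_checked = 0
    for bg in (REFERENCE, MUTANT):
        sub = fitness[(fitness.background == bg) & fitness.passed_filter]
        sub = sub.set_index("guide_id")
        expected = truth.expected_log2fc(bg, sim.generations)
        err = (sub["log2fc_centered"] - expected.loc[sub.index]).abs()
        worst = max(worst, float(err.max()))
        n_checked += len(err)
    return {"max_abs_error": worst, "n_guides_checked": n_checked}
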