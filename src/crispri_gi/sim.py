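"""Synthetic paired CRISPRi screens with planted genetic interactions.

The generator emulates a genome-wide knockdown screen run in two isogenic
backgrounds: a library of ~5 guides per gene plus non-targeting controls is
grown competitively for ~17 generations after dCas9 induction, and guide
abundances are read out by sequencing at the start and end timepoints, in
replicate.

The growth model is deterministic exponential competition: a guide with
per-generation fitness effect ``w`` changes abundance ∝ 2^(G·w) over G
generations, where ``w = s_gene(background) · efficacy`` and non-targeting
controls have ``w = 0``.  The only stochastic element is multinomial
sequencing sampling at each timepoint — the minimal noise model matching
what the downstream scoring assumes.  Gene effects are neutral for a
configurable majority and half-normal (deleterious) for the rest; a planted
subset of genes additionally carries an interaction delta, expressed only in
the mutant background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CrisprGiError
from .io import (
    BACKGROUNDS,
    END,
    MUTANT,
    RAW,
    REFERENCE,
    START,
    CountTable,
    GuideAnnotation,
    SampleMeta,
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a simulated paired screen.

    Defaults mirror the screen layout being emulated: five guides per gene,
    two replicates, and ~17 generations of competitive growth after
    induction.  ``depth_per_guide`` is the mean sequencing reads per guide;
    each sample receives ``depth_per_guide × n_guides`` reads in total.
    ``fitness_sd`` scales the per-generation fitness effects of the
    non-neutral genes (half-normal, deleterious); ``delta_effect`` is the
    per-generation interaction effect added in the mutant background for the
    planted ``frac_interacting`` fraction of genes.
    """

    n_genes: int
    guides_per_gene: int = 5
    n_controls: int = 100
    generations: float = 17.0
    replicates: int = 2
    depth_per_guide: int = 500
    fitness_sd: float = 0.05
    frac_neutral: float = 0.8
    frac_interacting: float = 0.0
    delta_effect: float = -0.15
    efficacy_range: tuple[float, float] = (0.6, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.guides_per_gene < 1:
            raise CrisprGiError("n_genes and guides_per_gene must be positive")
        if self.n_controls < 0:
            raise CrisprGiError("n_controls must be nonnegative")
        if self.generations < 0 or self.replicates < 1 or self.depth_per_guide < 1:
            raise CrisprGiError(
                "generations must be nonnegative; replicates and "
                "depth_per_guide must be positive"
            )
        if not 0.0 <= self.frac_interacting <= 1.0:
            raise CrisprGiError("frac_interacting must lie in [0, 1]")
        if not 0.0 <= self.frac_neutral <= 1.0:
            raise CrisprGiError("frac_neutral must lie in [0, 1]")
        lo, hi = self.efficacy_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise CrisprGiError("efficacy_range must satisfy 0 ≤ lo ≤ hi ≤ 1")
        if self.fitness_sd < 0:
            raise CrisprGiError("fitness_sd must be nonnegative")


@dataclass
class SimTruth:
    """Planted ground truth of a simulated screen.

    ``genes`` has one row per gene: per-generation fitness effect in each
    background (``s_ref``, ``s_mut``), their difference ``delta`` and the
    ``interacting`` flag.  ``efficacy`` maps each targeting guide to its
    knockdown efficacy in [0, 1]; control guides carry efficacy 0 and no
    effect.
    """

    genes: pd.DataFrame
    efficacy: pd.Series
    seed: int

    def expected_log2fc(self, background: str, generations: float) -> pd.Series:
        """Noise-free centered log2FC each guide converges to at high depth:
        G · s(background) · efficacy (0 for controls and absent genes)."""
        col = "s_ref" if background == REFERENCE else "s_mut"
        s = self.genes.set_index("gene")[col]
        gene_of = self.efficacy.index.to_series().map(self._guide_gene)
        return generations * gene_of.map(s).fillna(0.0) * self.efficacy

    @property
    def _guide_gene(self) -> pd.Series:
        return pd.Series(
            {g: g.rsplit("_", 1)[0] for g in self.efficacy.index}, dtype=object
        )


def _rng(seed: int, *key: int) -> np.random.Generator:
    # counter-based sub-streams: every sample / stage gets its own child
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def build_synthetic_library(config: SimConfig) -> tuple[GuideAnnotation, SimTruth]:
    """Draw the library layout, gene effects, interactions and efficacies."""
    width = max(4, len(str(config.n_genes)))
    genes = [f"gene{i + 1:0{width}d}" for i in range(config.n_genes)]
    rng = _rng(config.seed, 0)

    neutral = rng.random(config.n_genes) < config.frac_neutral
    s_ref = np.where(
        neutral, 0.0, -np.abs(rng.normal(0.0, config.fitness_sd, config.n_genes))
    )
    n_int = int(np.floor(config.frac_interacting * config.n_genes))
    interacting = np.zeros(config.n_genes, dtype=bool)
    interacting[rng.choice(config.n_genes, size=n_int, replace=False)] = True
    s_mut = np.where(interacting, s_ref + config.delta_effect, s_ref)
    delta = s_mut - s_ref  # exact fp identity; ≈ delta_effect where planted

    guide_ids, target_gene, is_control = [], [], []
    for g in genes:
        for j in range(config.guides_per_gene):
            guide_ids.append(f"{g}_{j + 1}")
            target_gene.append(g)
            is_control.append(False)
    for j in range(config.n_controls):
        guide_ids.append(f"control_{j + 1:04d}")
        target_gene.append(None)
        is_control.append(True)

    lo, hi = config.efficacy_range
    n_targeting = config.n_genes * config.guides_per_gene
    eff = np.concatenate(
        [rng.uniform(lo, hi, n_targeting), np.zeros(config.n_controls)]
    )

    annotation = GuideAnnotation(
        pd.DataFrame(
            {
                "guide_id": guide_ids,
                "target_gene": pd.Series(target_gene, dtype=object),
                "is_control": is_control,
            }
        )
    )
    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "gene": genes,
                "s_ref": s_ref,
                "s_mut": s_mut,
                "delta": delta,
                "interacting": interacting,
            }
        ),
        efficacy=pd.Series(eff, index=pd.Index(guide_ids, name="guide_id")),
        seed=config.seed,
    )
    return annotation, truth


def _guide_fitness(
    annotation: GuideAnnotation, truth: SimTruth, background: str
) -> np.ndarray:
    if background not in BACKGROUNDS:
        raise CrisprGiError(f"unknown background {background!r}")
    col = "s_ref" if background == REFERENCE else "s_mut"
    s = truth.genes.set_index("gene")[col]
    f = annotation.frame
    w = np.zeros(len(f))
    targeting = ~f["is_control"].to_numpy()
    gene_s = f.loc[targeting, "target_gene"].map(s).to_numpy(dtype=float)
    eff = truth.efficacy.loc[f.loc[targeting, "guide_id"]].to_numpy()
    w[targeting] = gene_s * eff
    return w


def simulate_growth(
    annotation: GuideAnnotation,
    truth: SimTruth,
    background: str,
    generations: float,
) -> pd.Series:
    """Relative guide abundances after competitive exponential growth.

    Starting from uniform initial abundance, guide i ends at abundance
    ∝ 2^(G · w_i) with w_i = s_gene(background) · efficacy_i (0 for
    controls); the returned vector sums to 1.
    """
    w = _guide_fitness(annotation, truth, background)
    logab = generations * w
    ab = np.exp2(logab - logab.max())  # stabilised before normalisation
    ab /= ab.sum()
    return pd.Series(ab, index=pd.Index(annotation.guide_ids, name="guide_id"))


def sample_sequencing(
    abundance: pd.Series, depth: int, seed: int
) -> pd.Series:
    """One multinomial sequencing draw of ``depth`` reads per guide.

    The multinomial size is ``depth × len(abundance)``; abundances must be a
    probability vector.
    """
    p = abundance.to_numpy(dtype=float)
    if depth < 1:
        raise CrisprGiError("depth must be ≥ 1")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise CrisprGiError("abundances must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth * len(p), p / p.sum())
    return pd.Series(counts, index=abundance.index)


def simulate_paired_screens(
    config: SimConfig,
) -> tuple[GuideAnnotation, CountTable, SimTruth]:
    """Full paired-screen simulation: library, growth, and sequencing.

    Produces one raw CountTable with 2 backgrounds × 2 timepoints ×
    ``replicates`` samples.  All randomness flows from ``config.seed``
    through per-sample counter-derived sub-seeds, so equal configs yield
    bitwise-identical output regardless of sample order.
    """
    annotation, truth = build_synthetic_library(config)
    n = len(annotation)
    initial = pd.Series(
        np.full(n, 1.0 / n), index=pd.Index(annotation.guide_ids, name="guide_id")
    )

    samples: list[SampleMeta] = []
    columns: dict[str, pd.Series] = {}
    idx = 0
    for background in BACKGROUNDS:
        grown = simulate_growth(annotation, truth, background, config.generations)
        for timepoint in (START, END):
            ab = initial if timepoint == START else grown
            for rep in range(1, config.replicates + 1):
                sid = f"{background}_{timepoint}_r{rep}"
                sub = _rng(config.seed, 1, idx)
                counts = pd.Series(
                    sub.multinomial(config.depth_per_guide * n, ab.to_numpy()),
                    index=ab.index,
                )
                samples.append(SampleMeta(sid, background, timepoint, rep))
                columns[sid] = counts
                idx += 1
    table = CountTable(pd.DataFrame(columns), samples, stage=RAW)
    return annotation, table, truth


def write_truth(truth: SimTruth, path) -> None:
    """Write the planted gene effects as TSV (gene, s_ref, s_mut, delta,
    interacting)."""
    out = truth.genes.copy()
    out["interacting"] = out["interacting"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")
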