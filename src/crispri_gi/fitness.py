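"""Per-guide fitness (log2 fold-change) from raw screen counts.

The processing chain is: per-sample normalization by sample size → pooling
of replicate columns → renormalization of the pooled columns → coverage
filter on the initial timepoint → log2FC with a +1 pseudocount → centering
on the median of the non-targeting controls.

    log2FC = log2( (norm_end + 1) / (norm_start + 1) )

Centering subtracts, per background, the median log2FC of the control
guides that pass the coverage filter, so that a fitness of 0 means "grows
like a cell carrying a non-targeting guide".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CrisprGiError, DataError
from .io import (
    END,
    MUTANT,
    NORMALIZED,
    RAW,
    REFERENCE,
    START,
    CountTable,
    GuideAnnotation,
    SampleMeta,
)

MEAN_DEPTH = "mean_depth"
PER_MILLION = "per_million"


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds.

    ``min_norm_reads``: guides with fewer normalized reads than this at the
    initial timepoint are discarded (strict ``<``).  ``fdr_threshold`` and
    the two GI-magnitude cutoffs define the hit tiers.  ``normalization_target``
    chooses the constant each column is scaled to: the mean raw column sum
    (keeps values on a read-count-like scale, so the read filter stays
    meaningful) or one million.
    """

    min_norm_reads: float = 100.0
    fdr_threshold: float = 0.05
    gi_tier1: float = 1.0
    gi_tier2: float = 2.0
    normalization_target: str = MEAN_DEPTH

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise CrisprGiError("fdr_threshold must lie in (0, 1)")
        if not 0.0 <= self.gi_tier1 <= self.gi_tier2:
            raise CrisprGiError("need 0 ≤ gi_tier1 ≤ gi_tier2")
        if self.min_norm_reads < 0:
            raise CrisprGiError("min_norm_reads must be nonnegative")
        if self.normalization_target not in (MEAN_DEPTH, PER_MILLION):
            raise CrisprGiError(
                f"unknown normalization target {self.normalization_target!r}"
            )


def _normalize(counts: pd.DataFrame, target_mode: str) -> pd.DataFrame:
    sums = counts.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise DataError(f"sample {zero.index[0]!r} has zero total reads")
    target = 1e6 if target_mode == PER_MILLION else float(sums.mean())
    return counts / sums * target


def normalize_and_pool(
    raw: CountTable, config: PipelineConfig | None = None
) -> CountTable:
    """Normalize each sample by size, pool replicates, renormalize.

    Output has one column per (background, timepoint), named
    ``{background}:{timepoint}``, with equal column sums.
    """
    config = config or PipelineConfig()
    if raw.stage != RAW:
        raise CrisprGiError("normalize_and_pool expects a raw-stage CountTable")
    norm = _normalize(raw.counts.astype(float), config.normalization_target)

    groups: dict[tuple[str, str], list[str]] = {}
    for s in raw.samples:
        groups.setdefault((s.background, s.timepoint), []).append(s.sample_id)

    order = [
        (bg, tp)
        for bg in (REFERENCE, MUTANT)
        for tp in (START, END)
        if (bg, tp) in groups
    ]
    pooled = pd.DataFrame(
        {f"{bg}:{tp}": norm[groups[(bg, tp)]].sum(axis=1) for bg, tp in order}
    )
    pooled = _normalize(pooled, config.normalization_target)
    samples = [SampleMeta(f"{bg}:{tp}", bg, tp, 1) for bg, tp in order]
    return CountTable(pooled, samples, stage=NORMALIZED)


def filter_guides(norm: CountTable, config: PipelineConfig) -> pd.DataFrame:
    """Coverage filter: per background, a guide passes iff its pooled
    normalized read count at the initial timepoint is ≥ ``min_norm_reads``
    (strictly fewer reads fail)."""
    backgrounds = sorted({s.background for s in norm.samples})
    out = {}
    for bg in backgrounds:
        start_col = f"{bg}:{START}"
        out[bg] = norm.counts[start_col] >= config.min_norm_reads
    return pd.DataFrame(out)


def guide_log2fc(norm: CountTable) -> pd.DataFrame:
    """Uncentered per-guide, per-background log2FC with +1 pseudocounts.

    Returns a long table: guide_id, background, norm_start, norm_end,
    log2fc_raw.
    """
    if norm.stage != NORMALIZED:
        raise CrisprGiError("guide_log2fc expects a normalized CountTable")
    backgrounds = [
        bg for bg in (REFERENCE, MUTANT) if f"{bg}:{START}" in norm.counts
    ]
    frames = []
    for bg in backgrounds:
        start = norm.counts[f"{bg}:{START}"]
        end = norm.counts[f"{bg}:{END}"]
        frames.append(
            pd.DataFrame(
                {
                    "guide_id": norm.counts.index,
                    "background": bg,
                    "norm_start": start.to_numpy(),
                    "norm_end": end.to_numpy(),
                    "log2fc_raw": np.log2(
                        (end.to_numpy() + 1.0) / (start.to_numpy() + 1.0)
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def center_on_controls(
    fitness: pd.DataFrame, annotation: GuideAnnotation
) -> pd.DataFrame:
    """Subtract, per background, the median raw log2FC of the non-targeting
    control guides passing the coverage filter.

    ``fitness`` must already carry a boolean ``passed_filter`` column.
    """
    controls = set(annotation.control_ids)
    out = fitness.copy()
    out["log2fc_centered"] = np.nan
    for bg, sub in fitness.groupby("background", sort=False):
        ok = sub["guide_id"].isin(controls) & sub["passed_filter"]
        if not ok.any():
            raise DataError(
                f"no control guides pass the filter in background {bg!r}"
            )
        shift = float(sub.loc[ok, "log2fc_raw"].median())
        mask = out["background"] == bg
        out.loc[mask, "log2fc_centered"] = out.loc[mask, "log2fc_raw"] - shift
    return out


def compute_fitness(
    raw: CountTable,
    annotation: GuideAnnotation,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Raw counts → centered fitness table (the full chain above).

    Returns the long table with columns guide_id, background, norm_start,
    norm_end, log2fc_raw, log2fc_centered, passed_filter.
    """
    config = config or PipelineConfig()
    norm = normalize_and_pool(raw, config)
    passed = filter_guides(norm, config)
    fit = guide_log2fc(norm)
    fit["passed_filter"] = [
        bool(passed.at[g, bg])
        for g, bg in zip(fit["guide_id"], fit["background"])
    ]
    return center_on_controls(fit, annotation)
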