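"""Gene-level genetic-interaction scoring between two screens.

For every guide passing the coverage filter in both backgrounds, the
difference of centered log2FC (mutant − reference) is computed and the
guides are ranked from the most negative difference (stronger fitness
defect in the mutant: synthetic sickness) to the most positive (suppression).
Per gene, the ranked membership list of its guides is tested with the exact
minimum-hypergeometric test in both orientations — enrichment at the
negative extreme and, on the reversed list, at the positive extreme — and
the smaller one-sided p-value is Bonferroni-doubled.  The genetic-interaction
(GI) score is the signed median of the gene's guide differences; hits are
tiered by FDR and |GI| magnitude.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import CrisprGiError
from .fitness import PipelineConfig
from .io import MUTANT, REFERENCE, GeneInteraction, GuideAnnotation
from .mhg import DEFAULT_MAX_CELLS, mhg_exact_pvalue

NEGATIVE = "negative"
POSITIVE = "positive"


def guide_delta(fitness: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-guide Δlog2FC (mutant − reference), ranked ascending.

    Only guides passing the filter in both backgrounds enter the ranking;
    the second return value reports every excluded guide with a reason.
    Ties are broken by guide_id for determinism.
    """
    required = {REFERENCE, MUTANT}
    present = set(fitness["background"])
    if not required <= present:
        raise CrisprGiError(
            f"both backgrounds required, found {sorted(present)}"
        )
    wide_fc = fitness.pivot(
        index="guide_id", columns="background", values="log2fc_centered"
    )
    wide_ok = fitness.pivot(
        index="guide_id", columns="background", values="passed_filter"
    )

    exclusions = []
    for gid in wide_fc.index:
        missing = [bg for bg in (REFERENCE, MUTANT) if pd.isna(wide_fc.at[gid, bg])]
        if missing:
            exclusions.append((gid, f"absent in {','.join(missing)}"))
            continue
        failed = [
            bg
            for bg in (REFERENCE, MUTANT)
            if not bool(wide_ok.at[gid, bg])
        ]
        if failed:
            exclusions.append((gid, f"failed filter in {','.join(failed)}"))
    excluded_ids = {g for g, _ in exclusions}

    keep = wide_fc.loc[[g for g in wide_fc.index if g not in excluded_ids]]
    delta = (keep[MUTANT] - keep[REFERENCE]).rename("delta").reset_index()
    delta = delta.sort_values(
        ["delta", "guide_id"], kind="stable", ignore_index=True
    )
    delta["rank"] = np.arange(1, len(delta) + 1)
    report = pd.DataFrame(exclusions, columns=["guide_id", "reason"])
    return delta, report


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise CrisprGiError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tie_aware_stat(
    pos: np.ndarray, N: int, B: int, allowed_n: np.ndarray
) -> float:
    """Minimum prefix tail over prefix lengths that do not split a block of
    tied delta values.

    ``pos`` holds the sorted 0-based ranks of the gene's guides and
    ``allowed_n`` the ascending prefix lengths lying on tie-block
    boundaries.  The tail can only fall when a labeled guide is appended,
    so the minimum is attained at the first allowed boundary at or after
    each label; with no ties every prefix is allowed and this reduces to
    the plain statistic.
    """
    if len(allowed_n) == 0:
        return 1.0
    idx = np.searchsorted(allowed_n, pos + 1, side="left")
    idx = idx[idx < len(allowed_n)]
    if len(idx) == 0:
        return 1.0
    cand = np.unique(allowed_n[idx])
    b = np.searchsorted(pos, cand, side="left")  # labels within prefix
    tails = hypergeom.sf(b - 1, N, B, cand)
    return min(float(tails.min()), 1.0)


def score_genes(
    delta: pd.DataFrame,
    annotation: GuideAnnotation,
    config: PipelineConfig | None = None,
    max_cells: int = DEFAULT_MAX_CELLS,
) -> list[GeneInteraction]:
    """Score every annotated gene on the ranked Δlog2FC list.

    Runs the exact mHG test on the ascending list (negative interactions)
    and on the reversed list (positive interactions); the reported p-value
    is min(1, 2·min(p_neg, p_pos)) and the direction is the smaller side
    (negative on ties).  Prefix cuts that would split a block of exactly
    tied deltas are disallowed, so an all-tied list carries no ranking
    signal (statistic 1).  Genes with no guide surviving the filters are
    returned untested with NaN statistics and are excluded from the FDR
    input.  q-values and hit tiers are filled in before returning.
    """
    config = config or PipelineConfig()
    if len(delta) == 0:
        raise CrisprGiError("empty delta table")
    N = len(delta)
    rank_of = pd.Series(
        np.arange(N), index=pd.Index(delta["guide_id"], name="guide_id")
    )
    delta_of = pd.Series(delta["delta"].to_numpy(), index=rank_of.index)
    # prefix lengths on tie-block boundaries, for each orientation
    dvals = delta["delta"].to_numpy()
    block_edge = np.flatnonzero(dvals[:-1] != dvals[1:])
    allowed_asc = block_edge + 1
    allowed_desc = np.sort(N - 1 - block_edge)

    results: list[GeneInteraction] = []
    cache: dict[tuple[float, int], float] = {}

    def exact(stat: float, B: int) -> float:
        key = (stat, B)
        if key not in cache:
            cache[key] = mhg_exact_pvalue(stat, N, B, max_cells=max_cells)
        return cache[key]

    for gene, guides in annotation.gene_to_guides().items():
        in_list = [g for g in guides if g in rank_of.index]
        B = len(in_list)
        if B == 0:
            results.append(GeneInteraction(gene=gene, n_guides=0, tested=False))
            continue
        pos = np.sort(rank_of.loc[in_list].to_numpy())
        gi = float(np.median(delta_of.loc[in_list].to_numpy()))

        stat_neg = _tie_aware_stat(pos, N, B, allowed_asc)
        stat_pos = _tie_aware_stat(np.sort(N - 1 - pos), N, B, allowed_desc)
        p_neg = exact(stat_neg, B)
        p_pos = exact(stat_pos, B)
        if p_neg <= p_pos:
            direction, stat, p_min = NEGATIVE, stat_neg, p_neg
        else:
            direction, stat, p_min = POSITIVE, stat_pos, p_pos
        results.append(
            GeneInteraction(
                gene=gene,
                n_guides=B,
                gi_score=gi,
                mhg_stat=stat,
                pvalue=min(1.0, 2.0 * p_min),
                direction=direction,
            )
        )

    tested = [r for r in results if r.tested]
    if tested:
        q = bh_adjust([max(r.pvalue, 1e-300) for r in tested])
        for r, qv in zip(tested, q):
            r.qvalue = float(qv)
    return classify_hits(results, config)


def classify_hits(
    results: list[GeneInteraction], config: PipelineConfig | None = None
) -> list[GeneInteraction]:
    """Assign hit tiers: tier2 when q < FDR threshold and |GI| exceeds the
    stringent cutoff, tier1 when it exceeds the permissive one."""
    config = config or PipelineConfig()
    for r in results:
        r.tier = "none"
        if not r.tested or math.isnan(r.qvalue):
            continue
        if r.qvalue < config.fdr_threshold:
            if abs(r.gi_score) > config.gi_tier2:
                r.tier = "tier2"
            elif abs(r.gi_score) > config.gi_tier1:
                r.tier = "tier1"
    return results
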