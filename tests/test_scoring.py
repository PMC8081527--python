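import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crispri_gi import (
    GuideAnnotation,
    PipelineConfig,
    GeneInteraction,
    bh_adjust,
    classify_hits,
    guide_delta,
    score_genes,
)


def fitness_frame(rows):
    """rows: (guide_id, background, centered, passed)."""
    return pd.DataFrame(
        rows, columns=["guide_id", "background", "log2fc_centered", "passed_filter"]
    )


class TestGuideDelta:
    def test_mutant_minus_reference(self):
        fit = fitness_frame(
            [("g1", "reference", -1.0, True), ("g1", "mutant", -3.0, True)]
        )
        delta, report = guide_delta(fit)
        assert delta.loc[0, "delta"] == pytest.approx(-2.0)
        assert report.empty

    def test_ties_rank_by_guide_id(self):
        fit = fitness_frame(
            [(g, bg, 0.0, True) for g in ("b", "a", "c") for bg in ("reference", "mutant")]
        )
        delta, _ = guide_delta(fit)
        assert delta["guide_id"].tolist() == ["a", "b", "c"]
        assert delta["rank"].tolist() == [1, 2, 3]

    def test_rank_is_ascending_permutation(self):
        fit = fitness_frame(
            [("g1", "reference", 0.0, True), ("g1", "mutant", 0.5, True),
             ("g2", "reference", 0.0, True), ("g2", "mutant", -2.0, True),
             ("g3", "reference", 0.0, True), ("g3", "mutant", 0.0, True)]
        )
        delta, _ = guide_delta(fit)
        by_guide = delta.set_index("guide_id")["rank"]
        assert by_guide.to_dict() == {"g1": 3, "g2": 1, "g3": 2}
        assert (delta["delta"].diff().dropna() >= 0).all()

    def test_filter_failures_reported_not_ranked(self):
        fit = fitness_frame(
            [("g1", "reference", -1.0, False), ("g1", "mutant", -3.0, True),
             ("g2", "reference", 0.0, True), ("g2", "mutant", 0.1, True)]
        )
        delta, report = guide_delta(fit)
        assert delta["guide_id"].tolist() == ["g2"]
        assert report.loc[0, "guide_id"] == "g1"
        assert "reference" in report.loc[0, "reason"]

    def test_guide_in_one_background_only_excluded(self):
        fit = fitness_frame(
            [("g1", "reference", -1.0, True),
             ("g2", "reference", 0.0, True), ("g2", "mutant", 0.1, True)]
        )
        delta, report = guide_delta(fit)
        assert "g1" not in set(delta["guide_id"])
        assert "absent" in report.loc[0, "reason"]


def annotation_for(genes: dict[str, list[str]], controls=()):
    rows = [
        (g, gene, False) for gene, guides in genes.items() for g in guides
    ] + [(c, None, True) for c in controls]
    return GuideAnnotation(
        pd.DataFrame(rows, columns=["guide_id", "target_gene", "is_control"]).astype(
            {"is_control": bool}
        )
    )


class TestScoreGenes:
    def build_fitness(self, deltas: dict[str, float]):
        rows = []
        for g, d in deltas.items():
            rows.append((g, "reference", 0.0, True))
            rows.append((g, "mutant", d, True))
        return fitness_frame(rows)

    def test_gi_score_is_median_delta(self):
        deltas = {"a_1": -2.0, "a_2": -1.5, "a_3": -3.0, "a_4": -2.5, "a_5": -1.0}
        deltas.update({f"x_{i}": 0.1 * i for i in range(1, 6)})
        ann = annotation_for(
            {"a": list(deltas)[:5], "x": list(deltas)[5:]}
        )
        delta, _ = guide_delta(self.build_fitness(deltas))
        res = {r.gene: r for r in score_genes(delta, ann)}
        assert res["a"].gi_score == pytest.approx(-2.0)
        assert res["a"].direction == "negative"
        assert res["a"].n_guides == 5

    def test_all_zero_deltas_give_p_one(self):
        deltas = {f"g{i}": 0.0 for i in range(10)}
        ann = annotation_for(
            {"a": [f"g{i}" for i in range(5)], "b": [f"g{i}" for i in range(5, 10)]}
        )
        delta, _ = guide_delta(self.build_fitness(deltas))
        for r in score_genes(delta, ann):
            assert r.pvalue == 1.0

    def test_extreme_gene_pvalue_matches_doubled_one_sided(self):
        """A gene whose guides occupy the top ranks gets exactly twice the
        one-sided exact p."""
        from crispri_gi import mhg_exact_pvalue, mhg_statistic

        deltas = {f"hit_{i}": -5.0 - 0.1 * i for i in range(1, 6)}
        deltas.update({f"bg_{i}": 0.001 * i for i in range(95)})
        ann = annotation_for(
            {"hit": [f"hit_{i}" for i in range(1, 6)],
             "bg0": [f"bg_{i}" for i in range(5)]}
        )
        delta, _ = guide_delta(self.build_fitness(deltas))
        res = {r.gene: r for r in score_genes(delta, ann)}
        labels = np.zeros(100, dtype=int)
        labels[:5] = 1
        stat, _ = mhg_statistic(labels)
        assert res["hit"].mhg_stat == pytest.approx(stat, rel=1e-12)
        assert res["hit"].pvalue == pytest.approx(
            2 * mhg_exact_pvalue(stat, 100, 5), rel=1e-12
        )

    def test_gene_with_no_surviving_guides_flagged(self):
        deltas = {f"g{i}": float(i) for i in range(5)}
        ann = annotation_for(
            {"a": [f"g{i}" for i in range(5)], "ghost": ["zz1", "zz2"]}
        )
        delta, _ = guide_delta(self.build_fitness(deltas))
        res = {r.gene: r for r in score_genes(delta, ann)}
        ghost = res["ghost"]
        assert not ghost.tested
        assert ghost.n_guides == 0
        assert math.isnan(ghost.pvalue) and math.isnan(ghost.qvalue)
        # untested genes do not enter the FDR input
        assert not math.isnan(res["a"].qvalue)

    def test_antisymmetry_under_background_swap(self, small_screen, small_fitness):
        """Relabeling the two screens negates deltas and GI scores and
        swaps every direction."""
        cfg, annotation, counts, truth = small_screen
        swapped = small_fitness.copy()
        swapped["background"] = swapped["background"].map(
            {"reference": "mutant", "mutant": "reference"}
        )
        d1, _ = guide_delta(small_fitness)
        d2, _ = guide_delta(swapped)
        m1 = d1.set_index("guide_id")["delta"]
        m2 = d2.set_index("guide_id")["delta"]
        assert np.allclose(m1.sort_index(), -m2.sort_index())
        r1 = {r.gene: r for r in score_genes(d1, annotation)}
        r2 = {r.gene: r for r in score_genes(d2, annotation)}
        for gene in r1:
            assert r1[gene].gi_score == pytest.approx(-r2[gene].gi_score)
            if r1[gene].pvalue < 0.5:  # direction meaningful only with signal
                assert r1[gene].direction != r2[gene].direction


class TestBHAdjust:
    def test_step_up_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    @given(
        st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=40)
    )
    @settings(max_examples=60, deadline=None)
    def test_dominates_p_and_preserves_order(self, ps):
        q = bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-15).all()
        assert (q <= 1.0 + 1e-15).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=25))
    @settings(max_examples=40, deadline=None)
    def test_matches_hand_rolled_step_up(self, ps):
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        want = np.empty(m)
        want[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), want, atol=1e-12)


class TestClassifyHits:
    def make(self, q, gi):
        return GeneInteraction(
            gene="g", n_guides=5, gi_score=gi, mhg_stat=0.01, pvalue=q,
            qvalue=q, direction="negative",
        )

    @pytest.mark.parametrize(
        "q,gi,tier",
        [
            (0.01, -2.5, "tier2"),
            (0.01, -1.5, "tier1"),
            (0.2, -3.0, "none"),
            (0.01, 2.5, "tier2"),  # magnitude, not sign
            (0.01, -0.5, "none"),
            (0.01, -2.0, "tier1"),  # boundary: strict >
        ],
    )
    def test_tiering(self, q, gi, tier):
        (r,) = classify_hits([self.make(q, gi)], PipelineConfig())
        assert r.tier == tier
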