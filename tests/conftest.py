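import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from crispri_gi import (
    CountTable,
    GuideAnnotation,
    SampleMeta,
    SimConfig,
    compute_fitness,
    simulate_paired_screens,
)


@pytest.fixture
def tiny_annotation():
    return GuideAnnotation(
        pd.DataFrame(
            {
                "guide_id": ["g1", "g2", "g3", "g4", "c1", "c2", "c3"],
                "target_gene": pd.Series(
                    ["geneA", "geneA", "geneB", "geneB", None, None, None],
                    dtype=object,
                ),
                "is_control": [False, False, False, False, True, True, True],
            }
        )
    )


def make_count_table(counts: dict[str, list], guides: list[str]) -> CountTable:
    """Raw CountTable from column dict; sample ids 'bg_tp_rN'."""
    samples = []
    for sid in counts:
        bg, tp, rep = sid.rsplit("_", 2)
        samples.append(SampleMeta(sid, bg, tp, int(rep[1:])))
    df = pd.DataFrame(counts, index=pd.Index(guides, name="guide_id"))
    return CountTable(df, samples, stage="raw")


@pytest.fixture(scope="session")
def small_screen():
    """One modest paired screen with planted interactions, shared across
    tests: 120 genes x 5 guides + 30 controls, 10% interacting."""
    cfg = SimConfig(
        n_genes=120,
        n_controls=30,
        depth_per_guide=5000,
        frac_interacting=0.1,
        delta_effect=-0.15,
        seed=20240917,
    )
    annotation, counts, truth = simulate_paired_screens(cfg)
    return cfg, annotation, counts, truth


@pytest.fixture(scope="session")
def small_fitness(small_screen):
    cfg, annotation, counts, truth = small_screen
    return compute_fitness(counts, annotation)
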