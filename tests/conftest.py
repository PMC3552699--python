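import numpy as np
import pandas as pd
import pytest

import pathclust as pc
from pathclust.quantify import SCALE_LOG2

# two plasma-like replicate measurement series used throughout the t-test
# tests; the first has visibly smaller spread than the second
SAMPLE_X = (30.02, 29.99, 30.11, 29.97, 30.01, 29.99)
SAMPLE_Y = (29.89, 29.93, 29.72, 29.98, 30.02, 29.98)


@pytest.fixture(scope="session")
def reference_distances():
    """Cohort-level distance-score matrix between the five subtypes."""
    from pathclust.datasets import load_reference_subtype_distances

    return load_reference_subtype_distances()


@pytest.fixture(scope="session")
def small_db():
    return pc.generate_pathway_db(
        n_pathways=12, size_range=(8, 20), overlap_fraction=0.1, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_db):
    """Compact two-subtype cohort with planted signal, for unit tests."""
    plan = pc.make_block_plan(
        small_db, seed=12, n_diff_per_subtype=10, pathways_per_group=3
    )
    design = pc.CohortDesign(
        n_healthy=10,
        subtype_counts={"LuminalA": 5, "BasalLike": 5},
        n_proteins=80,
        seed=13,
    )
    plan2 = pc.EffectPlan(
        effects={
            "LuminalA": plan.effects["LuminalA"],
            "BasalLike": plan.effects["BasalLike"],
        },
        active_pathways={
            "LuminalA": plan.active_pathways["LuminalA"],
            "BasalLike": plan.active_pathways["BasalLike"],
        },
    )
    matrix, annotation, truth = pc.generate_cohort(design, plan2)
    return matrix, annotation, truth


@pytest.fixture()
def log2_matrix():
    def make(values, columns=None):
        df = pd.DataFrame(values, columns=columns)
        df.index = [f"p{i}" for i in range(len(df))]
        df.attrs["scale"] = SCALE_LOG2
        return df

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
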