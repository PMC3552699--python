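"""Synthetic cohort and pathway-database generators: determinism, planted
structure, and consistency with the documented noise model."""

import numpy as np
import pytest

import pathclust as pc
from pathclust.pathways import write_gmt
from pathclust.simulate import DEFAULT_SUBTYPE_COUNTS


class TestGeneratePathwayDB:
    def test_zero_overlap_gives_disjoint_pathways(self):
        db = pc.generate_pathway_db(10, (5, 15), overlap_fraction=0.0, seed=3)
        names = db.names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                assert pc.jaccard(db[names[i]], db[names[j]]) == 0.0

    def test_same_seed_identical_gmt_bytes(self, tmp_path):
        paths = []
        for run in (1, 2):
            db = pc.generate_pathway_db(15, (5, 30), 0.3, seed=99)
            p = tmp_path / f"run{run}.gmt"
            write_gmt(db, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_mean_jaccard_matches_brute_force_oracle(self):
        db = pc.generate_pathway_db(50, (5, 40), overlap_fraction=0.3, seed=7)
        names = db.names
        package, oracle = [], []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = set(db[names[i]]), set(db[names[j]])
                oracle.append(len(a & b) / len(a | b))
                package.append(pc.jaccard(db[names[i]], db[names[j]]))
        assert np.mean(package) == pytest.approx(np.mean(oracle), abs=0.05)
        # overlap raises similarity above the disjoint baseline
        assert np.mean(oracle) > 0.0

    def test_overlap_fraction_is_monotone_in_expectation(self):
        means = []
        for frac in (0.0, 0.3, 0.6):
            db = pc.generate_pathway_db(30, (10, 20), frac, seed=5)
            names = db.names
            sims = [
                pc.jaccard(db[a], db[b])
                for i, a in enumerate(names)
                for b in names[i + 1 :]
            ]
            means.append(np.mean(sims))
        assert means[0] < means[1] < means[2]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            pc.generate_pathway_db(1, (5, 10), 0.1, seed=0)
        with pytest.raises(ValueError):
            pc.generate_pathway_db(5, (0, 10), 0.1, seed=0)
        with pytest.raises(ValueError):
            pc.generate_pathway_db(5, (5, 10), 1.0, seed=0)


class TestGenerateCohort:
    def test_default_design_matches_study_composition(self):
        plan = pc.EffectPlan(effects={})
        design = pc.CohortDesign(n_proteins=30, seed=1)
        matrix, ann, _ = pc.generate_cohort(design, plan)
        cancer = ann[ann["group"] == "cancer"]
        healthy = ann[ann["group"] == "healthy"]
        assert cancer["individual_id"].nunique() == 80
        assert healthy["individual_id"].nunique() == 80
        counts = (
            cancer.drop_duplicates("individual_id")["subtype"].value_counts().to_dict()
        )
        assert counts == DEFAULT_SUBTYPE_COUNTS
        assert matrix.shape == (30, 160 * design.n_replicates_per_sample)

    def test_zero_noise_zero_effect_columns_equal_baseline(self):
        plan = pc.EffectPlan(
            effects={}, sigma_individual=0.0, sigma_replicate=0.0, sigma_residual=0.0
        )
        design = pc.CohortDesign(
            n_healthy=3,
            subtype_counts={"LuminalA": 2},
            n_proteins=10,
            seed=2,
        )
        matrix, _, _ = pc.generate_cohort(design, plan)
        first = matrix.iloc[:, 0]
        assert np.allclose(matrix.to_numpy(), first.to_numpy()[:, None])

    def test_planted_effect_recovered_by_group_mean_oracle(self):
        """Mean difference (subtype minus healthy) recovers the planted
        +2 shift to within three standard errors, per protein."""
        n_diff, n_sub, n_h, reps = 50, 12, 12, 3
        effects = {"BasalLike": {f"F{i + 1:06d}": 2.0 for i in range(n_diff)}}
        plan = pc.EffectPlan(
            effects=effects,
            sigma_individual=0.0,
            sigma_replicate=0.0,
            sigma_residual=0.1,
        )
        design = pc.CohortDesign(
            n_healthy=n_h,
            subtype_counts={"BasalLike": n_sub},
            n_proteins=60,
            n_replicates_per_sample=reps,
            seed=8,
        )
        matrix, ann, _ = pc.generate_cohort(design, plan)
        ann_i = ann.set_index("sample_id")
        sub_cols = [c for c in matrix.columns if ann_i.loc[c, "subtype"] == "BasalLike"]
        h_cols = [c for c in matrix.columns if ann_i.loc[c, "group"] == "healthy"]
        diff = matrix[sub_cols].mean(axis=1) - matrix[h_cols].mean(axis=1)
        se = 0.1 * np.sqrt(1 / (n_sub * reps) + 1 / (n_h * reps))
        planted = list(effects["BasalLike"])
        assert (np.abs(diff.loc[planted] - 2.0) < 3 * se * np.sqrt(n_diff)).all()
        assert np.abs(diff.loc[planted] - 2.0).mean() < 3 * se

    def test_receptor_status_round_trips_to_true_label(self):
        plan = pc.EffectPlan(effects={})
        design = pc.CohortDesign(n_healthy=2, n_proteins=5, seed=3)
        _, ann, truth = pc.generate_cohort(design, plan)
        from pathclust.subtypes import ReceptorStatus, assign_subtype

        cancer = ann[ann["group"] == "cancer"].drop_duplicates("individual_id")
        for _, row in cancer.iterrows():
            derived = assign_subtype(
                ReceptorStatus(row["ER"], row["PR"], row["HER2"])
            ).value
            assert derived == truth.labels[row["individual_id"]]

    def test_bit_identical_across_runs(self):
        db = pc.generate_pathway_db(10, (5, 15), 0.2, seed=4)
        plan = pc.make_block_plan(db, seed=5, n_diff_per_subtype=5, pathways_per_group=3)
        design = pc.CohortDesign(n_healthy=4, n_proteins=120, seed=6)
        m1, a1, _ = pc.generate_cohort(design, plan)
        m2, a2, _ = pc.generate_cohort(design, plan)
        assert (m1.to_numpy() == m2.to_numpy()).all()
        assert a1.equals(a2)

    def test_random_dropout_blanks_requested_fraction(self):
        plan = pc.EffectPlan(effects={})
        design = pc.CohortDesign(n_healthy=10, n_proteins=100, seed=9)
        matrix, _, _ = pc.generate_cohort(design, plan, dropout_rate=0.1)
        frac = matrix.isna().to_numpy().mean()
        assert frac == pytest.approx(0.1, abs=0.02)
        with pytest.raises(ValueError, match="dropout"):
            pc.generate_cohort(design, plan, dropout_rate=1.5)

    def test_plan_subtype_absent_from_design_rejected(self):
        plan = pc.EffectPlan(effects={"HER2Plus": {"F000001": 1.0}})
        design = pc.CohortDesign(
            n_healthy=3, subtype_counts={"LuminalA": 2}, n_proteins=5, seed=0
        )
        with pytest.raises(ValueError, match="absent"):
            pc.generate_cohort(design, plan)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            pc.CohortDesign(n_healthy=0)
        with pytest.raises(ValueError):
            pc.CohortDesign(subtype_counts={"NotASubtype": 3})
        with pytest.raises(ValueError):
            pc.EffectPlan(effects={}, sigma_residual=-1.0)


class TestMakeBlockPlan:
    def test_pair_sharing_structure(self, small_db):
        plan = pc.make_block_plan(
            small_db, seed=1, n_diff_per_subtype=10, pathways_per_group=3
        )
        sets = {s: set(v) for s, v in plan.effects.items()}

        def overlap(a, b):
            return len(sets[a] & sets[b]) / 10

        assert overlap("LuminalA", "LuminalB") == pytest.approx(0.9)
        assert overlap("HER2Plus", "BasalLike") == pytest.approx(0.9)
        assert overlap("LuminalA", "HER2Plus") == pytest.approx(0.1)
        assert overlap("LuminalA", "Unknown") == 0.0

    def test_shared_proteins_share_signs(self, small_db):
        plan = pc.make_block_plan(
            small_db, seed=2, n_diff_per_subtype=10, pathways_per_group=3
        )
        for s1 in plan.effects:
            for s2 in plan.effects:
                for p in set(plan.effects[s1]) & set(plan.effects[s2]):
                    assert plan.effects[s1][p] == plan.effects[s2][p]

    def test_differential_proteins_are_pathway_members(self, small_db):
        plan = pc.make_block_plan(
            small_db, seed=3, n_diff_per_subtype=10, pathways_per_group=3
        )
        universe = small_db.proteins()
        for eff in plan.effects.values():
            assert set(eff) <= universe
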