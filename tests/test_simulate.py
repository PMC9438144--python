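import numpy as np
import pandas as pd
import pytest

import mirnanet as mn
from mirnanet.io import filter_interactions
from mirnanet.simulate import mirna_ids


class TestConfigValidation:
    def test_non_positive_dimensions_rejected(self):
        with pytest.raises(ValueError):
            mn.SimulationConfig(n_mirna=0)
        with pytest.raises(ValueError):
            mn.SimulationConfig(n_per_group={"healthy": 0, "interictal": 4})

    def test_dispersion_and_correlation_ranges(self):
        with pytest.raises(ValueError):
            mn.SimulationConfig(dispersion=0.0)
        with pytest.raises(ValueError):
            mn.SimulationConfig(pairing_correlation=1.0)

    def test_unknown_planted_id_rejected(self):
        cfg = mn.SimulationConfig(n_mirna=10, planted_de={"not-a-mirna": 1.0})
        with pytest.raises(ValueError, match="planted ids"):
            mn.simulate_counts(cfg)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        cfg = mn.SimulationConfig(n_mirna=50, n_gene=80, planted_de=mn.default_planted_effects(50, 5, 1), seed=9)
        cm1, d1, t1 = mn.simulate_counts(cfg)
        cm2, d2, t2 = mn.simulate_counts(cfg)
        np.testing.assert_array_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(d1.table, d2.table)
        assert t1.true_edges == t2.true_edges
        db1 = mn.simulate_interaction_db(cfg, t1)
        db2 = mn.simulate_interaction_db(cfg, t2)
        pd.testing.assert_frame_equal(db1, db2)
        m1 = mn.simulate_mrna_logfc(t1, seed=3)
        m2 = mn.simulate_mrna_logfc(t2, seed=3)
        pd.testing.assert_frame_equal(m1, m2)

    def test_different_seeds_differ(self):
        cfg_a = mn.SimulationConfig(n_mirna=50, n_gene=80, seed=1)
        cfg_b = mn.SimulationConfig(n_mirna=50, n_gene=80, seed=2)
        cm_a, _, _ = mn.simulate_counts(cfg_a)
        cm_b, _, _ = mn.simulate_counts(cfg_b)
        assert not np.array_equal(cm_a.counts, cm_b.counts)


class TestCounts:
    def test_design_structure(self, small_study):
        _, cm, design, _ = small_study
        assert design.samples_in("healthy") and design.samples_in("interictal") and design.samples_in("ictal")
        pairs = design.paired_samples()
        assert len(pairs) == len(design.samples_in("ictal"))
        assert cm.sample_ids == list(design.table["sample_id"])

    def test_planted_features_shift_group_means(self, two_group_study):
        _, cm, design, truth = two_group_study
        df = cm.to_frame()
        case = design.samples_in("interictal")
        control = design.samples_in("healthy")
        logcpm = np.log2(df / df.sum(axis=0) * 1e6 + 0.5)
        for fid, effect in truth.true_de_mirnas.items():
            observed = logcpm.loc[fid, case].mean() - logcpm.loc[fid, control].mean()
            assert np.sign(observed) == np.sign(effect)

    def test_paired_samples_positively_correlated(self):
        # strong pairing: within-patient residual log-ratios should correlate
        cfg = mn.SimulationConfig(
            n_mirna=400,
            n_per_group={"interictal": 12, "ictal": 12},
            planted_de={},
            pairing_correlation=0.8,
            sample_noise_sd=0.5,
            dispersion=0.05,
            seed=21,
        )
        cm, design, _ = mn.simulate_counts(cfg)
        df = np.log2(cm.to_frame() + 0.5)
        df = df - df.mean(axis=0)
        centered = df.sub(df.mean(axis=1), axis=0)
        pairs = design.paired_samples()
        within = np.mean([centered[i].corr(centered[r]) for _, i, r in pairs])
        others = np.mean(
            [centered[i].corr(centered[r2]) for _, i, _ in pairs for _, _, r2 in pairs if r2 != i][:20]
        )
        assert within > others + 0.2


class TestInteractionDB:
    def test_true_edges_pass_and_decoys_fail(self, small_study):
        cfg, _, _, truth = small_study
        records = mn.simulate_interaction_db(cfg, truth)
        recovered = filter_interactions(records)
        assert recovered == truth.true_edges

    def test_score_tier_construction(self, small_study):
        cfg, _, _, truth = small_study
        records = mn.simulate_interaction_db(cfg, truth)
        truth_keys = truth.true_edges
        is_true = records.apply(lambda r: (r["mirna_id"], r["gene_symbol"]) in truth_keys, axis=1)
        score_tier = records["source"] == "predicted_score"
        mirsvr_tier = records["source"] == "predicted_mirsvr"
        assert (records.loc[is_true & score_tier, "score"] > 80.0).all()
        assert (records.loc[is_true & mirsvr_tier, "score"] < -1.2).all()
        assert (records.loc[~is_true & score_tier, "score"] <= 80.0).all()
        decoy_mirsvr = records.loc[~is_true & mirsvr_tier, "score"]
        assert ((decoy_mirsvr > -1.2) & (decoy_mirsvr <= 0.0)).all()

    def test_requires_populated_truth(self, small_study):
        cfg, _, _, _ = small_study
        with pytest.raises(ValueError, match="no edges"):
            mn.simulate_interaction_db(cfg, mn.GroundTruth())


class TestMrnaLogFC:
    def test_flip_fraction_bounds(self, small_study):
        _, _, _, truth = small_study
        with pytest.raises(ValueError):
            mn.simulate_mrna_logfc(truth, flip_fraction=1.5)

    def test_signs_oppose_strengths_without_flips(self, small_study):
        _, _, _, truth = small_study
        mrna = mn.simulate_mrna_logfc(truth, flip_fraction=0.0, seed=5, n_background=0).set_index("gene")
        for gene, s in truth.true_node_strengths.items():
            if s != 0:
                assert np.sign(mrna.loc[gene, "log2fc"]) == -np.sign(s)

    def test_flip_fraction_convergence(self, small_study):
        _, _, _, truth = small_study
        n = sum(1 for s in truth.true_node_strengths.values() if s != 0)
        mrna = mn.simulate_mrna_logfc(truth, flip_fraction=0.4, seed=6, n_background=0).set_index("gene")
        consistent = sum(
            1
            for g, s in truth.true_node_strengths.items()
            if s != 0 and np.sign(mrna.loc[g, "log2fc"]) == -np.sign(s)
        )
        frac = consistent / n
        tol = 3 * np.sqrt(0.6 * 0.4 / n)
        assert abs(frac - 0.6) < tol


class TestGeneSets:
    def test_frequencies_straddle_cutoff(self, small_study):
        _, _, _, truth = small_study
        coll = mn.simulate_gene_sets(20, truth, seed=7)
        freqs = [gs.frequency for gs in coll]
        assert any(f < 0.15 for f in freqs) and any(f >= 0.15 for f in freqs)

    def test_general_term_removed_by_filter(self, small_study):
        _, _, _, truth = small_study
        coll = mn.simulate_gene_sets(10, truth, seed=8)
        universe = sorted(truth.true_node_strengths)
        query = {g for g, s in truth.true_node_strengths.items() if s > 0}
        table = mn.run_ora(query, universe, coll)
        filtered = mn.specificity_filter(table)
        assert set(filtered["term_id"]) == {
            gs.term_id for gs in coll if gs.frequency is not None and gs.frequency < 0.15
        }

    def test_disjoint_terms_give_p_one(self, small_study):
        _, _, _, truth = small_study
        from mirnanet.io import GeneSet, GeneSetCollection

        universe = sorted(truth.true_node_strengths) + ["X1", "X2", "X3"]
        coll = GeneSetCollection([GeneSet("T1", "disjoint", ["X1", "X2", "X3"])])
        query = set(list(truth.true_node_strengths)[:10])
        table = mn.run_ora(query, universe, coll)
        assert (table["p_hyper"] == 1.0).all()

    def test_needs_two_terms(self, small_study):
        _, _, _, truth = small_study
        with pytest.raises(ValueError):
            mn.simulate_gene_sets(1, truth)


class TestNullCalibration:
    def test_false_positive_rate_near_nominal(self):
        # small version of the calibration study: 10 null replicates, 8 vs 8
        from mirnanet.pipeline import _design_matrix

        sig = tot = 0
        for rep in range(10):
            cfg = mn.SimulationConfig(
                n_mirna=150, n_per_group={"healthy": 8, "interictal": 8}, planted_de={}, seed=500 + rep
            )
            cm, design, _ = mn.simulate_counts(cfg)
            expr = mn.normalize(cm, _design_matrix(design))
            de = mn.fit_moderated_de(expr, design, "interictal_vs_healthy")
            sig += int((de["p_raw"] < 0.05).sum())
            tot += len(de)
        rate = sig / tot
        tol = 3 * np.sqrt(0.05 * 0.95 / tot)
        assert abs(rate - 0.05) < tol


class TestPowerRecovery:
    def test_planted_de_mostly_recovered(self, two_group_study):
        from mirnanet.pipeline import _design_matrix

        cfg, cm, design, truth = two_group_study
        expr = mn.normalize(cm, _design_matrix(design))
        de = mn.fit_moderated_de(expr, design, "interictal_vs_healthy")
        recovered = set(mn.filter_de(de)["feature_id"]) & set(truth.true_de_mirnas)
        assert len(recovered) / len(truth.true_de_mirnas) >= 0.8
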