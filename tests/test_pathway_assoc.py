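import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycohub import pathway_assoc as pa
from glycohub.io import GeneSet, GeneSetCollection

from conftest import make_expression


class TestPathwayActivity:
    def test_single_gene_mean_is_identity(self, rng):
        expr = make_expression(rng.normal(size=(3, 8)))
        act = pa.pathway_activity(expr, ["g1"], method="mean")
        np.testing.assert_allclose(act.scores, expr.values.loc["g1"])

    def test_rank_one_eigengene_tracks_the_genes(self, rng):
        base = rng.normal(size=10)
        vals = np.vstack([base, 2 * base + 1])  # perfectly correlated pair
        expr = make_expression(vals)
        act = pa.pathway_activity(expr, ["g0", "g1"], method="eigengene")
        r = np.corrcoef(act.scores, expr.values.loc["g0"])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)
        assert act.scores.mean() == pytest.approx(0.0, abs=1e-10)

    def test_sign_alignment_under_global_flip(self, rng):
        vals = rng.normal(size=(4, 12))
        expr = make_expression(vals)
        act = pa.pathway_activity(expr, list(expr.genes), method="eigengene")
        flipped = make_expression(-vals)
        act_f = pa.pathway_activity(flipped, list(expr.genes), method="eigengene")
        # the alignment rule ties the score to the member mean in both cases
        r = np.corrcoef(act.scores, vals.mean(axis=0))[0, 1]
        r_f = np.corrcoef(act_f.scores, -vals.mean(axis=0))[0, 1]
        assert r >= 0 and r_f >= 0

    def test_eigengene_invariant_to_gene_order_and_constant_shift(self, rng):
        vals = rng.normal(size=(5, 15))
        e1 = pa.pathway_activity(
            make_expression(vals), [f"g{i}" for i in range(5)], method="eigengene"
        )
        shuffled = vals[::-1] + np.arange(5)[:, None]  # reorder + per-gene shift
        e2 = pa.pathway_activity(
            make_expression(shuffled, genes=[f"g{i}" for i in range(4, -1, -1)]),
            [f"g{i}" for i in range(5)],
            method="eigengene",
        )
        np.testing.assert_allclose(e1.scores, e2.scores, atol=1e-8)

    def test_absent_members_rejected(self, rng):
        expr = make_expression(rng.normal(size=(2, 6)))
        with pytest.raises(ValueError):
            pa.pathway_activity(expr, ["zz"], method="mean")


class TestEcmSignature:
    def test_token_matching(self):
        coll = GeneSetCollection(
            [
                GeneSet("NABA_ECM_GLYCOPROTEINS", "", ("a", "b")),
                GeneSet("REACTOME_COLLAGEN_FORMATION", "", ("b", "c")),
                GeneSet("KEGG_GLYCOLYSIS", "", ("d",)),
                GeneSet("GO_EXTRACELLULAR_STRUCTURE", "", ("e",)),
            ]
        )
        names, sig = pa.ecm_pathway_signature(coll)
        assert names == [
            "NABA_ECM_GLYCOPROTEINS",
            "REACTOME_COLLAGEN_FORMATION",
            "GO_EXTRACELLULAR_STRUCTURE",
        ]
        assert sig == ["a", "b", "c", "e"]

    def test_no_match_warns_empty(self):
        coll = GeneSetCollection([GeneSet("KEGG_GLYCOLYSIS", "", ("d",))])
        with pytest.warns(UserWarning):
            names, sig = pa.ecm_pathway_signature(coll)
        assert names == [] and sig == []


class TestPcaRegression:
    def test_perfect_association_hits_permutation_floor(self, rng):
        expr = make_expression(rng.normal(size=(10, 40)))
        members = [f"g{i}" for i in range(10)]
        from glycohub.pathway_assoc import _pc_scores, _standardize

        pc1 = _pc_scores(_standardize(expr.values.to_numpy()), 1)[:, 0]
        outcome = pd.Series(pc1, index=expr.sample_ids)
        p = pa.pca_regression_association(
            expr, outcome, members, n_perm=99, seed=0
        )
        assert p == pytest.approx(1 / 100)

    def test_null_outcome_pvalues_uniform(self, rng):
        ps = []
        for b in range(120):
            expr = make_expression(rng.normal(size=(6, 30)))
            outcome = pd.Series(rng.normal(size=30), index=expr.sample_ids)
            ps.append(
                pa.pca_regression_association(
                    expr, outcome, list(expr.genes), n_perm=49, seed=b
                )
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_driver_detected(self, rng):
        hits = 0
        for b in range(10):
            t = rng.normal(size=100)
            driver = t + 0.5 * rng.normal(size=(8, 100))
            expr = make_expression(driver)
            outcome = pd.Series(
                t + 0.5 * rng.normal(size=100), index=expr.sample_ids
            )
            p = pa.pca_regression_association(
                expr, outcome, list(expr.genes), n_perm=199, seed=b
            )
            hits += p < 0.01
        assert hits >= 9

    def test_excluded_genes_are_removed(self, rng):
        expr = make_expression(rng.normal(size=(4, 20)))
        outcome = pd.Series(rng.normal(size=20), index=expr.sample_ids)
        with pytest.raises(ValueError, match="predictor"):
            pa.pca_regression_association(
                expr, outcome, ["g0", "g1"], exclude=["g0", "g1"]
            )

    def test_too_few_samples_rejected(self, rng):
        expr = make_expression(rng.normal(size=(4, 2)))
        outcome = pd.Series(rng.normal(size=2), index=expr.sample_ids)
        with pytest.raises(ValueError, match="samples"):
            pa.pca_regression_association(expr, outcome, ["g0", "g1"])


class TestFisherCombine:
    def test_no_evidence_case(self):
        x2, df, p = pa.fisher_combine([1.0, 1.0, 1.0])
        assert x2 == 0.0 and p == 1.0 and df == 6

    def test_closed_form_even_df(self):
        # chi-square survival at df=4: e^(-x/2) (1 + x/2)
        x2, df, p = pa.fisher_combine([0.5, 0.5])
        assert x2 == pytest.approx(-4 * np.log(0.5), rel=1e-12)
        assert df == 4
        closed = np.exp(-x2 / 2) * (1 + x2 / 2)
        assert p == pytest.approx(closed, abs=1e-10)
        assert p == pytest.approx(0.59657, abs=5e-6)

    def test_order_invariance(self, rng):
        ps = rng.uniform(0.01, 1, size=6)
        _, _, p1 = pa.fisher_combine(ps)
        _, _, p2 = pa.fisher_combine(ps[::-1])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            _, _, p = pa.fisher_combine([0.0, 0.5])
        assert 0 < p < 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pa.fisher_combine([])


class TestGeneSignatureCorrelation:
    def test_gene_with_itself(self, rng):
        expr = make_expression(rng.normal(size=(3, 10)))
        out = pa.gene_signature_correlation(expr, "g0", "g0")
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_planted_correlation_in_fisher_band(self):
        from glycohub.synth import BulkSimSpec, CorrelatedPair, simulate_bulk

        spec = BulkSimSpec(
            n_cohorts=1, n_regions=1, n_per_arm=100, de_genes={}, hub=None,
            ecm_driver=None,
            correlated_pairs=[CorrelatedPair("GENE0000", "GENE0001", 0.9)],
            seed=12,
        )
        (expr,), _ = simulate_bulk(spec)
        out = pa.gene_signature_correlation(expr, "GENE0000", "GENE0001")
        z = np.arctanh(out["r"].iloc[0])
        half = 1.96 / np.sqrt(out["n"].iloc[0] - 3)
        assert np.arctanh(0.9) - half <= z <= np.arctanh(0.9) + half

    def test_independent_noise_p_uniform(self, rng):
        ps = []
        for b in range(150):
            expr = make_expression(rng.normal(size=(2, 100)))
            ps.append(pa.gene_signature_correlation(expr, "g0", "g1")["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_rejected(self):
        vals = np.vstack([np.ones(10), np.arange(10.0)])
        expr = make_expression(vals)
        with pytest.raises(ValueError, match="zero-variance"):
            pa.gene_signature_correlation(expr, "g0", "g1")

    def test_activity_partner(self, rng):
        expr = make_expression(rng.normal(size=(5, 12)))
        act = pa.pathway_activity(expr, ["g1", "g2"], method="mean")
        out = pa.gene_signature_correlation(expr, "g0", act)
        assert len(out) == 1 and -1 <= out["r"].iloc[0] <= 1


class TestSignatureEffectSummary:
    def _effects(self, gs, genes=None):
        genes = genes or [f"g{i}" for i in range(len(gs))]
        return pd.DataFrame(
            {"gene": genes, "cohort": "c1", "region": "r1", "g": gs,
             "se": [0.1] * len(gs)}
        )

    def test_constant_effects_have_zero_width(self):
        out = pa.signature_effect_summary(self._effects([0.5, 0.5, 0.5]),
                                          ["g0", "g1", "g2"])
        assert out["estimate"].iloc[0] == pytest.approx(0.5)
        assert out["hi"].iloc[0] == pytest.approx(out["lo"].iloc[0])

    def test_hand_arithmetic(self):
        out = pa.signature_effect_summary(self._effects([0.2, 0.4, 0.6]),
                                          ["g0", "g1", "g2"])
        assert out["estimate"].iloc[0] == pytest.approx(0.4)
        half = 1.96 * 0.2 / np.sqrt(3)
        assert out["hi"].iloc[0] == pytest.approx(0.4 + half)

    def test_single_gene_uses_its_se(self):
        out = pa.signature_effect_summary(self._effects([0.3]), ["g0"])
        assert out["hi"].iloc[0] == pytest.approx(0.3 + 1.96 * 0.1)

    def test_disjoint_signature_rejected(self):
        with pytest.raises(ValueError, match="no overlap"):
            pa.signature_effect_summary(self._effects([0.3]), ["nope"])
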