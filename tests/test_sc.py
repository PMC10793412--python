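import anndata as ad
import numpy as np
import pandas as pd
import pytest

from glycohub import enrich, sc, synth
from glycohub.sc import LrPair


def make_adata(counts, cell_types=None, conditions=None, genes=None):
    counts = np.asarray(counts, dtype=float)
    n_cells, n_genes = counts.shape
    return ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {
                "cell_type": cell_types or ["t1"] * n_cells,
                "condition": conditions or ["AD"] * n_cells,
            },
            index=[f"c{i}" for i in range(n_cells)],
        ),
        var=pd.DataFrame(index=genes or [f"g{i}" for i in range(n_genes)]),
    )


class TestNormalize:
    def test_direct_formula(self):
        adata = sc.normalize(make_adata([[10, 0]]), scale=1e4)
        np.testing.assert_allclose(
            adata.layers["lognorm"][0], [np.log1p(1e4), 0.0]
        )

    def test_depth_doubling_invariance(self):
        a = sc.normalize(make_adata([[3, 5, 2]]))
        b = sc.normalize(make_adata([[6, 10, 4]]))
        np.testing.assert_allclose(a.layers["lognorm"], b.layers["lognorm"])

    def test_within_cell_ordering_preserved(self, rng):
        counts = rng.poisson(5, size=(10, 20))
        counts[:, 0] += 1  # avoid zero-total cells
        adata = sc.normalize(make_adata(counts))
        for i in range(10):
            order_raw = np.argsort(counts[i], kind="mergesort")
            order_norm = np.argsort(adata.layers["lognorm"][i], kind="mergesort")
            np.testing.assert_array_equal(order_raw, order_norm)

    def test_zero_total_cell_names_barcode(self):
        with pytest.raises(ValueError, match="c1"):
            sc.normalize(make_adata([[1, 2], [0, 0]]))


class TestSelectHvg:
    def test_constant_gene_never_selected(self, rng):
        counts = rng.poisson(5, size=(50, 10))
        counts[:, 3] = 7  # constant gene
        adata = make_adata(counts)
        top = sc.select_hvg(adata, 9)
        assert "g3" not in top

    def test_deterministic(self, rng):
        counts = rng.poisson(4, size=(60, 30))
        adata = make_adata(counts)
        assert sc.select_hvg(adata, 10) == sc.select_hvg(adata, 10)

    def test_planted_high_dispersion_recovered(self):
        spec = synth.ScSimSpec(
            cell_types=("t1",), n_cells_per_type=400, n_genes=100,
            dispersion=50.0,
            dispersion_overrides={f"SGENE{i:04d}": 0.2 for i in range(10)},
            lr=None, module=None, seed=5,
        )
        adata, _ = synth.simulate_single_cell(spec)
        top = set(sc.select_hvg(adata, 10))
        planted = {f"SGENE{i:04d}" for i in range(10)}
        assert len(top & planted) >= 9

    def test_requesting_too_many_rejected(self, rng):
        adata = make_adata(rng.poisson(3, size=(5, 4)))
        with pytest.raises(ValueError):
            sc.select_hvg(adata, 10)


class TestCelltypeProfile:
    def test_type_restricted_expression(self):
        counts = [[5, 1], [3, 1], [0, 1], [0, 2]]
        adata = sc.normalize(
            make_adata(counts, cell_types=["T", "T", "U", "U"])
        )
        prof = sc.celltype_profile(adata, "g0")
        by = prof.set_index("cell_type")
        assert by.loc["T", "mean_norm"] > 0 and by.loc["U", "mean_norm"] == 0
        assert by.loc["U", "frac_detected"] == 0

    def test_fraction_bounds_and_saturation(self):
        adata = sc.normalize(make_adata([[2, 1], [5, 3]]))
        prof = sc.celltype_profile(adata, "g1")
        assert prof["frac_detected"].iloc[0] == 1.0

    def test_sender_elevated_ligand_tops_profile(self):
        adata, truth = synth.simulate_single_cell(synth.default_sc_spec(seed=3))
        sc.normalize(adata)
        prof = sc.celltype_profile(adata, truth["lr"]["ligand"]).set_index(
            "cell_type"
        )
        sender = truth["lr"]["sender"]
        others = prof.drop(index=sender)["mean_norm"]
        assert (prof.loc[sender, "mean_norm"] > others).all()

    def test_unknown_gene_rejected(self):
        adata = sc.normalize(make_adata([[1, 2]]))
        with pytest.raises(KeyError):
            sc.celltype_profile(adata, "zz")


class TestFindMarkers:
    def test_duplicated_groups_give_p_one(self, rng):
        counts = rng.poisson(5, size=(30, 20)) + 1
        doubled = np.vstack([counts, counts])
        adata = sc.normalize(
            make_adata(doubled, conditions=["AD"] * 30 + ["NCI"] * 30)
        )
        out = sc.find_markers(
            adata, "condition", "AD", "NCI", min_frac=0, min_abs_lfc=0
        )
        assert (out["p"] == 1.0).all()
        assert np.allclose(out["lfc"], 0.0)

    def test_swap_negates_lfc_keeps_p(self, rng):
        counts = rng.poisson(4, size=(40, 15)) + 1
        adata = sc.normalize(
            make_adata(counts, conditions=["AD"] * 20 + ["NCI"] * 20)
        )
        a = sc.find_markers(adata, "condition", "AD", "NCI", min_frac=0,
                            min_abs_lfc=0)
        b = sc.find_markers(adata, "condition", "NCI", "AD", min_frac=0,
                            min_abs_lfc=0)
        np.testing.assert_allclose(a["lfc"], -b["lfc"], atol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_planted_condition_fold_flagged(self):
        hits = 0
        for seed in range(5):
            spec = synth.ScSimSpec(
                cell_types=("t1",), n_cells_per_type=200, n_genes=100,
                condition_fold={"SGENE0000": 4.0}, lr=None, module=None,
                seed=seed,
            )
            adata, _ = synth.simulate_single_cell(spec)
            sc.normalize(adata)
            out = sc.find_markers(adata, "condition", "AD", "NCI")
            row = out[out["gene"] == "SGENE0000"]
            hits += (not row.empty) and row["q"].iloc[0] < 0.05
        assert hits == 5

    def test_agrees_with_shared_wilcoxon(self, rng):
        counts = rng.poisson(6, size=(24, 6)) + 1
        adata = sc.normalize(
            make_adata(counts, conditions=["AD"] * 12 + ["NCI"] * 12)
        )
        out = sc.find_markers(adata, "condition", "AD", "NCI", min_frac=0,
                              min_abs_lfc=0)
        norm = adata.layers["lognorm"]
        for _, row in out.iterrows():
            j = adata.var_names.get_loc(row["gene"])
            _, p = enrich.wilcoxon_rank_sum(norm[:12, j], norm[12:, j])
            assert row["p"] == p

    def test_empty_group_rejected(self, rng):
        adata = sc.normalize(make_adata(rng.poisson(3, size=(6, 4)) + 1))
        with pytest.raises(ValueError, match="empty group"):
            sc.find_markers(adata, "condition", "AD", "missing")


class TestEcmScoreMatrix:
    def test_log_transform_identities(self):
        ora = {
            "astro": pd.DataFrame({"set": ["NABA_ECM", "OTHER"], "q": [0.01, 0.5]}),
            "oligo": pd.DataFrame({"set": ["NABA_ECM"], "q": [1.0]}),
        }
        mat = sc.ecm_score_matrix(ora)
        assert mat.loc["astro", "NABA_ECM"] == pytest.approx(2.0)
        assert mat.loc["oligo", "NABA_ECM"] == 0.0
        assert "OTHER" not in mat.columns
        assert (mat.to_numpy() >= 0).all()

    def test_no_match_warns(self):
        with pytest.warns(UserWarning):
            mat = sc.ecm_score_matrix(
                {"astro": pd.DataFrame({"set": ["OTHER"], "q": [0.5]})}
            )
        assert mat.empty or mat.shape[1] == 0


class TestLigandReceptorScore:
    def _two_type_adata(self, lig_counts, rec_counts):
        # 2 sender cells then 2 receiver cells x genes (LIG, REC, filler)
        counts = np.array(
            [[lig_counts, 1, 5], [lig_counts, 1, 5], [1, rec_counts, 5],
             [1, rec_counts, 5]],
            dtype=float,
        )
        return sc.normalize(
            make_adata(
                counts,
                cell_types=["S", "S", "R", "R"],
                genes=["LIG", "REC", "F"],
            )
        )

    def test_absent_ligand_scores_zero(self):
        adata = self._two_type_adata(0, 10)
        out = sc.ligand_receptor_score(adata, [LrPair("LIG", ("REC",))], "S", "R")
        assert out["score"].iloc[0] == 0.0

    def test_exact_saturation_value(self):
        # lognorm means engineered to 1 via a synthetic layer
        adata = self._two_type_adata(5, 5)
        adata.layers["lognorm"] = np.array(
            [[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0]], dtype=float
        )
        out = sc.ligand_receptor_score(
            adata, [LrPair("LIG", ("REC",))], "S", "R", kh=0.5
        )
        assert out["score"].iloc[0] == pytest.approx(2 / 3)

    def test_score_monotone_in_ligand_and_bounded(self):
        scores = []
        for c in (1, 5, 20, 100):
            adata = self._two_type_adata(c, 10)
            out = sc.ligand_receptor_score(
                adata, [LrPair("LIG", ("REC",))], "S", "R"
            )
            scores.append(out["score"].iloc[0])
        assert all(np.diff(scores) > 0)
        assert all(0 <= s < 1 for s in scores)

    def test_multisubunit_geometric_mean(self):
        counts = np.array(
            [[9, 1, 1], [1, 4, 16]], dtype=float
        )
        adata = make_adata(counts, cell_types=["S", "R"],
                           genes=["LIG", "R1", "R2"])
        sc.normalize(adata)
        norm = adata.layers["lognorm"]
        expected_r = np.sqrt(norm[1, 1] * norm[1, 2])
        out = sc.ligand_receptor_score(
            adata, [LrPair("LIG", ("R1", "R2"))], "S", "R"
        )
        assert out["R"].iloc[0] == pytest.approx(expected_r)

    def test_missing_gene_skipped_with_warning(self):
        adata = self._two_type_adata(5, 5)
        with pytest.warns(UserWarning, match="missing"):
            out = sc.ligand_receptor_score(
                adata, [LrPair("LIG", ("NOPE",))], "S", "R"
            )
        assert out.empty

    def test_nonpositive_kh_rejected(self):
        adata = self._two_type_adata(5, 5)
        with pytest.raises(ValueError):
            sc.ligand_receptor_score(adata, [LrPair("LIG", ("REC",))], "S", "R",
                                     kh=0.0)


class TestInteractionPermutation:
    def test_planted_pair_hits_floor(self):
        spec = synth.ScSimSpec(
            cell_types=("astrocyte", "oligodendrocyte"), n_cells_per_type=200,
            n_genes=60, lr=synth.LrPlant(fold=5.0), module=None, seed=1,
        )
        adata, truth = synth.simulate_single_cell(spec)
        sc.normalize(adata)
        pair = LrPair(truth["lr"]["ligand"], tuple(truth["lr"]["receptors"]))
        score, p = sc.interaction_permutation_test(
            adata, pair, truth["lr"]["sender"], truth["lr"]["receiver"],
            n_perm=100, seed=0,
        )
        assert p == pytest.approx(1 / 101)
        assert score > 0

    def test_p_never_below_floor(self):
        spec = synth.ScSimSpec(
            cell_types=("a", "b"), n_cells_per_type=50, n_genes=30,
            lr=synth.LrPlant(sender="a", receiver="b", fold=1.0), module=None,
            seed=2,
        )
        adata, truth = synth.simulate_single_cell(spec)
        sc.normalize(adata)
        pair = LrPair(truth["lr"]["ligand"], tuple(truth["lr"]["receptors"]))
        _, p = sc.interaction_permutation_test(adata, pair, "a", "b", n_perm=20,
                                               seed=3)
        assert p >= 1 / 21

    def test_invalid_n_perm_rejected(self):
        spec = synth.ScSimSpec(cell_types=("a", "b"), n_cells_per_type=10,
                               n_genes=20,
                               lr=synth.LrPlant(sender="a", receiver="b"),
                               module=None, seed=0)
        adata, truth = synth.simulate_single_cell(spec)
        sc.normalize(adata)
        pair = LrPair(truth["lr"]["ligand"], tuple(truth["lr"]["receptors"]))
        with pytest.raises(ValueError):
            sc.interaction_permutation_test(adata, pair, "a", "b", n_perm=0)
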