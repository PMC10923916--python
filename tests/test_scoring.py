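import numpy as np
import pandas as pd
import pytest

import dspsig as ds
from dspsig.containers import CohortDataset, ExpressionMatrix, Scale

from conftest import toy_macrosig


def make_cohort(expr: pd.DataFrame):
    surv = pd.DataFrame(
        {"time": 10.0, "event": 1}, index=pd.Index(expr.columns, name="patient_id")
    )
    labels = pd.DataFrame(index=surv.index)
    return CohortDataset(ExpressionMatrix(expr, Scale.LOG2), surv, labels)


class TestSignatureScore:
    def test_single_gene_hand_value(self):
        cohort = make_cohort(pd.DataFrame({"p1": [1.0]}, index=["g"]))
        sig = toy_macrosig(["g"], p=[0.1], lfc=[1.0])
        scores, _ = ds.signature_score(cohort, sig, standardize=False)
        assert scores["p1"] == pytest.approx(1.0)  # -log10(0.1) * 1 * +1

    def test_sign_flip_antisymmetry(self):
        cohort = make_cohort(pd.DataFrame({"p1": [1.0]}, index=["g"]))
        sig = toy_macrosig(["g"], p=[0.1], lfc=[-1.0])
        scores, _ = ds.signature_score(cohort, sig, standardize=False)
        assert scores["p1"] == pytest.approx(-1.0)

    def test_three_gene_hand_case(self):
        # (p, I, x) = (0.01,+1,2), (0.1,-1,3), (0.001,+1,-1)
        #   -> 2*2 + 1*(-3) + 3*(-1) = -2
        cohort = make_cohort(
            pd.DataFrame({"p1": [2.0, 3.0, -1.0]}, index=["a", "b", "c"])
        )
        sig = toy_macrosig(["a", "b", "c"], p=[0.01, 0.1, 0.001], lfc=[1.0, -1.0, 1.0])
        scores, _ = ds.signature_score(cohort, sig, standardize=False)
        assert scores["p1"] == pytest.approx(-2.0)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(5, 1, (10, 12)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"p{j}" for j in range(12)],
        )
        cohort = make_cohort(expr)
        p = rng.uniform(0.001, 0.2, 10)
        lfc = rng.choice([-1.0, 1.0], 10)
        sig = toy_macrosig(expr.index, p=p, lfc=lfc)
        doubled = toy_macrosig(expr.index, p=p, lfc=lfc)
        doubled.entries["weight"] *= 2
        s1, _ = ds.signature_score(cohort, sig)
        s2, _ = ds.signature_score(cohort, doubled)
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-14)

    def test_invariant_to_gene_and_patient_order(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.normal(5, 1, (8, 10)),
            index=[f"g{i}" for i in range(8)],
            columns=[f"p{j}" for j in range(10)],
        )
        sig = toy_macrosig(expr.index, p=[0.01] * 8, lfc=rng.choice([-1.0, 1.0], 8))
        s1, _ = ds.signature_score(make_cohort(expr), sig)
        perm = expr.sample(frac=1, random_state=2)[rng.permutation(expr.columns)]
        s2, _ = ds.signature_score(make_cohort(perm), sig)
        pd.testing.assert_series_equal(s1.sort_index(), s2.sort_index())

    def test_standardize_removes_gene_level_shifts(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.normal(5, 1, (6, 9)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"p{j}" for j in range(9)],
        )
        sig = toy_macrosig(expr.index, p=[0.01] * 6, lfc=[1.0] * 6)
        s1, _ = ds.signature_score(make_cohort(expr), sig, standardize=True)
        shifted = expr.copy()
        shifted.loc["g2"] += 100.0
        s2, _ = ds.signature_score(make_cohort(shifted), sig, standardize=True)
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_insufficient_overlap_is_error(self):
        cohort = make_cohort(pd.DataFrame({"p1": [1.0]}, index=["g0"]))
        sig = toy_macrosig(["g0", "zz1", "zz2"], p=[0.01] * 3, lfc=[1.0] * 3)
        with pytest.raises(ValueError, match="missing"):
            ds.signature_score(cohort, sig)

    def test_zero_variance_gene_dropped_under_standardize(self, caplog):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            rng.normal(5, 1, (4, 8)),
            index=[f"g{i}" for i in range(4)],
            columns=[f"p{j}" for j in range(8)],
        )
        expr.loc["g0"] = 7.0
        sig = toy_macrosig(expr.index, p=[0.01] * 4, lfc=[1.0] * 4)
        with caplog.at_level("WARNING", logger="dspsig"):
            _, info = ds.signature_score(make_cohort(expr), sig, standardize=True)
        assert "g0" in info["genes_dropped"]


class TestTertileStratify:
    def test_nine_distinct_scores(self):
        scores = pd.Series(
            np.arange(1.0, 10.0), index=[f"p{i}" for i in range(1, 10)]
        )
        strat = ds.tertile_stratify(scores)
        assert strat.members("low") == ["p1", "p2", "p3"]
        assert strat.members("mid") == ["p4", "p5", "p6"]
        assert strat.members("high") == ["p7", "p8", "p9"]

    def test_identical_scores_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            ds.tertile_stratify(pd.Series([1.0] * 8))

    def test_too_few_patients_is_error(self):
        with pytest.raises(ValueError, match=">=6"):
            ds.tertile_stratify(pd.Series([1.0, 2, 3, 4, 5]))

    def test_matches_quantile_oracle(self):
        rng = np.random.default_rng(5)
        scores = pd.Series(rng.normal(size=10), index=[f"p{i}" for i in range(10)])
        strat = ds.tertile_stratify(scores)
        srt = np.sort(scores.to_numpy())
        q1 = np.quantile(srt, 1 / 3)
        q2 = np.quantile(srt, 2 / 3)
        for pat, row in strat.table.iterrows():
            expected = "low" if row["score"] <= q1 else ("high" if row["score"] > q2 else "mid")
            assert row["group"] == expected

    def test_negated_scores_swap_extremes(self):
        rng = np.random.default_rng(6)
        scores = pd.Series(rng.normal(size=12), index=[f"p{i}" for i in range(12)])
        a = ds.tertile_stratify(scores)
        b = ds.tertile_stratify(-scores)
        assert set(a.members("low")) == set(b.members("high"))
        assert set(a.members("high")) == set(b.members("low"))


class TestSCQC:
    def _cells(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(300)] + ["MT-1", "MT-2"]
        counts = pd.DataFrame(
            rng.poisson(2.0, (302, 5)),
            index=genes,
            columns=[f"c{i}" for i in range(5)],
        )
        counts += 1  # ensure all genes detected everywhere by default
        return counts

    def test_low_complexity_cell_removed(self):
        counts = self._cells()
        counts["c0"] = 0
        counts.loc[[f"g{i}" for i in range(150)], "c0"] = 5  # 150 detected genes
        out = ds.sc_qc_filter(
            ExpressionMatrix(counts, Scale.COUNTS), ["MT-1", "MT-2"]
        )
        assert "c0" not in out.sample_ids

    def test_high_mito_cell_removed(self):
        counts = self._cells()
        total = counts["c1"].sum()
        counts.loc["MT-1", "c1"] = int(0.12 * total / (1 - 0.12)) + 2  # ~12% mito
        out = ds.sc_qc_filter(
            ExpressionMatrix(counts, Scale.COUNTS), ["MT-1", "MT-2"]
        )
        assert "c1" not in out.sample_ids

    def test_rare_gene_removed(self):
        counts = self._cells()
        counts.loc["g0"] = 0
        counts.loc["g0", ["c0", "c1"]] = 3  # present in 2 cells only
        out = ds.sc_qc_filter(
            ExpressionMatrix(counts, Scale.COUNTS), ["MT-1", "MT-2"]
        )
        assert "g0" not in out.gene_ids

    def test_all_cells_removed_is_error(self):
        counts = self._cells() * 0
        with pytest.raises(ValueError, match="all cells"):
            ds.sc_qc_filter(ExpressionMatrix(counts, Scale.COUNTS), ["MT-1"])


class TestModuleScore:
    def _log_cells(self, rng, n_genes=400, n_cells=120):
        return ExpressionMatrix(
            pd.DataFrame(
                rng.normal(1.0, 0.5, (n_genes, n_cells)),
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"c{j}" for j in range(n_cells)],
            ),
            Scale.LOG2,
        )

    def test_null_scores_centered_at_zero(self):
        rng = np.random.default_rng(8)
        cells = self._log_cells(rng)
        sig = toy_macrosig([f"g{i}" for i in range(0, 400, 20)], p=[0.01] * 20, lfc=[1.0] * 20)
        res = ds.module_score(cells, sig, seed=0)
        se = res["score"].std() / np.sqrt(len(res))
        assert abs(res["score"].mean()) < 3 * se + 1e-3

    def test_expressing_call_uses_threshold(self):
        rng = np.random.default_rng(9)
        cells = self._log_cells(rng, n_genes=100, n_cells=10)
        sig = toy_macrosig([f"g{i}" for i in range(10)], p=[0.01] * 10, lfc=[1.0] * 10)
        res = ds.module_score(cells, sig, seed=0, threshold=0.1)
        pd.testing.assert_series_equal(
            res["expressing"], res["score"] > 0.1, check_names=False
        )

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(10)
        cells = self._log_cells(rng)
        sig = toy_macrosig([f"g{i}" for i in range(15)], p=[0.01] * 15, lfc=[1.0] * 15)
        r1 = ds.module_score(cells, sig, seed=3)
        r2 = ds.module_score(cells, sig, seed=3)
        pd.testing.assert_frame_equal(r1, r2)

    def test_planted_cluster_called_expressing(self):
        """Cells of the overexpressing cluster are called expressing
        (score > 0.1) and background cells mostly are not."""
        sig = toy_macrosig([f"m{i}" for i in range(25)], p=[0.01] * 25, lfc=[1.0] * 25)
        params = ds.SimParams(seed=12, n_genes=500, cells_per_cluster=150, lfc_magnitude=2.0)
        counts, labels = ds.simulate_single_cell(params, [sig])
        filtered = ds.sc_qc_filter(counts, [g for g in counts.gene_ids if g.startswith("MT-")],
                                   min_genes_per_cell=1)
        logged = ExpressionMatrix(np.log1p(
            filtered.data / filtered.data.sum(axis=0) * 1e4), Scale.LOG2)
        res = ds.module_score(logged, sig, seed=1)
        calls = res["expressing"].groupby(labels.reindex(res.index)).mean()
        assert calls["Sig"] >= 0.9
        assert calls["background"] <= 0.1
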