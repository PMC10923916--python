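import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dspsig as ds
from dspsig.containers import AOIAnnotation, DSPExperiment, ExpressionMatrix, Scale


def make_experiment(counts: pd.DataFrame, raw_reads=None, saturation=None, neg=None):
    n = counts.shape[1]
    raw_reads = raw_reads or [50000] * n
    saturation = saturation or [0.9] * n
    anns = [
        AOIAnnotation(
            aoi_id=c, roi_id=f"roi{i}", patient_id=f"p{i}", tissue="RLT",
            mask="CD68", region="GC", batch="B1",
            raw_reads=raw_reads[i], saturation=saturation[i],
        )
        for i, c in enumerate(counts.columns)
    ]
    if neg is None:
        neg = pd.DataFrame(1.0, index=["n1", "n2", "n3"], columns=counts.columns)
    return DSPExperiment(ExpressionMatrix(counts, Scale.COUNTS), anns, neg)


def counts_frame(values, columns=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=columns or [f"a{j}" for j in range(arr.shape[1])],
    )


class TestFilterAOIs:
    def test_read_and_saturation_boundaries(self):
        """'fewer than 10,000 reads' and 'saturation < 50%' are strict."""
        counts = counts_frame(np.full((10, 4), 50.0))
        exp = make_experiment(
            counts,
            raw_reads=[9999, 10000, 50000, 50000],
            saturation=[0.9, 0.9, 0.49, 0.5],
        )
        out = ds.filter_aois(exp)
        assert [a.aoi_id for a in out.annotations] == ["a1", "a3"]

    def test_low_detected_gene_fraction_removed(self):
        counts = counts_frame(np.full((100, 3), 10.0))
        counts.iloc[3:, 0] = 0  # AOI a0 detects 3% of genes
        exp = make_experiment(counts)
        out = ds.filter_aois(exp)
        assert "a0" not in out.counts.sample_ids

    def test_all_pass_identity(self):
        counts = counts_frame(np.full((10, 3), 5.0))
        exp = make_experiment(counts)
        out = ds.filter_aois(exp)
        pd.testing.assert_frame_equal(out.counts.data, exp.counts.data)

    def test_all_removed_is_error(self):
        counts = counts_frame(np.full((10, 2), 5.0))
        exp = make_experiment(counts, raw_reads=[100, 100])
        with pytest.raises(ValueError, match="empty experiment"):
            ds.filter_aois(exp)


class TestLOQ:
    def test_equal_probes_degenerate_spread(self):
        neg = pd.DataFrame(7.0, index=["n1", "n2", "n3"], columns=["a", "b"])
        loq = ds.compute_loq(neg, epsilon=0.5)
        np.testing.assert_allclose(loq, 7.5)

    def test_two_probe_hand_computation(self):
        neg = pd.DataFrame({"a": [1.0, 100.0]}, index=["n1", "n2"])
        loq = ds.compute_loq(neg, epsilon=0.0)
        logs = np.log([1.0, 100.0])
        expected = math.exp(logs.mean()) * math.exp(logs.std(ddof=1)) ** 2
        assert abs(loq["a"] - expected) < 1e-12

    def test_single_probe_is_error(self):
        neg = pd.DataFrame({"a": [1.0]}, index=["n1"])
        with pytest.raises(ValueError, match=">=2 negative probes"):
            ds.compute_loq(neg)

    def test_gene_filter_boundary_is_inclusive(self):
        """A gene above LOQ in exactly ceil(0.05*N) AOIs is retained."""
        n_aoi = 30
        k = math.ceil(0.05 * n_aoi)  # = 2
        counts = counts_frame(np.zeros((3, n_aoi)))
        counts.iloc[0, :] = 100.0  # above LOQ everywhere
        counts.iloc[1, :k] = 100.0  # above LOQ in exactly k AOIs
        counts.iloc[2, :] = 0.0  # never above
        exp = make_experiment(
            counts, neg=pd.DataFrame(1.0, index=["n1", "n2"], columns=counts.columns)
        )
        loq = ds.compute_loq(exp.neg_probes)
        out = ds.filter_genes_by_loq(exp, loq)
        assert out.counts.gene_ids == ["g0", "g1"]


class TestQ3Normalize:
    def test_identical_columns_unchanged(self):
        rng = np.random.default_rng(0)
        col = rng.lognormal(2, 1, 50)
        m = ExpressionMatrix(counts_frame(np.column_stack([col, col])), Scale.COUNTS)
        out = ds.q3_normalize(m)
        np.testing.assert_allclose(out.values, m.values, rtol=1e-14)

    def test_scaled_column_maps_to_same_output(self):
        rng = np.random.default_rng(1)
        col = rng.lognormal(2, 1, 40)
        m = ExpressionMatrix(
            counts_frame(np.column_stack([col, 2.0 * col])), Scale.COUNTS
        )
        out = ds.q3_normalize(m)
        np.testing.assert_array_equal(out.values[:, 0], out.values[:, 1])

    def test_toy_matrix_hand_computed(self):
        # 4 genes x 2 AOIs; type-7 quartiles computed by hand:
        # col a: sorted (1,2,3,4) -> Q3 at position 0.75*3=2.25 -> 3.25
        # col b: sorted (2,4,6,8) -> Q3 = 6.5
        m = ExpressionMatrix(
            counts_frame(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])),
            Scale.COUNTS,
        )
        out = ds.q3_normalize(m)
        geo = math.sqrt(3.25 * 6.5)
        expected = np.column_stack(
            [np.array([1, 2, 3, 4]) / 3.25 * geo, np.array([2, 4, 6, 8]) / 6.5 * geo]
        )
        np.testing.assert_allclose(out.values, expected, rtol=1e-14)

    def test_post_normalization_q3_equals_geomean(self):
        rng = np.random.default_rng(2)
        m = ExpressionMatrix(counts_frame(rng.lognormal(2, 1, (60, 5))), Scale.COUNTS)
        q3_in = np.quantile(m.values, 0.75, axis=0)
        out = ds.q3_normalize(m)
        q3_out = np.quantile(out.values, 0.75, axis=0)
        np.testing.assert_allclose(q3_out, np.exp(np.mean(np.log(q3_in))), rtol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_up_to_scale(self, seed):
        """Renormalizing a normalized matrix changes nothing: every Q3
        already equals the geometric mean."""
        rng = np.random.default_rng(seed)
        m = ExpressionMatrix(counts_frame(rng.lognormal(2, 1, (30, 4))), Scale.COUNTS)
        once = ds.q3_normalize(m)
        twice = ds.q3_normalize(ExpressionMatrix(once.data, Scale.COUNTS))
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_zero_q3_names_aoi(self):
        counts = counts_frame(np.zeros((4, 2)))
        counts.iloc[:, 1] = [1, 2, 3, 4]
        m = ExpressionMatrix(counts, Scale.COUNTS)
        with pytest.raises(ValueError, match="a0"):
            ds.q3_normalize(m)


class TestLogTransform:
    def test_known_values(self):
        m = ExpressionMatrix(counts_frame([[0.0], [3.0]]), Scale.Q3_NORMALIZED)
        out = ds.log_transform(m)
        np.testing.assert_array_equal(out.values.ravel(), [0.0, 2.0])

    def test_monotonicity_preserved(self):
        rng = np.random.default_rng(3)
        m = ExpressionMatrix(counts_frame(rng.lognormal(1, 2, (40, 3))), Scale.Q3_NORMALIZED)
        out = ds.log_transform(m)
        for j in range(3):
            assert (
                np.argsort(out.values[:, j], kind="stable")
                == np.argsort(m.values[:, j], kind="stable")
            ).all()


class TestRemoveBatchEffect:
    def _matrix(self, values):
        return ExpressionMatrix(counts_frame(values), Scale.LOG2)

    def test_single_batch_identity(self):
        rng = np.random.default_rng(4)
        m = self._matrix(rng.normal(5, 1, (10, 6)))
        batch = pd.Series("B1", index=m.sample_ids)
        masks = pd.Series("CD68", index=m.sample_ids)
        out = ds.remove_batch_effect(m, batch, masks)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_constant_shift_removed_exactly(self):
        rng = np.random.default_rng(5)
        base = rng.normal(5, 1, (8, 8))
        shifted = base.copy()
        batch = pd.Series(["B1"] * 4 + ["B2"] * 4)
        masks = pd.Series(["CD68", "CD68", "CD3", "CD3"] * 2)
        shifted[:, 4:] += 0.7
        m = self._matrix(shifted)
        m0 = self._matrix(base)
        batch.index = m.sample_ids
        masks.index = m.sample_ids
        out = ds.remove_batch_effect(m, batch, masks)
        out0 = ds.remove_batch_effect(m0, batch, masks)
        # the added constant is removed exactly: corrected(shifted) equals
        # corrected(base), so within-group means are restored
        np.testing.assert_allclose(out.values, out0.values, atol=1e-10)

    def test_matches_least_squares_residualization_oracle(self):
        rng = np.random.default_rng(6)
        n = 12
        m = self._matrix(rng.normal(0, 1, (15, n)))
        batch = pd.Series(rng.permutation(["B1"] * 6 + ["B2"] * 6), index=m.sample_ids)
        masks = pd.Series(rng.permutation(["CD68"] * 6 + ["CD20"] * 6), index=m.sample_ids)
        out = ds.remove_batch_effect(m, batch, masks)
        # oracle: per gene, OLS on [1, mask, batch] via pseudo-inverse, then
        # subtract the batch column's contribution
        x = np.column_stack(
            [
                np.ones(n),
                (masks == "CD68").astype(float),
                (batch == "B2").astype(float),
            ]
        )
        for gi in range(15):
            y = m.values[gi]
            beta = np.linalg.pinv(x) @ y
            expected = y - x[:, 2] * beta[2]
            np.testing.assert_allclose(out.values[gi], expected, atol=1e-9)

    def test_confounded_design_is_error(self):
        rng = np.random.default_rng(7)
        m = self._matrix(rng.normal(0, 1, (5, 6)))
        batch = pd.Series(["B1"] * 3 + ["B2"] * 3, index=m.sample_ids)
        masks = pd.Series(["CD68"] * 3 + ["CD20"] * 3, index=m.sample_ids)
        with pytest.raises(ValueError, match="confounded"):
            ds.remove_batch_effect(m, batch, masks)


class TestPCAOutliers:
    def test_identical_aois_not_flagged(self):
        m = ExpressionMatrix(counts_frame(np.ones((10, 5))), Scale.LOG2)
        assert not ds.pca_outlier_flags(m).any()

    def test_extreme_aoi_flagged(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 1, (20, 10))
        values[:, 0] += 50.0 * values.std()
        m = ExpressionMatrix(counts_frame(values), Scale.LOG2)
        flags = ds.pca_outlier_flags(m)
        assert flags["a0"]

    def test_infinite_k_flags_nothing(self):
        rng = np.random.default_rng(9)
        m = ExpressionMatrix(counts_frame(rng.normal(0, 1, (20, 8))), Scale.LOG2)
        assert not ds.pca_outlier_flags(m, k_mads=np.inf).any()

    def test_too_few_aois_is_error(self):
        m = ExpressionMatrix(counts_frame(np.ones((5, 2))), Scale.LOG2)
        with pytest.raises(ValueError, match=">=3"):
            ds.pca_outlier_flags(m)


def test_full_preprocess_rerun_is_noop(default_experiment):
    """Running the QC+LOQ filters again on already-filtered data keeps
    everything (the chain is a projection)."""
    exp_f, normalized, _, _ = ds.run_preprocess(default_experiment)
    again = ds.filter_aois(exp_f)
    loq = ds.compute_loq(again.neg_probes)
    again = ds.filter_genes_by_loq(again, loq)
    assert again.counts.shape == exp_f.counts.shape
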