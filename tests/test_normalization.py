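import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfnorm.correlation import spearman_rho
from pfnorm.data_model import LongTable, pivot_wide
from pfnorm.normalization import (
    DegenerateGroupError,
    NormalizationSpec,
    iqr_transform,
    normalize,
    partition_groups,
    proportion_transform,
    range_transform,
    z_transform,
)

from conftest import random_long_table

finite_vectors = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=3, max_size=40
)


class TestZTransform:
    def test_symmetric_triple(self):
        np.testing.assert_allclose(z_transform([1, 2, 3]), [-1, 0, 1])

    def test_moments_on_normal_draws(self):
        x = np.random.default_rng(0).normal(200, 40, size=1000)
        z = z_transform(x)
        assert abs(z.mean()) < 0.01
        assert abs(z.std(ddof=1) - 1) < 0.01

    @given(finite_vectors)
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, x):
        x = np.asarray(x)
        if np.std(x, ddof=1) <= 1e-9 * (1 + np.abs(x).max()):
            return
        np.testing.assert_allclose(z_transform(z_transform(x)), z_transform(x), atol=1e-9)

    def test_affine_equivariance(self):
        x = np.random.default_rng(1).normal(size=50)
        np.testing.assert_allclose(z_transform(3.5 * x + 11), z_transform(x), atol=1e-10)

    def test_clamp(self):
        x = np.concatenate([np.zeros(99), [1000.0]])
        z = z_transform(x, clamp=3.0)
        assert z.max() == 3.0 and z.min() >= -3.0

    def test_degenerate(self):
        with pytest.raises(DegenerateGroupError):
            z_transform([5.0, 5.0, 5.0])
        with pytest.raises(DegenerateGroupError):
            z_transform([5.0])


class TestRangeTransform:
    def test_unit_interval(self):
        np.testing.assert_allclose(range_transform([2, 4, 6], 0, 1), [0, 0.5, 1])

    def test_symmetric_interval(self):
        np.testing.assert_allclose(range_transform([2, 4, 6], -1, 1), [-1, 0, 1])

    def test_extremes_exact(self):
        x = np.random.default_rng(2).normal(size=100)
        y = range_transform(x, 0.25, 0.75)
        assert y.min() == 0.25 and y.max() == 0.75

    def test_idempotent(self):
        x = np.random.default_rng(3).normal(size=30)
        y = range_transform(x, -2, 5)
        np.testing.assert_allclose(range_transform(y, -2, 5), y, atol=1e-12)

    def test_degenerate_and_bad_bounds(self):
        with pytest.raises(DegenerateGroupError):
            range_transform([1.0, 1.0], 0, 1)
        with pytest.raises(ValueError):
            range_transform([1.0, 2.0], 1, 1)


class TestProportionTransform:
    def test_example(self):
        np.testing.assert_allclose(proportion_transform([1, 1, 2]), [0.25, 0.25, 0.5])

    @given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_positive_sums_to_one(self, x):
        assert proportion_transform(np.asarray(x)).sum() == pytest.approx(1.0)

    def test_negative_sum_warns_and_reverses(self):
        with pytest.warns(UserWarning, match="order-reversing"):
            y = proportion_transform([-1, -1, -2])
        np.testing.assert_allclose(y, [0.25, 0.25, 0.5])

    def test_zero_sum_degenerate(self):
        with pytest.raises(DegenerateGroupError):
            proportion_transform([-1.0, 1.0])


class TestIqrTransform:
    def test_hand_computed_five(self):
        np.testing.assert_allclose(iqr_transform([1, 2, 3, 4, 5]), [-1, -0.5, 0, 0.5, 1])

    def test_median_zero_iqr_one(self):
        x = np.random.default_rng(4).lognormal(size=201)
        y = iqr_transform(x)
        assert np.median(y) == pytest.approx(0.0, abs=1e-12)
        q1, q3 = np.percentile(y, [25, 75])
        assert q3 - q1 == pytest.approx(1.0)

    def test_idempotent(self):
        x = np.random.default_rng(5).normal(size=60)
        y = iqr_transform(x)
        np.testing.assert_allclose(iqr_transform(y), y, atol=1e-12)

    def test_affine_equivariance(self):
        x = np.random.default_rng(6).normal(size=50)
        np.testing.assert_allclose(iqr_transform(2.0 * x + 3), iqr_transform(x), atol=1e-12)

    def test_outlier_resistance_vs_range(self):
        rng = np.random.default_rng(7)
        x = rng.normal(100, 10, size=100)
        contaminated = x.copy()
        contaminated[0] = x[0] * 100
        d_iqr = np.abs(iqr_transform(contaminated)[1:] - iqr_transform(x)[1:]).max()
        d_range = np.abs(
            range_transform(contaminated, 0, 1)[1:] - range_transform(x, 0, 1)[1:]
        ).max()
        assert d_iqr < d_range

    def test_degenerate(self):
        with pytest.raises(DegenerateGroupError):
            iqr_transform([1.0] * 10)


class TestPartitionGroups:
    def test_counts_on_synthetic(self, demo_study):
        table, _ = demo_study
        per_attr = partition_groups(table, "per_attribute")
        assert len(per_attr) == 3 and all(len(v) == 60 for _, v in per_attr)
        per_tp = partition_groups(table, "per_timepoint")
        assert len(per_tp) == 3 and all(len(v) == 60 for _, v in per_tp)
        whole = partition_groups(table, "all")
        assert len(whole) == 1 and len(whole[0][1]) == 180

    @pytest.mark.parametrize("scope", ["all", "per_attribute", "per_timepoint"])
    def test_partition_property_random_tables(self, scope):
        rng = np.random.default_rng(8)
        for _ in range(25):
            t = random_long_table(rng)
            groups = partition_groups(t, scope)
            total = sum(len(v) for _, v in groups)
            assert total == len(t)
            pooled = np.sort(np.concatenate([v for _, v in groups]))
            np.testing.assert_array_equal(pooled, np.sort(t.df["value"].to_numpy()))


class TestNormalizeTable:
    def test_z_per_attribute_postcondition(self, demo_study):
        table, _ = demo_study
        out, _ = normalize(table, NormalizationSpec("z", "per_attribute"))
        for _, sub in out.df.groupby("attribute"):
            assert sub["value"].mean() == pytest.approx(0.0, abs=1e-10)
            assert sub["value"].std(ddof=1) == pytest.approx(1.0)

    def test_range_per_timepoint_postcondition(self, demo_study):
        table, _ = demo_study
        out, _ = normalize(table, NormalizationSpec("range", "per_timepoint"))
        for _, sub in out.df.groupby("timepoint", observed=True):
            assert sub["value"].min() == 0.0
            assert sub["value"].max() == 1.0

    def test_proportion_all_postcondition(self, demo_study):
        table, _ = demo_study
        out, _ = normalize(table, NormalizationSpec("proportion", "all"))
        assert out.df["value"].sum() == pytest.approx(1.0)

    def test_labels_unchanged(self, demo_study):
        table, _ = demo_study
        out, _ = normalize(table, NormalizationSpec("iqr", "per_attribute"))
        left = table.df[["patient_id", "timepoint", "attribute"]]
        right = out.df[["patient_id", "timepoint", "attribute"]]
        pd.testing.assert_frame_equal(
            left.reset_index(drop=True), right.reset_index(drop=True)
        )

    def test_report_group_statistics(self, demo_study):
        table, _ = demo_study
        _, report = normalize(table, NormalizationSpec("z", "per_attribute"))
        assert {g.key for g in report.groups} == set(table.attributes)
        for g in report.groups:
            assert g.minimum <= g.q1 <= g.median <= g.q3 <= g.maximum
            assert g.n == 60
        assert report.to_json()  # serializable

    def _with_constant_attr(self, table):
        const = pd.DataFrame(
            {
                "patient_id": table.patients,
                "timepoint": "S1",
                "attribute": "const",
                "value": 7.0,
            }
        )
        return LongTable(pd.concat([table.df, const]), timepoint_order=table.timepoint_order)

    def test_degenerate_skip_drops_group(self, demo_study):
        table = self._with_constant_attr(demo_study[0])
        out, report = normalize(table, NormalizationSpec("z", "per_attribute"))
        assert "const" not in out.attributes
        assert report.degenerate_groups == ["const"]
        assert any("degenerate" in w for w in report.warnings)

    def test_degenerate_zero_policy(self, demo_study):
        table = self._with_constant_attr(demo_study[0])
        out, _ = normalize(table, NormalizationSpec("z", "per_attribute", degenerate="zero"))
        vals = out.df.loc[out.df["attribute"] == "const", "value"]
        assert (vals == 0.0).all()

    def test_degenerate_error_policy(self, demo_study):
        table = self._with_constant_attr(demo_study[0])
        with pytest.raises(DegenerateGroupError, match="const"):
            normalize(table, NormalizationSpec("z", "per_attribute", degenerate="error"))

    @pytest.mark.parametrize("method", ["z", "range", "iqr", "proportion"])
    @pytest.mark.parametrize("scope", ["all", "per_attribute", "per_timepoint"])
    def test_rank_preservation_within_groups(self, demo_study, method, scope):
        # all demo values are positive, so proportion is increasing too
        table, _ = demo_study
        out, _ = normalize(table, NormalizationSpec(method, scope))
        merged = table.df.assign(normed=out.df["value"].to_numpy())
        if scope == "all":
            groups = [merged]
        else:
            key = "attribute" if scope == "per_attribute" else "timepoint"
            groups = [g for _, g in merged.groupby(key, observed=True)]
        for g in groups:
            order = np.argsort(g["value"].to_numpy(), kind="stable")
            assert np.all(np.diff(g["normed"].to_numpy()[order]) >= 0)


class TestSpearmanInvariance:
    @pytest.mark.parametrize("method", ["z", "range", "iqr"])
    def test_per_attribute_preserves_rho(self, demo_derived, method):
        w0 = pivot_wide(demo_derived)
        rho0 = spearman_rho(w0["PlatCt"], w0["MCF EXTEM"])
        out, _ = normalize(demo_derived, NormalizationSpec(method, "per_attribute"))
        w1 = pivot_wide(out)
        rho1 = spearman_rho(w1["PlatCt"], w1["MCF EXTEM"])
        assert abs(rho1 - rho0) < 1e-12

    def test_per_timepoint_destroys_rho(self, demo_derived):
        w0 = pivot_wide(demo_derived)
        rho0 = spearman_rho(w0["PlatCt"], w0["MCF EXTEM"])
        out, _ = normalize(demo_derived, NormalizationSpec("z", "per_timepoint"))
        w1 = pivot_wide(out)
        rho1 = spearman_rho(w1["PlatCt"], w1["MCF EXTEM"])
        assert abs(rho1 - rho0) > 0.1


class TestSpecValidation:
    def test_bad_method(self):
        with pytest.raises(ValueError, match="method"):
            NormalizationSpec("log", "all")

    def test_bad_scope(self):
        with pytest.raises(ValueError, match="scope"):
            NormalizationSpec("z", "per_patient")

    def test_bad_range(self):
        with pytest.raises(ValueError, match="range_lo"):
            NormalizationSpec("range", "all", range_lo=1.0, range_hi=0.0)

    def test_bad_clamp(self):
        with pytest.raises(ValueError, match="clamp_z"):
            NormalizationSpec("z", "all", clamp_z=-1.0)
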