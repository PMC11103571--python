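import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpquant.io_tables import AnnotationSet, ChannelAnnotation
from scpquant.normalization import (
    NormalizationError,
    PSMGroup,
    compute_ratios,
    compute_weights,
    log2_transform,
    normalize_protein_table,
    weighted_median,
)

from conftest import make_matrix, make_psm


def oracle_weighted_median(Xr, Fr, tol=1e-9):
    """Independent exhaustive search over every index k satisfying the
    two-sided cumulative-weight condition; returns the smallest valid k."""
    order = np.argsort(Xr, kind="stable")
    Xs = np.asarray(Xr)[order]
    W = np.asarray(Fr)[order]
    n = len(Xs)
    for k in range(n):
        if sum(W[:k]) <= 0.5 + tol and sum(W[k + 1:]) <= 0.5 + tol:
            return float(Xs[k])
    raise AssertionError("no valid k exists")


def group(X, R=None, P=None, T=None, channel_sums=None):
    X = np.asarray(X, dtype=float)
    n = len(X)
    return PSMGroup(
        protein_id="P1",
        channel=3,
        X=X,
        R=np.asarray(R, dtype=float) if R is not None else np.full(n, np.nan),
        P=np.asarray(P, dtype=float) if P is not None else np.ones(n),
        T=np.asarray(T, dtype=float) if T is not None else np.ones(n),
        channel_sums=np.asarray(channel_sums, dtype=float) if channel_sums is not None else np.ones(n),
    )


class TestComputeRatios:
    def test_reference_mode_exact_division(self):
        assert compute_ratios(group([4, 6], R=[2, 3]), "reference").tolist() == [2.0, 2.0]

    def test_channel_sum_mode(self):
        # one PSM with channel intensities [2, 2, 4]; target channel holds 4
        g = group([4], channel_sums=[8])
        assert compute_ratios(g, "channel_sum").tolist() == [0.5]

    def test_psm_sum_fractions(self):
        out = compute_ratios(group([1, 3]), "psm_sum")
        assert out.tolist() == [0.25, 0.75]

    def test_unknown_mode(self):
        with pytest.raises(NormalizationError, match="mode"):
            compute_ratios(group([1.0]), "bogus")

    def test_reference_mode_requires_positive_reference(self):
        with pytest.raises(NormalizationError, match="reference"):
            compute_ratios(group([1.0], R=[0.0]), "reference")

    def test_retained_drops_missing_target_and_bad_reference(self):
        g = group([1.0, np.nan, 3.0], R=[2.0, 2.0, np.nan])
        kept = g.retained("reference")
        assert kept.n == 1
        assert kept.X.tolist() == [1.0]
        # without reference mode only the missing target is dropped
        assert g.retained("psm_sum").n == 2


class TestComputeWeights:
    def test_sixteen_to_the_three_quarters(self):
        F, Fr = compute_weights(np.array([16.0]), np.array([1.0]))
        assert F.tolist() == [8.0]
        assert Fr.tolist() == [1.0]

    def test_symmetry(self):
        _, Fr = compute_weights(np.array([16.0, 16.0]), np.array([1.0, 1.0]))
        assert Fr.tolist() == [0.5, 0.5]

    def test_derived_two_psm_values(self):
        # F = [1^0.75, 3^0.75] = [1, 2.2795...]; normalize
        _, Fr = compute_weights(np.array([1.0, 3.0]), np.array([1.0, 1.0]))
        expected = np.array([1.0, 3.0**0.75])
        expected /= expected.sum()
        np.testing.assert_allclose(Fr, expected, rtol=1e-12)
        # frozen from the oracle: 1/(1 + 3^0.75) = 0.3049239, 3^0.75/(1 + 3^0.75) = 0.6950761
        np.testing.assert_allclose(Fr, [0.3049239, 0.6950761], atol=5e-7)

    def test_all_zero_products_fall_back_to_uniform(self):
        _, Fr = compute_weights(np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        assert Fr.tolist() == [0.5, 0.5]

    def test_missing_fill_time_falls_back_to_precursor(self):
        _, Fr = compute_weights(np.array([1.0, 3.0]), np.array([np.nan, np.nan]))
        expected = np.array([1.0, 3.0**0.75])
        expected /= expected.sum()
        np.testing.assert_allclose(Fr, expected, rtol=1e-12)

    def test_custom_exponent(self):
        F, _ = compute_weights(np.array([4.0]), np.array([1.0]), exponent=0.5)
        assert F.tolist() == [2.0]


class TestWeightedMedian:
    def test_classic_median(self):
        assert weighted_median([1, 2, 3], [1 / 3, 1 / 3, 1 / 3]) == 2

    def test_heavy_weight_at_smallest_ratio(self):
        assert weighted_median([3, 1, 2], [0.2, 0.6, 0.2]) == 1

    def test_single_element(self):
        assert weighted_median([7], [1.0]) == 7

    def test_empty_is_missing(self):
        assert np.isnan(weighted_median(np.empty(0), np.empty(0)))

    def test_bad_weight_sum_rejected(self):
        with pytest.raises(NormalizationError, match="sum to 1"):
            weighted_median([1, 2], [0.2, 0.2])

    def test_equal_weights_even_n_lower_median(self):
        # both middle elements satisfy the condition; smallest k wins
        assert weighted_median([10, 20, 30, 40], [0.25] * 4) == 20

    @given(
        st.integers(min_value=1, max_value=6).flatmap(
            lambda n: st.tuples(
                st.lists(st.floats(0.01, 100), min_size=n, max_size=n),
                st.lists(st.floats(0.01, 1), min_size=n, max_size=n),
            )
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_exhaustive_oracle(self, xw):
        X, W = xw
        W = np.asarray(W) / np.sum(W)
        assert weighted_median(X, W) == oracle_weighted_median(X, W)

    @given(
        st.integers(min_value=1, max_value=8).flatmap(
            lambda n: st.tuples(
                st.lists(st.floats(0.01, 100), min_size=n, max_size=n),
                st.lists(st.floats(0.01, 1), min_size=n, max_size=n),
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_within_range_and_permutation_invariant(self, xw):
        X, W = xw
        X = np.asarray(X)
        W = np.asarray(W) / np.sum(W)
        m = weighted_median(X, W)
        assert X.min() <= m <= X.max()
        perm = np.random.default_rng(0).permutation(len(X))
        assert weighted_median(X[perm], W[perm]) == m

    def test_equal_weights_reduce_to_classic_median_odd_n(self):
        rng = np.random.default_rng(5)
        for n in (1, 3, 5, 7):
            x = rng.normal(size=n)
            assert weighted_median(x, np.full(n, 1 / n)) == np.median(x)


def two_psm_annotation():
    return AnnotationSet(
        [
            ChannelAnnotation("b1", 0, "reference"),
            ChannelAnnotation("b1", 1, "single_cell", "t1"),
            ChannelAnnotation("b1", 2, "single_cell", "t2"),
        ]
    )


class TestNormalizeProteinTable:
    def test_single_psm_reference_mode(self):
        psms = [make_psm(reporters=[2.0, 4.0, 10.0])]
        m = normalize_protein_table(psms, two_psm_annotation())
        assert m.scale == "linear"
        assert m.data.loc["P1", "b1:1"] == 2.0
        assert m.data.loc["P1", "b1:2"] == 5.0

    def test_reference_and_carrier_columns_excluded(self):
        ann = AnnotationSet(
            [
                ChannelAnnotation("b1", 0, "carrier"),
                ChannelAnnotation("b1", 1, "reference"),
                ChannelAnnotation("b1", 2, "unused"),
                ChannelAnnotation("b1", 3, "single_cell", "t1"),
            ]
        )
        psms = [make_psm(reporters=[1000.0, 10.0, 1.0, 20.0])]
        m = normalize_protein_table(psms, ann)
        assert list(m.samples) == ["b1:3"]

    def test_control_channel_config(self):
        ann = AnnotationSet(
            [
                ChannelAnnotation("b1", 0, "reference"),
                ChannelAnnotation("b1", 1, "control"),
                ChannelAnnotation("b1", 2, "single_cell", "t1"),
            ]
        )
        psms = [make_psm(reporters=[10.0, 5.0, 20.0])]
        kept = normalize_protein_table(psms, ann, keep_control_channels=True)
        dropped = normalize_protein_table(psms, ann, keep_control_channels=False)
        assert "b1:1" in kept.samples
        assert "b1:1" not in dropped.samples

    def test_protein_absent_from_one_batch_is_half_missing(self):
        ann = AnnotationSet(
            [
                ChannelAnnotation("b1", 0, "reference"),
                ChannelAnnotation("b1", 1, "single_cell", "t1"),
                ChannelAnnotation("b2", 0, "reference"),
                ChannelAnnotation("b2", 1, "single_cell", "t1"),
            ]
        )
        psms = [make_psm(batch="b1", reporters=[2.0, 4.0])]
        m = normalize_protein_table(psms, ann)
        assert m.valid_fraction_per_protein()["P1"] == 0.5

    def test_equal_weight_tiebreak_picks_lower_ratio(self):
        # two PSMs, equal weights, ratios r1 < r2 -> lower ratio wins
        psms = [
            make_psm(reporters=[2.0, 4.0, 1.0], psm_id="a"),
            make_psm(reporters=[2.0, 6.0, 1.0], psm_id="b"),
        ]
        m = normalize_protein_table(psms, two_psm_annotation())
        assert m.data.loc["P1", "b1:1"] == 2.0

    def test_no_reference_channel_is_config_error(self):
        ann = AnnotationSet([ChannelAnnotation("b1", 0, "single_cell", "t1")])
        with pytest.raises(NormalizationError, match="reference"):
            normalize_protein_table([make_psm(reporters=[1.0])], ann, mode="reference")

    def test_channel_sum_mode_without_reference(self):
        ann = AnnotationSet(
            [
                ChannelAnnotation("b1", 0, "single_cell", "t1"),
                ChannelAnnotation("b1", 1, "single_cell", "t2"),
            ]
        )
        psms = [make_psm(reporters=[2.0, 6.0])]
        m = normalize_protein_table(psms, ann, mode="channel_sum")
        assert m.data.loc["P1", "b1:0"] == 0.25
        assert m.data.loc["P1", "b1:1"] == 0.75

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        reporters = rng.uniform(1, 100, size=(3, 3))
        psms = [make_psm(reporters=r, psm_id=str(i), precursor=float(10 + i)) for i, r in enumerate(reporters)]
        base = normalize_protein_table(psms, two_psm_annotation())
        scaled = [make_psm(reporters=r * 7.5, psm_id=str(i), precursor=float(10 + i)) for i, r in enumerate(reporters)]
        same = normalize_protein_table(scaled, two_psm_annotation())
        np.testing.assert_allclose(base.values(), same.values(), rtol=1e-12)


class TestLog2Transform:
    def test_values(self):
        m = log2_transform(make_matrix([[8.0, 1.0]], scale="linear"))
        assert m.data.iloc[0].tolist() == [3.0, 0.0]
        assert m.scale == "log2"

    def test_mask_preserved(self):
        m = log2_transform(make_matrix([[8.0, np.nan]], scale="linear"))
        assert np.isnan(m.data.iloc[0, 1])
        assert not m.mask.iloc[0, 0]

    def test_nonpositive_rejected(self):
        with pytest.raises(NormalizationError, match="positive"):
            log2_transform(make_matrix([[0.0]], scale="linear"))

    def test_double_transform_rejected(self):
        m = log2_transform(make_matrix([[2.0]], scale="linear"))
        with pytest.raises(NormalizationError):
            log2_transform(m)
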