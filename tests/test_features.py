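"""Ordinal contrasts, composition transforms and the M1-M22 registry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirdmi.features import (
    CONSTRUCTS,
    ConstructEncoder,
    OrthogonalPolynomialBasis,
    build_construct,
    fa_to_fat_proportion,
    orthogonal_contrasts,
    retained_fa_panel,
)
from mirdmi.records import fa_slug


class TestOrthogonalContrasts:
    def test_k2(self):
        np.testing.assert_allclose(orthogonal_contrasts(2),
                                   [[-1 / np.sqrt(2)], [1 / np.sqrt(2)]],
                                   atol=1e-12)

    def test_k3_linear_and_quadratic(self):
        M = orthogonal_contrasts(3)
        np.testing.assert_allclose(M[:, 0], np.array([-1, 0, 1]) / np.sqrt(2),
                                   atol=1e-12)
        np.testing.assert_allclose(M[:, 1], np.array([1, -2, 1]) / np.sqrt(6),
                                   atol=1e-12)

    @given(st.integers(min_value=2, max_value=50))
    @settings(max_examples=49, deadline=None)
    def test_orthonormal_and_centered(self, k):
        M = orthogonal_contrasts(k)
        assert M.shape == (k, k - 1)
        np.testing.assert_allclose(M.T @ M, np.eye(k - 1), atol=1e-10)
        np.testing.assert_allclose(M.sum(axis=0), 0, atol=1e-10)

    def test_k_below_2_raises(self):
        with pytest.raises(ValueError):
            orthogonal_contrasts(1)


class TestFunctionalEvaluation:
    def test_evaluate_reproduces_contrasts_at_nodes(self):
        for k in (3, 10, 43):
            basis = OrthogonalPolynomialBasis(np.arange(1, k + 1))
            np.testing.assert_allclose(basis.evaluate(np.arange(1, k + 1)),
                                       basis.contrasts(), atol=1e-12)

    def test_out_of_range_week_is_finite(self):
        basis = OrthogonalPolynomialBasis(np.arange(1, 24))  # weeks 1..23
        row = basis.evaluate([30.0])
        assert row.shape == (1, 22)
        assert np.all(np.isfinite(row))

    def test_degree_one_column_is_linear_everywhere(self):
        basis = OrthogonalPolynomialBasis(np.arange(1, 24))
        x = np.array([1.0, 12.0, 30.0, 40.0])
        col = basis.evaluate(x)[:, 0]
        slopes = np.diff(col) / np.diff(x)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)


class TestFatProportion:
    def test_examples(self):
        assert fa_to_fat_proportion(4.0, 4.0) == pytest.approx(100.0)
        assert fa_to_fat_proportion(0.4, 4.0) == pytest.approx(10.0)
        assert fa_to_fat_proportion(0.0, 4.0) == pytest.approx(0.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            fa_to_fat_proportion(0.4, 0.0)
        with pytest.raises(ValueError):
            fa_to_fat_proportion(-0.1, 4.0)


def test_retained_fa_panel_default_and_override():
    panel = retained_fa_panel()
    assert panel == ["C8:0", "C10:0", "C12:0", "C14:0", "C18:0", "C18:1 cis-9"]
    enc = ConstructEncoder("M3", fa_panel=["C8:0", "C10:0"])
    assert enc.fa_panel == ["C8:0", "C10:0"]


class TestConstructRegistry:
    def test_registry_shape(self):
        assert len(CONSTRUCTS) == 22
        assert CONSTRUCTS["M12"] == ("PRT", "MIR", "pBW")
        assert CONSTRUCTS["M19"] == ("PRT", "MIR", "MY", "pBW", "WOL", "pFA")
        assert CONSTRUCTS["M22"] == ("PRT", "MIR", "MY", "pBW", "WOL", "pFA", "pMC")

    def test_unknown_construct(self, small_cohort):
        records, _ = small_cohort
        with pytest.raises(KeyError):
            build_construct(records.head(20), "M23")


class TestBuildConstruct:
    def test_m5_single_column(self, small_cohort):
        records, _ = small_cohort
        fm = build_construct(records.head(50), "M5")
        assert fm.X.shape == (50, 1)
        np.testing.assert_allclose(fm.X[:, 0], records.head(50)["my"])

    def test_group_column_counts_add_up(self, cleaned_small):
        clean, _, _ = cleaned_small
        sub = clean.head(400)
        fm = build_construct(sub, "M22")
        n_weeks = sub["wol"].nunique()
        n_mir = sum(c.startswith("wn_") for c in sub.columns)
        expected = 2 + n_mir + 1 + 1 + (n_weeks - 1) + 6 + 3
        assert fm.X.shape[1] == expected
        for name, count in (("PRT", 2), ("MY", 1), ("pBW", 1),
                            ("WOL", n_weeks - 1), ("pFA", 6), ("pMC", 3),
                            ("MIR", n_mir)):
            assert len(fm.group_indices(name)) == count

    def test_parity_collapse_and_two_columns(self, small_cohort):
        records, _ = small_cohort
        sub = records.head(100).copy()
        sub["parity"] = [1, 2, 3, 5] * 25
        fm = build_construct(sub, "M2")
        assert fm.X.shape[1] == 2
        # parity 3 and 5 share one row of the contrast matrix
        rows = {p: fm.X[i] for i, p in enumerate(sub["parity"].head(4))}
        np.testing.assert_allclose(rows[3], fm.X[3])

    def test_single_parity_category_warns(self, small_cohort):
        records, _ = small_cohort
        sub = records.head(30).copy()
        sub["parity"] = 1
        with pytest.warns(UserWarning, match="single parity"):
            build_construct(sub, "M2")

    def test_parity_below_one_raises(self, small_cohort):
        records, _ = small_cohort
        sub = records.head(5).copy()
        sub["parity"] = 0
        with pytest.raises(ValueError):
            build_construct(sub, "M2")

    def test_row_permutation_equivariance(self, small_cohort):
        records, _ = small_cohort
        sub = records.head(60)
        enc = ConstructEncoder("M16").fit(sub)
        fm = enc.transform(sub)
        perm = np.random.default_rng(0).permutation(60)
        fm_p = enc.transform(sub.iloc[perm])
        np.testing.assert_allclose(fm_p.X, fm.X[perm])

    def test_wol_encoder_extrapolates_for_unseen_week(self, small_cohort):
        records, _ = small_cohort
        aus = records[records.country == "AUS"]           # weeks 6..23
        enc = ConstructEncoder("M6").fit(aus)
        can = records[records.country == "CAN"].head(200)  # weeks incl. <6
        fm = enc.transform(can)
        assert np.all(np.isfinite(fm.X))
        assert fm.X.shape[1] == aus["wol"].nunique() - 1
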