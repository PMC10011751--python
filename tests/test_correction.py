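"""Unit and property tests for the MEff correction core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meffpower.correction import (
    BlockSpec,
    CorrelationMatrix,
    CorrelationMatrixError,
    MeffResult,
    alpha_meff,
    block_matrix,
    bonferroni_alpha,
    closed_form_equicorrelated_spectrum,
    eigen_variance,
    equicorrelated_matrix,
    fwer_independent,
    lookup_table,
    mean_offdiag,
    meff,
    meff_from_eigenvalues,
    round_half_up,
    sidak_alpha,
)

# Published eigen-summary for six equicorrelated outcomes:
# r -> (eigen1, remaining eigenvalue, Var, MEff, AlphaMEff)
SIX_OUTCOME_TABLE = {
    0.0: (1.0, 1.0, 0.00, 6.0, 0.008),
    0.2: (2.0, 0.8, 0.24, 5.8, 0.009),
    0.4: (3.0, 0.6, 0.96, 5.2, 0.010),
    0.6: (4.0, 0.4, 2.16, 4.2, 0.012),
    0.8: (5.0, 0.2, 3.84, 2.8, 0.018),
    1.0: (6.0, 0.0, 6.00, 1.0, 0.050),
}


@pytest.mark.parametrize("r", sorted(SIX_OUTCOME_TABLE))
def test_six_outcome_eigen_summary(r):
    """Eigenvalues, their variance, MEff and the adjusted alpha reproduce the
    worked six-outcome example at the printed precision."""
    e1, erest, var, me, al = SIX_OUTCOME_TABLE[r]
    m = equicorrelated_matrix(6, r)
    ev = m.eigenvalues
    assert round_half_up(ev[0], 1) == e1
    assert all(round_half_up(e, 1) == erest for e in ev[1:])
    assert round_half_up(eigen_variance(m), 2) == var
    assert round_half_up(meff(m), 1) == me
    assert round_half_up(alpha_meff(m), 3) == al


def test_eigen_variance_uses_sample_denominator():
    """With r=.4 and k=6 the squared deviations sum to 4.8, so only the
    k-1 denominator yields the published 0.96 (4.8/6 = 0.80 would not)."""
    m = equicorrelated_matrix(6, 0.4)
    assert eigen_variance(m) == pytest.approx(0.96, abs=1e-10)
    assert np.var(m.eigenvalues, ddof=0) == pytest.approx(0.80, abs=1e-10)


@pytest.mark.parametrize(
    "k, r, expected_meff",
    [
        (6, 0.4, 5.2),
        (6, 1.0, 1.0),
        (5, 0.6, 3.56),  # 1 + 4*(1 - .36), the five-outcome worked case
    ],
)
def test_meff_examples(k, r, expected_meff):
    assert meff(equicorrelated_matrix(k, r)) == pytest.approx(expected_meff, abs=1e-9)


def test_eigenvalues_sum_to_k():
    for k, r in [(2, 0.9), (6, 0.4), (12, 0.75), (8, -0.1)]:
        m = equicorrelated_matrix(k, r)
        assert m.eigenvalues.sum() == pytest.approx(k, abs=1e-8)


@given(
    st.integers(min_value=2, max_value=12).flatmap(
        lambda k: st.tuples(
            st.just(k),
            st.floats(min_value=-1.0 / (k - 1) + 1e-6, max_value=1.0),
        )
    )
)
def test_equicorrelated_spectrum_matches_closed_form(k_r):
    """Numeric eigendecomposition agrees with the analytic spectrum
    {1+(k-1)r, (1-r) x (k-1)} to 1e-10."""
    k, r = k_r
    m = equicorrelated_matrix(k, r)
    expected = closed_form_equicorrelated_spectrum(k, r)
    np.testing.assert_allclose(m.eigenvalues, expected, atol=1e-10)


@pytest.mark.parametrize(
    "sizes, r",
    [((2, 2), 0.5), ((4, 4), 0.8), ((3, 2), 0.6), ((4, 4), 0.2), ((3, 3), 0.4)],
)
def test_block_matrix_spectrum_is_union_of_block_spectra(sizes, r):
    """With zero cross-block correlation the spectrum is the union of the
    blocks' equicorrelated spectra."""
    m = block_matrix(sizes, r)
    expected = np.sort(
        np.concatenate(
            [closed_form_equicorrelated_spectrum(b, r) for b in sizes]
        )
    )[::-1]
    np.testing.assert_allclose(m.eigenvalues, expected, atol=1e-10)


def test_block_matrix_examples():
    assert round_half_up(alpha_meff(block_matrix((4, 4), 0.5)), 3) == 0.007
    assert round_half_up(mean_offdiag(block_matrix((4, 4), 0.8)), 3) == 0.343
    identity = block_matrix((2, 2), 0.0)
    np.testing.assert_allclose(identity.values, np.eye(4))
    assert block_matrix(BlockSpec((2, 2), 0.5)).k == 4


@pytest.mark.parametrize(
    "builder, expected",
    [
        (lambda: block_matrix((4, 4), 0.2), 0.086),
        (lambda: equicorrelated_matrix(6, 0.4), 0.4),
        (lambda: block_matrix((2, 2), 0.5), 0.167),
    ],
)
def test_mean_offdiag(builder, expected):
    assert round_half_up(mean_offdiag(builder()), 3) == expected


# Published adjusted-alpha grid: mean correlation (rows) x suite size N2..N12.
LOOKUP_GRID = {
    0.0: (0.025, 0.017, 0.013, 0.010, 0.008, 0.007, 0.006, 0.006, 0.005, 0.005, 0.004),
    0.1: (0.025, 0.017, 0.013, 0.010, 0.008, 0.007, 0.006, 0.006, 0.005, 0.005, 0.004),
    0.2: (0.026, 0.017, 0.013, 0.010, 0.009, 0.007, 0.006, 0.006, 0.005, 0.005, 0.004),
    0.3: (0.026, 0.018, 0.013, 0.011, 0.009, 0.008, 0.007, 0.006, 0.005, 0.005, 0.005),
    0.4: (0.027, 0.019, 0.014, 0.011, 0.010, 0.008, 0.007, 0.006, 0.006, 0.005, 0.005),
    0.5: (0.029, 0.020, 0.015, 0.013, 0.011, 0.009, 0.008, 0.007, 0.006, 0.006, 0.005),
    0.6: (0.030, 0.022, 0.017, 0.014, 0.012, 0.010, 0.009, 0.008, 0.007, 0.007, 0.006),
    0.7: (0.033, 0.025, 0.020, 0.016, 0.014, 0.012, 0.011, 0.010, 0.009, 0.008, 0.008),
    0.8: (0.037, 0.029, 0.024, 0.020, 0.018, 0.016, 0.014, 0.013, 0.012, 0.011, 0.010),
    0.9: (0.042, 0.036, 0.032, 0.028, 0.026, 0.023, 0.021, 0.020, 0.018, 0.017, 0.016),
    1.0: (0.050, 0.050, 0.050, 0.050, 0.050, 0.050, 0.050, 0.050, 0.050, 0.050, 0.050),
}


def test_lookup_table_reproduces_published_grid():
    grid = lookup_table()
    assert list(grid.columns) == ["corr"] + [f"N{k}" for k in range(2, 13)]
    assert len(grid) == 11
    for _, row in grid.iterrows():
        expected = LOOKUP_GRID[round(row["corr"], 1)]
        for k, want in zip(range(2, 13), expected):
            assert row[f"N{k}"] == want, (row["corr"], k)


def test_lookup_table_unrounded_scales_linearly_in_alpha():
    g5 = lookup_table(nominal_alpha=0.05, rounded=False)
    g10 = lookup_table(nominal_alpha=0.10, rounded=False)
    np.testing.assert_allclose(
        g10.drop(columns="corr").to_numpy(),
        2 * g5.drop(columns="corr").to_numpy(),
        rtol=1e-12,
    )


def test_alpha_monotonicity_on_grid():
    """alpha_meff grows with correlation (fixed k) and shrinks with suite
    size (fixed r < 1)."""
    grid = lookup_table(rounded=False).set_index("corr")
    for k in range(2, 13):
        col = grid[f"N{k}"].to_numpy()
        assert np.all(np.diff(col) >= -1e-15)
    for r in grid.index:
        if r < 1.0:
            row = grid.loc[r, [f"N{k}" for k in range(2, 13)]].to_numpy(float)
            assert np.all(np.diff(row) <= 1e-15)


def test_alpha_bounds():
    """bonferroni <= alpha_meff <= nominal and bonferroni <= sidak <= nominal
    for every grid matrix; for moderately correlated outcomes the MEff alpha
    also clears the Sidak threshold."""
    for k in range(2, 13):
        assert bonferroni_alpha(k) <= sidak_alpha(k) <= 0.05
        for r in np.arange(0.0, 1.01, 0.1):
            a = alpha_meff(equicorrelated_matrix(k, r))
            assert bonferroni_alpha(k) - 1e-15 <= a <= 0.05 + 1e-15
            if r >= 0.2:
                assert a >= sidak_alpha(k)


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        (bonferroni_alpha, (12, 0.05), 0.004),
        (bonferroni_alpha, (1, 0.05), 0.050),
        (sidak_alpha, (4, 0.05), 0.013),
        (fwer_independent, (6, 0.05), 0.265),
        (fwer_independent, (1, 0.05), 0.050),
        (fwer_independent, (2, 0.5), 0.750),
    ],
)
def test_simple_alpha_formulas(fn, args, expected):
    assert round_half_up(fn(*args), 3) == expected


@pytest.mark.parametrize("start_r", [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
@pytest.mark.parametrize("k", [4, 6, 8])
def test_block_vs_uniform_alpha_agreement(start_r, k):
    """MEff is robust to correlation structure: a two-block matrix and the
    uniform matrix with the same mean off-diagonal give adjusted alphas
    within 0.002 of each other."""
    l2 = block_matrix((k // 2, k // 2), start_r)
    l1 = equicorrelated_matrix(k, mean_offdiag(l2))
    assert abs(alpha_meff(l2) - alpha_meff(l1)) <= 0.002


def test_meff_result_summary_layout():
    res = MeffResult.from_matrix(equicorrelated_matrix(6, 0.4))
    text = res.summary()
    assert "Eigen1" in text and "AlphaMEff" in text
    assert "3.0" in text and "0.96" in text and "5.2" in text and "0.010" in text
    assert res.k == 6
    assert res.alpha_meff == pytest.approx(0.05 / 5.2, abs=1e-12)


def test_meff_from_eigenvalues_matches_matrix_path():
    m = block_matrix((3, 3), 0.6)
    assert meff_from_eigenvalues(m.eigenvalues) == pytest.approx(meff(m), abs=1e-12)


class TestValidation:
    def test_asymmetric_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(CorrelationMatrixError, match="not symmetric"):
            CorrelationMatrix(a)

    def test_non_psd_rejected(self):
        a = np.full((3, 3), -0.9)
        np.fill_diagonal(a, 1.0)
        with pytest.raises(CorrelationMatrixError, match="positive semi-definite"):
            CorrelationMatrix(a)

    def test_bad_diagonal_rejected(self):
        a = np.eye(4) * 1.5
        with pytest.raises(CorrelationMatrixError, match="diagonal"):
            CorrelationMatrix(a)

    def test_single_outcome_rejected(self):
        with pytest.raises(CorrelationMatrixError, match="k >= 2"):
            CorrelationMatrix([[1.0]])

    def test_equicorrelated_r_outside_psd_range(self):
        with pytest.raises(CorrelationMatrixError):
            equicorrelated_matrix(4, -0.5)  # PSD needs r >= -1/3

    def test_invalid_block_sizes(self):
        with pytest.raises(CorrelationMatrixError):
            block_matrix((0, 3), 0.5)

    def test_bad_nominal_alpha(self):
        with pytest.raises(ValueError):
            alpha_meff(equicorrelated_matrix(3, 0.2), nominal_alpha=1.5)

    def test_nearly_symmetric_input_accepted(self):
        a = np.full((4, 4), 0.3)
        np.fill_diagonal(a, 1.0)
        a[0, 1] += 5e-7  # inside the symmetry tolerance
        m = CorrelationMatrix(a)
        assert np.allclose(m.values, m.values.T)


class TestCsvRoundTrip:
    def test_plain_grid(self, tmp_path):
        path = tmp_path / "m.csv"
        m = equicorrelated_matrix(4, 0.3)
        np.savetxt(path, m.values, delimiter=",")
        m2 = CorrelationMatrix.from_csv(path)
        np.testing.assert_allclose(m2.values, m.values, atol=1e-12)

    def test_named_header(self, tmp_path):
        path = tmp_path / "m.csv"
        m = CorrelationMatrix(
            equicorrelated_matrix(3, 0.5).values, names=["wm", "read", "vocab"]
        )
        m.to_csv(path)
        m2 = CorrelationMatrix.from_csv(path)
        assert m2.names == ["wm", "read", "vocab"]
        np.testing.assert_allclose(m2.values, m.values, atol=1e-12)

    def test_asymmetric_csv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1,0.5,0\n0.4,1,0\n0,0,1\n")
        with pytest.raises(CorrelationMatrixError, match="not symmetric"):
            CorrelationMatrix.from_csv(path)

    def test_non_numeric_cell_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,V1,V2\nV1,1,oops\nV2,0.2,1\n")
        with pytest.raises(CorrelationMatrixError):
            CorrelationMatrix.from_csv(path)


def test_round_half_up_ties_go_up():
    assert round_half_up(0.0125, 3) == 0.013
    assert round_half_up(0.0135, 3) == 0.014
    assert round_half_up(2.16, 2) == 2.16
    assert round_half_up(5.15, 1) == 5.2
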