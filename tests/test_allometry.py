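import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from foliar import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
    OLSLine,
    SMALine,
    UndefinedSlopeSignError,
    adjusted_r2,
    log10_pairs,
    ols_fit,
    sma_fit,
)


def normal_equations(x, y):
    """Independent OLS oracle: solve the 2x2 normal equations directly."""
    n = len(x)
    A = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return slope, intercept


def sma_loss(x, y, slope, intercept):
    """Sum of right-triangle areas between points and the line."""
    resid = y - intercept - slope * x
    return np.sum(resid**2) / (2.0 * abs(slope))


def sma_grid_oracle(x, y, center, half_width=0.05, step=1e-4):
    """Minimize the triangle-area loss over a dense slope grid."""
    grid = np.arange(center - half_width, center + half_width + step, step)
    losses = [
        sma_loss(x, y, b, y.mean() - b * x.mean()) for b in grid
    ]
    i = int(np.argmin(losses))
    assert 0 < i < len(grid) - 1, "grid minimum on boundary"
    return grid[i]


class TestOLS:
    def test_exact_line(self):
        fit = ols_fit([1, 2, 3], [3, 5, 7])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_zero_covariance(self):
        fit = ols_fit([0, 1, 2], [0, 1, 0])
        assert fit.slope == pytest.approx(0.0, abs=1e-14)
        assert fit.intercept == pytest.approx(1 / 3)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 50)
        y = 0.5 * x + rng.normal(0, 0.3, 50)
        fit = ols_fit(x, y)
        slope, intercept = normal_equations(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_slope_ci_brackets_slope(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, 30)
        fit = ols_fit(x, 2 * x + rng.normal(0, 0.5, 30))
        lo, hi = fit.slope_ci
        assert lo <= fit.slope <= hi

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            ols_fit([1, 2], [1, 2])
        with pytest.raises(DegenerateInputError):
            ols_fit([2, 2, 2], [1, 2, 3])
        with pytest.raises(InvalidInputError):
            ols_fit([1, 2, 3], [1, 2])


class TestSMA:
    def test_exact_proportionality(self):
        fit = sma_fit([1, 2, 3], [2, 4, 6])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.p_value == 0.0

    def test_slope_magnitude_and_sign(self):
        # sd(y) = 3 sd(x) with negative correlation -> slope -3
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 40)
        y = -3 * x + 5
        fit = sma_fit(x, y)
        assert fit.slope == pytest.approx(-3.0)
        assert np.sign(fit.slope) == np.sign(np.corrcoef(x, y)[0, 1])

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.uniform(1, 5, 40)
        y = 1.5 * x + rng.normal(0, 0.4, 40)
        fit = sma_fit(x, y)
        assert fit.slope == pytest.approx(
            sma_grid_oracle(x, y, fit.slope), abs=2e-4
        )

    def test_ci_brackets_slope(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 5, 25)
        fit = sma_fit(x, 2 * x + rng.normal(0, 0.5, 25))
        lo, hi = fit.slope_ci
        assert lo <= fit.slope <= hi

    def test_errors(self):
        with pytest.raises(DegenerateInputError):
            sma_fit([1, 1, 1], [1, 2, 3])
        with pytest.raises(DegenerateInputError):
            sma_fit([1, 2, 3], [4, 4, 4])
        with pytest.raises(UndefinedSlopeSignError):
            sma_fit([0, 1, 2], [0, 1, 0])  # exactly zero correlation


@pytest.mark.parametrize(
    "r2_raw,n,expected",
    [(1.0, 10, 1.0), (0.9, 12, 0.89), (0.0, 5, -1 / 3)],
)
def test_adjusted_r2(r2_raw, n, expected):
    assert adjusted_r2(r2_raw, n) == pytest.approx(expected)


def test_adjusted_r2_requires_n3():
    with pytest.raises(InsufficientDataError):
        adjusted_r2(0.5, 2)


class TestLog10Pairs:
    def test_basic(self):
        lx, ly = log10_pairs([1, 10, 100], [1, 1, 1])
        assert lx == pytest.approx([0, 1, 2])
        assert ly == pytest.approx([0, 0, 0])

    def test_reports_offending_index(self):
        with pytest.raises(InvalidInputError, match="index: 1"):
            log10_pairs([1, 2, 3], [5, 0, 3])

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            log10_pairs([2], [5, 3])


@settings(max_examples=40, derandomize=True)
@given(seed=st.integers(0, 2**16), slope=st.floats(0.2, 4), noise=st.floats(0.01, 0.5))
def test_sma_reciprocity_and_ols_relation(seed, slope, noise):
    rng = np.random.default_rng(seed)
    x = rng.uniform(1, 10, 30)
    y = slope * x + rng.normal(0, noise, 30)
    forward = sma_fit(x, y).slope
    backward = sma_fit(y, x).slope
    assert forward == pytest.approx(1.0 / backward, abs=1e-10)
    # |SMA| is the geometric mean of |OLS(y~x)| and 1/|OLS(x~y)|
    b_yx = ols_fit(x, y).slope
    b_xy = ols_fit(y, x).slope
    assert abs(forward) == pytest.approx(np.sqrt(abs(b_yx) / abs(b_xy)), rel=1e-10)


@settings(max_examples=30, derandomize=True)
@given(seed=st.integers(0, 2**16), c=st.floats(0.1, 100))
def test_log_scale_shift_equivariance(seed, c):
    rng = np.random.default_rng(seed)
    x = rng.uniform(1, 10, 25)
    y = x**1.7 * 10 ** rng.normal(0, 0.05, 25)
    base = ols_fit(*log10_pairs(x, y))
    shifted = ols_fit(*log10_pairs(c * x, y))
    assert shifted.slope == pytest.approx(base.slope, abs=1e-10)
    assert shifted.intercept == pytest.approx(
        base.intercept - base.slope * np.log10(c), abs=1e-9
    )


class TestEstimators:
    def test_ols_line_fit_predict(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        est = OLSLine().fit(x.reshape(-1, 1), 3 * x + 1)
        assert est.slope_ == pytest.approx(3.0)
        assert est.predict(np.array([[10.0]])) == pytest.approx([31.0])

    def test_log10_scale_is_a_power_law(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        est = SMALine(scale="log10").fit(x, x**2.5)
        assert est.slope_ == pytest.approx(2.5)
        assert est.predict(np.array([3.0])) == pytest.approx([3.0**2.5])

    def test_params_and_clone(self):
        est = SMALine(scale="log10")
        assert est.get_params() == {"scale": "log10"}
        assert clone(est).get_params() == {"scale": "log10"}
        est.set_params(scale="linear")
        assert est.scale == "linear"

    def test_matches_function_surface(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 5, 20)
        y = 2 * x + rng.normal(0, 0.2, 20)
        assert OLSLine().fit(x, y).result_ == ols_fit(x, y)
        assert SMALine().fit(x, y).result_ == sma_fit(x, y)
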