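"""Variance decomposition by interaction order and global epistasis."""

import math

import numpy as np
import pytest

from combiplate.epistasis import (
    epistasis_fits_table,
    epistasis_null,
    global_epistasis_fit,
    mean_r_squared,
    reconstruct_from_walsh,
    variance_by_order,
    walsh_coefficients,
)
from combiplate.errors import ValidationError
from combiplate.landscape import FunctionLandscape
from combiplate.synth import (
    LandscapeGeneratorConfig,
    generate_landscape,
    global_epistasis_coefficients,
    random_coefficients,
    singleton_coefficients,
    walsh_character,
)


def mean_landscape(means: np.ndarray, m: int) -> FunctionLandscape:
    return FunctionLandscape(m, {i: np.array([v]) for i, v in enumerate(means)})


# ---------------------------------------------------------------------------
# Independent oracles


def walsh_oracle(values: np.ndarray, m: int) -> np.ndarray:
    """Coefficients by explicit ±1 character enumeration (no Hadamard matrix)."""
    n = 1 << m
    out = np.zeros(n)
    for subset in range(n):
        acc = 0.0
        for c in range(n):
            acc += values[c] * walsh_character(subset, c)
        out[subset] = acc / n
    return out


def ols_oracle(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R² from the normal equations."""
    n = x.size
    a = np.array([[n, x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(a, b)
    resid = y - (intercept + slope * x)
    sst = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1.0 - (resid**2).sum() / sst


# ---------------------------------------------------------------------------
# Walsh decomposition


def test_walsh_round_trip_reconstruction():
    rng = np.random.default_rng(0)
    values = rng.normal(size=64)
    coeffs = walsh_coefficients(values)
    np.testing.assert_allclose(reconstruct_from_walsh(coeffs), values, atol=1e-12)


def test_walsh_matches_character_enumeration_oracle():
    rng = np.random.default_rng(1)
    values = rng.normal(size=32)
    fast = walsh_coefficients(values)
    slow = walsh_oracle(values, 5)
    # implementation uses (−1)^{|S∩c|} characters, oracle the ±1 coding:
    # they agree up to a fixed per-coefficient sign, so squared masses match
    np.testing.assert_allclose(fast**2, slow**2, atol=1e-12)


def test_additive_landscape_is_pure_order_one():
    cfg = LandscapeGeneratorConfig(5, singleton_coefficients([0.5, -0.2, 0.3, 0.1, 0.4], 5))
    dec = variance_by_order(generate_landscape(cfg).landscape)
    assert dec.fractions[0] == pytest.approx(1.0, abs=1e-12)
    np.testing.assert_allclose(dec.fractions[1:], 0.0, atol=1e-12)


def test_pairwise_only_landscape_is_captured_by_orders_one_two():
    coeffs = singleton_coefficients([0.5, -0.2, 0.3, 0.1, 0.4], 5)
    coeffs.update({0b00011: -0.3, 0b10100: 0.25})
    dec = variance_by_order(generate_landscape(LandscapeGeneratorConfig(5, coeffs)).landscape)
    assert dec.cumulative[1] == pytest.approx(1.0, abs=1e-12)
    assert dec.fractions[1] > 0


def test_fractions_sum_to_one():
    coeffs = random_coefficients(6, {1: 0.5, 2: 0.2, 3: 0.1, 4: 0.05}, seed=3)
    dec = variance_by_order(generate_landscape(LandscapeGeneratorConfig(6, coeffs)).landscape)
    assert abs(dec.fractions.sum() - 1.0) < 1e-9
    assert (dec.fractions >= 0).all()


def test_equal_walsh_coefficients_split_by_subset_counts():
    """Planting equal-magnitude orthogonal coefficients at orders 1..3 puts
    a fraction proportional to (number of subsets × coef²) at each order."""
    m, coef = 5, 0.2
    coeffs = {mask: coef for mask in range(1, 1 << m) if mask.bit_count() <= 3}
    cfg = LandscapeGeneratorConfig(m, coeffs, basis="walsh")
    dec = variance_by_order(generate_landscape(cfg).landscape)
    counts = np.array([math.comb(m, r) for r in range(1, m + 1)], dtype=float)
    counts[3:] = 0.0
    np.testing.assert_allclose(dec.fractions, counts / counts.sum(), atol=1e-12)


def test_measurement_noise_pushes_mass_into_higher_orders_on_average():
    base = singleton_coefficients([1.0, 0.8, 0.6, 0.9, 0.7], 5)
    high = []
    for sd in (0.0, 0.3):
        mass = []
        for seed in range(15):
            cfg = LandscapeGeneratorConfig(5, base, noise_sd=sd, replicates=1, seed=seed)
            dec = variance_by_order(generate_landscape(cfg).landscape)
            mass.append(dec.fractions[2:].sum())  # orders >= 3
        high.append(np.mean(mass))
    assert high[1] > high[0]


# ---------------------------------------------------------------------------
# Global epistasis fits


def test_multiplicative_landscape_fits_exactly():
    """F(c) = A·prod(1+w_k) gives dF_k(b) = w_k · F(b): slope w_k, R² = 1."""
    weights = [0.3, -0.2, 0.15, 0.4, -0.1]
    cfg = LandscapeGeneratorConfig(5, global_epistasis_coefficients(5, weights))
    ls = generate_landscape(cfg).landscape
    for k, w in enumerate(weights, start=1):
        fit = global_epistasis_fit(k, ls)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(w, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.n_backgrounds == 16


def test_additive_landscape_has_zero_r_squared_by_convention():
    cfg = LandscapeGeneratorConfig(4, singleton_coefficients([0.5, -0.2, 0.3, 0.1], 4))
    ls = generate_landscape(cfg).landscape
    for k in range(1, 5):
        fit = global_epistasis_fit(k, ls)
        assert fit.r_squared == 0.0  # constant effect: nothing to explain


def test_fit_agrees_with_normal_equations_oracle():
    coeffs = random_coefficients(5, {1: 0.5, 2: 0.25, 3: 0.1}, seed=9)
    ls = generate_landscape(LandscapeGeneratorConfig(5, coeffs)).landscape
    means = ls.means_vector()
    for k in range(1, 6):
        bit = 1 << (k - 1)
        bgs = np.array([b for b in range(32) if not b & bit])
        x = means[bgs]
        y = means[bgs | bit] - x
        slope, intercept, r2 = ols_oracle(x, y)
        fit = global_epistasis_fit(k, ls)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)


def test_fits_table_shape():
    coeffs = random_coefficients(4, {1: 0.5, 2: 0.2}, seed=2)
    ls = generate_landscape(LandscapeGeneratorConfig(4, coeffs)).landscape
    table = epistasis_fits_table(ls)
    assert table["strain"].tolist() == [1, 2, 3, 4]
    assert ((table["r2"] >= 0) & (table["r2"] <= 1)).all()
    assert (table["n_backgrounds"] == 8).all()


# ---------------------------------------------------------------------------
# Permutation null


def test_null_is_seeded_and_reproducible():
    coeffs = random_coefficients(4, {1: 0.5, 2: 0.2}, seed=5)
    ls = generate_landscape(LandscapeGeneratorConfig(4, coeffs)).landscape
    a = epistasis_null(ls, b=25, seed=42)
    b = epistasis_null(ls, b=25, seed=42)
    np.testing.assert_array_equal(a.null, b.null)
    assert a.observed == mean_r_squared(ls)
    with pytest.raises(ValidationError):
        epistasis_null(ls, b=0, seed=1)


def test_identity_permutation_reproduces_observed_statistic():
    """A null replicate built from the unpermuted values must equal the
    observed statistic — permuting with the identity changes nothing."""
    coeffs = random_coefficients(4, {1: 0.5, 2: 0.2}, seed=5)
    ls = generate_landscape(LandscapeGeneratorConfig(4, coeffs)).landscape
    from combiplate.epistasis import _mean_r2_from_means

    means = ls.means_vector()
    assert _mean_r2_from_means(means, 4) == epistasis_null(ls, 2, 0).observed


def test_planted_global_epistasis_beats_the_permutation_null():
    weights = [0.35, -0.25, 0.2, 0.45, -0.15]
    coeffs = global_epistasis_coefficients(5, weights)
    cfg = LandscapeGeneratorConfig(5, coeffs, noise_sd=0.02, replicates=3, seed=4)
    ls = generate_landscape(cfg).landscape
    null = epistasis_null(ls, b=200, seed=13)
    assert null.observed > null.percentile_95
    assert null.p_value < 0.05
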