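"""Variance decomposition by interaction order, and global epistasis.

**Variance by order.**  On a complete landscape the replicate-mean function
F is a vector over {0,1}^m and admits an orthogonal (Walsh–Hadamard /
Fourier) expansion in ±1-coded presence variables s_k = 2 x_k − 1:

    F(c) = sum_S  a_S  prod_{k in S} s_k(c)

By Parseval, Var(F) over the hypercube splits exactly across the non-empty
subsets S, and the fraction of functional variance at interaction order r
is the squared-coefficient mass of the weight-r terms divided by the total
over orders >= 1 (the constant term is excluded).  Order 1 is the additive
contribution of the individual strains; order 2 the pairwise interactions;
and so on.

**Global epistasis.**  For each strain k, regress its functional effect
dF_k(b) on the background function F(b) over all 2^(m−1) backgrounds not
containing k (ordinary least squares).  A high R² means the strain's
contribution is predictable from how well the background already performs.
Whether observed R² values are larger than chance is assessed against a
null in which the function values are randomly permuted across consortia,
preserving the value distribution while destroying all compositional
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import hadamard
from scipy.stats import linregress

from .errors import ValidationError
from .landscape import FunctionLandscape

__all__ = [
    "OrderDecomposition",
    "EpistasisFit",
    "NullComparison",
    "walsh_coefficients",
    "reconstruct_from_walsh",
    "variance_by_order",
    "global_epistasis_fit",
    "epistasis_fits_table",
    "mean_r_squared",
    "epistasis_null",
]


@dataclass
class OrderDecomposition:
    m: int
    fractions: np.ndarray  # index r-1 -> fraction of variance at order r
    cumulative: np.ndarray
    total_variance: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "order": np.arange(1, self.m + 1),
                "fraction": self.fractions,
                "cumulative": self.cumulative,
            }
        )


@dataclass(frozen=True)
class EpistasisFit:
    strain: int
    slope: float
    intercept: float
    r_squared: float
    n_backgrounds: int


@dataclass
class NullComparison:
    observed: float  # observed mean R² across strains
    null: np.ndarray  # B permutation replicates of the statistic
    seed: int
    b: int
    p_value: float  # P(null >= observed), add-one estimator
    method: str = "value permutation across consortia"

    @property
    def percentile_95(self) -> float:
        return float(np.quantile(self.null, 0.95))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replicate": np.arange(1, self.b + 1), "mean_r2": self.null}
        )


# ---------------------------------------------------------------------------
# Walsh–Hadamard machinery


def walsh_coefficients(values: np.ndarray) -> np.ndarray:
    """Walsh–Hadamard coefficients of a length-2^m vector indexed by mask.

    Uses the Sylvester Hadamard matrix, whose (S, c) entry is
    (−1)^{popcount(S & c)}; coefficient signs thus follow the 0/1 character
    convention, which differs from the ±1 coding only by a per-coefficient
    sign — squared masses, orders and round-trips are identical.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    m = n.bit_length() - 1
    if n != 1 << m or n < 2:
        raise ValidationError(f"need a vector of length 2^m >= 2, got {n}")
    h = hadamard(n)
    return h @ values / n


def reconstruct_from_walsh(coefficients: np.ndarray) -> np.ndarray:
    """Inverse transform; exact round-trip with :func:`walsh_coefficients`."""
    coefficients = np.asarray(coefficients, dtype=float).ravel()
    return hadamard(coefficients.size) @ coefficients


def variance_by_order(landscape: FunctionLandscape) -> OrderDecomposition:
    """Fraction of functional variance at each interaction order 1..m.

    Requires a combinatorially complete landscape; operates on replicate
    means.  Fractions are non-negative and sum to 1 (a flat landscape, with
    zero variance, returns all-zero fractions).
    """
    landscape.require_complete("variance_by_order")
    m = landscape.m
    coeffs = walsh_coefficients(landscape.means_vector())
    weights = np.array([mask.bit_count() for mask in range(coeffs.size)])
    sq = coeffs**2
    per_order = np.array([sq[weights == r].sum() for r in range(1, m + 1)])
    total = per_order.sum()
    fractions = per_order / total if total > 0 else np.zeros(m)
    return OrderDecomposition(m, fractions, np.cumsum(fractions), float(total))


# ---------------------------------------------------------------------------
# Global epistasis


def _effects_xy(means: np.ndarray, k: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    bit = 1 << (k - 1)
    backgrounds = np.array([b for b in range(1 << m) if not b & bit])
    x = means[backgrounds]
    y = means[backgrounds | bit] - x
    return x, y


def global_epistasis_fit(k: int, landscape: FunctionLandscape) -> EpistasisFit:
    """OLS of strain k's functional effect on the background function.

    R² is defined as 0 when the effect is constant across backgrounds
    (zero-variance response: nothing to explain, nothing explained).
    """
    landscape.require_complete("global_epistasis_fit")
    m = landscape.m
    if not 1 <= k <= m:
        raise ValidationError(f"strain index {k} outside 1..{m}")
    x, y = _effects_xy(landscape.means_vector(), k, m)
    if x.size < 3:
        raise ValidationError(
            f"global epistasis fit needs at least 3 backgrounds, got {x.size}"
        )
    if np.allclose(y, y[0]):
        return EpistasisFit(k, 0.0, float(y.mean()), 0.0, int(x.size))
    if np.allclose(x, x[0]):
        # degenerate: all backgrounds at the same function value
        return EpistasisFit(k, 0.0, float(y.mean()), 0.0, int(x.size))
    fit = linregress(x, y)
    return EpistasisFit(
        k, float(fit.slope), float(fit.intercept), float(fit.rvalue**2), int(x.size)
    )


def epistasis_fits_table(landscape: FunctionLandscape) -> pd.DataFrame:
    rows = [
        {
            "strain": f.strain,
            "slope": f.slope,
            "intercept": f.intercept,
            "r2": f.r_squared,
            "n_backgrounds": f.n_backgrounds,
        }
        for f in (
            global_epistasis_fit(k, landscape) for k in range(1, landscape.m + 1)
        )
    ]
    return pd.DataFrame(rows)


def _mean_r2_from_means(means: np.ndarray, m: int) -> float:
    r2s = []
    for k in range(1, m + 1):
        x, y = _effects_xy(means, k, m)
        if np.allclose(y, y[0]) or np.allclose(x, x[0]):
            r2s.append(0.0)
            continue
        r2s.append(float(linregress(x, y).rvalue ** 2))
    return float(np.mean(r2s))


def mean_r_squared(landscape: FunctionLandscape) -> float:
    """Mean of the per-strain global-epistasis R² values."""
    landscape.require_complete("mean_r_squared")
    return _mean_r2_from_means(landscape.means_vector(), landscape.m)


def epistasis_null(
    landscape: FunctionLandscape, b: int = 1000, seed: int = 0
) -> NullComparison:
    """Permutation null for the mean global-epistasis R².

    Each of the ``b`` null replicates permutes the replicate-mean function
    values across the 2^m consortia (seeded, reproducible) and recomputes
    the mean R².  The p-value is the add-one permutation estimator
    ``(1 + #{null >= observed}) / (b + 1)``.
    """
    if b < 1:
        raise ValidationError(f"number of permutations must be >= 1, got {b}")
    landscape.require_complete("epistasis_null")
    m = landscape.m
    means = landscape.means_vector()
    observed = _mean_r2_from_means(means, m)
    rng = np.random.default_rng(seed)
    null = np.empty(b)
    for rep in range(b):
        null[rep] = _mean_r2_from_means(rng.permutation(means), m)
    p = (1.0 + np.sum(null >= observed)) / (b + 1.0)
    return NullComparison(observed, null, seed, b, float(p))
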