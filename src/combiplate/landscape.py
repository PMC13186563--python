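"""Community-function landscapes on the {0,1}^m hypercube and the
interaction calculus built on them.

A landscape maps every consortium code to replicate measurements of a
scalar community function F (e.g. Abs600 as a biomass proxy).  On top of
it we compute:

* the *functional effect* of strain k in background b,
  ``dF_k(b) = F(b + k) − F(b)``;
* the *functional interaction* of a pair (i, j) in background b,
  ``eps_ij(b) = F(b+i+j) − F(b+i) − F(b+j) + F(b)``, the deviation of the
  pair's joint effect from additivity;
* the third-order interaction of a trio, the alternating inclusion–
  exclusion sum over the 2^3 sub-lattice, which measures the deviation of
  the trio from the additive-plus-pairwise null;
* diversity–function curves, rankings and the Hamming-distance-1
  adjacency graph of the hypercube.

These are statistical quantities: the additive null is a minimal baseline,
not a mechanistic model.  All of them operate on replicate means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .codec import ConsortiumCode
from .errors import IncompleteLandscapeError, ValidationError

__all__ = [
    "FunctionLandscape",
    "EffectRecord",
    "InteractionRecord",
    "functional_effect",
    "effects_table",
    "pairwise_interaction",
    "interactions_table",
    "third_order_interaction",
    "diversity_function_curve",
    "rank_consortia",
    "adjacency_graph",
]


class FunctionLandscape:
    """Replicate-aware mapping consortium code -> function values.

    Parameters
    ----------
    m
        Library size; codes are bitmasks in ``[0, 2^m)``.
    values
        Mapping ``mask -> sequence of replicate values``.

    If the empty consortium (mask 0) has no measured value, its function is
    taken as 0 with a warning; every interaction formula then uses that
    convention consistently.
    """

    def __init__(self, m: int, values: dict[int, np.ndarray]):
        if m < 1:
            raise ValidationError(f"m must be >= 1, got {m}")
        self.m = m
        self.values: dict[int, np.ndarray] = {}
        for mask, reps in values.items():
            mask = int(mask)
            if not 0 <= mask < (1 << m):
                raise ValidationError(f"code {mask} outside [0, 2^{m})")
            arr = np.asarray(reps, dtype=float).ravel()
            if arr.size == 0:
                raise ValidationError(f"code {mask} has no replicate values")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"code {mask} has non-finite values")
            self.values[mask] = arr
        self._empty_imputed = False
        if 0 not in self.values:
            warnings.warn(
                "no measured value for the empty consortium; using F(empty)=0"
            )
            self.values[0] = np.zeros(1)
            self._empty_imputed = True

    # -- construction -----------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, m: int | None = None) -> "FunctionLandscape":
        """Build from a tidy table with columns
        ``consortium_binary``, ``replicate``, ``value``."""
        missing = [c for c in ("consortium_binary", "value") if c not in df.columns]
        if missing:
            raise ValidationError(f"function table is missing columns {missing}")
        if df.empty:
            raise ValidationError("function table is empty")
        if m is None:
            m = len(str(df["consortium_binary"].iloc[0]))
        values = {}
        for sample, grp in df.groupby("consortium_binary"):
            code = ConsortiumCode.from_string(str(sample))
            if code.m != m:
                raise ValidationError(
                    f"code {sample} has width {code.m}, expected {m}"
                )
            values[code.mask] = grp["value"].to_numpy(dtype=float)
        return cls(m, values)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "consortium_binary": format(mask, f"0{self.m}b"),
                "replicate": r + 1,
                "value": v,
            }
            for mask in sorted(self.values)
            for r, v in enumerate(self.values[mask])
            if not (mask == 0 and self._empty_imputed)
        ]
        return pd.DataFrame(rows)

    # -- access -----------------------------------------------------------

    def mean(self, code: ConsortiumCode | int) -> float:
        mask = code.mask if isinstance(code, ConsortiumCode) else int(code)
        if mask not in self.values:
            raise IncompleteLandscapeError(
                f"no measurement for consortium {format(mask, f'0{self.m}b')}",
                missing=[format(mask, f"0{self.m}b")],
            )
        return float(self.values[mask].mean())

    def sd(self, code: ConsortiumCode | int) -> float:
        mask = code.mask if isinstance(code, ConsortiumCode) else int(code)
        arr = self.values[mask]
        return float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    def n_replicates(self, code: ConsortiumCode | int) -> int:
        mask = code.mask if isinstance(code, ConsortiumCode) else int(code)
        return int(self.values[mask].size)

    @property
    def missing_codes(self) -> list[str]:
        return [
            format(mask, f"0{self.m}b")
            for mask in range(1 << self.m)
            if mask not in self.values
        ]

    @property
    def is_complete(self) -> bool:
        """All 2^m codes carry values (the imputed blank counts)."""
        return not self.missing_codes

    def require_complete(self, operation: str) -> None:
        missing = self.missing_codes
        if missing:
            shown = missing[:10] + (["..."] if len(missing) > 10 else [])
            raise IncompleteLandscapeError(
                f"{operation} needs a combinatorially complete landscape; "
                f"{len(missing)} of {1 << self.m} codes missing: {shown}",
                missing=missing,
            )

    def means_vector(self) -> np.ndarray:
        """Replicate means for all 2^m codes, indexed by mask."""
        self.require_complete("means_vector")
        return np.array([self.values[mask].mean() for mask in range(1 << self.m)])

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "consortium_binary": format(mask, f"0{self.m}b"),
                "richness": mask.bit_count(),
                "mean": self.values[mask].mean(),
                "sd": self.sd(mask),
                "n_replicates": self.values[mask].size,
            }
            for mask in sorted(self.values)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Effects and interactions


@dataclass(frozen=True)
class EffectRecord:
    strain: int
    background: str  # binary code without the strain
    background_function: float
    effect: float  # F(background + strain) − F(background)


@dataclass(frozen=True)
class InteractionRecord:
    pair: tuple[int, int]
    background: str  # binary code without either strain
    epsilon: float
    epsilon_sd: float  # propagated under replicate independence (approximate)


def _strain_bit(k: int, m: int) -> int:
    if not 1 <= k <= m:
        raise ValidationError(f"strain index {k} outside 1..{m}")
    return 1 << (k - 1)


def functional_effect(
    k: int, background: ConsortiumCode | int, landscape: FunctionLandscape
) -> EffectRecord:
    """Functional effect of strain ``k`` in ``background`` (which must not
    contain it), computed on replicate means."""
    m = landscape.m
    b = background.mask if isinstance(background, ConsortiumCode) else int(background)
    bit = _strain_bit(k, m)
    if b & bit:
        raise ValidationError(
            f"background {format(b, f'0{m}b')} already contains strain {k}"
        )
    fb = landscape.mean(b)
    return EffectRecord(k, format(b, f"0{m}b"), fb, landscape.mean(b | bit) - fb)


def effects_table(landscape: FunctionLandscape, strains=None) -> pd.DataFrame:
    """Functional effects of each strain across all 2^(m−1) backgrounds."""
    landscape.require_complete("effects_table")
    m = landscape.m
    strains = list(strains) if strains is not None else list(range(1, m + 1))
    rows = []
    for k in strains:
        bit = _strain_bit(k, m)
        for b in range(1 << m):
            if b & bit:
                continue
            rec = functional_effect(k, b, landscape)
            rows.append(
                {
                    "strain": k,
                    "background": rec.background,
                    "background_function": rec.background_function,
                    "effect": rec.effect,
                }
            )
    return pd.DataFrame(rows)


def pairwise_interaction(
    i: int, j: int, background: ConsortiumCode | int, landscape: FunctionLandscape
) -> InteractionRecord:
    """Functional interaction eps_ij(b) = F(b+i+j) − F(b+i) − F(b+j) + F(b).

    The SD is propagated from per-code replicate SDs assuming independence;
    it is an approximation, labeled as such.
    """
    m = landscape.m
    b = background.mask if isinstance(background, ConsortiumCode) else int(background)
    bi, bj = _strain_bit(i, m), _strain_bit(j, m)
    if i == j:
        raise ValidationError("pairwise interaction needs two distinct strains")
    if b & (bi | bj):
        raise ValidationError(
            f"background {format(b, f'0{m}b')} must exclude strains {i} and {j}"
        )
    masks = (b | bi | bj, b | bi, b | bj, b)
    eps = (
        landscape.mean(masks[0])
        - landscape.mean(masks[1])
        - landscape.mean(masks[2])
        + landscape.mean(masks[3])
    )
    var = 0.0
    for mk in masks:
        n = landscape.n_replicates(mk)
        var += landscape.sd(mk) ** 2 / max(n, 1)
    pair = (i, j) if i < j else (j, i)
    return InteractionRecord(pair, format(b, f"0{m}b"), eps, float(np.sqrt(var)))


def interactions_table(landscape: FunctionLandscape, pairs=None) -> pd.DataFrame:
    """eps_ij for every pair across all 2^(m−2) shared backgrounds."""
    landscape.require_complete("interactions_table")
    m = landscape.m
    if pairs is None:
        pairs = list(combinations(range(1, m + 1), 2))
    rows = []
    for i, j in pairs:
        excl = _strain_bit(i, m) | _strain_bit(j, m)
        for b in range(1 << m):
            if b & excl:
                continue
            rec = pairwise_interaction(i, j, b, landscape)
            rows.append(
                {
                    "strain_i": rec.pair[0],
                    "strain_j": rec.pair[1],
                    "background": rec.background,
                    "epsilon": rec.epsilon,
                    "epsilon_sd_approx": rec.epsilon_sd,
                }
            )
    return pd.DataFrame(rows)


def third_order_interaction(
    i: int,
    j: int,
    k: int,
    landscape: FunctionLandscape,
    background: ConsortiumCode | int = 0,
) -> float:
    """Third-order interaction of a trio over ``background``.

    The alternating inclusion–exclusion sum over the trio's 2^3
    sub-lattice: the deviation of the trio's function from the null built
    out of the additive effects and the pairwise interactions.
    """
    m = landscape.m
    if len({i, j, k}) != 3:
        raise ValidationError("third-order interaction needs three distinct strains")
    bits = [_strain_bit(s, m) for s in (i, j, k)]
    b = background.mask if isinstance(background, ConsortiumCode) else int(background)
    if b & (bits[0] | bits[1] | bits[2]):
        raise ValidationError("background must exclude all three strains")
    total = 0.0
    for sub in range(8):
        chosen = [bits[t] for t in range(3) if sub >> t & 1]
        sign = (-1) ** (3 - len(chosen))
        mask = b
        for bit in chosen:
            mask |= bit
        total += sign * landscape.mean(mask)
    return float(total)


# ---------------------------------------------------------------------------
# Landscape-level summaries


def diversity_function_curve(landscape: FunctionLandscape) -> pd.DataFrame:
    """Mean and SD of function by richness (number of strains present).

    SD is across consortia of the same richness; the group of richness r
    has C(m, r) members on a complete landscape.
    """
    landscape.require_complete("diversity_function_curve")
    means = landscape.means_vector()
    rows = []
    richness = np.array([mask.bit_count() for mask in range(means.size)])
    for r in range(landscape.m + 1):
        vals = means[richness == r]
        rows.append(
            {
                "richness": r,
                "mean_function": float(vals.mean()),
                "sd_function": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n_consortia": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def rank_consortia(landscape: FunctionLandscape, top_n: int | None = None) -> pd.DataFrame:
    """Consortia ordered by descending mean function.

    Ties break by ascending code integer, so the ordering is deterministic.
    Works on partial landscapes (only measured codes are ranked).
    """
    rows = [
        {
            "consortium_binary": format(mask, f"0{landscape.m}b"),
            "consortium_int": mask,
            "richness": mask.bit_count(),
            "mean": landscape.values[mask].mean(),
            "sd": landscape.sd(mask),
            "n_replicates": landscape.n_replicates(mask),
        }
        for mask in landscape.values
        if not (mask == 0 and landscape._empty_imputed)
    ]
    df = pd.DataFrame(rows).sort_values(
        ["mean", "consortium_int"], ascending=[False, True], ignore_index=True
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.head(top_n) if top_n is not None else df


def adjacency_graph(m: int) -> pd.DataFrame:
    """Edge list of the m-hypercube: consortia at Hamming distance 1.

    Each edge records the lower and higher code and the strain whose
    presence differs; a complete landscape has m·2^(m−1) edges.
    """
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    rows = []
    for mask in range(1 << m):
        for k in range(1, m + 1):
            bit = 1 << (k - 1)
            if not mask & bit:
                rows.append(
                    {
                        "code_without": format(mask, f"0{m}b"),
                        "code_with": format(mask | bit, f"0{m}b"),
                        "strain": k,
                    }
                )
    return pd.DataFrame(rows)
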