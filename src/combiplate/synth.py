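"""Synthetic datasets with known ground truth for every analysis stage.

Two generators mirror the structure of the two kinds of experiment the
pipeline analyses:

* :func:`generate_spectra` — a palette of colorant-like absorbance spectra
  (sums of Gaussian peaks on a 380–780 nm grid) and the measured spectra
  of all 2^m mixtures, where each constituent's aliquot is perturbed by a
  multiplicative pipetting error ``1 + eta``, ``eta ~ N(0, CV)``, drawn
  independently per mixture and constituent.  The default CV of 0.0075
  sits in the 0.5–1% band typical of handheld micropipettes.  With CV=0
  every mixture is exactly additive.

* :func:`generate_landscape` — a community-function landscape with planted
  coefficients.  In the default ``taylor`` basis the noise-free function
  is the subset sum ``F(c) = sum_{S subset of c} coef(S)``, which makes the
  background-referenced interaction formulas recover planted terms
  exactly; the ``walsh`` basis plants orthogonal ±1 characters instead,
  which makes variance-by-order fractions exact.  Gaussian replicate noise
  of a chosen SD is added on top.

Both generators are byte-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .landscape import FunctionLandscape

__all__ = [
    "SpectraGeneratorConfig",
    "SpectraResult",
    "generate_spectra",
    "LandscapeGeneratorConfig",
    "LandscapeResult",
    "generate_landscape",
    "singleton_coefficients",
    "random_coefficients",
    "global_epistasis_coefficients",
    "walsh_character",
]


# ---------------------------------------------------------------------------
# Colorant-like spectra


@dataclass
class SpectraGeneratorConfig:
    m: int = 8
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(380.0, 781.0, 1.0)
    )
    #: per colorant: list of (center_nm, width_nm, height_AU) Gaussian peaks;
    #: None draws a random palette (each colorant normalized to max ~1 A.U.)
    peaks: list[list[tuple[float, float, float]]] | None = None
    cv: float = 0.0075
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError(f"m must be >= 1, got {self.m}")
        if self.cv < 0:
            raise ValidationError(f"pipetting CV must be >= 0, got {self.cv}")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)


@dataclass
class SpectraResult:
    monocultures: pd.DataFrame  # noise-free reference spectra (singletons)
    mixtures: pd.DataFrame  # measured spectra of all 2^m combinations
    aliquot_factors: pd.DataFrame  # ground-truth (1+eta) per (sample, species)
    config: SpectraGeneratorConfig


def _random_palette(cfg: SpectraGeneratorConfig, rng: np.random.Generator):
    palette = []
    lo, hi = cfg.wavelengths[0], cfg.wavelengths[-1]
    for _ in range(cfg.m):
        n_peaks = int(rng.integers(1, 4))
        peaks = [
            (
                float(rng.uniform(lo + 20, hi - 20)),
                float(rng.uniform(20.0, 60.0)),
                float(rng.uniform(0.3, 1.0)),
            )
            for _ in range(n_peaks)
        ]
        palette.append(peaks)
    return palette


def _spectrum_from_peaks(wl: np.ndarray, peaks) -> np.ndarray:
    spec = np.zeros_like(wl)
    for center, width, height in peaks:
        if height < 0 or width <= 0:
            raise ValidationError("peak heights must be >= 0 and widths > 0")
        spec += height * np.exp(-0.5 * ((wl - center) / width) ** 2)
    # comparable maximum absorbances across the palette
    peak = spec.max()
    return spec / peak if peak > 0 else spec


def generate_spectra(cfg: SpectraGeneratorConfig) -> SpectraResult:
    """Simulate the full 2^m mixture experiment.

    The mixture spectrum of consortium c is
    ``sum_{k in c} (1 + eta_{c,k}) * mono_k`` with independent
    ``eta ~ N(0, CV)`` per (mixture, constituent): each constituent's
    aliquot is pipetted once per mixture, slightly off-volume.
    """
    rng = np.random.default_rng(cfg.seed)
    palette = cfg.peaks if cfg.peaks is not None else _random_palette(cfg, rng)
    if len(palette) != cfg.m:
        raise ValidationError(
            f"palette has {len(palette)} colorants, expected m={cfg.m}"
        )
    wl = cfg.wavelengths
    mono = np.vstack([_spectrum_from_peaks(wl, p) for p in palette])

    mono_rows = []
    for k in range(1, cfg.m + 1):
        sample = format(1 << (k - 1), f"0{cfg.m}b")
        mono_rows.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "replicate": 1,
                    "wavelength_nm": wl,
                    "absorbance": mono[k - 1],
                }
            )
        )

    mix_rows, factor_rows = [], []
    for mask in range(1 << cfg.m):
        sample = format(mask, f"0{cfg.m}b")
        spec = np.zeros_like(wl)
        for k in range(1, cfg.m + 1):
            if mask >> (k - 1) & 1:
                factor = 1.0 + (rng.normal(0.0, cfg.cv) if cfg.cv > 0 else 0.0)
                spec += factor * mono[k - 1]
                factor_rows.append(
                    {"sample": sample, "species": k, "factor": factor}
                )
        mix_rows.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "replicate": 1,
                    "wavelength_nm": wl,
                    "absorbance": spec,
                }
            )
        )
    return SpectraResult(
        pd.concat(mono_rows, ignore_index=True),
        pd.concat(mix_rows, ignore_index=True),
        pd.DataFrame(factor_rows, columns=["sample", "species", "factor"]),
        cfg,
    )


# ---------------------------------------------------------------------------
# Function landscapes with planted coefficients


def walsh_character(subset_mask: int, code_mask: int) -> int:
    """±1 character of a subset at a code: prod_{k in S} (2 x_k − 1)."""
    s = subset_mask.bit_count()
    overlap = (subset_mask & code_mask).bit_count()
    return 1 if (s - overlap) % 2 == 0 else -1


@dataclass
class LandscapeGeneratorConfig:
    m: int
    #: subset bitmask -> coefficient value
    coefficients: dict[int, float] = field(default_factory=dict)
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0
    basis: str = "taylor"  # "taylor" (subset sums) | "walsh" (±1 characters)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError(f"m must be >= 1, got {self.m}")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise SD must be >= 0")
        if self.basis not in ("taylor", "walsh"):
            raise ValidationError(f"unknown basis {self.basis!r}")
        for s in self.coefficients:
            if not 0 <= int(s) < (1 << self.m):
                raise ValidationError(f"coefficient subset {s} outside [0, 2^{self.m})")


@dataclass
class LandscapeResult:
    landscape: FunctionLandscape
    true_means: np.ndarray  # noise-free F over all 2^m codes, by mask
    config: LandscapeGeneratorConfig


def generate_landscape(cfg: LandscapeGeneratorConfig) -> LandscapeResult:
    """Complete landscape from planted coefficients plus replicate noise."""
    n = 1 << cfg.m
    f0 = np.zeros(n)
    for subset, value in cfg.coefficients.items():
        subset = int(subset)
        if cfg.basis == "taylor":
            for c in range(n):
                if c & subset == subset:
                    f0[c] += value
        else:
            for c in range(n):
                f0[c] += value * walsh_character(subset, c)
    rng = np.random.default_rng(cfg.seed)
    values = {}
    for c in range(n):
        noise = (
            rng.normal(0.0, cfg.noise_sd, size=cfg.replicates)
            if cfg.noise_sd > 0
            else np.zeros(cfg.replicates)
        )
        values[c] = f0[c] + noise
    return LandscapeResult(FunctionLandscape(cfg.m, values), f0, cfg)


# ---------------------------------------------------------------------------
# Coefficient constructors


def singleton_coefficients(effects: dict[int, float] | list[float], m: int) -> dict[int, float]:
    """Additive coefficients: strain k (1-based) -> its constant effect."""
    if isinstance(effects, dict):
        items = effects.items()
    else:
        if len(effects) != m:
            raise ValidationError(f"need {m} singleton effects, got {len(effects)}")
        items = enumerate(effects, start=1)
    out = {}
    for k, v in items:
        if not 1 <= int(k) <= m:
            raise ValidationError(f"strain index {k} outside 1..{m}")
        out[1 << (int(k) - 1)] = float(v)
    return out


def random_coefficients(
    m: int, sd_by_order: dict[int, float], seed: int = 0
) -> dict[int, float]:
    """Gaussian coefficients for every subset at the requested orders.

    ``sd_by_order`` maps interaction order (1..m) to the SD of its
    coefficients; orders not listed get none.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for mask in range(1, 1 << m):
        sd = sd_by_order.get(mask.bit_count())
        if sd:
            out[mask] = float(rng.normal(0.0, sd))
    return out


def global_epistasis_coefficients(
    m: int, weights: list[float], baseline: float = 1.0
) -> dict[int, float]:
    """Coefficients of the multiplicative landscape F(c) = A·prod(1 + w_k).

    In the taylor basis this expands to ``coef(S) = A · prod_{k in S} w_k``.
    The resulting landscape shows perfect global epistasis: the effect of
    strain k in background b is exactly ``w_k · F(b)`` (slope w_k,
    intercept 0, R² = 1 in the noise-free case).
    """
    if len(weights) != m:
        raise ValidationError(f"need {m} strain weights, got {len(weights)}")
    out = {}
    for mask in range(1 << m):
        coef = float(baseline)
        for k in range(1, m + 1):
            if mask >> (k - 1) & 1:
                coef *= weights[k - 1]
        out[mask] = coef
    return out
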