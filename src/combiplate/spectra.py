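"""Additive spectral expectations for mixtures, and deviation statistics.

If the components of a mixture do not interact optically, the absorbance
spectrum of the mixture is the pointwise sum of its constituents'
monoculture spectra.  The relative deviation between the measured spectrum
and that additive expectation,

    delta(c, lambda) = |Abs(c, lambda) - Abs_add(c, lambda)| / Abs(c, lambda),

quantifies cumulative pipetting error for non-interacting components
(e.g. colorants) or interaction signal for co-cultures.  Relative
deviations are only meaningful when the measured absorbance is
appreciable, so they are masked below a threshold (default 0.1 A.U.)
applied to the measured spectrum; absolute deviations are kept everywhere.

Tables are tidy pandas DataFrames:

monoculture / measurement table columns
    ``sample`` (binary consortium string), ``replicate``,
    ``wavelength_nm``, ``absorbance``
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .codec import ConsortiumCode
from .errors import ValidationError

__all__ = [
    "SPECTRUM_COLUMNS",
    "additive_expectation",
    "deviation_table",
    "relative_deviation",
    "deviation_summary",
]

SPECTRUM_COLUMNS = ("sample", "replicate", "wavelength_nm", "absorbance")


def _require_columns(df: pd.DataFrame, what: str) -> None:
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing columns {missing}")


def _replicate_mean(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicates: one spectrum per sample (mean over replicates)."""
    return (
        df.groupby(["sample", "wavelength_nm"], as_index=False)["absorbance"]
        .mean()
        .sort_values(["sample", "wavelength_nm"], ignore_index=True)
    )


def _monoculture_map(monocultures: pd.DataFrame, m: int) -> dict[int, pd.Series]:
    """Per-species spectrum Series indexed by wavelength, from singleton rows."""
    mono = _replicate_mean(monocultures)
    out: dict[int, pd.Series] = {}
    for sample, grp in mono.groupby("sample"):
        code = ConsortiumCode.from_string(str(sample))
        if code.m != m:
            raise ValidationError(
                f"monoculture code {sample} has width {code.m}, expected {m}"
            )
        if code.richness != 1:
            continue
        (k,) = code.members
        out[k] = grp.set_index("wavelength_nm")["absorbance"]
    return out


def additive_expectation(
    code: ConsortiumCode, monocultures: pd.DataFrame
) -> pd.Series:
    """Pointwise sum of the constituent monoculture spectra of ``code``.

    ``monocultures`` must contain a singleton spectrum for every species in
    ``code``, all on an identical wavelength grid.  The empty consortium
    yields the all-zero spectrum on that grid.
    """
    _require_columns(monocultures, "monoculture")
    mono = _monoculture_map(monocultures, code.m)
    grids = {tuple(s.index) for s in mono.values()}
    if len(grids) > 1:
        raise ValidationError("monoculture spectra are not on a common wavelength grid")
    if not mono:
        raise ValidationError("no singleton monoculture spectra found")
    grid = next(iter(mono.values())).index
    expectation = pd.Series(np.zeros(len(grid)), index=grid, name="absorbance")
    for k in sorted(code.members):
        if k not in mono:
            raise ValidationError(
                f"no monoculture spectrum for species {k} (needed by {code})"
            )
        expectation = expectation + mono[k]
    return expectation


def relative_deviation(
    empirical: pd.Series, expectation: pd.Series, threshold: float = 0.1
) -> pd.DataFrame:
    """Deviation statistics between one measured spectrum and its expectation.

    Both inputs are absorbance Series indexed by wavelength on identical
    grids.  Returns a frame with ``empirical``, ``additive_expectation``,
    ``absolute_deviation`` and ``relative_deviation`` (NaN wherever the
    measured absorbance is at or below ``threshold``).
    """
    if not empirical.index.equals(expectation.index):
        raise ValidationError("empirical and expected spectra are on different grids")
    emp = empirical.to_numpy(dtype=float)
    exp = expectation.to_numpy(dtype=float)
    absdev = np.abs(emp - exp)
    rel = np.where(emp > threshold, absdev / np.where(emp > threshold, emp, 1.0), np.nan)
    return pd.DataFrame(
        {
            "wavelength_nm": empirical.index,
            "empirical": emp,
            "additive_expectation": exp,
            "absolute_deviation": absdev,
            "relative_deviation": rel,
        }
    )


def deviation_table(
    measurements: pd.DataFrame,
    monocultures: pd.DataFrame | None = None,
    threshold: float = 0.1,
    m: int | None = None,
) -> pd.DataFrame:
    """Deviation statistics for every mixture in a measurement table.

    Replicates are averaged before the comparison.  When ``monocultures``
    is omitted, the singleton rows of ``measurements`` provide the
    monoculture spectra (the usual case: every sample sat on the same
    plates).  The returned frame has one row per (sample, wavelength) with
    a ``richness`` column for downstream grouping.
    """
    _require_columns(measurements, "measurement")
    if measurements.empty:
        raise ValidationError("measurement table is empty")
    if monocultures is None:
        monocultures = measurements
    meas = _replicate_mean(measurements)
    if m is None:
        m = len(str(meas["sample"].iloc[0]))
    mono = _monoculture_map(monocultures, m)
    if not mono:
        raise ValidationError("no singleton monoculture spectra available")
    grid = next(iter(mono.values())).index

    frames = []
    for sample, grp in meas.groupby("sample"):
        code = ConsortiumCode.from_string(str(sample))
        empirical = grp.set_index("wavelength_nm")["absorbance"]
        if not empirical.index.equals(grid):
            raise ValidationError(
                f"sample {sample} is not on the shared wavelength grid"
            )
        expectation = pd.Series(np.zeros(len(grid)), index=grid)
        for k in sorted(code.members):
            if k not in mono:
                raise ValidationError(f"no monoculture spectrum for species {k}")
            expectation = expectation + mono[k]
        out = relative_deviation(empirical, expectation, threshold)
        out.insert(0, "sample", str(sample))
        out.insert(1, "richness", code.richness)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def deviation_summary(
    deviations: pd.DataFrame,
    group_by: str = "overall",
    min_richness: int = 2,
) -> pd.DataFrame:
    """Mean/median deviation statistics, pooled with equal weight.

    ``group_by`` is one of ``overall``, ``sample``, ``cardinality`` (i.e.
    richness, the Hamming weight of the sample code) or ``wavelength``.
    Only mixtures of at least ``min_richness`` constituents enter the
    summary; relative deviations additionally exclude masked (NaN) points.
    """
    sub = deviations[deviations["richness"] >= min_richness]
    if sub.empty or sub["relative_deviation"].notna().sum() == 0:
        warnings.warn("all deviations masked or filtered out; empty summary")
        return pd.DataFrame(
            columns=["group", "mean_relative", "median_relative",
                     "mean_absolute", "median_absolute", "n"]
        )
    keys = {
        "overall": None,
        "sample": "sample",
        "cardinality": "richness",
        "wavelength": "wavelength_nm",
    }
    if group_by not in keys:
        raise ValidationError(f"unknown group_by {group_by!r}")

    def _stats(g: pd.DataFrame) -> pd.Series:
        rel = g["relative_deviation"].dropna()
        return pd.Series(
            {
                "mean_relative": rel.mean(),
                "median_relative": rel.median(),
                "mean_absolute": g["absolute_deviation"].mean(),
                "median_absolute": g["absolute_deviation"].median(),
                "n": int(rel.size),
            }
        )

    if keys[group_by] is None:
        out = _stats(sub).to_frame().T
        out.insert(0, "group", "overall")
        return out
    grouped = sub.groupby(keys[group_by]).apply(_stats, include_groups=False)
    grouped = grouped.reset_index(names="group")
    grouped["n"] = grouped["n"].astype(int)
    return grouped
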