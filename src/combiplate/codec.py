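"""Binary encoding of consortia and the consortium <-> well bijection.

A consortium drawn from a library of ``m`` species is identified by the
binary string ``x_m … x_2 x_1``, where bit ``k-1`` encodes the presence of
species ``k``.  Reading codes as integers makes three things cheap:

* merging two *disjoint* consortia is plain integer addition (bitwise OR),
* the Hamming weight of a code is the consortium's richness,
* the canonical plate layout places code ``n`` at the ``n``-th well counted
  top-to-bottom within a column, columns left-to-right, continuing onto
  further plates once the first runs out of columns.

On a 96-well plate (8 rows = 2^3) the low three bits of a code select the
row and the remaining ``m-3`` bits select the global column; on a 384-well
plate (16 rows = 2^4) the split is at four bits.  Every function here is a
pure function of that split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

from .errors import ValidationError

__all__ = [
    "PLATE_FORMATS",
    "SpeciesLibrary",
    "ConsortiumCode",
    "WellAddress",
    "PlacementRule",
    "PlateLayout",
    "encode",
    "decode",
    "hamming_weight",
    "merge_disjoint",
    "row_bits",
    "code_to_well",
    "well_to_code",
    "species_positions",
    "hamming_split",
    "plates_required",
    "total_columns",
]

#: plate format -> (rows, columns)
PLATE_FORMATS: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24)}

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"


def _check_format(plate_format: int) -> tuple[int, int]:
    try:
        return PLATE_FORMATS[int(plate_format)]
    except (KeyError, ValueError):
        raise ValidationError(
            f"unsupported plate format {plate_format!r}; expected one of {sorted(PLATE_FORMATS)}"
        ) from None


@dataclass(frozen=True)
class SpeciesLibrary:
    """An ordered library of ``m`` uniquely named species.

    Species ``k`` (1-based) corresponds to ``names[k-1]`` and to bit ``k-1``
    of every :class:`ConsortiumCode` drawn from this library.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) < 1:
            raise ValidationError("a species library needs at least one species")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("species names must be unique")

    @classmethod
    def with_size(cls, m: int, prefix: str = "species") -> "SpeciesLibrary":
        if m < 1:
            raise ValidationError(f"m must be >= 1, got {m}")
        return cls(tuple(f"{prefix}_{k}" for k in range(1, m + 1)))

    @property
    def m(self) -> int:
        return len(self.names)

    def name(self, k: int) -> str:
        """Name of species ``k`` (1-based)."""
        if not 1 <= k <= self.m:
            raise ValidationError(f"species index {k} outside 1..{self.m}")
        return self.names[k - 1]


@dataclass(frozen=True)
class ConsortiumCode:
    """A species combination encoded as an integer bitmask of width ``m``.

    ``str(code)`` renders the m-character binary string with species ``m``
    leftmost, matching the ``x_m … x_1`` convention.
    """

    mask: int
    m: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValidationError(f"code width m must be >= 1, got {self.m}")
        if not 0 <= self.mask < (1 << self.m):
            raise ValidationError(
                f"mask {self.mask} outside [0, 2^{self.m}) for width m={self.m}"
            )

    @classmethod
    def from_string(cls, bits: str) -> "ConsortiumCode":
        if not bits or set(bits) - {"0", "1"}:
            raise ValidationError(f"not a binary consortium string: {bits!r}")
        return cls(int(bits, 2), len(bits))

    @classmethod
    def from_members(cls, members: Iterable[int], m: int) -> "ConsortiumCode":
        return encode(members, m)

    @property
    def members(self) -> frozenset[int]:
        """1-based indices of the species present."""
        return frozenset(k for k in range(1, self.m + 1) if self.mask >> (k - 1) & 1)

    @property
    def richness(self) -> int:
        return self.mask.bit_count()

    def contains(self, k: int) -> bool:
        if not 1 <= k <= self.m:
            raise ValidationError(f"species index {k} outside 1..{self.m}")
        return bool(self.mask >> (k - 1) & 1)

    def merge(self, other: "ConsortiumCode") -> "ConsortiumCode":
        return merge_disjoint(self, other)

    def __str__(self) -> str:
        return format(self.mask, f"0{self.m}b")


def encode(members: Iterable[int], m: int) -> ConsortiumCode:
    """Encode a set of 1-based species indices as a consortium code.

    >>> str(encode({1, 2, 3}, m=6))
    '000111'
    """
    mask = 0
    for k in members:
        if not 1 <= k <= m:
            raise ValidationError(f"species index {k} outside 1..{m}")
        mask |= 1 << (k - 1)
    return ConsortiumCode(mask, m)


def decode(code: ConsortiumCode) -> frozenset[int]:
    """Inverse of :func:`encode`: the set of species present."""
    return code.members


def hamming_weight(code: ConsortiumCode | int) -> int:
    """Number of species present (richness): the count of 1-bits."""
    mask = code.mask if isinstance(code, ConsortiumCode) else int(code)
    if mask < 0:
        raise ValidationError("negative mask has no Hamming weight")
    return mask.bit_count()


def merge_disjoint(c1: ConsortiumCode, c2: ConsortiumCode) -> ConsortiumCode:
    """Merge two disjoint consortia: binary addition of their codes.

    Raises :class:`ValidationError` if the consortia share any species
    (binary addition then no longer represents the union) or if the code
    widths differ.
    """
    if c1.m != c2.m:
        raise ValidationError(f"code width mismatch: {c1.m} vs {c2.m}")
    if c1.mask & c2.mask:
        shared = sorted(c1.members & c2.members)
        raise ValidationError(
            "this operation only works for disjoint consortia; "
            f"species shared: {shared}"
        )
    return ConsortiumCode(c1.mask + c2.mask, c1.m)


def row_bits(m: int, plate_format: int = 96) -> int:
    """How many low-order bits of a code select the row.

    3 for 96-well (8 rows), 4 for 384-well (16 rows); fewer when the
    library is smaller than the row capacity, in which case everything
    fits in the first column.
    """
    rows, _ = _check_format(plate_format)
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return min(m, rows.bit_length() - 1)


def total_columns(m: int, plate_format: int = 96) -> int:
    """Number of *global* columns the full 2^m layout occupies."""
    return 1 << (m - row_bits(m, plate_format))


def plates_required(m: int, plate_format: int = 96) -> int:
    """How many plates the complete 2^m layout needs."""
    _, cols = _check_format(plate_format)
    return math.ceil(total_columns(m, plate_format) / cols)


@dataclass(frozen=True)
class WellAddress:
    """A physical well position, aware of multi-plate column continuation.

    ``j_global`` counts columns across all plates (columns 13–24 of a
    96-well layout live on plate 2, and so on); ``j_local`` is the column
    within its plate.
    """

    plate: int
    i: int
    j_global: int
    j_local: int
    well_name: str

    @classmethod
    def from_indices(cls, i: int, j_global: int, plate_format: int = 96) -> "WellAddress":
        rows, cols = _check_format(plate_format)
        if not 1 <= i <= rows:
            raise ValidationError(f"row index {i} outside 1..{rows}")
        if j_global < 1:
            raise ValidationError(f"global column index {j_global} must be >= 1")
        plate = (j_global - 1) // cols + 1
        j_local = (j_global - 1) % cols + 1
        return cls(plate, i, j_global, j_local, f"{_ROW_LETTERS[i - 1]}{j_local:02d}")

    @property
    def row_letter(self) -> str:
        return _ROW_LETTERS[self.i - 1]


def code_to_well(code: ConsortiumCode, plate_format: int = 96) -> WellAddress:
    """Map a consortium code to its canonical well.

    The low ``row_bits`` bits of the code give the row (``B(i-1)``) and the
    remaining high bits give the global column (``B(j-1)``).
    """
    r = row_bits(code.m, plate_format)
    i = (code.mask & ((1 << r) - 1)) + 1
    j_global = (code.mask >> r) + 1
    return WellAddress.from_indices(i, j_global, plate_format)


def well_to_code(i: int, j_global: int, m: int, plate_format: int = 96) -> ConsortiumCode:
    """Inverse of :func:`code_to_well`."""
    rows, _ = _check_format(plate_format)
    r = row_bits(m, plate_format)
    if not 1 <= i <= (1 << r):
        raise ValidationError(f"row index {i} outside 1..{1 << r} for m={m}")
    n_cols = total_columns(m, plate_format)
    if not 1 <= j_global <= n_cols:
        raise ValidationError(f"global column {j_global} outside 1..{n_cols} for m={m}")
    return ConsortiumCode(((j_global - 1) << r) | (i - 1), m)


def hamming_split(i: int, j_global: int) -> int:
    """Richness of the consortium at (row i, global column j).

    Sum of the Hamming weights of the row index and column index (both
    zero-based): ``H(B(i-1)) + H(B(j-1))``.  Equals
    ``hamming_weight(well_to_code(i, j))`` at every well.
    """
    if i < 1 or j_global < 1:
        raise ValidationError("row and column indices are 1-based")
    return (i - 1).bit_count() + (j_global - 1).bit_count()


@dataclass(frozen=True)
class PlacementRule:
    """Where species ``k`` goes: alternating blocks of rows or global columns."""

    species: int
    axis: str  # "rows" or "columns"
    block: int  # size of each alternating block
    positions: tuple[int, ...]


def species_positions(k: int, m: int, plate_format: int = 96) -> PlacementRule:
    """Placement rule for species ``k`` under the canonical layout.

    Low-index species (k <= 3 on 96-well) occupy alternating sets of
    ``2^(k-1)`` rows; the rest occupy alternating sets of ``2^(k-1-row_bits)``
    global columns.  Agrees with the bit decomposition of
    :func:`well_to_code` at every well.
    """
    if not 1 <= k <= m:
        raise ValidationError(f"species index {k} outside 1..{m}")
    r = row_bits(m, plate_format)
    if k <= r:
        block = 1 << (k - 1)
        positions = tuple(i for i in range(1, (1 << r) + 1) if (i - 1) >> (k - 1) & 1)
        return PlacementRule(k, "rows", block, positions)
    block = 1 << (k - 1 - r)
    n_cols = total_columns(m, plate_format)
    positions = tuple(j for j in range(1, n_cols + 1) if (j - 1) >> (k - 1 - r) & 1)
    return PlacementRule(k, "columns", block, positions)


@dataclass
class PlateLayout:
    """The bijection between all 2^m consortium codes and well addresses.

    Codes appear in increasing integer order top-to-bottom within a column
    and left-to-right across columns and plates, so the empty consortium is
    well A01 of plate 1 and the full consortium is the last used well of
    the last plate.
    """

    library: SpeciesLibrary
    plate_format: int = 96
    _by_code: dict[int, WellAddress] = field(init=False, repr=False)
    _by_well: dict[tuple[int, str], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        _check_format(self.plate_format)
        m = self.library.m
        self._by_code = {}
        self._by_well = {}
        for mask in range(1 << m):
            addr = code_to_well(ConsortiumCode(mask, m), self.plate_format)
            self._by_code[mask] = addr
            self._by_well[(addr.plate, addr.well_name)] = mask

    @property
    def m(self) -> int:
        return self.library.m

    @property
    def n_consortia(self) -> int:
        return 1 << self.m

    @property
    def n_plates(self) -> int:
        return plates_required(self.m, self.plate_format)

    def well_of(self, code: ConsortiumCode | int) -> WellAddress:
        mask = code.mask if isinstance(code, ConsortiumCode) else int(code)
        return self._by_code[mask]

    def code_at(self, plate: int, well_name: str) -> ConsortiumCode:
        try:
            mask = self._by_well[(plate, well_name)]
        except KeyError:
            raise ValidationError(
                f"well {well_name!r} on plate {plate} is not part of the layout"
            ) from None
        return ConsortiumCode(mask, self.m)

    def __iter__(self) -> Iterator[tuple[ConsortiumCode, WellAddress]]:
        for mask in range(self.n_consortia):
            yield ConsortiumCode(mask, self.m), self._by_code[mask]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per used well, in code order."""
        rows = []
        for code, addr in self:
            rows.append(
                {
                    "plate": addr.plate,
                    "row_letter": addr.row_letter,
                    "col_local": addr.j_local,
                    "well_name": addr.well_name,
                    "col_global": addr.j_global,
                    "consortium_binary": str(code),
                    "consortium_int": code.mask,
                    "richness": code.richness,
                }
            )
        return pd.DataFrame(rows)
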