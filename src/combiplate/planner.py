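"""Pipetting plans for full-factorial consortium assembly, plus an exact
liquid-transfer simulator that verifies them.

Two strategies realize the same endpoint:

``direct_dispense`` (default)
    The 2^3 (or 2^4 on 384-well) starting mixes of the row-wise species are
    prepared in tubes, dispensed into every global column with a
    row-channel pipette, and the remaining species are then added
    column-wise wherever the layout places them.  With full density
    homogenization the tubes already carry their buffer share, so the
    row-wise buffer pass is bypassed and every dispense is a single
    uniform-volume multichannel stroke.

``block_duplication``
    The literal column-doubling scheme: build the starting column, then at
    round t copy columns 1..2^(t-1) onto columns 2^(t-1)+1..2^t (half of
    each well's content) and add the next species to the new columns.  To
    end with each present species at one aliquot v0, species entering at
    round t are pipetted at 2^(rounds-t)·v0 and the starting column at
    2^rounds·v0 per species — so first-column volumes grow as 3·2^(m-3)·v0
    and the planner raises :class:`CapacityError` when a well would
    overflow, which is the honest outcome for large m at bench volumes.

Density homogenization adds buffer so that every present species sits at
1/m of its monoculture density: a consortium c receives v0·(m − H(c)) of
buffer, split positionally into a column-wise term v0·(m−3−H(B(j−1))) and
a row-wise term v0·(3−H(B(i−1))).

All volumes are exact :class:`fractions.Fraction` internally; exports
round to 0.1 µL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Literal, Sequence

import pandas as pd

from .codec import (
    ConsortiumCode,
    PlateLayout,
    SpeciesLibrary,
    WellAddress,
    code_to_well,
    plates_required,
    row_bits,
    total_columns,
    well_to_code,
)
from .errors import CapacityError, SimulationError, ValidationError

__all__ = [
    "PlanConfig",
    "PipettingStep",
    "ProtocolPlan",
    "WellState",
    "SimulationResult",
    "StockSource",
    "BufferSource",
    "TubeSource",
    "TubeRackSource",
    "WellsSource",
    "TubeDest",
    "buffer_volume_code",
    "buffer_volume_positional",
    "plan_assembly",
    "simulate_transfers",
    "verify_plan",
    "naive_event_count",
    "inoculation_summary",
    "expected_total_volume",
]

Strategy = Literal["direct_dispense", "block_duplication"]
Homogenize = Literal["full", "column_only", "off"]

PHASES = (
    "starting_mixes",
    "duplication",
    "species_addition",
    "buffer_column",
    "buffer_row",
    "inoculation",
)


def _as_fraction(x) -> Fraction:
    """Exact volume from int/float/str/Fraction; floats go via str to keep
    e.g. 0.1 µL exact."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


# ---------------------------------------------------------------------------
# Sources and destinations


@dataclass(frozen=True)
class StockSource:
    """Monoculture stock of one species (effectively unlimited)."""

    species: int

    def label(self, library: SpeciesLibrary) -> str:
        return f"stock:{library.name(self.species)}"


@dataclass(frozen=True)
class BufferSource:
    def label(self, library: SpeciesLibrary) -> str:
        return "buffer"


@dataclass(frozen=True)
class TubeSource:
    """One starting-mix tube, identified by its row-species bitmask."""

    tube: int  # mask over the row-wise species
    bits: int  # number of row-wise species (render width)

    def label(self, library: SpeciesLibrary) -> str:
        return f"tube:{format(self.tube, f'0{self.bits}b')}"


@dataclass(frozen=True)
class TubeRackSource:
    """The full tube rack: destination row i draws from tube B(i-1)."""

    bits: int

    def label(self, library: SpeciesLibrary) -> str:
        return "tube_rack"


@dataclass(frozen=True)
class WellsSource:
    """Plate wells, aligned one-to-one with the step's destinations."""

    wells: tuple[WellAddress, ...]

    def label(self, library: SpeciesLibrary) -> str:
        if len(self.wells) == 1:
            w = self.wells[0]
            return f"plate{w.plate}:{w.well_name}"
        plates = {w.plate for w in self.wells}
        names = f"{self.wells[0].well_name}-{self.wells[-1].well_name}"
        return f"plate{min(plates)}:{names}"


@dataclass(frozen=True)
class TubeDest:
    tube: int
    bits: int

    @property
    def name(self) -> str:
        return f"tube:{format(self.tube, f'0{self.bits}b')}"


Source = StockSource | BufferSource | TubeSource | TubeRackSource | WellsSource
Destination = WellAddress | TubeDest


# ---------------------------------------------------------------------------
# Config / plan containers


@dataclass
class PlanConfig:
    """Everything needed to lay out and pipette a full-factorial assembly."""

    library: SpeciesLibrary
    v0: Fraction  # per-species aliquot volume, µL
    plate_format: int = 96
    strategy: Strategy = "direct_dispense"
    homogenize: Homogenize = "full"
    buffer_name: str = "buffer"
    well_capacity: Fraction = Fraction(300)  # µL; 96-well working volume
    inoculum_volume: Fraction = Fraction(1, 2)  # µL
    culture_volume: Fraction = Fraction(200)  # µL

    def __post_init__(self) -> None:
        self.v0 = _as_fraction(self.v0)
        self.well_capacity = _as_fraction(self.well_capacity)
        self.inoculum_volume = _as_fraction(self.inoculum_volume)
        self.culture_volume = _as_fraction(self.culture_volume)
        if self.v0 <= 0:
            raise ValidationError(f"v0 must be positive, got {self.v0}")
        if self.well_capacity <= 0:
            raise ValidationError("well_capacity must be positive")
        if self.strategy not in ("direct_dispense", "block_duplication"):
            raise ValidationError(f"unknown strategy {self.strategy!r}")
        if self.homogenize not in ("full", "column_only", "off"):
            raise ValidationError(f"unknown homogenize mode {self.homogenize!r}")

    @property
    def m(self) -> int:
        return self.library.m


@dataclass(frozen=True)
class PipettingStep:
    index: int
    phase: str
    reagent: str
    source: Source
    destinations: tuple[Destination, ...]
    volume: Fraction  # µL per destination
    channel_mode: str  # "single" | "8-channel" | "12-channel" | ...

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValidationError(f"step {self.index}: volume must be positive")
        if not self.destinations:
            raise ValidationError(f"step {self.index}: no destinations")
        if self.phase not in PHASES:
            raise ValidationError(f"step {self.index}: unknown phase {self.phase!r}")


@dataclass
class ProtocolPlan:
    config: PlanConfig
    steps: list[PipettingStep]
    resources: dict
    notes: list[str] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def worklist_frame(self) -> pd.DataFrame:
        """Machine-readable worklist, one row per step."""
        lib = self.config.library
        rows = []
        for s in self.steps:
            dests = [
                d.well_name if isinstance(d, WellAddress) else d.name
                for d in s.destinations
            ]
            dest_plates = sorted(
                {d.plate for d in s.destinations if isinstance(d, WellAddress)}
            )
            rows.append(
                {
                    "step": s.index,
                    "phase": s.phase,
                    "reagent": s.reagent,
                    "source": s.source.label(lib),
                    "dest_plate": ";".join(str(p) for p in dest_plates) or "rack",
                    "dest_wells": ";".join(dests),
                    "volume_uL": round(float(s.volume), 1),
                    "channel_mode": s.channel_mode,
                }
            )
        return pd.DataFrame(rows)

    def protocol_text(self) -> str:
        """Human-readable numbered protocol, grouped by phase."""
        lib = self.config.library
        lines = [
            f"Full-factorial assembly protocol: m={self.config.m} species, "
            f"v0={float(self.config.v0):g} uL, {self.config.plate_format}-well plates, "
            f"strategy={self.config.strategy}, homogenize={self.config.homogenize}",
            f"Resources: {self.resources['plates']} plate(s), "
            f"{self.resources['tubes']} tube(s), ~{self.resources['tips_estimate']} tips",
            "",
        ]
        current_phase = None
        for s in self.steps:
            if s.phase != current_phase:
                current_phase = s.phase
                lines.append(f"-- {s.phase.replace('_', ' ')} --")
            dests = [
                f"plate {d.plate} {d.well_name}" if isinstance(d, WellAddress) else d.name
                for d in s.destinations
            ]
            if len(dests) > 4:
                dest_txt = f"{dests[0]} .. {dests[-1]} ({len(dests)} wells)"
            else:
                dest_txt = ", ".join(dests)
            lines.append(
                f"{s.index:4d}. [{s.channel_mode}] {round(float(s.volume), 1)} uL "
                f"of {s.reagent} from {s.source.label(lib)} -> {dest_txt}"
            )
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Buffer arithmetic


def buffer_volume_code(code: ConsortiumCode, v0) -> Fraction:
    """Buffer needed by consortium c for full homogenization: v0·(m − H(c))."""
    return _as_fraction(v0) * (code.m - code.richness)


def buffer_volume_positional(
    i: int, j_global: int, m: int, v0, plate_format: int = 96
) -> tuple[Fraction, Fraction]:
    """(row term, column term) of the homogenization buffer at well (i, j).

    row term = v0·(r − H(B(i−1))), column term = v0·(m − r − H(B(j−1)))
    with r the number of row-wise species (3 on 96-well).  Their sum equals
    :func:`buffer_volume_code` of the well's consortium.
    """
    v0 = _as_fraction(v0)
    r = row_bits(m, plate_format)
    row_term = v0 * (r - (i - 1).bit_count())
    col_term = v0 * (m - r - (j_global - 1).bit_count())
    if row_term < 0 or col_term < 0:
        raise ValidationError(f"indices (i={i}, j={j_global}) outside the m={m} layout")
    return row_term, col_term


def naive_event_count(m: int) -> int:
    """Liquid-handling events a well-by-well assembly would need: m·2^(m−1).

    Each of the m species must be pipetted individually into each of the
    2^(m−1) consortia containing it.  The planner's step count is compared
    against this baseline.
    """
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return m * (1 << (m - 1))


def inoculation_summary(config: PlanConfig) -> dict:
    """Dilution bookkeeping for seeding fresh medium from assembled consortia.

    With fully homogenized densities, an inoculum of volume V from any
    consortium carries V/m of each present species' monoculture.
    """
    if config.homogenize != "full":
        raise ValidationError(
            "inoculation summary assumes uniform densities (homogenize='full')"
        )
    dilution = config.culture_volume / config.inoculum_volume
    return {
        "inoculum_volume_uL": float(config.inoculum_volume),
        "culture_volume_uL": float(config.culture_volume),
        "dilution_factor": f"1:{float(dilution):g}",
        "per_strain_volume_uL": float(config.inoculum_volume / config.m),
    }


def expected_total_volume(code: ConsortiumCode, config: PlanConfig) -> Fraction:
    """Final per-well volume the plan must reach for consortium ``code``."""
    v0 = config.v0
    h = code.richness
    m = code.m
    if config.homogenize == "full":
        return m * v0
    if config.homogenize == "column_only":
        r = row_bits(m, config.plate_format)
        addr = code_to_well(code, config.plate_format)
        col_h = (addr.j_global - 1).bit_count()
        return h * v0 + v0 * (m - r - col_h)
    return h * v0


# ---------------------------------------------------------------------------
# Plan construction


def plan_assembly(config: PlanConfig, validate: bool = True) -> ProtocolPlan:
    """Build the ordered pipetting plan for the full 2^m layout.

    When ``validate`` is true (default) the plan is immediately run through
    :func:`simulate_transfers`; a well exceeding ``config.well_capacity``
    at any intermediate step raises :class:`CapacityError` naming the step,
    and any composition mismatch against the layout raises
    :class:`SimulationError` (which would indicate a planner bug).
    """
    m = config.m
    r = row_bits(m, config.plate_format)
    if config.strategy == "direct_dispense":
        steps, tubes = _plan_direct(config, r)
    else:
        steps, tubes = _plan_block(config, r)

    tips = 0
    for s in steps:
        if s.channel_mode == "single":
            tips += 1
        else:
            tips += int(s.channel_mode.split("-")[0])
    resources = {
        "plates": plates_required(m, config.plate_format),
        "tubes": tubes,
        "tips_estimate": tips,
        "n_steps": len(steps),
        "naive_event_count": naive_event_count(m),
    }
    notes = [
        "tip estimate assumes a fresh tip set per step",
        "volumes are exact; no dead-volume overage is included",
    ]
    plan = ProtocolPlan(config, steps, resources, notes)
    if validate:
        verify_plan(plan)
    return plan


def _column_wells(
    j_global: int, r: int, plate_format: int
) -> tuple[WellAddress, ...]:
    return tuple(
        WellAddress.from_indices(i, j_global, plate_format)
        for i in range(1, (1 << r) + 1)
    )


def _row_channel(r: int) -> str:
    return f"{1 << r}-channel"


def _plan_direct(config: PlanConfig, r: int) -> tuple[list[PipettingStep], int]:
    m, v0, fmt = config.m, config.v0, config.plate_format
    lib = config.library
    n_cols = total_columns(m, fmt)
    _, cols_per_plate = (8, 12) if fmt == 96 else (16, 24)
    steps: list[PipettingStep] = []
    idx = 0

    def add(phase, reagent, source, dests, volume, channel):
        nonlocal idx
        idx += 1
        steps.append(PipettingStep(idx, phase, reagent, source, tuple(dests), volume, channel))

    n_tubes = 1 << r
    # --- starting mixes in tubes ---------------------------------------
    for t in range(n_tubes):
        dest = (TubeDest(t, r),)
        for k in range(1, r + 1):
            if t >> (k - 1) & 1:
                add(
                    "starting_mixes",
                    lib.name(k),
                    StockSource(k),
                    dest,
                    v0 * n_cols,
                    "single",
                )
        if config.homogenize == "full":
            b = (r - t.bit_count()) * v0 * n_cols
            if b > 0:
                add("starting_mixes", config.buffer_name, BufferSource(), dest, b, "single")

    # --- dispense starting mixes to every column -----------------------
    if config.homogenize == "full":
        # every tube dispenses the same r·v0 per well: one multichannel
        # stroke per global column from the aligned tube rack
        for j in range(1, n_cols + 1):
            add(
                "duplication",
                "starting mixes",
                TubeRackSource(r),
                _column_wells(j, r, fmt),
                r * v0,
                _row_channel(r),
            )
    else:
        # per-tube volumes differ (H(t)·v0): dispense tube t row-wise into
        # its row across each plate's used columns
        n_plates = plates_required(m, fmt)
        for plate in range(1, n_plates + 1):
            lo = (plate - 1) * cols_per_plate + 1
            hi = min(plate * cols_per_plate, n_cols)
            for t in range(1, n_tubes):  # tube 0 is empty: nothing to dispense
                i = t + 1
                dests = tuple(
                    WellAddress.from_indices(i, j, fmt) for j in range(lo, hi + 1)
                )
                add(
                    "duplication",
                    f"starting mix {format(t, f'0{r}b')}",
                    TubeSource(t, r),
                    dests,
                    t.bit_count() * v0,
                    f"{len(dests)}-channel" if len(dests) > 1 else "single",
                )

    # --- column-wise additions of species r+1..m -----------------------
    for k in range(r + 1, m + 1):
        for j in range(1, n_cols + 1):
            if (j - 1) >> (k - 1 - r) & 1:
                add(
                    "species_addition",
                    lib.name(k),
                    StockSource(k),
                    _column_wells(j, r, fmt),
                    v0,
                    _row_channel(r),
                )

    # --- column-wise buffer ---------------------------------------------
    if config.homogenize in ("full", "column_only"):
        for j in range(1, n_cols + 1):
            b = v0 * (m - r - (j - 1).bit_count())
            if b > 0:
                add(
                    "buffer_column",
                    config.buffer_name,
                    BufferSource(),
                    _column_wells(j, r, fmt),
                    b,
                    _row_channel(r),
                )
    return steps, n_tubes


def _plan_block(config: PlanConfig, r: int) -> tuple[list[PipettingStep], int]:
    m, v0, fmt = config.m, config.v0, config.plate_format
    lib = config.library
    n_rounds = m - r
    n_cols = total_columns(m, fmt)
    _, cols_per_plate = (8, 12) if fmt == 96 else (16, 24)
    steps: list[PipettingStep] = []
    idx = 0

    def add(phase, reagent, source, dests, volume, channel):
        nonlocal idx
        idx += 1
        steps.append(PipettingStep(idx, phase, reagent, source, tuple(dests), volume, channel))

    # --- starting column: species 1..r at 2^rounds · v0 each ------------
    scale0 = (1 << n_rounds) * v0
    for k in range(1, r + 1):
        dests = tuple(
            WellAddress.from_indices(i, 1, fmt)
            for i in range(1, (1 << r) + 1)
            if (i - 1) >> (k - 1) & 1
        )
        add("starting_mixes", lib.name(k), StockSource(k), dests, scale0, "single")

    # --- doubling rounds -------------------------------------------------
    for t in range(1, n_rounds + 1):
        half = 1 << (t - 1)
        k = r + t
        transfer_unit = (1 << (n_rounds - t)) * v0  # per present species
        for j in range(1, half + 1):
            for i in range(1, (1 << r) + 1):
                src_code = well_to_code(i, j, m, fmt)
                h = src_code.richness
                if h == 0:
                    continue  # the empty well has nothing to transfer
                src = WellAddress.from_indices(i, j, fmt)
                dst = WellAddress.from_indices(i, j + half, fmt)
                add(
                    "duplication",
                    f"consortium {src_code}",
                    WellsSource((src,)),
                    (dst,),
                    h * transfer_unit,
                    "single",
                )
        for j in range(half + 1, 2 * half + 1):
            add(
                "species_addition",
                lib.name(k),
                StockSource(k),
                _column_wells(j, r, fmt),
                transfer_unit,
                _row_channel(r),
            )

    # --- homogenization buffer, column then row (positional split) ------
    if config.homogenize in ("full", "column_only"):
        for j in range(1, n_cols + 1):
            b = v0 * (m - r - (j - 1).bit_count())
            if b > 0:
                add(
                    "buffer_column",
                    config.buffer_name,
                    BufferSource(),
                    _column_wells(j, r, fmt),
                    b,
                    _row_channel(r),
                )
    if config.homogenize == "full":
        n_plates = plates_required(m, fmt)
        for plate in range(1, n_plates + 1):
            lo = (plate - 1) * cols_per_plate + 1
            hi = min(plate * cols_per_plate, n_cols)
            for i in range(1, (1 << r) + 1):
                b = v0 * (r - (i - 1).bit_count())
                if b > 0:
                    dests = tuple(
                        WellAddress.from_indices(i, j, fmt) for j in range(lo, hi + 1)
                    )
                    add(
                        "buffer_row",
                        config.buffer_name,
                        BufferSource(),
                        dests,
                        b,
                        f"{len(dests)}-channel" if len(dests) > 1 else "single",
                    )
    return steps, 0


# ---------------------------------------------------------------------------
# Transfer simulator (the oracle for every plan)


@dataclass
class WellState:
    """Contents of one well or tube, in monoculture-equivalent µL."""

    species: dict[int, Fraction] = field(default_factory=dict)
    buffer: Fraction = Fraction(0)

    @property
    def total(self) -> Fraction:
        return sum(self.species.values(), Fraction(0)) + self.buffer

    def add_species(self, k: int, vol: Fraction) -> None:
        self.species[k] = self.species.get(k, Fraction(0)) + vol

    def withdraw(self, vol: Fraction) -> "WellState":
        """Remove ``vol`` with proportional composition; return the aliquot."""
        total = self.total
        if vol > total:
            raise SimulationError(
                f"cannot withdraw {float(vol):g} uL from a source holding {float(total):g} uL"
            )
        frac = vol / total
        taken = WellState(
            {k: v * frac for k, v in self.species.items()}, self.buffer * frac
        )
        for k in list(self.species):
            self.species[k] -= taken.species[k]
        self.buffer -= taken.buffer
        return taken

    def receive(self, aliquot: "WellState") -> None:
        for k, v in aliquot.species.items():
            self.add_species(k, v)
        self.buffer += aliquot.buffer


@dataclass
class SimulationResult:
    wells: dict[WellAddress, WellState]
    tubes: dict[int, WellState]
    max_volume: Fraction
    max_volume_step: int

    def table(self, config: PlanConfig) -> pd.DataFrame:
        """Final per-well composition, joined to the layout codes."""
        m = config.m
        rows = []
        layout = PlateLayout(config.library, config.plate_format)
        for code, addr in layout:
            state = self.wells.get(addr, WellState())
            row = {
                "plate": addr.plate,
                "well_name": addr.well_name,
                "consortium_binary": str(code),
                "total_uL": float(state.total),
                "buffer_uL": float(state.buffer),
            }
            for k in range(1, m + 1):
                row[f"vol_{config.library.name(k)}_uL"] = float(
                    state.species.get(k, Fraction(0))
                )
            rows.append(row)
        return pd.DataFrame(rows)


def simulate_transfers(
    plan: ProtocolPlan, capacity_check: bool = True
) -> SimulationResult:
    """Deterministically propagate every step's volumes through the plates.

    Stocks and the buffer reservoir are unlimited; tubes and wells start
    empty and transfer with proportional composition.  Raises
    :class:`SimulationError` on a transfer from an empty source and, when
    ``capacity_check`` is set, :class:`CapacityError` the first time a well
    would exceed ``config.well_capacity``.
    """
    config = plan.config
    wells: dict[WellAddress, WellState] = {}
    tubes: dict[int, WellState] = {}
    max_vol, max_step = Fraction(0), 0

    def well(addr: WellAddress) -> WellState:
        return wells.setdefault(addr, WellState())

    for step in plan.steps:
        src = step.source
        for pos, dest in enumerate(step.destinations):
            if isinstance(src, StockSource):
                aliquot = WellState({src.species: step.volume})
            elif isinstance(src, BufferSource):
                aliquot = WellState(buffer=step.volume)
            elif isinstance(src, TubeSource):
                tube = tubes.get(src.tube)
                if tube is None or tube.total == 0:
                    raise SimulationError(
                        f"step {step.index}: transfer from empty tube {src.tube}"
                    )
                aliquot = tube.withdraw(step.volume)
            elif isinstance(src, TubeRackSource):
                assert isinstance(dest, WellAddress)
                t = dest.i - 1
                tube = tubes.get(t)
                if tube is None or tube.total == 0:
                    raise SimulationError(
                        f"step {step.index}: transfer from empty tube {t}"
                    )
                aliquot = tube.withdraw(step.volume)
            elif isinstance(src, WellsSource):
                src_addr = src.wells[pos if len(src.wells) > 1 else 0]
                src_state = wells.get(src_addr)
                if src_state is None or src_state.total == 0:
                    raise SimulationError(
                        f"step {step.index}: transfer from empty well "
                        f"plate {src_addr.plate} {src_addr.well_name}"
                    )
                aliquot = src_state.withdraw(step.volume)
            else:  # pragma: no cover
                raise SimulationError(f"step {step.index}: unknown source {src!r}")

            if isinstance(dest, TubeDest):
                tubes.setdefault(dest.tube, WellState()).receive(aliquot)
            else:
                state = well(dest)
                state.receive(aliquot)
                if state.total > max_vol:
                    max_vol, max_step = state.total, step.index
                if capacity_check and state.total > config.well_capacity:
                    raise CapacityError(
                        f"step {step.index} ({step.phase}) raises well "
                        f"plate {dest.plate} {dest.well_name} to "
                        f"{float(state.total):g} uL, above the "
                        f"{float(config.well_capacity):g} uL capacity",
                        step_index=step.index,
                        volume=state.total,
                    )
    return SimulationResult(wells, tubes, max_vol, max_step)


def verify_plan(plan: ProtocolPlan) -> SimulationResult:
    """Simulate a plan and check it reaches the layout's exact endpoint.

    Every well must contain precisely the species of its layout code, each
    at one aliquot v0 of monoculture equivalent, with the buffer volume the
    homogenization mode prescribes.
    """
    config = plan.config
    result = simulate_transfers(plan)
    layout = PlateLayout(config.library, config.plate_format)
    v0 = config.v0
    for code, addr in layout:
        state = result.wells.get(addr, WellState())
        present = {k for k, v in state.species.items() if v > 0}
        if present != set(code.members):
            raise SimulationError(
                f"well plate {addr.plate} {addr.well_name}: species {sorted(present)} "
                f"!= layout code {code} members {sorted(code.members)}"
            )
        for k in present:
            if state.species[k] != v0:
                raise SimulationError(
                    f"well plate {addr.plate} {addr.well_name}: species {k} at "
                    f"{float(state.species[k]):g} uL, expected v0={float(v0):g}"
                )
        expected = expected_total_volume(code, config)
        if state.total != expected:
            raise SimulationError(
                f"well plate {addr.plate} {addr.well_name}: total "
                f"{float(state.total):g} uL, expected {float(expected):g}"
            )
    return result
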