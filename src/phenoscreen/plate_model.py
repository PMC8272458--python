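"""Domain model for 384-well screening plates.

Plate maps are long-format CSV with header
``well,role,compound_id,concentration_uM,replicate`` and zero-padded well
addresses ("A01".."P24").  A plate layout is only valid when every one of the
384 addresses is present exactly once, every compound well carries a
compound identifier, and concentrations are positive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

ROWS = "ABCDEFGHIJKLMNOP"
N_COLUMNS = 24
N_WELLS = len(ROWS) * N_COLUMNS

PLATE_MAP_COLUMNS = ["well", "role", "compound_id", "concentration_uM", "replicate"]


class PlateMapError(ValueError):
    """A plate-map file violates the layout contract."""


class WellRole(str, Enum):
    ACTIVE_CONTROL = "active_control"
    NEGATIVE_CONTROL = "negative_control"
    COMPOUND = "compound"
    EMPTY = "empty"


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well on a 384-well plate, e.g. row "B", column 2 -> "B02"."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise PlateMapError(f"row {self.row!r} outside A-{ROWS[-1]}")
        if not 1 <= self.column <= N_COLUMNS:
            raise PlateMapError(f"column {self.column} outside 1-{N_COLUMNS}")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        s = str(text).strip().upper()
        if len(s) < 2 or len(s) > 3 or not s[1:].isdigit():
            raise PlateMapError(f"malformed well address {text!r}")
        return cls(row=s[0], column=int(s[1:]))

    def __str__(self) -> str:
        return f"{self.row}{self.column:02d}"


def all_addresses() -> list[WellAddress]:
    """All 384 addresses in row-major (A01..A24, B01.., P24) order."""
    return [WellAddress(r, c) for r in ROWS for c in range(1, N_COLUMNS + 1)]


@dataclass(frozen=True)
class WellEntry:
    """Role plus compound assignment of one well."""

    role: WellRole
    compound_id: str | None = None
    concentration_um: float | None = None

    def __post_init__(self) -> None:
        if self.role is WellRole.COMPOUND and not self.compound_id:
            raise PlateMapError("compound well lacking compound_id")
        if self.role is not WellRole.COMPOUND and self.compound_id:
            raise PlateMapError(
                f"compound_id {self.compound_id!r} on a {self.role.value} well"
            )
        if self.concentration_um is not None and not self.concentration_um > 0:
            raise PlateMapError(f"non-positive concentration {self.concentration_um}")


@dataclass
class PlateLayout:
    """A fully specified 384-well plate: one entry per address."""

    plate_id: str
    replicate_id: int
    wells: dict[WellAddress, WellEntry]

    def __post_init__(self) -> None:
        if self.replicate_id < 1:
            raise PlateMapError(f"replicate_id {self.replicate_id} < 1")
        missing = set(all_addresses()) - set(self.wells)
        if missing:
            raise PlateMapError(
                f"plate {self.plate_id}: {len(missing)} of {N_WELLS} addresses "
                f"missing (e.g. {sorted(missing)[0]})"
            )
        if len(self.wells) != N_WELLS:
            raise PlateMapError(
                f"plate {self.plate_id}: {len(self.wells)} wells, expected {N_WELLS}"
            )

    def addresses_with_role(self, role: WellRole) -> list[WellAddress]:
        return sorted(a for a, e in self.wells.items() if e.role is role)

    def role_counts(self) -> dict[WellRole, int]:
        counts = {r: 0 for r in WellRole}
        for entry in self.wells.values():
            counts[entry.role] += 1
        return counts

    def compound_ids(self) -> list[str]:
        return [
            e.compound_id  # type: ignore[misc]
            for _, e in sorted(self.wells.items())
            if e.role is WellRole.COMPOUND
        ]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table in canonical (row-major) well order."""
        rows = []
        for addr in all_addresses():
            e = self.wells[addr]
            rows.append(
                {
                    "well": str(addr),
                    "role": e.role.value,
                    "compound_id": e.compound_id,
                    "concentration_uM": e.concentration_um,
                    "replicate": self.replicate_id,
                }
            )
        return pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS)


def parse_plate_map(path: str | Path | io.IOBase, plate_id: str | None = None) -> PlateLayout:
    """Read a long-format CSV plate map into a validated :class:`PlateLayout`.

    ``plate_id`` defaults to a ``plate`` column if present, else the file stem.
    """
    df = pd.read_csv(path, dtype={"compound_id": "string"})
    missing_cols = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PlateMapError(f"plate map missing columns {missing_cols}")
    if plate_id is None:
        if "plate" in df.columns:
            plate_id = str(df["plate"].iloc[0])
        elif isinstance(path, (str, Path)):
            plate_id = Path(path).stem
        else:
            plate_id = "plate"

    replicates = df["replicate"].unique()
    if len(replicates) != 1:
        raise PlateMapError(f"plate map mixes replicates {sorted(replicates)}")

    wells: dict[WellAddress, WellEntry] = {}
    for rec in df.itertuples(index=False):
        addr = WellAddress.parse(rec.well)
        if addr in wells:
            raise PlateMapError(f"duplicate well address {addr}")
        try:
            role = WellRole(str(rec.role))
        except ValueError:
            raise PlateMapError(f"unknown role {rec.role!r} at {addr}") from None
        compound = None if pd.isna(rec.compound_id) else str(rec.compound_id)
        conc = None if pd.isna(rec.concentration_uM) else float(rec.concentration_uM)
        wells[addr] = WellEntry(role=role, compound_id=compound, concentration_um=conc)

    return PlateLayout(plate_id=plate_id, replicate_id=int(replicates[0]), wells=wells)


def write_plate_map(layout: PlateLayout, path: str | Path) -> None:
    """Write the canonical CSV form (row-major well order, empty cells blank)."""
    layout.to_frame().to_csv(path, index=False, na_rep="")


def validate_layout(layout: PlateLayout, min_controls: int = 8) -> list[str]:
    """Named findings preventing (or qualifying) use of a plate for scoring.

    Empty list means the layout is usable.  Findings, not exceptions: a
    caller may still inspect a deficient plate.
    """
    findings: list[str] = []
    counts = layout.role_counts()
    if counts[WellRole.ACTIVE_CONTROL] < min_controls:
        findings.append("insufficient_active_controls")
    if counts[WellRole.NEGATIVE_CONTROL] < min_controls:
        findings.append("insufficient_negative_controls")
    if counts[WellRole.COMPOUND] == 0:
        findings.append("no_compound_wells")
    return findings


def read_compound_annotations(path: str | Path | io.IOBase) -> pd.DataFrame:
    """Read a compound -> target-class table (columns compound_id, target_class)."""
    df = pd.read_csv(path, dtype="string")
    for col in ("compound_id", "target_class"):
        if col not in df.columns:
            raise PlateMapError(f"annotation table missing column {col!r}")
    dup = df["compound_id"].duplicated()
    if dup.any():
        raise PlateMapError(
            f"duplicate compound_id in annotation table: {df.loc[dup, 'compound_id'].iloc[0]}"
        )
    return df[["compound_id", "target_class"]].reset_index(drop=True)


@dataclass
class ScreenRun:
    """All plates of a screen plus the compound annotation table."""

    plates: list[PlateLayout]
    annotation: pd.DataFrame | None = None

    def by_replicate(self) -> dict[int, list[PlateLayout]]:
        grouped: dict[int, list[PlateLayout]] = {}
        for p in self.plates:
            grouped.setdefault(p.replicate_id, []).append(p)
        return grouped

    def validate(self, min_controls: int = 8) -> list[str]:
        """Layout findings for every plate plus cross-replicate coverage checks."""
        findings: list[str] = []
        for p in self.plates:
            findings += [f"{p.plate_id}:{f}" for f in validate_layout(p, min_controls)]
        seen: dict[str, set[int]] = {}
        for p in self.plates:
            for cid in p.compound_ids():
                seen.setdefault(cid, set()).add(p.replicate_id)
        for cid, reps in sorted(seen.items()):
            if len(reps) < 2:
                findings.append(f"compound_in_single_replicate:{cid}")
        return findings
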