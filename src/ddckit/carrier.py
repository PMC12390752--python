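"""Geometric and structural model of one DNA domino-array data carrier (DDC).

A carrier is a rectangular origami whose label lattice can sit in two
conformations: locked **OFF** (compact row pitch) and unlocked **ON**
(stretched row pitch).  Thirteen displaceable edge staples carry 3' overhangs
(a primer-binding domain plus a toehold) drawn from seven orthogonal domain
sequences; single-stranded scaffold gap regions on the short sides hold the
primers that start the polymerase gap-filling reaction.  Removing the edge
staples and resolving the gaps flips the structure OFF -> ON, which stretches
the lattice and moves every label — including a two-site marker pair whose
separation reports the conformation at a glance.

The geometry here is deliberately minimal: labels live on a rectangular
lattice with per-conformation pitches, and only the OFF < ON pitch ratio is
load-bearing for the rest of the system.  Absolute nanometre values are
configuration, not physics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

from .errors import DesignError

OFF = "OFF"
ON = "ON"
IC = "IC"  # intermediate conformation
UC = "UC"  # uncertain conformation (observation-side only)

CONFORMATIONS = (OFF, ON)

SCHEMA_VERSION = 1

#: Default overhang domain identifiers: 7 orthogonal domains cycled over the
#: 13 edge staples.
DEFAULT_DOMAIN_IDS = tuple(f"dom{i % 7 + 1}" for i in range(13))


@dataclass
class CarrierDesign:
    """Structural description of one DDC.

    ``marker_sites`` are lattice indices (row, col) of the two always-biotin
    marker labels; they may lie outside the data lattice (the default puts
    them in a column of their own, left of the array) and are placed with the
    same pitch rule as data sites.  The address row is lattice row -1, above
    message row 0.
    """

    design_id: str
    grid_rows: int = 5
    grid_cols: int = 5
    address_rows: int = 1
    n_edge_staples: int = 13
    overhang_domain_ids: tuple[str, ...] = DEFAULT_DOMAIN_IDS
    gap_region_seqs: tuple[str, ...] = ()
    overhang_domain_seqs: dict[str, str] = field(default_factory=dict)
    n_gap_regions: int = 2
    scaffold_id: str = "synM13-7249-s1942"
    breakpoint: int = 0
    pitch_off: tuple[float, float] = (6.0, 6.0)
    pitch_on: tuple[float, float] = (6.0, 12.0)
    marker_sites: tuple[tuple[int, int], tuple[int, int]] = ((2, -2), (4, -2))

    def __post_init__(self) -> None:
        self.overhang_domain_ids = tuple(self.overhang_domain_ids)
        self.gap_region_seqs = tuple(self.gap_region_seqs)
        self.marker_sites = tuple(tuple(m) for m in self.marker_sites)  # type: ignore[assignment]
        if min(self.grid_rows, self.grid_cols, self.address_rows) < 1:
            raise DesignError("grid dimensions must be positive")
        if any(p <= 0 for p in (*self.pitch_off, *self.pitch_on)):
            raise DesignError("pitches must be positive")
        if len(self.overhang_domain_ids) != self.n_edge_staples:
            raise DesignError(
                f"need one overhang domain per edge staple "
                f"({self.n_edge_staples}), got {len(self.overhang_domain_ids)}"
            )
        if self.gap_region_seqs and len(self.gap_region_seqs) != self.n_gap_regions:
            raise DesignError("gap_region_seqs length must equal n_gap_regions")
        if self.overhang_domain_seqs:
            missing = set(self.overhang_domain_ids) - set(self.overhang_domain_seqs)
            if missing:
                raise DesignError(f"missing sequences for overhang domains {sorted(missing)}")
        if self.marker_sites[0] == self.marker_sites[1]:
            raise DesignError("marker sites must be distinct")
        if not marker_distance(self, ON) > marker_distance(self, OFF):
            raise DesignError(
                "ON marker distance must exceed OFF marker distance "
                "(the lattice must stretch on unlocking)"
            )

    # -- derived quantities ---------------------------------------------

    @property
    def n_label_sites(self) -> int:
        """Addressable label sites: message array plus address row(s)."""
        return (self.grid_rows + self.address_rows) * self.grid_cols

    @property
    def domain_ids_distinct(self) -> tuple[str, ...]:
        """Distinct overhang domains in first-appearance order."""
        seen: dict[str, None] = {}
        for d in self.overhang_domain_ids:
            seen.setdefault(d)
        return tuple(seen)

    @property
    def has_sequences(self) -> bool:
        return bool(self.gap_region_seqs) and bool(self.overhang_domain_seqs)

    def lattice_sites(self) -> list[tuple[int, int]]:
        """All (row, col) label sites, address row(s) first (row -1 ...)."""
        return [
            (r, c)
            for r in range(-self.address_rows, self.grid_rows)
            for c in range(self.grid_cols)
        ]

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CarrierDesign":
        d = dict(d)
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise DesignError(f"unsupported design schema version {version}")
        d["overhang_domain_ids"] = tuple(d.get("overhang_domain_ids", DEFAULT_DOMAIN_IDS))
        d["gap_region_seqs"] = tuple(d.get("gap_region_seqs", ()))
        d["pitch_off"] = tuple(d["pitch_off"])
        d["pitch_on"] = tuple(d["pitch_on"])
        d["marker_sites"] = tuple(tuple(m) for m in d["marker_sites"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CarrierDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_design(name: str) -> CarrierDesign:
    """Load one of the shipped carrier designs (e.g. ``"DDC-1"``)."""
    ref = resources.files("ddckit") / "designs" / f"{name}.json"
    return CarrierDesign.from_dict(json.loads(ref.read_text()))


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _pitch(design: CarrierDesign, conf: str) -> tuple[float, float]:
    if conf == OFF:
        return design.pitch_off
    if conf == ON:
        return design.pitch_on
    raise DesignError(f"conformation must be {OFF!r} or {ON!r}, got {conf!r}")


def site_xy(design: CarrierDesign, row: int, col: int, conf: str) -> tuple[float, float]:
    """Deterministic label position (nm) of lattice site (row, col).

    Rows run from ``-address_rows`` (address row above the array) to
    ``grid_rows - 1``; the x pitch is shared by both conformations, the y
    pitch stretches OFF -> ON.
    """
    if not (-design.address_rows <= row < design.grid_rows):
        raise DesignError(f"row {row} outside lattice")
    if not (0 <= col < design.grid_cols):
        raise DesignError(f"col {col} outside lattice")
    dx, dy = _pitch(design, conf)
    return (col * dx, row * dy)


def _free_xy(design: CarrierDesign, row: int, col: int, conf: str) -> tuple[float, float]:
    dx, dy = _pitch(design, conf)
    return (col * dx, row * dy)


def site_xy_partial(
    design: CarrierDesign, row: int, col: int, pivot: int
) -> tuple[float, float]:
    """Label position in a partially transformed (intermediate) structure.

    Rows up to ``pivot`` keep the OFF row pitch; row gaps beyond it are
    stretched to the ON pitch — a one-dimensional picture of a conformational
    wave that stalled after ``pivot`` row intervals.
    """
    dx, dy_off = design.pitch_off
    _, dy_on = design.pitch_on
    if row <= pivot:
        y = row * dy_off
    else:
        y = pivot * dy_off + (row - pivot) * dy_on
    return (col * dx, y)


def marker_xy(design: CarrierDesign, index: int, conf: str) -> tuple[float, float]:
    row, col = design.marker_sites[index]
    return _free_xy(design, row, col, conf)


def marker_distance(design: CarrierDesign, conf: str) -> float:
    """Euclidean separation of the two conformation-marker labels (nm)."""
    (r1, c1), (r2, c2) = design.marker_sites
    x1, y1 = _free_xy(design, r1, c1, conf)
    x2, y2 = _free_xy(design, r2, c2, conf)
    return math.hypot(x2 - x1, y2 - y1)


# ---------------------------------------------------------------------------
# Conformation state machine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConformationState:
    """Structural state derived from per-edge and per-gap progress flags."""

    category: str
    edges_displaced: tuple[bool, ...]
    gaps_filled: tuple[bool, ...]


def derive_state(
    design: CarrierDesign,
    edges_displaced: Sequence[bool],
    gaps_filled: Sequence[bool],
) -> ConformationState:
    """Classify a structure from its reaction progress flags.

    No edge displaced and no gap resolved -> OFF; everything done -> ON;
    any partial combination -> IC.
    """
    edges = tuple(bool(e) for e in edges_displaced)
    gaps = tuple(bool(g) for g in gaps_filled)
    if len(edges) != design.n_edge_staples:
        raise DesignError(
            f"expected {design.n_edge_staples} edge flags, got {len(edges)}"
        )
    if len(gaps) != design.n_gap_regions:
        raise DesignError(
            f"expected {design.n_gap_regions} gap flags, got {len(gaps)}"
        )
    flags = edges + gaps
    if not any(flags):
        category = OFF
    elif all(flags):
        category = ON
    else:
        category = IC
    return ConformationState(category, edges, gaps)
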