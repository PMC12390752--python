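"""Stochastic readout simulator and synthetic-fixture generator.

One simulated observation of a carrier proceeds in three stages:

1. **Transformation.**  The key class fixes the net probability ``p`` that
   the structure reaches the unlocked ON conformation: ``p_admin`` for the
   polymerase key, ``p_user`` for a matched trigger-strand set, and
   ``p_spont`` (trigger-free background) for no key or a mismatched key.
   Internally the transformation *attempt* fires with probability
   ``p / (1 - p_ic)`` and a started attempt stalls in an intermediate (IC)
   conformation with probability ``p_ic``, so the configured ``p`` is
   exactly the ON-state yield — the quantity the yield model ``p * q**n``
   takes as input.  Stalled structures freeze at a random row pivot.
2. **Labelling.**  Every biotin site ("1" bit, plus the two always-biotin
   marker sites) independently acquires a streptavidin label with
   probability ``q``; plain-staple sites ("0" bits) produce a false spot
   with probability ``fp_rate`` (default 0).  Streptavidin multivalency is
   not a separate failure channel: the wet protocol suppresses it with
   excess label and blank spacing columns, so any residue is folded into
   ``1 - q``.
3. **Localisation.**  Each labelled site emits one spot at its lattice
   position under the realised conformation, blurred by isotropic Gaussian
   noise of ``loc_sigma_nm``.

The per-structure truth record (category, per-site binding, source grid)
makes simulated fields usable as ground-truthed fixtures for the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .access import AdminKey, Key, UserKey, matches
from .carrier import (
    IC,
    OFF,
    ON,
    CarrierDesign,
    marker_xy,
    site_xy,
    site_xy_partial,
)
from .codec import MessageGrid
from .errors import DesignError, ParameterError


@dataclass(frozen=True)
class ReadoutParams:
    """Probabilities and noise levels of one readout condition.

    ``p_user`` / ``p_admin`` are the ON-conformation yields measured for the
    two key classes; ``p_spont`` is the trigger-free transformation rate
    (1 - OFF retention).  ``p_ic`` and ``loc_sigma_nm`` are free parameters
    of the synthetic readout (no measured counterpart): defaults are a small
    stall fraction and a localisation error well under the lattice pitch.
    """

    p_user: float = 0.89
    p_admin: float = 0.76
    p_spont: float = 0.14
    p_ic: float = 0.05
    q: float = 0.95
    fp_rate: float = 0.0
    loc_sigma_nm: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_user", "p_admin", "p_spont", "p_ic", "q", "fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.loc_sigma_nm < 0:
            raise ParameterError("loc_sigma_nm must be >= 0")
        for name in ("p_user", "p_admin", "p_spont"):
            if getattr(self, name) > 1.0 - self.p_ic:
                raise ParameterError(
                    f"{name} > 1 - p_ic: requested ON yield is unreachable "
                    f"with stall fraction {self.p_ic}"
                )


@dataclass
class SpotTruth:
    """Ground-truth annotations attached to a simulated spot field."""

    category: str
    pivot: int | None
    bound: np.ndarray  # (address_rows + grid_rows, grid_cols) bool, spot emitted
    marker_bound: np.ndarray  # (n_markers,) bool
    grid: MessageGrid
    corrinfo: bool


@dataclass
class SpotField:
    """Observed or simulated 2-D label coordinates (nm)."""

    xy: np.ndarray  # (n_spots, 2) float
    truth: SpotTruth | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if not np.isfinite(self.xy).all():
            raise ParameterError("spot coordinates must be finite")

    @property
    def n_spots(self) -> int:
        return self.xy.shape[0]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.xy, columns=["x_nm", "y_nm"])
        if self.truth is not None:
            df["truth_category"] = self.truth.category
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpotField":
        df = pd.read_csv(path)
        return cls(df[["x_nm", "y_nm"]].to_numpy())


def transformation_probability(
    design: CarrierDesign, key: Key | None, params: ReadoutParams
) -> float:
    """Net ON-conformation probability for a key-design pairing."""
    if key is None:
        return params.p_spont
    if isinstance(key, AdminKey):
        return params.p_admin
    return params.p_user if matches(key, design) else params.p_spont


def _draw_category(p_on: float, p_ic: float, rng: np.random.Generator) -> str:
    p_attempt = p_on / (1.0 - p_ic) if p_ic < 1.0 else 1.0
    if rng.random() >= p_attempt:
        return OFF
    return IC if rng.random() < p_ic else ON


def _draw_pivot(design: CarrierDesign, rng: np.random.Generator) -> int:
    hi = max(design.grid_rows - 2, 1)
    return int(rng.integers(1, hi + 1)) if hi > 1 else 1


class _Geometry:
    """Precomputed site positions for every conformation of one design."""

    def __init__(self, design: CarrierDesign):
        self.design = design
        rows = range(-design.address_rows, design.grid_rows)
        self.site_rc = [(r, c) for r in rows for c in range(design.grid_cols)]
        self.pos: dict[tuple[str, int | None], np.ndarray] = {}
        for conf in (OFF, ON):
            sites = [site_xy(design, r, c, conf) for r, c in self.site_rc]
            markers = [marker_xy(design, i, conf) for i in range(len(design.marker_sites))]
            self.pos[(conf, None)] = np.array(sites + markers, dtype=float)
        for pivot in range(1, max(design.grid_rows - 1, 2)):
            sites = [site_xy_partial(design, r, c, pivot) for r, c in self.site_rc]
            markers = [
                site_xy_partial(design, mr, mc, pivot) for mr, mc in design.marker_sites
            ]
            self.pos[(IC, pivot)] = np.array(sites + markers, dtype=float)

    def positions(self, category: str, pivot: int | None) -> np.ndarray:
        if category == IC:
            return self.pos[(IC, pivot)]
        return self.pos[(category, None)]


_GEOMETRY_CACHE: dict[tuple, _Geometry] = {}


def _geometry(design: CarrierDesign) -> _Geometry:
    key = (
        design.design_id,
        design.grid_rows,
        design.grid_cols,
        design.address_rows,
        design.pitch_off,
        design.pitch_on,
        design.marker_sites,
    )
    geo = _GEOMETRY_CACHE.get(key)
    if geo is None:
        geo = _GEOMETRY_CACHE[key] = _Geometry(design)
    return geo


def _grid_bits(design: CarrierDesign, grid: MessageGrid) -> np.ndarray:
    """Stacked (address above message) bit matrix, checked against design."""
    if (
        grid.grid_rows != design.grid_rows
        or grid.grid_cols != design.grid_cols
        or grid.address_bits.shape[0] != design.address_rows
    ):
        raise DesignError(
            f"grid shape {grid.address_bits.shape[0]}+{grid.grid_rows}x{grid.grid_cols} "
            f"does not match design {design.design_id!r}"
        )
    return np.vstack([grid.address_bits, grid.message_bits])


def simulate_structure(
    design: CarrierDesign,
    grid: MessageGrid,
    key: Key | None,
    params: ReadoutParams,
    rng: np.random.Generator,
) -> SpotField:
    """Simulate one carrier readout.

    The grid is taken as the *physical* label layout — whether it is the
    scrambled or plain form is irrelevant to the physics.  Returns a spot
    field with full ground-truth annotation.
    """
    bits = _grid_bits(design, grid)
    geo = _geometry(design)
    p_on = transformation_probability(design, key, params)
    category = _draw_category(p_on, params.p_ic, rng)
    pivot = _draw_pivot(design, rng) if category == IC else None

    flat_bits = bits.ravel().astype(bool)
    u = rng.random(flat_bits.size)
    emitted = np.where(flat_bits, u < params.q, u < params.fp_rate)
    marker_emitted = rng.random(len(design.marker_sites)) < params.q

    positions = geo.positions(category, pivot)
    n_sites = flat_bits.size
    emit_mask = np.concatenate([emitted, marker_emitted])
    xy = positions[emit_mask]
    if params.loc_sigma_nm > 0 and len(xy):
        xy = xy + rng.normal(0.0, params.loc_sigma_nm, size=xy.shape)

    false_spot = bool((emitted & ~flat_bits).any())
    all_bound = bool(emitted[flat_bits].all())
    corrinfo = category == ON and all_bound and not false_spot
    truth = SpotTruth(
        category=category,
        pivot=pivot,
        bound=emitted.reshape(bits.shape),
        marker_bound=marker_emitted,
        grid=grid,
        corrinfo=corrinfo,
    )
    return SpotField(xy=xy.reshape(-1, 2), truth=truth)


@dataclass
class EnsembleResult:
    """Independent readout draws plus their truth tally."""

    fields: list[SpotField]
    tally: dict[str, int]
    corrinfo_count: int
    n: int
    seed: int | None = None

    @property
    def corrinfo_fraction(self) -> float:
        return self.corrinfo_count / self.n


def simulate_ensemble(
    design: CarrierDesign,
    grid: MessageGrid,
    key: Key | None,
    params: ReadoutParams,
    n_structures: int,
    seed: int | None = None,
    keep_fields: bool = True,
) -> EnsembleResult:
    """Simulate ``n_structures`` independent readouts.

    One root seed (argument wins over ``params.seed``) spawns a child stream
    per structure, so ensembles are reproducible bit for bit and individual
    structures can be re-simulated in isolation.  ``keep_fields=False``
    discards the spot fields and returns only the tally (cheap for large
    Monte-Carlo yield estimates).
    """
    if n_structures < 1:
        raise ParameterError("n_structures must be >= 1")
    root_seed = seed if seed is not None else params.seed
    root = np.random.default_rng(root_seed)
    streams = root.spawn(n_structures)
    tally = {OFF: 0, ON: 0, IC: 0}
    corrinfo = 0
    fields: list[SpotField] = []
    for rng in streams:
        f = simulate_structure(design, grid, key, params, rng)
        tally[f.truth.category] += 1
        corrinfo += int(f.truth.corrinfo)
        if keep_fields:
            fields.append(f)
    return EnsembleResult(
        fields=fields, tally=tally, corrinfo_count=corrinfo, n=n_structures, seed=root_seed
    )


def render_raster(
    field: SpotField,
    pixel_nm: float = 2.0,
    psf_sigma_nm: float = 3.0,
    pad_nm: float = 12.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Render a spot field as a synthetic AFM-like intensity image.

    Sum of unit-amplitude isotropic Gaussians on a square-pixel canvas padded
    around the spots (or explicit ``bounds = (x0, y0, x1, y1)``).  Returns
    ``(image, origin)`` with ``image[iy, ix]`` covering the point
    ``origin + pixel_nm * (ix, iy)``.  Deterministic; an empty field gives a
    blank canvas.
    """
    if pixel_nm <= 0:
        raise ParameterError("pixel_nm must be positive")
    if bounds is None:
        if field.n_spots == 0:
            bounds = (0.0, 0.0, 1.0, 1.0)
        else:
            x0, y0 = field.xy.min(axis=0) - pad_nm
            x1, y1 = field.xy.max(axis=0) + pad_nm
            bounds = (float(x0), float(y0), float(x1), float(y1))
    x0, y0, x1, y1 = bounds
    nx = max(int(np.ceil((x1 - x0) / pixel_nm)) + 1, 1)
    ny = max(int(np.ceil((y1 - y0) / pixel_nm)) + 1, 1)
    xs = x0 + pixel_nm * np.arange(nx)
    ys = y0 + pixel_nm * np.arange(ny)
    image = np.zeros((ny, nx), dtype=float)
    inv2s2 = 1.0 / (2.0 * psf_sigma_nm**2)
    for sx, sy in field.xy:
        gx = np.exp(-((xs - sx) ** 2) * inv2s2)
        gy = np.exp(-((ys - sy) ** 2) * inv2s2)
        image += np.outer(gy, gx)
    return image, (x0, y0)
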