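"""Observation-side pipeline: spots -> conformation -> bits -> plaintext.

Reading a carrier from a microscope-style spot field mirrors how labelled
origami are read from AFM images once shape-based reading rules are fixed:

1. **Conformation call.**  The spot cloud is fitted against position
   templates for the locked (OFF), unlocked (ON) and stalled-intermediate
   (IC, one template per stall pivot) lattices.  Fitting is
   translation-only: a nearest-site residual is computed, the median offset
   is removed, and the residual recomputed.  The category is the
   best-fitting template, demoted to UC (uncertain) when no fit passes the
   residual tolerance or when the OFF and ON fits are too close to call.
2. **Bit assignment.**  Each spot is assigned to the nearest template site
   within tolerance; marker-site spots are set aside; data/address sites
   with at least one spot call "1", the rest "0".  Ties break toward the
   lower (row, col) index; off-lattice spots are counted as noise.
3. **Message recovery.**  Only an ON-conformation call decodes: the address
   row is read, the column permutation inverted, and the bit columns mapped
   back to characters.  An OFF carrier read without a key yields only the
   scrambled ciphertext (see :func:`read_ciphertext`).

"Correct information" (CorrInfo) is scored strictly: the carrier must be ON
*and* every called bit must equal the ground-truth pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .carrier import (
    IC,
    OFF,
    ON,
    UC,
    CarrierDesign,
    marker_xy,
    site_xy,
    site_xy_partial,
)
from .codec import (
    EncodingScheme,
    MessageGrid,
    decode_text,
    descramble,
    get_scheme,
    render_ciphertext,
)
from .errors import StateError
from .simulate import SpotField

#: Default residual tolerance, as a fraction of the smallest lattice pitch.
DEFAULT_TOL = 0.35
#: OFF and ON fits within this relative residual of each other -> UC.
DEFAULT_AMBIGUITY = 0.10


@dataclass
class Template:
    """Candidate lattice: category, site positions and their identities."""

    category: str
    pivot: int | None
    sites_xy: np.ndarray  # (m, 2)
    site_rc: list[tuple]  # (row, col) lattice indices; markers as ("marker", i)
    tree: cKDTree


def _build_template(design: CarrierDesign, category: str, pivot: int | None) -> Template:
    rows = range(-design.address_rows, design.grid_rows)
    rc: list[tuple] = [(r, c) for r in rows for c in range(design.grid_cols)]
    if category == IC:
        xy = [site_xy_partial(design, r, c, pivot) for r, c in rc]
        xy += [site_xy_partial(design, mr, mc, pivot) for mr, mc in design.marker_sites]
    else:
        xy = [site_xy(design, r, c, category) for r, c in rc]
        xy += [marker_xy(design, i, category) for i in range(len(design.marker_sites))]
    rc += [("marker", i) for i in range(len(design.marker_sites))]
    arr = np.asarray(xy, dtype=float)
    return Template(category, pivot, arr, rc, cKDTree(arr))


_TEMPLATE_CACHE: dict[tuple, list[Template]] = {}


def build_templates(design: CarrierDesign) -> list[Template]:
    """OFF, ON and intermediate templates for a design (cached)."""
    key = (
        design.design_id,
        design.grid_rows,
        design.grid_cols,
        design.address_rows,
        design.pitch_off,
        design.pitch_on,
        design.marker_sites,
    )
    cached = _TEMPLATE_CACHE.get(key)
    if cached is None:
        pivots = range(1, max(design.grid_rows - 1, 2))
        cached = [_build_template(design, OFF, None), _build_template(design, ON, None)]
        cached += [_build_template(design, IC, p) for p in pivots]
        _TEMPLATE_CACHE[key] = cached
    return cached


def _fit(
    spots: np.ndarray, template: Template, max_shift_nm: float
) -> tuple[float, np.ndarray]:
    """Mean nearest-site residual after one median-offset refinement.

    The refinement shift is clipped to ``max_shift_nm`` per axis: lattice
    registration is anchored by the carrier outline, so only sub-pitch slack
    is physical.  An unbounded shift would let templates with equal internal
    row spacing slide onto one another (a stalled-pivot lattice translated by
    one OFF pitch coincides with the ON lattice on any row subset that skips
    the pivot row), making conformations indistinguishable.
    """
    d0, i0 = template.tree.query(spots)
    shift = np.median(spots - template.sites_xy[i0], axis=0)
    shift = np.clip(shift, -max_shift_nm, max_shift_nm)
    d1, _ = template.tree.query(spots - shift)
    if d1.mean() < d0.mean():
        return float(d1.mean()), shift
    return float(d0.mean()), np.zeros(2)


@dataclass
class ClassifyResult:
    category: str
    residual_nm: float
    translation: np.ndarray
    template: Template | None


def classify_conformation(
    field: SpotField,
    design: CarrierDesign,
    tol: float = DEFAULT_TOL,
    ambiguity: float = DEFAULT_AMBIGUITY,
) -> ClassifyResult:
    """Call the conformation of a spot field.

    Tolerance is expressed as a fraction of the smallest pitch.  An empty
    field is UC, not an error.  IC wins only when a stalled template fits
    strictly better than both pure conformations; an OFF/ON near-tie
    (relative residual gap below ``ambiguity``) is UC.
    """
    if field.n_spots == 0:
        return ClassifyResult(UC, float("inf"), np.zeros(2), None)
    min_pitch = min(*design.pitch_off, *design.pitch_on)
    max_shift = tol * min_pitch
    fits = [(t, *_fit(field.xy, t, max_shift)) for t in build_templates(design)]
    by_cat: dict[str, tuple[Template, float, np.ndarray]] = {}
    for t, res, shift in fits:
        if t.category not in by_cat or res < by_cat[t.category][1]:
            by_cat[t.category] = (t, res, shift)
    t_off, r_off, s_off = by_cat[OFF]
    t_on, r_on, s_on = by_cat[ON]
    t_ic, r_ic, s_ic = by_cat.get(IC, (None, float("inf"), np.zeros(2)))
    best = min(r_off, r_on, r_ic)
    if best > tol * min_pitch:
        return ClassifyResult(UC, best, np.zeros(2), None)
    if r_ic < r_off and r_ic < r_on:
        return ClassifyResult(IC, r_ic, s_ic, t_ic)
    # OFF vs ON: demand a clear margin between the two pure fits
    lo, hi = sorted((r_off, r_on))
    if hi - lo <= ambiguity * max(hi, 1e-12) and not (lo == hi == 0.0):
        return ClassifyResult(UC, lo, np.zeros(2), None)
    if lo == hi == 0.0:
        return ClassifyResult(UC, lo, np.zeros(2), None)
    if r_off <= r_on:
        return ClassifyResult(OFF, r_off, s_off, t_off)
    return ClassifyResult(ON, r_on, s_on, t_on)


@dataclass
class AssignResult:
    bits: np.ndarray  # (address_rows + grid_rows, grid_cols) of {0, 1}
    n_noise: int
    n_multi: int
    marker_hits: int


def assign_spots(
    field: SpotField,
    design: CarrierDesign,
    category: str,
    translation: np.ndarray | None = None,
    tol: float = DEFAULT_TOL,
) -> AssignResult:
    """Call bits by assigning each spot to its nearest template site.

    Requires a resolved pure conformation (OFF or ON).  Spots farther than
    the tolerance from every site are logged as noise; several spots on one
    site still call a single "1"; near-ties between sites break toward the
    lower (row, col) index so calls are deterministic.
    """
    if category not in (OFF, ON):
        raise StateError(f"bit assignment needs OFF or ON, got {category!r}")
    template = next(t for t in build_templates(design) if t.category == category)
    min_pitch = min(*design.pitch_off, *design.pitch_on)
    tol_nm = tol * min_pitch
    bits = np.zeros((design.address_rows + design.grid_rows, design.grid_cols), dtype=np.uint8)
    hit = np.zeros(len(template.site_rc), dtype=int)
    n_noise = 0
    spots = field.xy if translation is None else field.xy - translation
    if len(spots):
        dists, idx = template.tree.query(spots, k=min(2, len(template.site_rc)))
        dists = np.atleast_2d(dists)
        idx = np.atleast_2d(idx)
        for j in range(len(spots)):
            d1 = dists[j, 0]
            best = int(idx[j, 0])
            if idx.shape[1] > 1 and abs(dists[j, 1] - d1) < 1e-9:
                # exact tie: deterministic break toward the lower site index
                best = min(best, int(idx[j, 1]))
            if d1 > tol_nm:
                n_noise += 1
                continue
            hit[best] += 1
    marker_hits = 0
    for site_idx, rc in enumerate(template.site_rc):
        if hit[site_idx] == 0:
            continue
        if rc[0] == "marker":
            marker_hits += hit[site_idx]
            continue
        r, c = rc
        bits[r + design.address_rows, c] = 1
    n_multi = int((hit > 1).sum())
    return AssignResult(bits=bits, n_noise=n_noise, n_multi=n_multi, marker_hits=marker_hits)


@dataclass
class ReadoutCall:
    """Full decoding result for one observed carrier."""

    category: str
    bit_calls: np.ndarray | None
    assignment_residual_nm: float
    decoded_text: str | None
    word_index: int | None
    corrinfo: bool | None

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "bit_calls": None if self.bit_calls is None else self.bit_calls.tolist(),
            "assignment_residual_nm": self.assignment_residual_nm,
            "decoded_text": self.decoded_text,
            "word_index": self.word_index,
            "corrinfo": self.corrinfo,
        }


def _bits_to_grid(bits: np.ndarray, design: CarrierDesign, scheme_id: str) -> MessageGrid:
    return MessageGrid(
        bits[design.address_rows :],
        bits[: design.address_rows],
        scrambled=True,
        scheme_id=scheme_id,
    )


def decode_message(
    field: SpotField,
    design: CarrierDesign,
    scheme: EncodingScheme | None = None,
    truth: MessageGrid | None = None,
    tol: float = DEFAULT_TOL,
    ambiguity: float = DEFAULT_AMBIGUITY,
) -> ReadoutCall:
    """classify -> assign -> descramble -> decode, degrading gracefully.

    Text is recovered only from an ON call (a locked carrier keeps its
    content scrambled).  When the ground-truth grid is supplied, ``corrinfo``
    scores the strict success criterion: ON conformation and a perfect bit
    pattern.  Never raises on degraded input.
    """
    cls = classify_conformation(field, design, tol=tol, ambiguity=ambiguity)
    decoded_text: str | None = None
    word_index: int | None = None
    bit_calls: np.ndarray | None = None
    if cls.category in (OFF, ON):
        assign = assign_spots(field, design, cls.category, cls.translation, tol=tol)
        bit_calls = assign.bits
    if cls.category == ON and bit_calls is not None:
        scheme = scheme or get_scheme("a5")
        grid = _bits_to_grid(bit_calls, design, scheme.scheme_id)
        word_index = grid.word_index
        decoded_text = decode_text([descramble(grid)], scheme).text
    corrinfo: bool | None = None
    if truth is not None:
        truth_bits = np.vstack([truth.address_bits, truth.message_bits])
        corrinfo = (
            cls.category == ON
            and bit_calls is not None
            and bool(np.array_equal(bit_calls, truth_bits))
        )
    return ReadoutCall(
        category=cls.category,
        bit_calls=bit_calls,
        assignment_residual_nm=cls.residual_nm,
        decoded_text=decoded_text,
        word_index=word_index,
        corrinfo=corrinfo,
    )


def read_ciphertext(
    field: SpotField,
    design: CarrierDesign,
    scheme: EncodingScheme | None = None,
    tol: float = DEFAULT_TOL,
) -> str | None:
    """What an unauthorised reader sees on a locked carrier.

    Assigns bits under the OFF template and renders the (still scrambled)
    columns as text.  Returns ``None`` unless the field classifies OFF.
    """
    cls = classify_conformation(field, design, tol=tol)
    if cls.category != OFF:
        return None
    scheme = scheme or get_scheme("a5")
    assign = assign_spots(field, design, OFF, cls.translation, tol=tol)
    return render_ciphertext(_bits_to_grid(assign.bits, design, scheme.scheme_id), scheme)


def find_spots(
    image: np.ndarray,
    origin: tuple[float, float],
    pixel_nm: float,
    min_intensity_rel: float = 0.2,
    min_distance_px: int = 2,
) -> SpotField:
    """Peak detection on a rendered raster, returning spot coordinates (nm)."""
    from skimage.feature import peak_local_max

    if image.size == 0 or image.max() <= 0:
        return SpotField(np.empty((0, 2)))
    peaks = peak_local_max(
        image,
        min_distance=min_distance_px,
        threshold_abs=min_intensity_rel * float(image.max()),
    )
    x0, y0 = origin
    xy = np.column_stack([x0 + peaks[:, 1] * pixel_nm, y0 + peaks[:, 0] * pixel_nm])
    return SpotField(xy)
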