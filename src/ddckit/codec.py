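"""Text <-> bit-grid codec for domino-array data carriers.

A carrier stores one word of a message as a binary label pattern: a
``grid_rows x grid_cols`` message array plus a ``1 x grid_cols`` address row
above it.  Bit convention: 1 = biotin-labelled staple site (streptavidin will
bind there), 0 = plain staple.  Before a carrier is unlocked, the message
bits are mixed by an address-keyed permutation ("scrambled"); reading the
address row lets an authorised reader invert the permutation and recover the
plaintext.

Two encoding schemes ship by default:

``a5``
    5-bit alphabet (space = 0, A = 1 .. Z = 26), one character per column,
    most-significant bit in the top row.  This is the only scheme whose
    per-word footprint fits a 5 x 5 array, and it is the default.
``ascii8``
    8-bit printable ASCII packed row-major across the message array,
    three characters per carrier; words longer than that span carriers.

The scramble family implemented here (``colshift-v1``) cyclically shifts
column ``c`` downward by ``(word_index + c) mod grid_rows``.  It is an
invertible, address-keyed permutation; the rule identifier is stored on the
scheme so alternative families can be plugged in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import CapacityError, EncodingError, StateError

logger = logging.getLogger(__name__)

#: Fallback glyph for bit patterns that map to no character.  Decoding must
#: degrade gracefully on noisy data, never raise.
FALLBACK_GLYPH = "?"

SPACING_NONE = "none"
SPACING_BLANK_COLUMN = "inter_character_blank_column"

_A5_ALPHABET: dict[str, int] = {" ": 0}
_A5_ALPHABET.update({chr(ord("A") + i): i + 1 for i in range(26)})

_ASCII8_ALPHABET: dict[str, int] = {chr(c): c for c in range(32, 127)}


@dataclass(frozen=True)
class EncodingScheme:
    """Parameters of one text-to-grid encoding.

    ``alphabet_map`` must be injective (checked at construction); its inverse
    is used for decoding, with :data:`FALLBACK_GLYPH` for unknown codes.
    """

    scheme_id: str
    bits_per_char: int
    alphabet_map: Mapping[str, int]
    grid_rows: int = 5
    grid_cols: int = 5
    address_rows: int = 1
    spacing_rule: str = SPACING_NONE
    scramble_rule: str = "colshift-v1"

    def __post_init__(self) -> None:
        if self.bits_per_char not in (5, 8):
            raise EncodingError(f"bits_per_char must be 5 or 8, got {self.bits_per_char}")
        codes = list(self.alphabet_map.values())
        if len(set(codes)) != len(codes):
            raise EncodingError("alphabet_map is not injective")
        if max(codes) >= 2**self.bits_per_char:
            raise EncodingError("alphabet code exceeds bits_per_char range")

    @property
    def inverse_map(self) -> dict[int, str]:
        return {v: k for k, v in self.alphabet_map.items()}

    @property
    def chars_per_grid(self) -> int:
        """Maximum characters one carrier can hold (ignoring spacing)."""
        if self.bits_per_char == self.grid_rows:
            return self.grid_cols
        return (self.grid_rows * self.grid_cols) // self.bits_per_char

    @property
    def address_capacity(self) -> int:
        """Number of distinguishable carriers: 2**(address bits)."""
        return 2 ** (self.address_rows * self.grid_cols)


_SCHEMES: dict[str, EncodingScheme] = {}


def register_scheme(scheme: EncodingScheme) -> None:
    _SCHEMES[scheme.scheme_id] = scheme


def get_scheme(scheme_id: str) -> EncodingScheme:
    try:
        return _SCHEMES[scheme_id]
    except KeyError:
        raise EncodingError(f"unknown encoding scheme {scheme_id!r}") from None


register_scheme(
    EncodingScheme(
        scheme_id="a5",
        bits_per_char=5,
        alphabet_map=_A5_ALPHABET,
        spacing_rule=SPACING_BLANK_COLUMN,
    )
)
register_scheme(
    EncodingScheme(
        scheme_id="ascii8",
        bits_per_char=8,
        alphabet_map=_ASCII8_ALPHABET,
        spacing_rule=SPACING_NONE,
    )
)


@dataclass
class PlainMessage:
    """A message over a scheme alphabet, with its per-carrier partition."""

    text: str
    word_partition: list[str] = field(default_factory=list)


@dataclass
class MessageGrid:
    """One carrier's bit pattern: message array plus address row(s).

    Coordinate convention: row-major, origin top-left, 0-based.  The address
    row sits *above* the message array (lattice row -1 in carrier geometry).
    ``n_chars`` records how many characters were laid into the grid before
    spacing, so blank-column insertion knows where the payload ends.
    """

    message_bits: np.ndarray
    address_bits: np.ndarray
    scrambled: bool = False
    scheme_id: str = "a5"
    carrier_ref: str | None = None
    n_chars: int | None = None
    #: True when this carrier continues the previous carrier's word
    #: (multi-carrier words under wide schemes).
    continuation: bool = False

    def __post_init__(self) -> None:
        self.message_bits = np.asarray(self.message_bits, dtype=np.uint8)
        self.address_bits = np.asarray(self.address_bits, dtype=np.uint8)
        for arr, name in ((self.message_bits, "message"), (self.address_bits, "address")):
            if arr.ndim != 2:
                raise CapacityError(f"{name}_bits must be 2-D")
            if not np.isin(arr, (0, 1)).all():
                raise EncodingError(f"{name}_bits entries must be 0 or 1")
        if self.message_bits.shape[1] != self.address_bits.shape[1]:
            raise CapacityError("message and address arrays must share column count")

    @property
    def grid_rows(self) -> int:
        return self.message_bits.shape[0]

    @property
    def grid_cols(self) -> int:
        return self.message_bits.shape[1]

    @property
    def word_index(self) -> int:
        """Address row(s) read as a binary integer, MSB leftmost."""
        bits = self.address_bits.ravel()
        return int("".join(str(int(b)) for b in bits), 2) if bits.size else 0

    def copy(self) -> "MessageGrid":
        return MessageGrid(
            self.message_bits.copy(),
            self.address_bits.copy(),
            scrambled=self.scrambled,
            scheme_id=self.scheme_id,
            carrier_ref=self.carrier_ref,
            n_chars=self.n_chars,
            continuation=self.continuation,
        )

    def same_bits(self, other: "MessageGrid") -> bool:
        return bool(
            np.array_equal(self.message_bits, other.message_bits)
            and np.array_equal(self.address_bits, other.address_bits)
        )

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "scheme_id": self.scheme_id,
            "word_index": self.word_index,
            "bits": {
                "message": self.message_bits.tolist(),
                "address": self.address_bits.tolist(),
            },
            "scrambled": self.scrambled,
            "carrier_ref": self.carrier_ref,
            "n_chars": self.n_chars,
            "continuation": self.continuation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MessageGrid":
        return cls(
            np.array(d["bits"]["message"], dtype=np.uint8),
            np.array(d["bits"]["address"], dtype=np.uint8),
            scrambled=bool(d.get("scrambled", False)),
            scheme_id=d.get("scheme_id", "a5"),
            carrier_ref=d.get("carrier_ref"),
            n_chars=d.get("n_chars"),
            continuation=bool(d.get("continuation", False)),
        )

    def to_text_dump(self) -> str:
        """Plain-text dump: address rows prefixed ``A:``, then message rows."""
        lines = ["A:" + "".join(str(int(b)) for b in row) for row in self.address_bits]
        lines += ["".join(str(int(b)) for b in row) for row in self.message_bits]
        return "\n".join(lines)


def grids_to_json(grids: Sequence[MessageGrid]) -> str:
    return json.dumps([g.to_dict() for g in grids], indent=1)


def grids_from_json(text: str) -> list[MessageGrid]:
    return [MessageGrid.from_dict(d) for d in json.loads(text)]


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


def _char_code(ch: str, scheme: EncodingScheme) -> int:
    try:
        return scheme.alphabet_map[ch]
    except KeyError:
        raise EncodingError(
            f"character {ch!r} is not encodable under scheme {scheme.scheme_id!r}"
        ) from None


def _code_to_column(code: int, rows: int) -> np.ndarray:
    return np.array([(code >> (rows - 1 - r)) & 1 for r in range(rows)], dtype=np.uint8)


def _column_to_code(col: np.ndarray) -> int:
    return int("".join(str(int(b)) for b in col), 2)


def encode_text(msg: PlainMessage | str, scheme: EncodingScheme | None = None) -> list[MessageGrid]:
    """Encode a message into one unscrambled grid per word (per chunk for
    multi-carrier words under wide schemes).

    The address rows are left zeroed; call :func:`assign_address` to number
    the carriers.  Spacing (blank columns between character columns) is
    applied where the scheme requests it and the word is short enough.
    """
    scheme = scheme or get_scheme("a5")
    text = msg.text if isinstance(msg, PlainMessage) else msg
    words = text.split()
    grids: list[MessageGrid] = []
    for word in words:
        grids.extend(_encode_word(word, scheme))
    if len(grids) > scheme.address_capacity:
        raise CapacityError(
            f"message needs {len(grids)} carriers, address capacity is {scheme.address_capacity}"
        )
    return grids


def _encode_word(word: str, scheme: EncodingScheme) -> list[MessageGrid]:
    if scheme.bits_per_char == scheme.grid_rows:
        # column-per-character scheme
        if len(word) > scheme.grid_cols:
            raise CapacityError(
                f"word {word!r} has {len(word)} characters; "
                f"carrier holds at most {scheme.grid_cols}"
            )
        bits = np.zeros((scheme.grid_rows, scheme.grid_cols), dtype=np.uint8)
        for j, ch in enumerate(word):
            bits[:, j] = _code_to_column(_char_code(ch, scheme), scheme.grid_rows)
        grid = MessageGrid(
            bits,
            np.zeros((scheme.address_rows, scheme.grid_cols), dtype=np.uint8),
            scheme_id=scheme.scheme_id,
            n_chars=len(word),
        )
        return [apply_spacing(grid, scheme)]
    # packed row-major scheme: chunk long words over several carriers
    cpg = scheme.chars_per_grid
    out = []
    for start in range(0, len(word), cpg):
        chunk = word[start : start + cpg]
        flat = np.zeros(scheme.grid_rows * scheme.grid_cols, dtype=np.uint8)
        for j, ch in enumerate(chunk):
            code = _char_code(ch, scheme)
            for b in range(scheme.bits_per_char):
                flat[j * scheme.bits_per_char + b] = (code >> (scheme.bits_per_char - 1 - b)) & 1
        out.append(
            MessageGrid(
                flat.reshape(scheme.grid_rows, scheme.grid_cols),
                np.zeros((scheme.address_rows, scheme.grid_cols), dtype=np.uint8),
                scheme_id=scheme.scheme_id,
                n_chars=len(chunk),
                continuation=start > 0,
            )
        )
    return out


def apply_spacing(
    grid: MessageGrid, scheme: EncodingScheme, strict: bool = False
) -> MessageGrid:
    """Insert all-zero columns between character columns of a word.

    Blank columns keep adjacent biotin columns apart so one multivalent
    streptavidin cannot bridge two characters.  When the word is too long for
    interleaved blanks, spacing is dropped with a logged warning (the carrier
    still reads correctly); pass ``strict=True`` to raise instead.
    """
    if scheme.spacing_rule != SPACING_BLANK_COLUMN:
        return grid.copy()
    n = grid.n_chars
    if n is None:
        # infer payload width from the rightmost non-empty column
        nonzero = np.flatnonzero(grid.message_bits.any(axis=0))
        n = int(nonzero[-1]) + 1 if nonzero.size else 0
    if n <= 1:
        return grid.copy()
    needed = 2 * n - 1
    if needed > grid.grid_cols:
        if strict:
            raise CapacityError(
                f"{n} characters with blank-column spacing need {needed} columns, "
                f"grid has {grid.grid_cols}"
            )
        logger.warning(
            "dropping blank-column spacing: %d chars need %d columns, grid has %d",
            n,
            needed,
            grid.grid_cols,
        )
        return grid.copy()
    out = grid.copy()
    spaced = np.zeros_like(grid.message_bits)
    for j in range(n):
        spaced[:, 2 * j] = grid.message_bits[:, j]
    out.message_bits = spaced
    return out


def assign_address(
    grid: MessageGrid, word_index: int, scheme: EncodingScheme | None = None
) -> MessageGrid:
    """Write ``word_index`` into the address row(s), MSB leftmost."""
    scheme = scheme or get_scheme(grid.scheme_id)
    nbits = grid.address_bits.size
    if not 0 <= word_index < 2**nbits:
        raise CapacityError(
            f"word_index {word_index} out of range for {nbits} address bits"
        )
    out = grid.copy()
    bitstring = format(word_index, f"0{nbits}b")
    out.address_bits = np.array(
        [int(b) for b in bitstring], dtype=np.uint8
    ).reshape(grid.address_bits.shape)
    return out


# ---------------------------------------------------------------------------
# Scramble / descramble
# ---------------------------------------------------------------------------


def _column_shifts(grid: MessageGrid) -> np.ndarray:
    w = grid.word_index
    return np.array([(w + c) % grid.grid_rows for c in range(grid.grid_cols)])


def scramble(grid: MessageGrid) -> MessageGrid:
    """Mix address information into the layout: shift column ``c`` down by
    ``(word_index + c) mod grid_rows``.  Conserves the multiset of bits."""
    if grid.scrambled:
        raise StateError("grid is already scrambled")
    out = grid.copy()
    for c, s in enumerate(_column_shifts(grid)):
        out.message_bits[:, c] = np.roll(grid.message_bits[:, c], int(s))
    out.scrambled = True
    return out


def descramble(grid: MessageGrid) -> MessageGrid:
    """Exact inverse of :func:`scramble`, driven only by the address row."""
    if not grid.scrambled:
        raise StateError("grid is not scrambled")
    out = grid.copy()
    for c, s in enumerate(_column_shifts(grid)):
        out.message_bits[:, c] = np.roll(grid.message_bits[:, c], -int(s))
    out.scrambled = False
    return out


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def _decode_grid_word(grid: MessageGrid, scheme: EncodingScheme) -> str:
    inverse = scheme.inverse_map
    chars: list[str] = []
    if scheme.bits_per_char == scheme.grid_rows:
        for c in range(grid.grid_cols):
            code = _column_to_code(grid.message_bits[:, c])
            if code == 0:
                continue  # pad / blank spacing column
            chars.append(inverse.get(code, FALLBACK_GLYPH))
    else:
        flat = grid.message_bits.ravel()
        usable = (flat.size // scheme.bits_per_char) * scheme.bits_per_char
        for start in range(0, usable, scheme.bits_per_char):
            code = _column_to_code(flat[start : start + scheme.bits_per_char])
            if code == 0:
                continue
            chars.append(inverse.get(code, FALLBACK_GLYPH))
    return "".join(chars)


def decode_text(
    grids: Iterable[MessageGrid], scheme: EncodingScheme | None = None
) -> PlainMessage:
    """Recover plaintext from descrambled grids.

    Grids are ordered by their address ``word_index``; blank/pad columns are
    dropped; unknown codes degrade to the fallback glyph.  Never raises on
    unreadable content — only on grids still in the scrambled state.
    """
    grids = list(grids)
    if any(g.scrambled for g in grids):
        raise StateError("decode_text requires descrambled grids")
    scheme = scheme or (get_scheme(grids[0].scheme_id) if grids else get_scheme("a5"))
    ordered = sorted(grids, key=lambda g: g.word_index)
    words: list[str] = []
    for g in ordered:
        part = _decode_grid_word(g, scheme)
        if g.continuation and words:
            words[-1] += part
        elif part:
            words.append(part)
    return PlainMessage(" ".join(words), words)


def render_ciphertext(grid: MessageGrid, scheme: EncodingScheme | None = None) -> str:
    """Render a (typically scrambled) grid as text without descrambling.

    Five-bit column values ``v`` map to the character with code ``64 + v``
    (so A..Z for 1..26 and ``[ \\ ] ^ _`` for 27..31); 0 renders as a space.
    This shows what an unauthorised reader of the locked carrier would see.
    """
    scheme = scheme or get_scheme(grid.scheme_id)
    if scheme.bits_per_char != grid.grid_rows:
        return _decode_grid_word(grid, scheme) or FALLBACK_GLYPH
    out = []
    for c in range(grid.grid_cols):
        v = _column_to_code(grid.message_bits[:, c])
        out.append(" " if v == 0 else chr(64 + v))
    return "".join(out).rstrip()


# ---------------------------------------------------------------------------
# Convenience pipelines
# ---------------------------------------------------------------------------


def encode_message(text: str, scheme: EncodingScheme | None = None) -> list[MessageGrid]:
    """encode -> address -> scramble, the full storage-side pipeline."""
    scheme = scheme or get_scheme("a5")
    grids = encode_text(text, scheme)
    return [scramble(assign_address(g, i, scheme)) for i, g in enumerate(grids)]


def decode_grids(grids: Iterable[MessageGrid], scheme: EncodingScheme | None = None) -> PlainMessage:
    """descramble (where needed) -> decode, the full access-side pipeline."""
    plain = [descramble(g) if g.scrambled else g for g in grids]
    return decode_text(plain, scheme)
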