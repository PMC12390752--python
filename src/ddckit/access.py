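"""Keys, key-carrier matching, and key-space enumeration.

Two key classes unlock a carrier:

* **Admin key** — a polymerase.  It recognises primer-bound regions without
  regard to their sequence, so one admin key transforms *every* well-formed
  carrier (one-to-many).
* **User key** — a set of DNA trigger strands: *competing strands* that are
  exact complements of the carrier's scaffold gap regions (they strip the
  primers by strand competition) and *invading strands* complementary to the
  toehold-bearing edge-staple overhangs (they remove the edge staples by
  toehold-mediated strand displacement).  Complementarity makes the key
  one-to-one with its carrier.

Because the gap-region and overhang sequences are read off the circular
scaffold starting at its breakpoint, shifting the breakpoint yields a fresh
trigger-strand set: the key space.  Candidate keys can be screened for
pairwise orthogonality with a shared reverse-complement k-mer rule.

User keys exist in two modes.  ``sequence`` mode carries actual strand
sequences and matching means exact reverse complementarity; ``abstract``
mode carries only a target design identifier, so the simulator and
statistics layers can run without any sequences at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .carrier import CarrierDesign
from .errors import DerivationError, ModeError, ParameterError

#: M13mp18 scaffold length in nucleotides.
M13MP18_LENGTH = 7249

#: Seed of the shipped synthetic stand-in scaffold.
DEFAULT_SCAFFOLD_SEED = 1942

# Sequence layout carved out of the scaffold, measured from the breakpoint:
# two short-side gap regions, then the seven orthogonal overhang domains
# (toehold + primer-binding segment) in order.
GAP_REGION_LEN = 16
TOEHOLD_LEN = 5
PRIMER_LEN = 10
OVERHANG_LEN = TOEHOLD_LEN + PRIMER_LEN

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string (hot path; plain translate)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Scaffold
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldModel:
    """A circular single-stranded scaffold with a breakpoint register."""

    scaffold_id: str
    length_nt: int
    sequence: str
    breakpoint: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) != self.length_nt:
            raise ParameterError(
                f"sequence length {len(self.sequence)} != declared {self.length_nt}"
            )
        if not 0 <= self.breakpoint < self.length_nt:
            raise ParameterError("breakpoint must lie within the scaffold")
        if set(self.sequence) - set("ACGT"):
            raise ParameterError("scaffold sequence must be over ACGT")

    def window(self, start: int, length: int) -> str:
        """Circular slice of ``length`` nt beginning at position ``start``.

        Wraps as often as needed, so toy scaffolds shorter than the layout
        regions still resolve (the sequence simply repeats).
        """
        start %= self.length_nt
        reps = (start + length) // self.length_nt + 1
        return (self.sequence * reps)[start : start + length]


def random_scaffold(
    seed: int = DEFAULT_SCAFFOLD_SEED,
    length: int = M13MP18_LENGTH,
    scaffold_id: str | None = None,
) -> ScaffoldModel:
    """Seeded synthetic circular scaffold of M13mp18 length.

    A pseudorandom stand-in used where only sequence *diversity* matters
    (key derivation and orthogonality screening), so no sequence download is
    required.  Real scaffolds load via :func:`read_scaffold_fasta`.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return ScaffoldModel(
        scaffold_id=scaffold_id or f"synM13-{length}-s{seed}",
        length_nt=length,
        sequence=seq,
    )


def read_scaffold_fasta(path: str | Path, scaffold_id: str | None = None) -> ScaffoldModel:
    record = next(SeqIO.parse(str(path), "fasta"))
    seq = str(record.seq).upper()
    return ScaffoldModel(
        scaffold_id=scaffold_id or record.id, length_nt=len(seq), sequence=seq
    )


def write_fasta(path: str | Path, entries: Iterable[tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in entries]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Keys
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdminKey:
    """Universal key: a strand-displacing polymerase (dose is informational)."""

    label: str = "admin"
    params: str = "Klenow 8 kU/l, 4 h"


@dataclass(frozen=True)
class UserKey:
    """Design-specific trigger-strand set (or its abstract stand-in)."""

    mode: str = "abstract"
    target_design_id: str | None = None
    competing_strands: tuple[str, ...] = ()
    invading_strands: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("abstract", "sequence"):
            raise ModeError(f"unknown key mode {self.mode!r}")
        if self.mode == "abstract" and not self.target_design_id:
            raise ModeError("abstract keys need a target_design_id")
        if self.mode == "sequence" and not (
            self.competing_strands and self.invading_strands
        ):
            raise ModeError("sequence keys need competing and invading strands")

    @property
    def strands(self) -> tuple[str, ...]:
        return self.competing_strands + self.invading_strands

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "target_design_id": self.target_design_id,
            "competing_strands": list(self.competing_strands),
            "invading_strands": list(self.invading_strands),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UserKey":
        return cls(
            mode=d["mode"],
            target_design_id=d.get("target_design_id"),
            competing_strands=tuple(d.get("competing_strands", ())),
            invading_strands=tuple(d.get("invading_strands", ())),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "UserKey":
        return cls.from_dict(json.loads(Path(path).read_text()))


Key = AdminKey | UserKey


# ---------------------------------------------------------------------------
# Design <-> scaffold resolution and matching
# ---------------------------------------------------------------------------


def breakpoint_sequences(
    scaffold: ScaffoldModel, breakpoint: int, n_gaps: int = 2, n_domains: int = 7
) -> tuple[tuple[str, ...], dict[str, str]]:
    """Gap-region and overhang-domain sequences implied by a breakpoint."""
    gaps = tuple(
        scaffold.window(breakpoint + i * GAP_REGION_LEN, GAP_REGION_LEN)
        for i in range(n_gaps)
    )
    base = breakpoint + n_gaps * GAP_REGION_LEN
    domains = {
        f"dom{i + 1}": scaffold.window(base + i * OVERHANG_LEN, OVERHANG_LEN)
        for i in range(n_domains)
    }
    return gaps, domains


def resolve_design(
    design_id: str,
    scaffold: ScaffoldModel,
    breakpoint: int,
    **overrides,
) -> CarrierDesign:
    """Build a sequence-resolved carrier design at a scaffold breakpoint."""
    gaps, domains = breakpoint_sequences(scaffold, breakpoint)
    return CarrierDesign(
        design_id=design_id,
        gap_region_seqs=gaps,
        overhang_domain_seqs=domains,
        scaffold_id=scaffold.scaffold_id,
        breakpoint=breakpoint % scaffold.length_nt,
        **overrides,
    )


def _design_key_strands(design: CarrierDesign) -> tuple[tuple[str, ...], tuple[str, ...]]:
    competing = tuple(revcomp(g) for g in design.gap_region_seqs)
    invading = tuple(
        revcomp(design.overhang_domain_seqs[d]) for d in design.domain_ids_distinct
    )
    return competing, invading


def matches(key: Key, design: CarrierDesign) -> bool:
    """Does this key unlock this carrier?

    Admin keys match every well-formed design.  Abstract user keys match on
    the design identifier; sequence-mode user keys match iff every trigger
    strand is the exact reverse complement of its counterpart region.
    """
    if isinstance(key, AdminKey):
        return True
    if key.mode == "abstract":
        return key.target_design_id == design.design_id
    if not design.has_sequences:
        raise ModeError(
            f"sequence-mode key against sequenceless design {design.design_id!r}"
        )
    competing, invading = _design_key_strands(design)
    return sorted(key.competing_strands) == sorted(competing) and sorted(
        key.invading_strands
    ) == sorted(invading)


def derive_user_key(design: CarrierDesign, scaffold: ScaffoldModel) -> UserKey:
    """The unique sequence-mode user key for a design.

    Competing strands complement the gap regions; invading strands complement
    the distinct overhang domains (the toehold extension is part of the
    overhang, so full-overhang complements are toehold-extended by
    construction).  ``matches(derive_user_key(D, S), D)`` always holds.
    """
    if design.scaffold_id != scaffold.scaffold_id:
        raise DerivationError(
            f"design references scaffold {design.scaffold_id!r}, "
            f"got {scaffold.scaffold_id!r}"
        )
    if not design.has_sequences:
        gaps, domains = breakpoint_sequences(scaffold, design.breakpoint)
        design = CarrierDesign.from_dict(
            {**design.to_dict(), "gap_region_seqs": gaps, "overhang_domain_seqs": domains}
        )
    competing, invading = _design_key_strands(design)
    return UserKey(
        mode="sequence",
        target_design_id=design.design_id,
        competing_strands=competing,
        invading_strands=invading,
    )


# ---------------------------------------------------------------------------
# Orthogonality and key-space enumeration
# ---------------------------------------------------------------------------


def _longest_common_substring(a: str, b: str) -> int:
    """Length of the longest common substring (dynamic programming)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def cross_hybridization(a: UserKey, b: UserKey) -> int:
    """Longest stretch over which a strand of ``a`` could act on key ``b``'s
    carrier (and vice versa).

    A strand of ``a`` invades a region of ``b``'s carrier iff its reverse
    complement occurs in that region; since ``b``'s regions are the reverse
    complements of ``b``'s own strands, the score reduces to the longest
    common substring between the two strand sets.  Symmetric by
    construction, and equal to the full strand length on self-comparison
    (a key is maximally non-orthogonal to itself).
    """
    for key in (a, b):
        if key.mode != "sequence":
            raise ModeError("cross_hybridization requires sequence-mode keys")
    best = 0
    for sa in a.strands:
        for sb in b.strands:
            best = max(best, _longest_common_substring(sa, sb))
    return best


@dataclass(frozen=True)
class OrthogonalityPolicy:
    """Keys are orthogonal iff no shared reverse-complement k-mer exists.

    ``k = 8`` is a conventional strand-displacement leakage heuristic: an
    8-bp unintended duplex is long enough to nucleate displacement at
    working temperatures.
    """

    k: int = 8

    def orthogonal(self, a: UserKey, b: UserKey) -> bool:
        return cross_hybridization(a, b) < self.k


@dataclass
class KeySpaceResult:
    """Outcome of a breakpoint-shift key enumeration."""

    count: int
    candidates: list[tuple[int, UserKey]]
    min_shift_nt: int
    policy: OrthogonalityPolicy | None


def key_at_breakpoint(scaffold: ScaffoldModel, breakpoint: int) -> UserKey:
    """Sequence-mode key implied by opening the scaffold at ``breakpoint``."""
    gaps, domains = breakpoint_sequences(scaffold, breakpoint)
    return UserKey(
        mode="sequence",
        target_design_id=f"{scaffold.scaffold_id}@bp{breakpoint % scaffold.length_nt}",
        competing_strands=tuple(revcomp(g) for g in gaps),
        invading_strands=tuple(revcomp(s) for s in domains.values()),
    )


def enumerate_breakpoint_keys(
    scaffold: ScaffoldModel,
    min_shift_nt: int = 1,
    orthogonality: OrthogonalityPolicy | None = None,
) -> KeySpaceResult:
    """Enumerate user-key candidates by shifting the scaffold breakpoint.

    Without a policy, every shift of ``min_shift_nt`` gives a candidate:
    ``floor(length_nt / min_shift_nt)`` keys.  With a policy, candidates are
    scanned greedily in breakpoint order and kept only if pairwise orthogonal
    to everything already kept (first-come selection; maximal-independent-set
    optimisation is deliberately out of scope).
    """
    if min_shift_nt < 1:
        raise ParameterError("min_shift_nt must be >= 1")
    n_candidates = scaffold.length_nt // min_shift_nt
    breakpoints = [i * min_shift_nt for i in range(n_candidates)]
    candidates = [(bp, key_at_breakpoint(scaffold, bp)) for bp in breakpoints]
    if orthogonality is not None:
        kept: list[tuple[int, UserKey]] = []
        for bp, key in candidates:
            if all(orthogonality.orthogonal(key, other) for _, other in kept):
                kept.append((bp, key))
        candidates = kept
    return KeySpaceResult(
        count=len(candidates),
        candidates=candidates,
        min_shift_nt=min_shift_nt,
        policy=orthogonality,
    )
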