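"""Standard scaffold, carrier designs and demo payloads.

The two shipped carriers mirror a two-user deployment: DDC-1 and DDC-2 fold
the *same* circular scaffold but open it at different breakpoints, so their
gap-region and edge-overhang sequences — and therefore their user keys —
differ.  DDC-2's breakpoint is chosen by scanning forward from the far side
of the scaffold for the first register whose trigger set is orthogonal to
DDC-1's under the shared reverse-complement k-mer policy.
"""

from __future__ import annotations

import numpy as np

from .access import (
    DEFAULT_SCAFFOLD_SEED,
    OrthogonalityPolicy,
    ScaffoldModel,
    cross_hybridization,
    derive_user_key,
    key_at_breakpoint,
    random_scaffold,
    resolve_design,
)
from .carrier import CarrierDesign
from .codec import MessageGrid, assign_address, scramble
from .errors import DerivationError


def default_scaffold() -> ScaffoldModel:
    """The seeded synthetic scaffold all shipped designs reference."""
    return random_scaffold(seed=DEFAULT_SCAFFOLD_SEED)


def orthogonal_breakpoint(
    scaffold: ScaffoldModel,
    reference_breakpoint: int = 0,
    min_separation: int | None = None,
    policy: OrthogonalityPolicy | None = None,
) -> int:
    """First breakpoint at least ``min_separation`` nt downstream of the
    reference whose key is orthogonal to the reference key."""
    policy = policy or OrthogonalityPolicy()
    if min_separation is None:
        min_separation = scaffold.length_nt // 2
    ref_key = key_at_breakpoint(scaffold, reference_breakpoint)
    for shift in range(min_separation, scaffold.length_nt):
        bp = (reference_breakpoint + shift) % scaffold.length_nt
        if policy.orthogonal(key_at_breakpoint(scaffold, bp), ref_key):
            return bp
    raise DerivationError("no orthogonal breakpoint found on this scaffold")


def standard_designs(
    scaffold: ScaffoldModel | None = None,
) -> tuple[CarrierDesign, CarrierDesign]:
    """Build the DDC-1 / DDC-2 pair used throughout the examples."""
    scaffold = scaffold or default_scaffold()
    ddc1 = resolve_design("DDC-1", scaffold, breakpoint=0)
    bp2 = orthogonal_breakpoint(scaffold, reference_breakpoint=0)
    ddc2 = resolve_design("DDC-2", scaffold, breakpoint=bp2)
    return ddc1, ddc2


def standard_keys(scaffold: ScaffoldModel | None = None):
    """(admin, user-1, user-2) keys for the standard design pair."""
    from .access import AdminKey

    scaffold = scaffold or default_scaffold()
    ddc1, ddc2 = standard_designs(scaffold)
    return AdminKey(), derive_user_key(ddc1, scaffold), derive_user_key(ddc2, scaffold)


#: 5x5 heart-shaped icon payload (1 = biotin site), a non-text data format.
HEART_PATTERN = (
    (0, 1, 0, 1, 0),
    (1, 1, 1, 1, 1),
    (1, 1, 1, 1, 1),
    (0, 1, 1, 1, 0),
    (0, 0, 1, 0, 0),
)


def pattern_grid(
    pattern=HEART_PATTERN, word_index: int = 0, scheme_id: str = "a5"
) -> MessageGrid:
    """Wrap a raw bit pattern as an addressed, scrambled carrier payload."""
    pattern = np.asarray(pattern, dtype=np.uint8)
    grid = MessageGrid(
        pattern,
        np.zeros((1, pattern.shape[1]), dtype=np.uint8),
        scheme_id=scheme_id,
    )
    return scramble(assign_address(grid, word_index))
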