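"""Yield statistics and experiment harnesses.

Two quantities summarise every readout experiment:

* the **empirical yield** ``y_exp = M / N`` — the fraction of intact
  structures showing the expected conformation or pattern, reported with a
  Wilson 95% interval (appropriate for the small counts of image-based
  tallies);
* the **theoretical CorrInfo yield** ``y_theo = p * q**n`` — the chance
  that a carrier both reaches the ON conformation (probability ``p``) and
  has all ``n`` of its biotin sites labelled (each independently with
  probability ``q``).  It decreases monotonically in ``n`` for ``q < 1``:
  denser patterns are harder to read perfectly.

On top sit condition and permission-matrix harnesses that simulate, decode
and tabulate ensembles, attaching the matching ``y_theo`` prediction to
every row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .access import AdminKey, Key, UserKey
from .carrier import IC, OFF, ON, UC, CarrierDesign
from .codec import MessageGrid
from .decode import decode_message
from .errors import ParameterError, UndefinedYieldError
from .simulate import (
    ReadoutParams,
    simulate_ensemble,
    transformation_probability,
)

N_MARKER_SITES = 2


@dataclass(frozen=True)
class YieldEstimate:
    """Empirical yield M/N with a Wilson confidence interval."""

    M: int
    N: int
    y_exp: float
    ci_low: float
    ci_high: float


def yield_exp(M: int, N: int, conf_level: float = 0.95) -> YieldEstimate:
    """Exact fraction of expected outcomes among N intact structures."""
    if N < 1:
        raise UndefinedYieldError("yield undefined for N = 0 structures")
    if not 0 <= M <= N:
        raise ParameterError(f"M={M} must satisfy 0 <= M <= N={N}")
    lo, hi = proportion_confint(M, N, alpha=1 - conf_level, method="wilson")
    return YieldEstimate(M=M, N=N, y_exp=M / N, ci_low=float(lo), ci_high=float(hi))


@dataclass(frozen=True)
class TheoYield:
    """Theoretical CorrInfo yield p * q**n."""

    p: float
    q: float
    n: int
    y_theo: float


def yield_theo(p: float, q: float, n: int) -> TheoYield:
    """ON-conformation probability times per-site labelling success to the
    power of the biotin-site count."""
    if not (0.0 <= p <= 1.0 and 0.0 <= q <= 1.0):
        raise ParameterError("p and q must lie in [0, 1]")
    if n < 0 or int(n) != n:
        raise ParameterError("n must be a non-negative integer")
    return TheoYield(p=p, q=q, n=int(n), y_theo=p * q ** int(n))


def count_biotin_sites(
    grid: MessageGrid, include_markers: bool = False, n_marker_sites: int = N_MARKER_SITES
) -> int:
    """Number of biotin ("1") sites across the data *and* address arrays.

    The two always-biotin marker sites are excluded by default: the
    conformation markers are scored separately from the data pattern.
    """
    n = int(grid.message_bits.sum()) + int(grid.address_bits.sum())
    return n + (n_marker_sites if include_markers else 0)


def _key_label(key: Key | None) -> str:
    if key is None:
        return "none"
    if isinstance(key, AdminKey):
        return key.label
    return f"user:{key.target_design_id}"


def run_condition(
    design: CarrierDesign,
    grid: MessageGrid,
    key: Key | None,
    params: ReadoutParams,
    n_structures: int,
    seed: int | None = None,
    decode_fields: bool = True,
    label: str | None = None,
) -> dict:
    """Simulate one condition and tabulate it as a yield-table row.

    With ``decode_fields=True`` every simulated field goes through the full
    decoder and the OFF/ON/IC/UC tallies are *observed* categories (UC can
    occur); CorrInfo is the decoder's strict pattern match against the
    simulated ground truth.  With ``decode_fields=False`` the tallies come
    from the simulation truth directly (no UC) — much faster for pure
    Monte-Carlo yield estimates and exactly the quantity ``y_theo`` models.
    """
    ens = simulate_ensemble(
        design, grid, key, params, n_structures, seed=seed, keep_fields=decode_fields
    )
    counts = {OFF: 0, ON: 0, IC: 0, UC: 0}
    if decode_fields:
        M = 0
        for f in ens.fields:
            call = decode_message(f, design, truth=grid)
            counts[call.category] += 1
            M += int(bool(call.corrinfo))
    else:
        counts.update(ens.tally)
        M = ens.corrinfo_count
    est = yield_exp(M, n_structures)
    p = transformation_probability(design, key, params)
    n_sites = count_biotin_sites(grid)
    theo = yield_theo(p, params.q, n_sites)
    row = {
        "condition": label or f"{design.design_id}/{_key_label(key)}",
        "design": design.design_id,
        "key": _key_label(key),
        "n_structures": n_structures,
        "n_biotin_sites": n_sites,
        "p": p,
        "q": params.q,
    }
    for cat in (OFF, ON, IC, UC):
        row[f"count_{cat}"] = counts[cat]
        row[f"frac_{cat}"] = counts[cat] / n_structures
    row.update(
        {
            "corrinfo_count": est.M,
            "corrinfo_frac": est.y_exp,
            "corrinfo_ci_low": est.ci_low,
            "corrinfo_ci_high": est.ci_high,
            "y_theo": theo.y_theo,
        }
    )
    return row


def yield_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def hierarchy_matrix(
    designs: list[CarrierDesign],
    grids: list[MessageGrid],
    keys: list[Key],
    params: ReadoutParams,
    n_structures: int,
    seed: int | None = None,
    decode_fields: bool = True,
) -> pd.DataFrame:
    """CorrInfo fraction for every key x carrier pairing.

    Rows are keys, columns are carrier designs.  With the defaults the admin
    row shows ``p_admin``-level access everywhere, the matched user diagonal
    ``p_user``-level access, and mismatched cells fall to the trigger-free
    background.  Per-cell seeds derive from one root seed, so identical
    seeds give identical matrices.
    """
    if len(grids) != len(designs):
        raise ParameterError("need one grid per design")
    root = np.random.default_rng(seed)
    cell_seeds = root.integers(0, 2**31 - 1, size=(len(keys), len(designs)))
    data = np.zeros((len(keys), len(designs)))
    for i, key in enumerate(keys):
        for j, (design, grid) in enumerate(zip(designs, grids)):
            row = run_condition(
                design,
                grid,
                key,
                params,
                n_structures,
                seed=int(cell_seeds[i, j]),
                decode_fields=decode_fields,
            )
            data[i, j] = row["corrinfo_frac"]
    return pd.DataFrame(
        data,
        index=[_key_label(k) for k in keys],
        columns=[d.design_id for d in designs],
    )
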