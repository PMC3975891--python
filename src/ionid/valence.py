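"""Bond-valence sum and VECSUM over a coordination shell.

Each contact j contributes a valence

    s_j = p * exp((r0 - d_j) / b)

where (r0, b) is the bond-valence parameter for the (ion, donor-element)
pair, d_j the contact distance and p the fractional occupancy of the ion
site. The bond-valence sum is the sum of the s_j and should be close to
the formal charge of a correctly assigned ion. VECSUM is the magnitude
of the valence-weighted vector sum of the unit directions to the donors,
normalized by the bond-valence sum: near 0 for a balanced shell, near 1
for one-sided coordination.

Donor atoms without a tabulated parameter contribute zero valence and
are recorded in ``ValenceResult.warnings``. Donor occupancies are not
folded in (only the ion's occupancy enters the formula); partially
occupied donors are noted instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .params import BondValenceParam, MissingParameterError, lookup_bv_param
from .structure import Contact

__all__ = ["ValenceResult", "valence_analysis", "bond_valence_sum", "vecsum"]


@dataclass
class ValenceResult:
    """Bond-valence sum, VECSUM and per-contact contributions for one ion guess."""

    bvs: float
    vecsum: float
    contributions: list[tuple[Contact, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def valence_analysis(
    contacts: Sequence[Contact],
    ion: str,
    occupancy: float = 1.0,
    bv_table: Mapping | None = None,
) -> ValenceResult:
    """Compute BVS and VECSUM for ``ion`` over ``contacts``.

    An empty contact list yields bvs = vecsum = 0 with a warning.
    """
    if occupancy <= 0:
        raise ValueError(f"ion occupancy must be positive, got {occupancy}")
    result = ValenceResult(bvs=0.0, vecsum=0.0)
    if not contacts:
        result.warnings.append("empty coordination shell; bvs = 0")
        return result
    vec = np.zeros(3)
    total = 0.0
    for contact in contacts:
        donor = contact.atom
        try:
            p = lookup_bv_param(ion, donor.element, table=bv_table)
        except MissingParameterError:
            result.warnings.append(
                f"no bond-valence parameter for ({ion}, {donor.element}); "
                f"{donor.id.short()} contributes 0")
            result.contributions.append((contact, 0.0))
            continue
        s = occupancy * math.exp((p.r0 - contact.distance) / p.b)
        result.contributions.append((contact, s))
        total += s
        vec += s * contact.vector
        if donor.occupancy < 1.0:
            result.warnings.append(
                f"donor {donor.id.short()} has partial occupancy "
                f"{donor.occupancy:.2f} (not folded into the sum)")
    result.bvs = total
    result.vecsum = float(np.linalg.norm(vec) / total) if total > 0 else 0.0
    return result


def bond_valence_sum(contacts: Sequence[Contact], ion: str, occupancy: float = 1.0,
                     bv_table: Mapping | None = None) -> float:
    """Bond-valence sum alone (valence units)."""
    return valence_analysis(contacts, ion, occupancy, bv_table).bvs


def vecsum(contacts: Sequence[Contact], ion: str, occupancy: float = 1.0,
           bv_table: Mapping | None = None) -> float:
    """Normalized valence-vector-sum magnitude in [0, 1] (0 if bvs = 0)."""
    return valence_analysis(contacts, ion, occupancy, bv_table).vecsum
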