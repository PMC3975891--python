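"""Curated chemistry for the supported candidate ions.

This module owns three lookup services used throughout the package:

* bond-valence parameters ``(r0, b)`` for ion/donor element pairs, loaded
  from a delimited table shipped with the package;
* per-element :class:`ElementProfile` records (formal charge, allowed
  donor atoms, coordination-number range, geometry requirement);
* expected anomalous scattering ``f''`` as a function of X-ray
  wavelength, tabulated on a 0.05 Angstrom grid from the Cromer-Liberman
  calculation in :mod:`gemmi` and linearly interpolated.

All three accept user overrides (see :func:`load_bv_table` and
:class:`FppTable`) but default to the bundled library.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import gemmi
import yaml

__all__ = [
    "SUPPORTED_ELEMENTS",
    "DEFAULT_CANDIDATES",
    "BondValenceParam",
    "ElementProfile",
    "UnsupportedElementError",
    "MissingParameterError",
    "get_profile",
    "lookup_bv_param",
    "expected_fpp",
    "FppTable",
    "atomic_number",
]

SUPPORTED_ELEMENTS = ("NA", "MG", "CL", "K", "CA", "MN", "FE", "CO", "NI", "CU", "ZN", "CD")

#: Default search candidates, chosen for their frequency in deposited structures.
DEFAULT_CANDIDATES = ("MG", "CA", "ZN", "CL")

#: Default bond-valence softness constant (Angstrom).
DEFAULT_B = 0.37

# Wavelength range (Angstrom) covered by the f'' table.
FPP_WAVELENGTH_RANGE = (0.5, 3.0)
_FPP_STEP = 0.05


class UnsupportedElementError(KeyError):
    """Raised for an element outside the supported candidate set."""

    def __init__(self, element: str):
        super().__init__(f"unsupported element: {element!r} "
                         f"(supported: {', '.join(SUPPORTED_ELEMENTS)})")
        self.element = element


class MissingParameterError(KeyError):
    """Raised when no bond-valence parameter exists for an (ion, donor) pair."""

    def __init__(self, ion: str, donor: str):
        super().__init__(f"no bond-valence parameter for pair ({ion}, {donor})")
        self.ion = ion
        self.donor = donor


@dataclass(frozen=True)
class BondValenceParam:
    """Bond-valence parameter for one ion/donor element pair.

    ``r0`` is the distance (Angstrom) at which a single bond contributes
    one valence unit; ``b`` is the softness constant, 0.37 Angstrom
    unless the source table states otherwise.
    """

    ion: str
    donor: str
    r0: float
    b: float = DEFAULT_B
    source: str = ""

    def __post_init__(self):
        if self.r0 <= 0 or self.b <= 0:
            raise ValueError(f"r0 and b must be positive, got r0={self.r0}, b={self.b}")


@dataclass(frozen=True)
class ElementProfile:
    """Chemical expectations for one candidate element."""

    element: str
    formal_charge: int
    atomic_number: int
    weight_class: str  # "light" (Na, Mg) or "heavy"
    allowed_donors: tuple[tuple[str, str], ...]  # (element, context) pairs
    coordination_range: tuple[int, int]
    required_geometry: str = "any"
    forbidden_donor_residues: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        lo, hi = self.coordination_range
        if lo > hi:
            raise ValueError(f"coordination range inverted for {self.element}: {lo} > {hi}")

    def allows_donor(self, donor_element: str, context: str) -> bool:
        """Whether an atom of ``donor_element`` in ``context`` is an acceptable donor.

        ``context`` is one of ``any``/``CYS``/``MET``/``HIS``/``LIG``/``backbone``;
        an ``(E, "any")`` profile entry accepts every context of element E.
        """
        e = donor_element.upper()
        for allowed_e, allowed_ctx in self.allowed_donors:
            if allowed_e == e and (allowed_ctx == "any" or allowed_ctx == context):
                return True
        return False


def _normalize(element: str) -> str:
    e = element.strip().upper()
    if e not in SUPPORTED_ELEMENTS:
        raise UnsupportedElementError(element)
    return e


def _data_text(name: str) -> str:
    return (resources.files("ionid") / "data" / name).read_text()


def load_bv_table(text: str | None = None) -> dict[tuple[str, str], BondValenceParam]:
    """Parse a bond-valence parameter table.

    The format is tab-separated with columns ion, donor, r0, b, source;
    lines starting with ``#`` are comments. With no argument the bundled
    table is loaded. The (ion, donor) key must be unique.
    """
    if text is None:
        text = _data_text("bond_valence_params.tsv")
    table: dict[tuple[str, str], BondValenceParam] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed bond-valence table line: {line!r}")
        ion, donor = parts[0].upper(), parts[1].upper()
        r0 = float(parts[2])
        b = float(parts[3]) if len(parts) > 3 and parts[3] else DEFAULT_B
        source = parts[4] if len(parts) > 4 else ""
        key = (ion, donor)
        if key in table:
            raise ValueError(f"duplicate bond-valence entry for {key}")
        table[key] = BondValenceParam(ion, donor, r0, b, source)
    return table


@functools.cache
def _default_bv_table() -> Mapping[tuple[str, str], BondValenceParam]:
    return load_bv_table()


def lookup_bv_param(
    ion: str,
    donor: str,
    table: Mapping[tuple[str, str], BondValenceParam] | None = None,
) -> BondValenceParam:
    """Return the bond-valence parameter for an (ion, donor element) pair.

    Raises :class:`MissingParameterError` when the pair is not tabulated;
    callers treat such donors as non-contributing and record a warning.
    """
    ion = _normalize(ion)
    donor = donor.strip().upper()
    tbl = table if table is not None else _default_bv_table()
    try:
        return tbl[(ion, donor)]
    except KeyError:
        raise MissingParameterError(ion, donor) from None


@functools.cache
def _profiles() -> dict[str, ElementProfile]:
    raw = yaml.safe_load(_data_text("element_profiles.yaml"))
    out = {}
    for element, rec in raw.items():
        donors = tuple(tuple(d.split(":", 1)) for d in rec["donors"])
        out[element] = ElementProfile(
            element=element,
            formal_charge=int(rec["formal_charge"]),
            atomic_number=int(rec["atomic_number"]),
            weight_class=rec["weight_class"],
            allowed_donors=donors,
            coordination_range=tuple(rec["coordination_range"]),
            required_geometry=rec.get("required_geometry", "any"),
        )
    return out


def get_profile(element: str) -> ElementProfile:
    """Return the immutable chemistry profile for a supported element."""
    return _profiles()[_normalize(element)]


def atomic_number(element: str) -> int:
    return get_profile(element).atomic_number


class FppTable:
    """Expected anomalous scattering f''(wavelength) per element.

    Values are sampled from the Cromer-Liberman calculation on a regular
    0.05 Angstrom wavelength grid over 0.5-3.0 Angstrom and linearly
    interpolated in between. A user-supplied override table (mapping
    element -> [(wavelength, fpp), ...]) replaces the computed curve for
    those elements.
    """

    def __init__(self, overrides: Mapping[str, Iterable[tuple[float, float]]] | None = None):
        self._grid: dict[str, tuple[list[float], list[float]]] = {}
        if overrides:
            for element, pairs in overrides.items():
                pts = sorted((float(w), float(f)) for w, f in pairs)
                self._grid[element.upper()] = ([p[0] for p in pts], [p[1] for p in pts])

    def _curve(self, element: str) -> tuple[list[float], list[float]]:
        element = _normalize(element)
        if element not in self._grid:
            z = atomic_number(element)
            lo, hi = FPP_WAVELENGTH_RANGE
            n = int(round((hi - lo) / _FPP_STEP)) + 1
            wl = [lo + i * _FPP_STEP for i in range(n)]
            fpp = []
            for w in wl:
                energy_ev = 12398.4 / w
                _, f2 = gemmi.cromer_liberman(z=z, energy=energy_ev)
                fpp.append(max(f2, 0.0))
            self._grid[element] = (wl, fpp)
        return self._grid[element]

    def __call__(self, element: str, wavelength: float) -> float:
        wl, fpp = self._curve(element)
        if not wl[0] <= wavelength <= wl[-1]:
            raise ValueError(
                f"wavelength {wavelength} Angstrom outside tabulated range "
                f"[{wl[0]}, {wl[-1]}]")
        # linear interpolation on the grid
        import bisect

        i = bisect.bisect_right(wl, wavelength) - 1
        if i == len(wl) - 1:
            return fpp[-1]
        frac = (wavelength - wl[i]) / (wl[i + 1] - wl[i])
        return fpp[i] * (1 - frac) + fpp[i + 1] * frac


@functools.cache
def _default_fpp_table() -> FppTable:
    return FppTable()


def expected_fpp(element: str, wavelength: float, table: FppTable | None = None) -> float:
    """Expected f'' (electrons) for ``element`` at ``wavelength`` (Angstrom).

    Nonnegative; raises ``ValueError`` outside the 0.5-3.0 Angstrom table range.
    """
    tbl = table if table is not None else _default_fpp_table()
    return tbl(element, wavelength)
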