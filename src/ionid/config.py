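"""Run configuration: every user-adjustable cutoff in one place.

The defaults are the method's published operating point: minimum B_iso
1.0 A^2; mFo-DFc and anomalous peak cutoffs 3.0 sigma; rejection below
-3.0 sigma (difference map) or 1.8 sigma (2mFo-DFc); refined f'' above
0; O-O close-contact cutoff 2.4 A; coordination-shell radius 3.5 A.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import DEFAULT_CANDIDATES

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All thresholds and switches for one identification run."""

    # candidate set and experiment metadata
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    wavelength: float | None = None  # Angstrom; enables f'' comparison

    # water-flagging cutoffs (screening)
    min_b_iso: float = 1.0            # A^2; below -> heavy candidate
    fofc_cutoff: float = 3.0          # sigma; residual peak -> heavy
    anom_cutoff: float = 3.0          # sigma; anomalous peak -> heavy
    fpp_min: float = 0.0              # electrons; refined f'' above -> heavy
    max_occupancy: float = 1.0        # above -> heavy
    reject_fofc_below: float = -3.0   # sigma; negative difference peak -> unreliable
    reject_2fofc_below: float = 1.8   # sigma; weak density -> unreliable
    light_b_fraction: float = 0.8     # B < fraction * solvent mean -> light candidate
    light_density_margin: float = 0.5  # 2mFo-DFc > solvent mean + margin -> light

    # environment
    shell_radius: float = 3.5         # A
    close_oo_cutoff: float = 2.4      # A; O-O clash distance
    halide_radius: float = 3.6        # A; amide/cation search for halides
    donor_density_min: float = 1.0    # sigma; donors below are excluded
    geometry_rmsd_max: float = 15.0   # degrees

    # decision tree
    bvs_window_strict: float = 0.25   # valence units around the formal charge
    bvs_window_weak: float = 0.5
    vecsum_max: float = 0.25
    fpp_band: tuple[float, float] = (0.2, 1.5)  # acceptable fpp / expected ratio
    fpp_negligible: float = 0.2       # electrons; below this f'' is "none expected"
    allow_waiver: bool = True         # waive strict-only tests for heavy ions
    require_valence: bool = False     # keep the strict BVS window even when waived

    # bookkeeping
    special_position_tol: float = 0.5  # A
    resolution_warn: float = 2.8       # A; warn at worse resolution

    seed: int = 0

    def __post_init__(self):
        self.candidates = tuple(e.upper() for e in self.candidates)
        if isinstance(self.fpp_band, list):
            self.fpp_band = tuple(self.fpp_band)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidates"] = list(self.candidates)
        d["fpp_band"] = list(self.fpp_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
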