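"""Screen modeled waters for signs of a mismodeled ion.

A water is rejected as unreliable when its density is untrustworthy
(negative difference-map peak below -3.0 sigma, or 2mFo-DFc support
below 1.8 sigma). Otherwise it is flagged as a possible heavy ion when
any one heavy criterion fires (B_iso below 1.0 A^2, difference peak
above 3.0 sigma, occupancy refined above 1, anomalous peak above
3.0 sigma, refined f'' above 0), or as a possible light ion (Na/Mg)
when its B factor or density stands out against the solvent mean.
Absent observables are treated as "not measured", never as zero, so the
method degrades gracefully without anomalous data.

Map-derived observables arrive through a per-site features table; this
package does not compute maps. Feature tables are delimited text with
columns: chain, resseq, icode, atom, altloc, b_iso, occupancy,
peak_2fofc, peak_fofc, peak_anom, fpp, solvent_b_mean,
solvent_2fofc_mean, wavelength. Missing columns mean "not measured".
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .environment import CoordinationShell
from .structure import AtomId

__all__ = [
    "SiteFeatures",
    "ScreenVerdict",
    "REJECTED", "PLAIN_WATER", "LIGHT_CANDIDATE", "HEAVY_CANDIDATE",
    "screen_site",
    "combine_with_environment",
    "read_features_table",
    "features_for",
    "density_support_map",
]

REJECTED = "rejected_unreliable"
PLAIN_WATER = "plain_water"
LIGHT_CANDIDATE = "light_candidate"
HEAVY_CANDIDATE = "heavy_candidate"

_HEAVY_TRIGGERS = ("low_b_absolute", "fofc_peak", "high_occupancy",
                   "anomalous_peak", "refined_fpp")


@dataclass
class SiteFeatures:
    """Density/anomalous observables for one candidate site.

    ``None`` means the quantity was not measured.
    """

    b_iso: float | None = None            # A^2
    occupancy: float | None = None
    peak_2fofc: float | None = None       # sigma
    peak_fofc: float | None = None        # sigma, signed
    peak_anom: float | None = None        # sigma
    fpp_refined: float | None = None      # electrons
    solvent_b_mean: float | None = None   # A^2
    solvent_2fofc_mean: float | None = None  # sigma
    wavelength: float | None = None       # Angstrom


@dataclass
class ScreenVerdict:
    status: str
    triggers: list[str] = field(default_factory=list)

    @property
    def has_heavy_trigger(self) -> bool:
        return any(t in _HEAVY_TRIGGERS for t in self.triggers)


def screen_site(f: SiteFeatures, config: RunConfig | None = None) -> ScreenVerdict:
    """Classify one water site from its scattering observables.

    Rejection takes precedence over every positive trigger; heavy
    criteria are checked before the relative light-ion criteria.
    """
    cfg = config or RunConfig()

    # unreliable density first
    if f.peak_fofc is not None and f.peak_fofc < cfg.reject_fofc_below:
        return ScreenVerdict(REJECTED, ["negative_fofc_peak"])
    if f.peak_2fofc is not None and f.peak_2fofc < cfg.reject_2fofc_below:
        return ScreenVerdict(REJECTED, ["weak_2fofc"])

    triggers = []
    if f.b_iso is not None and f.b_iso < cfg.min_b_iso:
        triggers.append("low_b_absolute")
    if f.peak_fofc is not None and f.peak_fofc > cfg.fofc_cutoff:
        triggers.append("fofc_peak")
    if f.occupancy is not None and f.occupancy > cfg.max_occupancy:
        triggers.append("high_occupancy")
    if f.peak_anom is not None and f.peak_anom > cfg.anom_cutoff:
        triggers.append("anomalous_peak")
    if f.fpp_refined is not None and f.fpp_refined > cfg.fpp_min:
        triggers.append("refined_fpp")
    if triggers:
        return ScreenVerdict(HEAVY_CANDIDATE, triggers)

    if (f.b_iso is not None and f.solvent_b_mean is not None
            and f.b_iso < cfg.light_b_fraction * f.solvent_b_mean):
        triggers.append("low_b_relative")
    if (f.peak_2fofc is not None and f.solvent_2fofc_mean is not None
            and f.peak_2fofc > f.solvent_2fofc_mean + cfg.light_density_margin):
        triggers.append("high_2fofc_relative")
    if triggers:
        return ScreenVerdict(LIGHT_CANDIDATE, triggers)
    return ScreenVerdict(PLAIN_WATER, [])


def combine_with_environment(verdict: ScreenVerdict,
                             shell: CoordinationShell) -> ScreenVerdict:
    """Fold the environmental filters into a screening verdict.

    A close O-O contact or a nearby nucleotide-phosphate O promotes a
    plain water to a light candidate; motifs never demote, and a
    rejected site stays rejected.
    """
    if verdict.status == REJECTED:
        return verdict
    triggers = list(verdict.triggers)
    status = verdict.status
    for motif in ("close_OO", "nucleotide_phosphate"):
        if shell.motifs.get(motif):
            triggers.append(motif)
            if status == PLAIN_WATER:
                status = LIGHT_CANDIDATE
    return ScreenVerdict(status, triggers)


# ---------------------------------------------------------------------------
# features table I/O

_FEATURE_COLUMNS = ("b_iso", "occupancy", "peak_2fofc", "peak_fofc", "peak_anom",
                    "fpp", "solvent_b_mean", "solvent_2fofc_mean", "wavelength")


def read_features_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV per-site features table keyed by atom id."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    for required in ("chain", "resseq"):
        if required not in df.columns:
            raise ValueError(f"features table lacks required column {required!r}")
    return df


def _row_key(row) -> tuple:
    def clean(col, default=""):
        v = row.get(col, default)
        if v is None or (isinstance(v, float) and pd.isna(v)):
            v = default
        return str(v).strip()

    icode = clean("icode") or " "
    alt = clean("altloc")
    atom = clean("atom") or "O"
    return (str(row["chain"]), int(row["resseq"]), icode, atom, alt)


def features_for(df: pd.DataFrame | None, aid: AtomId) -> SiteFeatures:
    """Look up the features row matching an atom id (missing -> empty features)."""
    feats = SiteFeatures()
    if df is None:
        return feats
    key = (aid.chain, aid.resseq, aid.icode, aid.name, aid.altloc)
    for _, row in df.iterrows():
        if _row_key(row) == key:
            for col in _FEATURE_COLUMNS:
                if col in df.columns and pd.notna(row[col]):
                    attr = "fpp_refined" if col == "fpp" else col
                    setattr(feats, attr, float(row[col]))
            break
    return feats


def density_support_map(df: pd.DataFrame | None) -> dict[tuple, float] | None:
    """Per-atom 2mFo-DFc support keyed like :func:`features_for` keys.

    Used to exclude shell donors not backed by density. Returns ``None``
    when the table has no 2mFo-DFc column (the filter is then skipped).
    """
    if df is None or "peak_2fofc" not in df.columns:
        return None
    out = {}
    for _, row in df.iterrows():
        if pd.notna(row["peak_2fofc"]):
            out[_row_key(row)] = float(row["peak_2fofc"])
    return out
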