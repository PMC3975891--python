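"""Synthetic structures and feature tables for testing every stage.

The generator emits small crystallographic models in which an ion site
is deliberately modeled as a water, surrounded by donors embedded in
minimal residue fragments (waters, carboxylates, imidazoles, thiolates,
backbone amides, a nucleotide phosphate). The accompanying features
table mimics what refinement would report for such a site: a low B
factor, a positive difference peak scaled with the electron-count
difference to oxygen, and an anomalous signal derived from the expected
f'' at the chosen wavelength. The feature synthesis is a deliberately
simple stand-in for real refinement output -- peak heights scale
linearly with excess electrons (0.5 sigma per electron by default) --
and is documented as synthetic throughout.

"Ideal" donor distances solve sum(s) = formal charge exactly for the
chosen template, i.e. d_j = r0_j - b * ln(|q| / n).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .environment import GEOMETRY_TEMPLATES
from .params import atomic_number, expected_fpp, get_profile, lookup_bv_param
from .structure import Model

__all__ = [
    "FixtureSpec", "FixtureBundle", "CANONICAL_SPECS",
    "make_site_fixture", "make_symmetry_fixture", "make_plain_water_model",
    "make_ambiguous_zn_cl_fixture", "ideal_distance",
]

#: sigma of synthetic mFo-DFc peak per electron of difference to oxygen
PEAK_SIGMA_PER_ELECTRON = 0.5

#: expected f'' (electrons) below which no synthetic anomalous signal is emitted
ANOMALOUS_EMISSION_FLOOR = 0.5

DEFAULT_SOLVENT_B = 30.0
# typical 2mFo-DFc level at a well-ordered water peak (sigma); comfortably
# above the 1.8 sigma reliability cutoff so nominal waters are not rejected
DEFAULT_SOLVENT_2FOFC = 2.5


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic ion-as-water site."""

    element: str
    geometry: str = "octahedral"
    donors: tuple[str, ...] = ()           # kind strings, e.g. "HOH:O", "CYS:SG"
    distance: float | str = "ideal"        # Angstrom, or "ideal"
    occupancy: float = 1.0
    noise_xyz: float = 0.0                 # Gaussian sigma, Angstrom
    cell: tuple[float, ...] = (40.0, 40.0, 40.0, 90.0, 90.0, 90.0)
    spacegroup: str = "P 1"
    feature_profile: str = "ideal_ion"     # ideal_ion | plain_water
    wavelength: float = 1.0
    solvent_b_mean: float = DEFAULT_SOLVENT_B
    solvent_2fofc_mean: float = DEFAULT_SOLVENT_2FOFC
    extra_waters: int = 0

    def n_donors(self) -> int:
        return len(self.donors)


@dataclass
class FixtureBundle:
    """A generated model, its features table and the ground truth."""

    model: Model
    features: pd.DataFrame
    truth: dict
    center_resseq: int = 1

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write model.pdb, model.cif, features.tsv and truth.json."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "pdb": directory / "model.pdb",
            "cif": directory / "model.cif",
            "features": directory / "features.tsv",
            "truth": directory / "truth.json",
        }
        self.model.structure.write_pdb(str(paths["pdb"]))
        self.model.structure.make_mmcif_document().write_file(str(paths["cif"]))
        self.features.to_csv(paths["features"], sep="\t", index=False)
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return paths


def ideal_distance(ion: str, donor_element: str, n_donors: int) -> float:
    """Distance at which each of n equal donors contributes |q|/n valence."""
    profile = get_profile(ion)
    p = lookup_bv_param(ion, donor_element)
    s = abs(profile.formal_charge) / n_donors
    return p.r0 - p.b * math.log(s)


# canonical environments, one per supported element
CANONICAL_SPECS: dict[str, FixtureSpec] = {
    "NA": FixtureSpec("NA", "octahedral", ("HOH:O",) * 6),
    "MG": FixtureSpec("MG", "octahedral", ("HOH:O",) * 6),
    "K": FixtureSpec("K", "octahedral", ("HOH:O",) * 6),
    "CA": FixtureSpec("CA", "pentagonal_bipyramidal",
                      ("ASP:OD1",) * 4 + ("HOH:O",) * 3),
    "MN": FixtureSpec("MN", "octahedral",
                      ("HIS:ND1",) * 2 + ("ASP:OD1",) * 2 + ("HOH:O",) * 2),
    "FE": FixtureSpec("FE", "octahedral",
                      ("HIS:ND1",) * 2 + ("ASP:OD1",) * 2 + ("HOH:O",) * 2),
    "CO": FixtureSpec("CO", "octahedral",
                      ("HIS:ND1",) * 2 + ("ASP:OD1",) * 2 + ("HOH:O",) * 2),
    "NI": FixtureSpec("NI", "octahedral",
                      ("HIS:ND1",) * 2 + ("ASP:OD1",) * 2 + ("HOH:O",) * 2),
    "CU": FixtureSpec("CU", "octahedral",
                      ("HIS:ND1",) * 2 + ("ASP:OD1",) * 2 + ("HOH:O",) * 2),
    "ZN": FixtureSpec("ZN", "tetrahedral", ("CYS:SG",) * 4),
    "CD": FixtureSpec("CD", "trigonal_bipyramidal",
                      ("ASP:OD1",) * 2 + ("HIS:ND1",) + ("HOH:O",) * 2),
    "CL": FixtureSpec("CL", "trigonal_planar", ("GLY:N",) * 3, distance=3.2,
                      wavelength=1.5418),
}

_NAME_ELEMENT = {
    "O": "O", "OD1": "O", "OD2": "O", "O1B": "O", "O2B": "O", "O3B": "O",
    "N": "N", "ND1": "N", "SG": "S", "CB": "C", "CG": "C", "CA": "C", "PB": "P",
}


def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _companions(kind: str, donor_pos: np.ndarray, u: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Framework atoms attached outward of a donor (name, element, position)."""
    lat = _perpendicular(u)
    out = []

    def place(name, element, origin, bond, dr):
        lateral = math.sqrt(max(bond * bond - dr * dr, 0.0))
        out.append((name, element, origin + dr * u + lateral * lat))

    resname = kind.split(":", 1)[0]
    if resname == "ASP":       # carboxylate: OD1 donor, CG and OD2 outward
        place("CG", "C", donor_pos, 1.25, 0.75)
        cg = out[-1][2]
        out.append(("OD2", "O", cg + 1.25 * u))
    elif resname == "HIS":     # imidazole stub
        place("CG", "C", donor_pos, 1.39, 0.83)
    elif resname == "CYS":
        place("CB", "C", donor_pos, 1.81, 1.09)
    elif resname == "GLY":     # backbone amide: N donor, CA outward
        place("CA", "C", donor_pos, 1.47, 0.88)
    elif resname == "ANP":     # beta-phosphate of AMP-PNP
        place("PB", "P", donor_pos, 1.60, 0.96)
        pb = out[-1][2]
        out.append(("O2B", "O", pb + 1.48 * u))
        place("O3B", "O", pb, 1.48, 0.89)
    return out


def _new_structure(spec_cell, spacegroup: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*spec_cell)
    st.spacegroup_hm = spacegroup
    st.add_model(gemmi.Model("1"))
    st[0].add_chain(gemmi.Chain("A"))
    return st


def _add_residue(chain: gemmi.Chain, resname: str, seq: int,
                 atoms: list[tuple[str, str, np.ndarray]],
                 occ: float = 1.0, b: float = DEFAULT_SOLVENT_B) -> None:
    r = gemmi.Residue()
    r.name = resname
    r.seqid = gemmi.SeqId(seq, " ")
    r.het_flag = "H"
    for name, element, pos in atoms:
        a = gemmi.Atom()
        a.name = name
        a.element = gemmi.Element(element.capitalize())
        a.pos = gemmi.Position(*np.round(pos, 3))  # PDB precision
        a.occ = occ
        a.b_iso = b
        r.add_atom(a)
    chain.add_residue(r)


def _feature_row(chain, resseq, atom, **values) -> dict:
    row = {"chain": chain, "resseq": resseq, "icode": "", "atom": atom, "altloc": ""}
    row.update(values)
    return row


def make_site_fixture(spec: FixtureSpec, seed: int = 0) -> FixtureBundle:
    """Build one synthetic site per ``spec``.

    The ion site is modeled AS WATER (residue HOH, O atom) at the cell
    center; donors sit on the requested geometry template, randomly
    rotated (seeded) and optionally perturbed with Gaussian noise.
    """
    template = GEOMETRY_TEMPLATES.get(spec.geometry)
    if template is None:
        raise ValueError(f"unknown geometry template {spec.geometry!r}")
    if len(template) != spec.n_donors():
        raise ValueError(
            f"geometry {spec.geometry!r} needs {len(template)} donors, "
            f"got {spec.n_donors()}")
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    center = np.array(spec.cell[:3]) / 2.0

    st = _new_structure(spec.cell, spec.spacegroup)
    chain = st[0]["A"]

    profile = get_profile(spec.element)
    z = profile.atomic_number

    feature_rows = []
    truth_donors = []
    b_center = (0.5 * spec.solvent_b_mean if spec.feature_profile == "ideal_ion"
                else spec.solvent_b_mean)
    _add_residue(chain, "HOH", 1, [("O", "O", center)], occ=min(spec.occupancy, 1.0),
                 b=b_center)

    for i, kind in enumerate(spec.donors):
        resname, atom_name = kind.split(":", 1)
        element = _NAME_ELEMENT[atom_name]
        if spec.distance == "ideal":
            d = ideal_distance(spec.element, element, spec.n_donors())
        else:
            d = float(spec.distance)
        u = rot @ template[i]
        pos = center + d * u + rng.normal(scale=spec.noise_xyz, size=3)
        atoms = [(atom_name, element, pos)] + _companions(kind, pos, u)
        _add_residue(chain, resname, 100 + i, atoms)
        truth_donors.append({"kind": kind, "distance": round(float(d), 4)})

    # far-away ordinary waters (plain solvent)
    extra_positions: list[np.ndarray] = []
    for j in range(spec.extra_waters):
        while True:
            pos = rng.uniform(4.0, np.array(spec.cell[:3]) - 4.0)
            if (np.linalg.norm(pos - center) > 8.0
                    and all(np.linalg.norm(pos - q) > 6.0 for q in extra_positions)):
                break
        extra_positions.append(pos)
        _add_residue(chain, "HOH", 200 + j, [("O", "O", pos)])
        feature_rows.append(_feature_row(
            "A", 200 + j, "O",
            b_iso=round(spec.solvent_b_mean * (1 + 0.05 * rng.standard_normal()), 2),
            occupancy=1.0,
            peak_2fofc=round(spec.solvent_2fofc_mean + 0.1 * rng.standard_normal(), 2),
            peak_fofc=round(float(np.clip(0.3 * rng.standard_normal(), -1.5, 1.5)), 2),
            solvent_b_mean=spec.solvent_b_mean,
            solvent_2fofc_mean=spec.solvent_2fofc_mean,
            wavelength=spec.wavelength))

    # features for the mismodeled center
    if spec.feature_profile == "ideal_ion":
        values = dict(
            b_iso=b_center,
            occupancy=spec.occupancy,
            peak_2fofc=round(min(spec.solvent_2fofc_mean + 1.0 + 0.2 * (z - 8), 9.0), 2),
            peak_fofc=round(PEAK_SIGMA_PER_ELECTRON * (z - 8) * spec.occupancy, 2),
            solvent_b_mean=spec.solvent_b_mean,
            solvent_2fofc_mean=spec.solvent_2fofc_mean,
            wavelength=spec.wavelength,
        )
        fpp = expected_fpp(spec.element, spec.wavelength)
        if fpp >= ANOMALOUS_EMISSION_FLOOR:
            values["fpp"] = round(fpp * spec.occupancy, 3)
            values["peak_anom"] = round(min(5.0 * fpp * spec.occupancy, 25.0), 2)
    else:
        values = dict(
            b_iso=b_center,
            occupancy=min(spec.occupancy, 1.0),
            peak_2fofc=round(spec.solvent_2fofc_mean + 0.1 * rng.standard_normal(), 2),
            peak_fofc=round(float(np.clip(0.3 * rng.standard_normal(), -1.5, 1.5)), 2),
            solvent_b_mean=spec.solvent_b_mean,
            solvent_2fofc_mean=spec.solvent_2fofc_mean,
            wavelength=spec.wavelength,
        )
    feature_rows.insert(0, _feature_row("A", 1, "O", **values))

    features = pd.DataFrame(feature_rows)
    truth = {
        "element": spec.element,
        "geometry": spec.geometry,
        "occupancy": spec.occupancy,
        "donors": truth_donors,
        "feature_profile": spec.feature_profile,
        "wavelength": spec.wavelength,
        "seed": seed,
    }
    return FixtureBundle(model=Model(st, source=f"fixture:{spec.element}"),
                         features=features, truth=truth)


def make_symmetry_fixture(seed: int = 0, element: str = "MG") -> FixtureBundle:
    """A site whose shell is completed only through a twofold symmetry mate.

    In a P2 cell, a water on the 2-fold axis is surrounded by four
    donors in the asymmetric unit; the axis maps two of them onto the
    missing octahedral vertices, so the full shell exists only with
    crystal symmetry taken into account.
    """
    del seed  # construction is deterministic; kept for interface symmetry
    cell = (20.0, 20.0, 20.0, 90.0, 90.0, 90.0)
    st = _new_structure(cell, "P 1 2 1")
    chain = st[0]["A"]
    center = np.array([0.0, 6.0, 0.0])
    d = ideal_distance(element, "O", 6)
    _add_residue(chain, "HOH", 1, [("O", "O", center)], b=15.0)
    # +x and +z donors (their -x/-z mates come from the 2-fold), +/-y on the axis
    offsets = [(d, 0, 0), (0, 0, d), (0, d, 0), (0, -d, 0)]
    for i, off in enumerate(offsets):
        _add_residue(chain, "HOH", 100 + i, [("O", "O", center + np.array(off))])
    profile = get_profile(element)
    features = pd.DataFrame([_feature_row(
        "A", 1, "O", b_iso=15.0, occupancy=1.0,
        peak_2fofc=3.0, peak_fofc=PEAK_SIGMA_PER_ELECTRON * (profile.atomic_number - 8),
        solvent_b_mean=DEFAULT_SOLVENT_B, solvent_2fofc_mean=DEFAULT_SOLVENT_2FOFC)])
    truth = {"element": element, "geometry": "octahedral", "n_asu_donors": 4,
             "ideal_distance": round(float(d), 4)}
    return FixtureBundle(model=Model(st, source="fixture:symmetry"),
                         features=features, truth=truth)


def make_plain_water_model(seed: int = 0, n_waters: int = 20,
                           cell_edge: float = 40.0) -> FixtureBundle:
    """A model of ordinary, well-behaved waters (negative control).

    Waters are kept at least 6 Angstrom apart so no clash or motif rule
    fires; B factors and map values fluctuate mildly around the solvent
    means.
    """
    rng = np.random.default_rng(seed)
    st = _new_structure((cell_edge,) * 3 + (90.0, 90.0, 90.0), "P 1")
    chain = st[0]["A"]
    positions: list[np.ndarray] = []
    rows = []
    attempts = 0
    while len(positions) < n_waters and attempts < 20000:
        attempts += 1
        pos = rng.uniform(3.0, cell_edge - 3.0, size=3)
        if any(np.linalg.norm(pos - q) < 6.0 for q in positions):
            continue
        # periodic images too: keep away from cell faces handled by margin above
        positions.append(pos)
        seq = len(positions)
        b = DEFAULT_SOLVENT_B * (1 + 0.12 * rng.standard_normal())
        b = float(np.clip(b, 0.85 * DEFAULT_SOLVENT_B, 1.3 * DEFAULT_SOLVENT_B))
        rows.append(_feature_row(
            "A", seq, "O",
            b_iso=round(b, 2), occupancy=1.0,
            peak_2fofc=round(DEFAULT_SOLVENT_2FOFC + float(np.clip(
                0.15 * rng.standard_normal(), -0.45, 0.45)), 2),
            peak_fofc=round(float(np.clip(0.5 * rng.standard_normal(), -2.0, 2.0)), 2),
            solvent_b_mean=DEFAULT_SOLVENT_B,
            solvent_2fofc_mean=DEFAULT_SOLVENT_2FOFC))
        _add_residue(chain, "HOH", seq, [("O", "O", pos)], b=b)
    truth = {"element": None, "n_waters": n_waters, "seed": seed}
    return FixtureBundle(model=Model(st, source="fixture:plain-water"),
                         features=pd.DataFrame(rows), truth=truth)


def make_ambiguous_zn_cl_fixture(seed: int = 0) -> FixtureBundle:
    """A site whose anomalous signal fits both Zn and Cl at Cu K-alpha.

    Four O donors at the Zn tetrahedral valence distance plus one
    backbone amide N: the cation route (Zn) and the halide route (Cl)
    both succeed, and at 1.5418 Angstrom their expected f'' differ by
    less than 0.1 electrons, so anomalous data cannot discriminate.
    """
    rng = np.random.default_rng(seed)
    cell = (40.0, 40.0, 40.0, 90.0, 90.0, 90.0)
    st = _new_structure(cell, "P 1")
    chain = st[0]["A"]
    center = np.array(cell[:3]) / 2.0
    _add_residue(chain, "HOH", 1, [("O", "O", center)], b=12.0)
    rot = _random_rotation(rng)
    d = ideal_distance("ZN", "O", 4)
    for i, t in enumerate(GEOMETRY_TEMPLATES["tetrahedral"]):
        _add_residue(chain, "HOH", 100 + i, [("O", "O", center + d * (rot @ t))])
    # backbone amide pointing between two tetrahedral vertices
    u = rot @ np.array([0.0, 0.0, 1.0])
    npos = center + 3.3 * u
    _add_residue(chain, "GLY", 110, [("N", "N", npos)] + _companions("GLY:N", npos, u))
    wl = 1.5418
    fpp = round((expected_fpp("ZN", wl) + expected_fpp("CL", wl)) / 2, 3)
    features = pd.DataFrame([_feature_row(
        "A", 1, "O", b_iso=12.0, occupancy=1.0, peak_2fofc=5.0, peak_fofc=4.5,
        peak_anom=6.0, fpp=fpp, solvent_b_mean=DEFAULT_SOLVENT_B,
        solvent_2fofc_mean=DEFAULT_SOLVENT_2FOFC, wavelength=wl)])
    truth = {"element": None, "viable": ["ZN", "CL"], "wavelength": wl}
    return FixtureBundle(model=Model(st, source="fixture:zn-cl"), features=features,
                         truth=truth)
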