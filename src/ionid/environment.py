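"""Coordination-shell construction, geometry classification and motifs.

The shell of a putative ion site is the set of heavy atoms within a
cutoff radius (default 3.5 Angstrom), symmetry mates included. Carbon
and phosphorus atoms that are covalently bonded to an included O donor
(carboxylate C, phosphate P) are bookkept as excluded framework atoms
rather than disqualifying the site; a nonpolar atom that close without
such bonding is a disqualifying contact. Donors not supported by the
electron density (when per-atom density is supplied) are excluded too.

Geometry is classified against ideal templates by finding the rotation
and donor-to-vertex assignment minimizing the angular deviation; a
template is accepted when the angle RMSD is at or below a threshold
(default 15 degrees).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .structure import AtomSite, Contact, Model, is_covalently_bonded

__all__ = [
    "CoordinationShell",
    "GeometryAssessment",
    "GEOMETRY_TEMPLATES",
    "build_shell",
    "classify_geometry",
    "fit_template",
    "detect_close_oo",
    "detect_nucleotide_phosphate",
    "detect_halide_environment",
]

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE".split())

NUCLEOTIDE_RESNAMES = frozenset(
    "ATP ADP AMP GTP GDP GMP ANP GNP ACP AGS UTP CTP TTP".split())

DONOR_ELEMENTS = frozenset({"O", "N", "S", "SE", "F", "CL", "BR", "I"})

METAL_ELEMENTS = frozenset(
    "LI NA MG K CA MN FE CO NI CU ZN CD RB CS SR BA AL HG PB PT AU AG".split())

#: N atoms counted as positively polarized halide partners, by residue.
_POSITIVE_N = {
    ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("LYS", "NZ"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("ASN", "ND2"), ("GLN", "NE2"),
}


def _unit_rows(v) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    return a / np.linalg.norm(a, axis=1, keepdims=True)


def _pbp():
    eq = [[math.cos(2 * math.pi * k / 5), math.sin(2 * math.pi * k / 5), 0.0] for k in range(5)]
    return _unit_rows(eq + [[0, 0, 1], [0, 0, -1]])


GEOMETRY_TEMPLATES: Mapping[str, np.ndarray] = {
    "linear": _unit_rows([[0, 0, 1], [0, 0, -1]]),
    "trigonal_planar": _unit_rows(
        [[1, 0, 0], [-0.5, math.sqrt(3) / 2, 0], [-0.5, -math.sqrt(3) / 2, 0]]),
    "tetrahedral": _unit_rows([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]),
    "square_planar": _unit_rows([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]]),
    "trigonal_bipyramidal": _unit_rows(
        [[1, 0, 0], [-0.5, math.sqrt(3) / 2, 0], [-0.5, -math.sqrt(3) / 2, 0],
         [0, 0, 1], [0, 0, -1]]),
    "square_pyramidal": _unit_rows(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]]),
    "octahedral": _unit_rows(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]),
    "pentagonal_bipyramidal": _pbp(),
}


@dataclass
class GeometryAssessment:
    """Best-matching ideal coordination geometry and its angular deviation."""

    name: str
    angle_rmsd: float
    n_donors: int


@dataclass
class CoordinationShell:
    """A center plus its filtered donor contacts.

    ``donors`` are the contacts used for valence and geometry analysis;
    ``excluded`` records contacts removed with a named reason;
    ``outer`` holds contacts between the shell radius and the (slightly
    larger) halide-environment radius, used only for motif detection.
    """

    center: AtomSite
    radius: float
    donors: list[Contact] = field(default_factory=list)
    excluded: list[tuple[Contact, str]] = field(default_factory=list)
    outer: list[Contact] = field(default_factory=list)
    motifs: dict[str, bool] = field(default_factory=dict)

    def donor_vectors(self) -> np.ndarray:
        return np.array([c.vector for c in self.donors]).reshape(-1, 3)

    def has_disqualifying_contact(self) -> bool:
        return any(reason == "nonbonded_close_contact" for _, reason in self.excluded)


def _donor_context(contact: Contact) -> str:
    """Chemical context string for donor-identity rules."""
    aid = contact.atom.id
    if aid.resname in ("CYS",) and aid.name == "SG":
        return "CYS"
    if aid.resname in ("MET", "MSE") and aid.name in ("SD", "SE"):
        return "MET"
    if aid.resname == "HIS" and aid.name in ("ND1", "NE2"):
        return "HIS"
    if aid.resname in STANDARD_AA:
        return "backbone" if aid.name in ("N", "O", "OXT") else "sidechain"
    if contact.atom.is_water:
        return "water"
    return "LIG"


def build_shell(
    center: AtomSite,
    model: Model,
    radius: float = 3.5,
    density_support: Mapping | None = None,
    density_threshold: float = 1.0,
    halide_radius: float = 3.6,
    close_oo_cutoff: float = 2.4,
) -> CoordinationShell:
    """Construct the filtered coordination shell around ``center``.

    ``density_support`` optionally maps :class:`AtomId` to a 2mFo-DFc
    sigma level; donors below ``density_threshold`` are excluded as
    unsupported by density. The motif flags (close O-O contact,
    nucleotide-phosphate O, amide/cation halide environment) are set on
    the returned shell.
    """
    search_radius = max(radius, halide_radius)
    contacts = model.neighbors(center.xyz, search_radius, exclude=center.id)
    shell = CoordinationShell(center=center, radius=radius)

    # altloc bookkeeping: adopt the first non-blank altloc compatible with the center
    used_altloc = center.id.altloc or None

    polar, nonpolar = [], []
    for c in contacts:
        if c.distance > radius:
            shell.outer.append(c)
            continue
        alt = c.atom.id.altloc
        if alt:
            if used_altloc is None:
                used_altloc = alt
            elif alt != used_altloc:
                shell.excluded.append((c, "altloc_conflict"))
                continue
        if c.atom.element in METAL_ELEMENTS:
            shell.excluded.append((c, "metal_contact"))
        elif c.atom.element in DONOR_ELEMENTS:
            polar.append(c)
        else:
            nonpolar.append(c)

    # density filter on polar donors
    donors = []
    for c in polar:
        if density_support is not None:
            aid = c.atom.id
            level = density_support.get(aid)
            if level is None:
                level = density_support.get(
                    (aid.chain, aid.resseq, aid.icode, aid.name, aid.altloc))
            if level is not None and level < density_threshold:
                shell.excluded.append((c, "weak_density"))
                continue
        donors.append(c)
    shell.donors = donors

    # carboxylate / phosphate framework: C or P bonded to an included donor
    donor_atoms = [c.atom for c in donors]
    for c in nonpolar:
        if c.atom.element in ("C", "P") and any(
                is_covalently_bonded(c.atom, d) for d in donor_atoms):
            shell.excluded.append((c, "bonded_framework"))
        else:
            shell.excluded.append((c, "nonbonded_close_contact"))

    shell.motifs = {
        "close_OO": detect_close_oo(shell, cutoff=close_oo_cutoff),
        "nucleotide_phosphate": detect_nucleotide_phosphate(shell, model),
        "amide_cation_environment": detect_halide_environment(shell, radius=halide_radius),
    }
    return shell


def detect_close_oo(shell: CoordinationShell, cutoff: float = 2.4) -> bool:
    """True iff an O donor lies closer than ``cutoff`` to a water center.

    The rule is oxygen-oxygen specific: for a center not modeled as
    water (O) it never fires, and N donors do not count.
    """
    if shell.center.element != "O":
        return False
    return any(c.atom.element == "O" and c.distance < cutoff for c in shell.donors)


def detect_nucleotide_phosphate(shell: CoordinationShell, model: Model) -> bool:
    """True iff a donor O belongs to the phosphate group of a nucleotide-like residue.

    A donor counts when its residue is in the nucleotide name list, or
    generically when the residue contains a P atom bonded to the donor O
    and to at least three O atoms (phosphate detection for residues not
    on the list). A hit marks the site as a candidate phosphate-bound
    cation (Mg/Mn/Ca prioritized downstream).
    """
    for c in shell.donors:
        if c.atom.element != "O":
            continue
        resname = c.atom.id.resname
        residue = model.residue_atoms(c.atom.id)
        for p in residue:
            if p.element != "P" or not is_covalently_bonded(p, c.atom):
                continue
            if resname in NUCLEOTIDE_RESNAMES:
                return True
            n_o = sum(1 for o in residue if o.element == "O" and is_covalently_bonded(p, o))
            if n_o >= 3:
                return True
    return False


def halide_partner(contact: Contact) -> bool:
    """Whether a contact is a positively polarized halide partner."""
    aid = contact.atom.id
    if contact.atom.element in METAL_ELEMENTS:
        return True
    if contact.atom.element != "N":
        return False
    if aid.resname in STANDARD_AA and aid.name == "N":
        return True  # backbone amide
    return (aid.resname, aid.name) in _POSITIVE_N


def detect_halide_environment(shell: CoordinationShell, radius: float = 3.6) -> bool:
    """True iff >= 1 contact within ``radius`` is an amide N, a positively
    charged side-chain N (Arg/Lys/His/Asn/Gln) or a modeled cation."""
    pool = itertools.chain(shell.donors, (c for c, _ in shell.excluded), shell.outer)
    return any(c.distance <= radius and halide_partner(c) for c in pool)


# ---------------------------------------------------------------------------
# geometry classification


def _kabsch(template: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Rotation R minimizing sum |observed_i - R template_i|^2."""
    h = template.T @ observed
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def _angles_deg(observed: np.ndarray, rotated_template: np.ndarray) -> np.ndarray:
    dots = np.clip(np.sum(observed * rotated_template, axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(dots))


def _frame(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame with first axis along ``a``."""
    f1 = a / np.linalg.norm(a)
    b2 = b - np.dot(b, f1) * f1
    if np.linalg.norm(b2) < 1e-8:  # collinear; pick any perpendicular
        b2 = np.array([1.0, 0, 0]) if abs(f1[0]) < 0.9 else np.array([0, 1.0, 0])
        b2 = b2 - np.dot(b2, f1) * f1
    f2 = b2 / np.linalg.norm(b2)
    f3 = np.cross(f1, f2)
    return np.column_stack([f1, f2, f3])


def fit_template(vectors: np.ndarray, template: np.ndarray,
                 max_iter: int = 20) -> tuple[float, np.ndarray, tuple[int, ...]]:
    """Best superposition of ``template`` onto observed unit ``vectors``.

    Returns (angle RMSD in degrees, rotation, assignment) where
    ``assignment[i]`` is the template vertex matched to observed donor i.
    The rotation/assignment pair is found by seeding rotations from
    pairs of directions and alternating optimal bipartite assignment
    (on squared angular deviation) with a least-squares rotation fit.
    """
    obs = _unit_rows(vectors)
    n = len(obs)
    assert len(template) == n
    best = (float("inf"), np.eye(3), tuple(range(n)))
    f_obs = _frame(obs[0], obs[1 % n])
    seeds = []
    for k in range(n):
        for l in range(n):
            if l == k and n > 1:
                continue
            seeds.append(f_obs @ _frame(template[k], template[l % n]).T)
    for rot in seeds:
        perm_prev = None
        for _ in range(max_iter):
            rotated = template @ rot.T
            ang = _angles_deg(obs[:, None, :].repeat(n, axis=1).reshape(n * n, 3),
                              np.tile(rotated, (n, 1))).reshape(n, n)
            rows, cols = linear_sum_assignment(ang ** 2)
            perm = tuple(cols)
            rot = _kabsch(template[list(perm)], obs)
            if perm == perm_prev:
                break
            perm_prev = perm
        rotated = template[list(perm)] @ rot.T
        rmsd = float(np.sqrt(np.mean(_angles_deg(obs, rotated) ** 2)))
        if rmsd < best[0]:
            best = (rmsd, rot, perm)
    return best


def classify_geometry(shell: CoordinationShell | np.ndarray,
                      rmsd_threshold: float = 15.0) -> GeometryAssessment:
    """Classify the donor arrangement against the ideal templates.

    Among templates with a matching donor count, the one with the lowest
    angle RMSD after optimal rotation/assignment wins; ``irregular`` is
    returned when no template scores at or below ``rmsd_threshold`` (or
    fewer than two donors are present). Assignment ties are broken by
    donor distance (shell input only; shorter donors keep their vertex).
    """
    if isinstance(shell, CoordinationShell):
        vectors = shell.donor_vectors()
    else:
        vectors = np.asarray(shell, dtype=float).reshape(-1, 3)
    n = len(vectors)
    if n < 2:
        return GeometryAssessment(name="irregular", angle_rmsd=0.0, n_donors=n)
    best_name, best_rmsd = "irregular", float("inf")
    for name, template in GEOMETRY_TEMPLATES.items():
        if len(template) != n:
            continue
        rmsd, _, _ = fit_template(vectors, template)
        if rmsd < best_rmsd:
            best_name, best_rmsd = name, rmsd
    if best_rmsd > rmsd_threshold:
        return GeometryAssessment(name="irregular",
                                  angle_rmsd=best_rmsd if math.isfinite(best_rmsd) else 0.0,
                                  n_donors=n)
    return GeometryAssessment(name=best_name, angle_rmsd=best_rmsd, n_donors=n)
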