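"""Model I/O, crystal-symmetry-aware neighbor search and connectivity.

Coordinates are handled in orthogonal Angstroms. Symmetry expansion is
delegated to :mod:`gemmi`: the neighbor search covers all space-group
images plus unit-cell translations, and every returned contact records
the generating operation as a symmetry code ("1_555" for direct
contacts). Models without cell/symmetry information fall back to a
non-crystallographic all-pairs search with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "AtomId",
    "AtomSite",
    "Contact",
    "Model",
    "parse_model",
    "neighbors",
    "is_covalently_bonded",
    "special_position_multiplicity",
    "WATER_RESNAMES",
]

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})

#: Residue names under which already-built monoatomic ions appear.
ION_RESNAMES = frozenset({"NA", "MG", "CL", "K", "CA", "MN", "FE", "CO", "NI", "CU", "ZN", "CD"})

#: Tolerance added to the sum of covalent radii when inferring bonds (Angstrom).
COVALENT_TOLERANCE = 0.4

# Identity symmetry code as produced by gemmi (symop 1, no cell translation).
IDENTITY_SYMOP = "1_555"


@dataclass(frozen=True)
class AtomId:
    """Unique identity of one atom in the model."""

    chain: str
    resname: str
    resseq: int
    icode: str = " "
    name: str = ""
    altloc: str = ""

    def short(self) -> str:
        alt = f".{self.altloc}" if self.altloc else ""
        return f"{self.chain}/{self.resname}{self.resseq}{self.icode.strip()}/{self.name}{alt}"


@dataclass
class AtomSite:
    """One atom with identity, orthogonal coordinates, occupancy and B factor."""

    id: AtomId
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for {self.id.short()}")
        if not self.element:
            raise ValueError(f"empty element for {self.id.short()}")

    @property
    def is_water(self) -> bool:
        return self.id.resname in WATER_RESNAMES


@dataclass(frozen=True)
class Contact:
    """A neighbor of some center: atom, distance and unit direction.

    ``vector`` points from the center toward the (possibly
    symmetry-generated) donor position; ``symop`` is a symmetry code,
    :data:`IDENTITY_SYMOP` for direct contacts. ``position`` is the
    actual contact position after applying the operation.
    """

    atom: AtomSite
    distance: float
    vector: np.ndarray
    symop: str = IDENTITY_SYMOP
    position: np.ndarray | None = None

    @property
    def is_direct(self) -> bool:
        return self.symop == IDENTITY_SYMOP


class Model:
    """A parsed macromolecular model plus symmetry machinery.

    Wraps a ``gemmi.Structure`` (first model only) and exposes flat atom
    lists, water enumeration and the neighbor search used for building
    coordination shells.
    """

    def __init__(self, structure: gemmi.Structure, source: str = "<memory>"):
        self.structure = structure
        self.source = source
        self.warnings: list[str] = []
        cell = structure.cell
        self.has_symmetry = bool(cell.is_crystal())
        if self.has_symmetry:
            structure.setup_cell_images()
        else:
            self.warnings.append(
                "no unit cell / symmetry information; running in non-crystallographic mode")
            log.warning("model %s: %s", source, self.warnings[-1])
        self.atoms: list[AtomSite] = []
        self._by_id: dict[AtomId, AtomSite] = {}
        self._residue_atoms: dict[tuple[str, int, str, str], list[AtomSite]] = {}
        model = structure[0]
        for chain in model:
            for residue in chain:
                for atom in residue:
                    aid = AtomId(
                        chain=chain.name,
                        resname=residue.name.strip(),
                        resseq=residue.seqid.num,
                        icode=residue.seqid.icode or " ",
                        name=atom.name,
                        altloc=atom.altloc.strip("\x00") if atom.altloc else "",
                    )
                    site = AtomSite(
                        id=aid,
                        element=atom.element.name.upper(),
                        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        b_iso=atom.b_iso,
                    )
                    self.atoms.append(site)
                    self._by_id[aid] = site
                    rkey = (aid.chain, aid.resseq, aid.icode, aid.resname)
                    self._residue_atoms.setdefault(rkey, []).append(site)
        self._ns: gemmi.NeighborSearch | None = None
        self._ns_radius = 0.0

    # -- accessors ---------------------------------------------------------

    @property
    def resolution(self) -> float | None:
        r = self.structure.resolution
        return r if r and r > 0 else None

    def waters(self) -> list[AtomSite]:
        return [a for a in self.atoms
                if a.id.resname in WATER_RESNAMES and a.element in ("O", "")]

    def modeled_ions(self) -> list[AtomSite]:
        """Single-atom hetero residues named like a supported ion."""
        out = []
        for a in self.atoms:
            rkey = (a.id.chain, a.id.resseq, a.id.icode, a.id.resname)
            if a.id.resname in ION_RESNAMES and len(self._residue_atoms[rkey]) == 1:
                out.append(a)
        return out

    def atom(self, aid: AtomId) -> AtomSite:
        return self._by_id[aid]

    def residue_atoms(self, aid: AtomId) -> list[AtomSite]:
        """All atoms of the residue that ``aid`` belongs to."""
        return self._residue_atoms.get((aid.chain, aid.resseq, aid.icode, aid.resname), [])

    # -- neighbor search ---------------------------------------------------

    def _search(self, radius: float) -> gemmi.NeighborSearch:
        if self._ns is None or radius > self._ns_radius:
            r = max(radius, 5.0)
            self._ns = gemmi.NeighborSearch(self.structure[0], self.structure.cell, r).populate()
            self._ns_radius = r
        return self._ns

    def neighbors(self, center: np.ndarray, radius: float,
                  exclude: AtomId | None = None,
                  include_hydrogen: bool = False) -> list[Contact]:
        """All atoms within ``radius`` Angstrom of ``center``.

        Includes symmetry mates and periodic images when the model has a
        crystal cell; each contact records the generating operation.
        Coincident images of the excluded atom itself (a center sitting
        on a special position) are dropped. Hydrogens are ignored unless
        requested, since coordination analysis is heavy-atom based.
        """
        if radius <= 0:
            raise ValueError("radius must be positive")
        center = np.asarray(center, dtype=float)
        if not self.has_symmetry:
            return self._naive_neighbors(center, radius, exclude, include_hydrogen)
        cell = self.structure.cell
        cpos = gemmi.Position(*center)
        marks = self._search(radius).find_atoms(cpos, "\0", radius=radius)
        model = self.structure[0]
        contacts: list[Contact] = []
        seen: set[tuple] = set()
        for mark in marks:
            cra = mark.to_cra(model)
            if not include_hydrogen and cra.atom.element.is_hydrogen:
                continue
            near = cell.find_nearest_pbc_image(cpos, cra.atom.pos, mark.image_idx)
            dist = near.dist()
            if dist > radius:
                continue
            aid = AtomId(
                chain=cra.chain.name,
                resname=cra.residue.name.strip(),
                resseq=cra.residue.seqid.num,
                icode=cra.residue.seqid.icode or " ",
                name=cra.atom.name,
                altloc=cra.atom.altloc.strip("\x00") if cra.atom.altloc else "",
            )
            symcode = near.symmetry_code(True)
            if aid == exclude and dist < 1e-3:
                continue  # the center itself (or a coincident special-position image)
            pos = cell.find_nearest_pbc_position(cpos, cra.atom.pos, mark.image_idx)
            ppos = np.array([pos.x, pos.y, pos.z])
            # one contact per (atom, position): an atom fixed by an operation
            # is not counted once per generating op
            key = (aid, round(ppos[0], 3), round(ppos[1], 3), round(ppos[2], 3))
            if key in seen:
                continue
            seen.add(key)
            if dist < 1e-6:
                continue  # degenerate zero-length contact
            vec = (ppos - center) / dist
            contacts.append(Contact(atom=self._by_id[aid], distance=dist,
                                    vector=vec, symop=symcode, position=ppos))
        contacts.sort(key=lambda c: (c.distance, c.atom.id.short(), c.symop))
        return contacts

    def _naive_neighbors(self, center, radius, exclude, include_hydrogen) -> list[Contact]:
        contacts = []
        for a in self.atoms:
            if not include_hydrogen and a.element in ("H", "D"):
                continue
            d = float(np.linalg.norm(a.xyz - center))
            if d > radius or d < 1e-6:
                continue
            if a.id == exclude:
                continue
            contacts.append(Contact(atom=a, distance=d, vector=(a.xyz - center) / d,
                                    position=a.xyz.copy()))
        contacts.sort(key=lambda c: (c.distance, c.atom.id.short(), c.symop))
        return contacts


def parse_model(path: str | Path) -> Model:
    """Read a PDB or mmCIF model.

    All ATOM/HETATM records are loaded with occupancies and B factors;
    waters are identified by residue name (HOH/WAT/DOD). A file without
    cell/symmetry loads in non-crystallographic mode with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    return Model(structure, source=str(path))


def neighbors(model: Model, center: np.ndarray, radius: float,
              exclude: AtomId | None = None) -> list[Contact]:
    """Module-level convenience wrapper for :meth:`Model.neighbors`."""
    return model.neighbors(center, radius, exclude=exclude)


def is_covalently_bonded(a: AtomSite, b: AtomSite) -> bool:
    """Distance-based bond test: d <= r_cov(a) + r_cov(b) + 0.4 Angstrom.

    Atoms of unknown element are treated as unbonded (with a warning).
    """
    ea, eb = gemmi.Element(a.element), gemmi.Element(b.element)
    ra, rb = ea.covalent_r, eb.covalent_r
    if ea.atomic_number == 0 or eb.atomic_number == 0 or ra <= 0 or rb <= 0:
        log.warning("unknown covalent radius for %s or %s; treating as unbonded",
                    a.id.short(), b.id.short())
        return False
    d = float(np.linalg.norm(a.xyz - b.xyz))
    return d <= ra + rb + COVALENT_TOLERANCE


def special_position_multiplicity(model: Model, site: np.ndarray,
                                  tolerance: float = 0.5) -> float:
    """Occupancy fraction 1/n for a site fixed by n space-group operations.

    A general-position site returns 1.0. Without symmetry information
    the multiplicity defaults to 1.0 with a warning.
    """
    if not model.has_symmetry:
        log.warning("special-position check without symmetry; returning 1.0")
        return 1.0
    sg = gemmi.SpaceGroup(model.structure.spacegroup_hm or "P 1")
    cell = model.structure.cell
    site = np.asarray(site, dtype=float)
    frac = cell.fractionalize(gemmi.Position(*site))
    f = np.array([frac.x, frac.y, frac.z])
    n_fixing = 0
    for op in sg.operations():
        fx = np.array(op.apply_to_xyz(list(f)))
        delta = fx - f
        delta -= np.round(delta)  # nearest lattice translation
        ortho = cell.orthogonalize(gemmi.Fractional(*delta))
        d = math.sqrt(ortho.x ** 2 + ortho.y ** 2 + ortho.z ** 2)
        if d <= tolerance:
            n_fixing += 1
    return 1.0 / max(n_fixing, 1)
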