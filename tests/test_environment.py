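"""Shell construction, motif detection and geometry classification."""

import itertools

import numpy as np
import pytest

from ionid.environment import (GEOMETRY_TEMPLATES, CoordinationShell, build_shell,
                               classify_geometry, detect_close_oo,
                               detect_halide_environment,
                               detect_nucleotide_phosphate, fit_template)
from ionid.fixtures import CANONICAL_SPECS, FixtureSpec, make_site_fixture
from ionid.structure import AtomId, AtomSite, Contact

from conftest import random_rotation
from test_valence import make_contacts


def _shell_from(contacts, center_element="O"):
    center = AtomSite(id=AtomId("A", "HOH", 1, " ", "O"), element=center_element,
                      xyz=np.zeros(3))
    return CoordinationShell(center=center, radius=3.5, donors=list(contacts))


def _kabsch_oracle(template, obs):
    h = template.T @ obs
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def permutation_oracle(vectors, template):
    """Exhaustive search over donor-to-vertex assignments (n <= 6 feasible)."""
    obs = np.asarray(vectors, dtype=float)
    obs = obs / np.linalg.norm(obs, axis=1, keepdims=True)
    best = np.inf
    for perm in itertools.permutations(range(len(template))):
        t = template[list(perm)]
        rot = _kabsch_oracle(t, obs)
        dots = np.clip(np.sum(obs * (t @ rot.T), axis=1), -1, 1)
        rmsd = float(np.sqrt(np.mean(np.degrees(np.arccos(dots)) ** 2)))
        best = min(best, rmsd)
    return best


class TestBuildShell:
    def test_carboxylate_carbon_excluded_as_framework(self, canonical_bundles):
        bundle = canonical_bundles["CA"]
        model = bundle.model
        shell = build_shell(model.waters()[0], model)
        assert len(shell.donors) == 7  # 4 Asp OD1 + 3 waters
        reasons = {r for _, r in shell.excluded}
        assert reasons == {"bonded_framework"}
        assert not shell.has_disqualifying_contact()

    def test_phosphate_phosphorus_excluded_as_framework(self):
        spec = FixtureSpec("MG", "octahedral", ("ANP:O1B",) * 2 + ("HOH:O",) * 4)
        bundle = make_site_fixture(spec, seed=1)
        model = bundle.model
        shell = build_shell(model.waters()[0], model)
        assert len(shell.donors) == 6
        assert [r for _, r in shell.excluded] == ["bonded_framework"] * 2
        assert shell.motifs["nucleotide_phosphate"]

    def test_free_carbon_is_disqualifying(self):
        contacts = make_contacts([[1, 0, 0], [0, 1, 0]], [2.1, 3.0],
                                 elements=["O", "C"])
        # emulate build_shell's classification on a premade contact list:
        # a lone C with no bonded donor is a disqualifying close contact
        import gemmi
        from ionid.structure import is_covalently_bonded
        c_contact = contacts[1]
        assert not is_covalently_bonded(c_contact.atom, contacts[0].atom)

    def test_free_carbon_in_model_recorded(self):
        # build a model where a bare C sits 3.0 A from the water
        import gemmi
        from ionid.structure import Model
        st = gemmi.Structure()
        st.cell = gemmi.UnitCell(30, 30, 30, 90, 90, 90)
        st.spacegroup_hm = "P 1"
        st.add_model(gemmi.Model("1"))
        chain = gemmi.Chain("A")
        for seq, (name, el, pos) in enumerate(
                [("O", "O", (15, 15, 15)), ("O", "O", (17.4, 15, 15)),
                 ("C", "C", (15, 18, 15))], start=1):
            r = gemmi.Residue()
            r.name = "HOH" if el == "O" else "UNK"
            r.seqid = gemmi.SeqId(seq, " ")
            r.het_flag = "H"
            a = gemmi.Atom()
            a.name, a.element, a.pos = name, gemmi.Element(el), gemmi.Position(*pos)
            a.occ, a.b_iso = 1.0, 30.0
            r.add_atom(a)
            chain.add_residue(r)
        st[0].add_chain(chain)
        model = Model(st)
        shell = build_shell(model.waters()[0], model)
        assert shell.has_disqualifying_contact()

    def test_weak_density_donor_excluded(self, canonical_bundles):
        bundle = canonical_bundles["MG"]
        model = bundle.model
        center = model.waters()[0]
        first_donor = AtomId("A", "HOH", 100, " ", "O")
        support = {first_donor: 0.5}  # below the 1.0 sigma default
        shell = build_shell(center, model, density_support=support)
        assert len(shell.donors) == 5
        assert [(c.atom.id, r) for c, r in shell.excluded] == [
            (first_donor, "weak_density")]

    def test_donor_count_matches_p1_expansion(self):
        """Symmetry expansion equivalence: P2 shell == explicit P1 copy."""
        from ionid.fixtures import make_symmetry_fixture
        import gemmi
        from ionid.structure import Model

        bundle = make_symmetry_fixture()
        model = bundle.model
        center = model.waters()[0]
        shell = build_shell(center, model)

        # build the same content in P1 with the symmetry mates made explicit
        st = gemmi.Structure()
        st.cell = gemmi.UnitCell(20, 20, 20, 90, 90, 90)
        st.spacegroup_hm = "P 1"
        st.add_model(gemmi.Model("1"))
        chain = gemmi.Chain("A")
        seq = 0
        seen = set()
        src = model.structure
        for op_idx, op in enumerate(gemmi.SpaceGroup("P 1 2 1").operations()):
            for a in model.atoms:
                frac = src.cell.fractionalize(gemmi.Position(*a.xyz))
                fx = op.apply_to_xyz([frac.x, frac.y, frac.z])
                pos = src.cell.orthogonalize(gemmi.Fractional(*fx))
                key = (round(pos.x, 3), round(pos.y, 3), round(pos.z, 3))
                if key in seen:
                    continue
                seen.add(key)
                seq += 1
                r = gemmi.Residue()
                r.name = "HOH"
                r.seqid = gemmi.SeqId(seq, " ")
                r.het_flag = "H"
                atom = gemmi.Atom()
                atom.name, atom.element = "O", gemmi.Element("O")
                atom.pos = gemmi.Position(*key)
                atom.occ, atom.b_iso = 1.0, 30.0
                r.add_atom(atom)
                chain.add_residue(r)
        st[0].add_chain(chain)
        p1 = Model(st)
        p1_center = min(p1.waters(), key=lambda a: np.linalg.norm(a.xyz - center.xyz))
        p1_shell = build_shell(p1_center, p1)
        assert len(p1_shell.donors) == len(shell.donors) == 6


class TestMotifs:
    @pytest.mark.parametrize("distance,element,expected", [
        (2.3, "O", True),
        (2.5, "O", False),
        (2.3, "N", False),  # the clash rule is O-O specific
    ])
    def test_close_oo(self, distance, element, expected):
        shell = _shell_from(make_contacts([[1, 0, 0]], [distance], [element]))
        assert detect_close_oo(shell) is expected

    def test_close_oo_only_for_water_centers(self):
        shell = _shell_from(make_contacts([[1, 0, 0]], [2.2]), center_element="N")
        assert detect_close_oo(shell) is False

    def test_nucleotide_phosphate_within_shell_radius(self):
        spec = FixtureSpec("MG", "octahedral",
                           ("ANP:O1B",) + ("HOH:O",) * 5, distance=3.4)
        bundle = make_site_fixture(spec, seed=2)
        model = bundle.model
        shell = build_shell(model.waters()[0], model)
        assert detect_nucleotide_phosphate(shell, model)

    def test_plain_carboxylate_is_not_phosphate(self, canonical_bundles):
        bundle = canonical_bundles["CA"]
        model = bundle.model
        shell = build_shell(model.waters()[0], model)
        assert not detect_nucleotide_phosphate(shell, model)

    @pytest.mark.parametrize("kind,distance,expected", [
        ("GLY:N", 3.2, True),    # backbone amide
        ("ASP:OD1", 3.0, False),  # anionic environment
    ])
    def test_halide_environment(self, kind, distance, expected):
        spec = FixtureSpec("CL", "linear", (kind,) * 2, distance=distance)
        bundle = make_site_fixture(spec, seed=3)
        model = bundle.model
        shell = build_shell(model.waters()[0], model)
        assert detect_halide_environment(shell) is expected

    def test_lysine_ammonium_counts_as_halide_partner(self):
        from ionid.environment import halide_partner
        contact = make_contacts([[1, 0, 0]], [3.0], ["N"])[0]
        # relabel as Lys NZ
        contact.atom.id = AtomId("A", "LYS", 10, " ", "NZ")
        assert halide_partner(contact)


class TestGeometry:
    @pytest.mark.parametrize("name", sorted(GEOMETRY_TEMPLATES))
    def test_ideal_templates_score_zero(self, name, rng):
        template = GEOMETRY_TEMPLATES[name]
        rot = random_rotation(rng)
        g = classify_geometry(template @ rot.T)
        assert g.name == name
        assert g.angle_rmsd == pytest.approx(0.0, abs=1e-5)

    def test_perturbed_octahedron_recovered(self, rng):
        template = GEOMETRY_TEMPLATES["octahedral"]
        rot = random_rotation(rng)
        vectors = []
        for t in template @ rot.T:
            axis = np.cross(t, rng.normal(size=3))
            axis /= np.linalg.norm(axis)
            angle = np.radians(8.0)
            v = t * np.cos(angle) + np.cross(axis, t) * np.sin(angle)
            vectors.append(v)
        g = classify_geometry(np.array(vectors))
        assert g.name == "octahedral"
        assert g.angle_rmsd <= 10.0

    def test_fewer_than_two_donors_is_irregular(self):
        g = classify_geometry(np.array([[0, 0, 1.0]]))
        assert g.name == "irregular" and g.n_donors == 1

    def test_badly_scattered_donors_are_irregular(self, rng):
        vectors = np.array([[1, 0, 0], [0.9, 0.3, 0], [0.8, -0.3, 0.2],
                            [0.95, 0.1, -0.2]])
        g = classify_geometry(vectors)
        assert g.name == "irregular"

    @pytest.mark.parametrize("name", ["tetrahedral", "square_planar",
                                      "trigonal_bipyramidal", "octahedral"])
    def test_assignment_matches_permutation_oracle(self, name, rng):
        template = GEOMETRY_TEMPLATES[name]
        for _ in range(8):
            rot = random_rotation(rng)
            vectors = template @ rot.T + rng.normal(scale=0.08, size=template.shape)
            vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
            rmsd, _, _ = fit_template(vectors, template)
            oracle = permutation_oracle(vectors, template)
            assert rmsd == pytest.approx(oracle, abs=1e-6)
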