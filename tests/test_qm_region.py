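"""Formal charges, link atoms, the surrogate backend, vacuum optimization, strain."""

import numpy as np
import pytest

from qrcryst.qm_region import (
    LIGANDS,
    LigandModel,
    LinkAtom,
    QMRegionSpec,
    SurrogateBackendParams,
    build_surrogate_backend,
    formal_charge,
    optimize_vacuum,
    place_link_atoms,
    qm_energy,
    strain_energy,
)
from qrcryst.synthetic import ToySiteConfig, build_toy_site


class TestFormalCharge:
    OXIDIZED = ["FE3+", "FE3+", "ASP", "GLU", "GLU", "GLU", "HIS", "HIS", "HOH", "HOH"]
    REDUCED = ["FE2+", "FE2+", "ASP", "GLU", "GLU", "GLU", "HIS", "HIS", "HOH"]

    @pytest.mark.parametrize("ligand,expected", [("H2O", 2), ("OH-", 1), ("O2-", 0)])
    def test_oxidized_site_charges(self, ligand, expected):
        # di-ferric site with 4 carboxylates, 2 His, 2 waters + bridging X
        assert formal_charge(self.OXIDIZED + [ligand]) == expected

    @pytest.mark.parametrize("ligand,expected", [("O2-", -2), ("OH-", -1), ("H2O", 0)])
    def test_reduced_site_charges(self, ligand, expected):
        assert formal_charge(self.REDUCED + [ligand]) == expected

    def test_empty_composition(self):
        assert formal_charge([]) == 0

    def test_unknown_constituent_rejected(self):
        with pytest.raises(KeyError, match="MYSTERY"):
            formal_charge(["MYSTERY"])

    def test_ligand_models_consistent(self):
        assert LIGANDS["O2-"].charge == -2 and LIGANDS["O2-"].n_hydrogens == 0
        assert LIGANDS["OH-"].charge == -1 and LIGANDS["OH-"].n_hydrogens == 1
        assert LIGANDS["H2O"].charge == 0 and LIGANDS["H2O"].n_hydrogens == 2
        with pytest.raises(ValueError):
            LigandModel("OH-", 0, 1, "HYD")


class TestLinkAtoms:
    def test_no_cut_bonds_leaves_coordinates(self, site_oh):
        spec = site_oh.spec
        elements, coords, _ = place_link_atoms(site_oh.model, spec)
        assert len(coords) == spec.n_region
        np.testing.assert_array_equal(coords, site_oh.model.positions[spec.selection])

    def test_geometric_placement(self, site_oh):
        model = site_oh.model.copy()
        # region excludes atom j; cut the (i, j) pair with i = a host inside
        host, nb = 5, 6
        pos = model.positions
        pos[host] = np.array([0.0, 0.0, 0.0])
        pos[nb] = np.array([0.0, 0.0, 1.5])
        model.set_positions(pos)
        sel = [i for i in range(len(model)) if i != nb]
        spec = QMRegionSpec(selection=sel, link_atoms=[LinkAtom(host, nb, 1.09)])
        _, coords, _ = place_link_atoms(model, spec)
        np.testing.assert_allclose(coords[-1], [0.0, 0.0, 1.09], atol=1e-12)

    def test_coincident_host_neighbor_rejected(self, site_oh):
        model = site_oh.model.copy()
        pos = model.positions
        pos[6] = pos[5]
        model.set_positions(pos)
        sel = [i for i in range(len(model)) if i != 6]
        spec = QMRegionSpec(selection=sel, link_atoms=[LinkAtom(5, 6, 1.09)])
        with pytest.raises(ValueError, match="coincident"):
            place_link_atoms(model, spec)

    def test_spec_invariants(self):
        with pytest.raises(ValueError):  # host outside selection
            QMRegionSpec(selection=[0, 1], link_atoms=[LinkAtom(5, 6)])
        with pytest.raises(ValueError):  # neighbor inside selection
            QMRegionSpec(selection=[0, 1, 2], link_atoms=[LinkAtom(0, 2)])

    def test_gradient_mapping_matches_finite_differences(self):
        # cut one methyl off an acetate: region = carboxylate + link H
        site = build_toy_site(ToySiteConfig(ligand="OH-"))
        model = site.model
        cb = model.atom_index("A", 84, "CB")
        outside = {cb} | {
            i for i, a in enumerate(model.atoms)
            if a.resnum == 84 and a.name.startswith("HB")
        }
        sel = [i for i in range(len(model)) if i not in outside]
        cg = model.atom_index("A", 84, "CG")
        spec = QMRegionSpec(
            selection=sel, link_atoms=[LinkAtom(cg, cb, 1.09)],
            ligand=site.spec.ligand, bridge_residue=site.spec.bridge_residue,
        )
        backend = build_surrogate_backend(model, spec, site.config.backend_params)
        rng = np.random.default_rng(3)
        m = model.copy()
        m.set_positions(m.positions + 0.03 * rng.standard_normal((len(m), 3)))
        t = qm_energy(m, spec, backend)
        h = 1e-6
        for atom in (cg, cb, sel[0]):
            for d in range(3):
                p1, p2 = m.positions, m.positions
                p1[atom, d] -= h
                m1 = m.copy(); m1.set_positions(p1)
                p1[atom, d] += h
                p2[atom, d] += h
                m2 = m.copy(); m2.set_positions(p2)
                p2[atom, d] -= h
                fd = (qm_energy(m2, spec, backend).value - qm_energy(m1, spec, backend).value) / (2 * h)
                assert t.grad_xyz[atom, d] == pytest.approx(fd, rel=1e-5, abs=1e-4)


class TestSurrogateBackend:
    def test_stationary_at_own_optimum(self, site_oh):
        t = qm_energy(site_oh.model, site_oh.spec, site_oh.backend)
        assert np.linalg.norm(t.grad_xyz) < 1e-4

    def test_rigid_translation_invariance(self, site_oh):
        model = site_oh.model.copy()
        e0 = qm_energy(model, site_oh.spec, site_oh.backend).value
        model.set_positions(model.positions + np.array([2.0, -1.0, 0.5]))
        e1 = qm_energy(model, site_oh.spec, site_oh.backend).value
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_rigid_rotation_invariance(self, site_oh):
        from scipy.spatial.transform import Rotation

        model = site_oh.model.copy()
        e0 = qm_energy(model, site_oh.spec, site_oh.backend).value
        rot = Rotation.from_euler("zyx", [11, 23, -37], degrees=True).as_matrix()
        model.set_positions(model.positions @ rot.T)
        assert qm_energy(model, site_oh.spec, site_oh.backend).value == pytest.approx(e0, abs=1e-8)

    def test_finite_difference_gradient_on_distorted_region(self, site_oh):
        rng = np.random.default_rng(11)
        m = site_oh.model.copy()
        m.set_positions(m.positions + 0.05 * rng.standard_normal((len(m), 3)))
        t = qm_energy(m, site_oh.spec, site_oh.backend)
        h = 1e-6
        for atom, d in [(0, 0), (1, 2), (7, 1), (25, 0)]:
            p1, p2 = m.positions, m.positions
            p1[atom, d] -= h
            m1 = m.copy(); m1.set_positions(p1)
            p2[atom, d] += h
            m2 = m.copy(); m2.set_positions(p2)
            fd = (qm_energy(m2, site_oh.spec, site_oh.backend).value
                  - qm_energy(m1, site_oh.spec, site_oh.backend).value) / (2 * h)
            assert t.grad_xyz[atom, d] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    def test_wrong_atom_count_rejected(self, site_oh):
        with pytest.raises(RuntimeError):
            qm_energy(
                type(site_oh.model)(site_oh.model.cell, site_oh.model.ops, site_oh.model.atoms[:10]),
                QMRegionSpec(selection=np.arange(10)),
                site_oh.backend,
            )

    def test_params_trend_invariant_enforced(self):
        with pytest.raises(ValueError):
            SurrogateBackendParams(fe_x_eq={"O2-": 2.2, "OH-": 1.98, "H2O": 2.08})


class TestVacuumOptimization:
    def test_start_at_optimum_returns_start(self, site_oh):
        elements, coords, _ = place_link_atoms(site_oh.model, site_oh.spec)
        opt = optimize_vacuum(elements, coords, site_oh.backend)
        np.testing.assert_allclose(opt, coords, atol=1e-5)

    def test_displaced_atom_returns_to_harmonic_minimum(self, site_oh):
        elements, coords, _ = place_link_atoms(site_oh.model, site_oh.spec)
        start = coords.copy()
        start[0] += np.array([0.2, 0.0, 0.0])
        opt = optimize_vacuum(elements, start, site_oh.backend)
        e_opt, _ = site_oh.backend.energy_gradient(elements, opt)
        e_ref, _ = site_oh.backend.energy_gradient(elements, coords)
        assert e_opt == pytest.approx(e_ref, abs=1e-6)

    def test_fixed_atoms_never_move(self, site_oh):
        elements, coords, _ = place_link_atoms(site_oh.model, site_oh.spec)
        start = coords.copy()
        start[5] += 0.1
        fixed = np.zeros(len(start), bool)
        fixed[5] = True
        opt = optimize_vacuum(elements, start, site_oh.backend, fixed=fixed)
        np.testing.assert_array_equal(opt[5], start[5])


class TestStrainEnergy:
    def test_zero_at_vacuum_optimum(self, site_oh):
        assert abs(strain_energy(site_oh.model, site_oh.spec, site_oh.backend)) < 0.1

    def test_harmonic_closed_form_for_stretched_bond(self, site_oh):
        # rigidly translate a terminal water along its Fe-O axis by delta:
        # only the Fe-O stretch is strained, so strain = k_metal * delta^2
        params = site_oh.config.backend_params
        model = site_oh.model.copy()
        fe = model.atom_index("A", 501, "FE")
        wat = [i for i, a in enumerate(model.atoms) if a.resnum == 601]
        o = model.atom_index("A", 601, "O")
        axis = model.atoms[o].pos - model.atoms[fe].pos
        axis /= np.linalg.norm(axis)
        delta = 0.1
        pos = model.positions
        pos[wat] += delta * axis
        model.set_positions(pos)
        strain = strain_energy(model, site_oh.spec, site_oh.backend)
        assert strain == pytest.approx(params.k_metal * delta**2, rel=1e-3)

    def test_nonnegative_for_seeded_distortions(self, site_oh):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            m = site_oh.model.copy()
            m.set_positions(m.positions + 0.05 * rng.standard_normal((len(m), 3)))
            assert strain_energy(m, site_oh.spec, site_oh.backend) >= -1e-6

    def test_invariant_under_rigid_motion(self, site_oh):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        m = site_oh.model.copy()
        m.set_positions(m.positions + 0.04 * rng.standard_normal((len(m), 3)))
        s0 = strain_energy(m, site_oh.spec, site_oh.backend)
        rot = Rotation.from_euler("xyz", [15, 30, -10], degrees=True).as_matrix()
        m.set_positions(m.positions @ rot.T + np.array([0.4, 1.1, -2.0]))
        s1 = strain_energy(m, site_oh.spec, site_oh.backend)
        assert s1 == pytest.approx(s0, abs=1e-4)


@pytest.mark.parametrize("ligand", ["O2-", "OH-", "H2O"])
def test_vacuum_optima_reproduce_ligand_equilibria(ligand):
    site = build_toy_site(ToySiteConfig(ligand=ligand))
    params = site.config.backend_params
    pos = site.model.positions
    o = next(i for i, a in enumerate(site.model.atoms) if a.resnum == 503 and a.element == "O")
    for fe_num in (501, 502):
        fe = site.model.atom_index("A", fe_num, "FE")
        d = np.linalg.norm(pos[o] - pos[fe])
        assert d == pytest.approx(params.fe_x_eq[ligand], abs=1e-3)


def test_water_oh_distance_restraints_hold_protons():
    # mirrors keeping water protons bonded during refinement via O-H restraints
    site = build_toy_site(ToySiteConfig(ligand="H2O"))
    model = site.model
    o = model.atom_index("A", 503, "O")
    h1 = model.atom_index("A", 503, "H1")
    spec = QMRegionSpec(
        selection=site.spec.selection, net_charge=site.spec.net_charge,
        ligand=site.spec.ligand, bridge_residue=site.spec.bridge_residue,
        distance_restraints=[(o, h1, 0.96, 4000.0)],
    )
    m = model.copy()
    pos = m.positions
    pos[h1] += np.array([0.0, 0.3, 0.0])
    m.set_positions(pos)
    t_plain = qm_energy(m, site.spec, site.backend)
    t_restr = qm_energy(m, spec, site.backend)
    assert t_restr.value > t_plain.value  # extra pull back toward the oxygen
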