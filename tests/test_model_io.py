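"""Unit cell math, file round trips, Friedel merging, merging statistics."""

import gemmi
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qrcryst.model_io import (
    Atom,
    ReflectionSet,
    SymmetryOps,
    UnitCell,
    assign_free_set,
    d_spacing,
    merge_friedel,
    merging_stats,
    read_model,
    read_reflections,
    theoretical_reflections,
    write_model,
    write_reflections,
)

THREE_ATOM_PDB = """\
CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1
ATOM      1  FE  FE  A 501       5.000   5.000   5.000  1.00 42.27          FE
ATOM      2  O   HOH A 601       2.500   5.000   5.000  1.00 20.00           O
ATOM      3  N   LIG A 701       5.000   2.000   5.000  0.50 15.50           N
END
"""


class TestUnitCell:
    @pytest.mark.parametrize(
        "cell",
        [
            UnitCell(10, 10, 10),
            UnitCell(7, 8, 9, 80, 95, 100),
            UnitCell(16, 17, 18, 90, 90, 90),
        ],
    )
    def test_fractionalize_orthogonalize_roundtrip(self, cell):
        rng = np.random.default_rng(0)
        xyz = rng.uniform(-20, 20, size=(50, 3))
        back = cell.orthogonalize(cell.fractionalize(xyz))
        np.testing.assert_allclose(back, xyz, atol=1e-10)

    @pytest.mark.parametrize(
        "bad", [(0, 10, 10, 90, 90, 90), (10, 10, 10, 0, 90, 90), (10, 10, 10, 90, 180, 90)]
    )
    def test_invalid_cells_rejected(self, bad):
        with pytest.raises(ValueError):
            UnitCell(*bad)

    def test_volume_positive(self):
        assert UnitCell(7, 8, 9, 80, 95, 100).volume > 0


class TestDSpacing:
    def test_cubic_axis(self):
        assert d_spacing(UnitCell(10, 10, 10), (1, 0, 0)) == pytest.approx(10.0)

    def test_cubic_111(self):
        assert d_spacing(UnitCell(10, 10, 10), (1, 1, 1)) == pytest.approx(10 / np.sqrt(3))

    def test_triclinic_matches_independent_evaluation(self):
        # oracle: gemmi's own metric-tensor implementation
        cell = UnitCell(7, 8, 9, 80, 95, 100)
        g = gemmi.UnitCell(7, 8, 9, 80, 95, 100)
        for hkl in [(2, -1, 3), (1, 0, 0), (0, 5, -2)]:
            assert d_spacing(cell, hkl) == pytest.approx(g.calculate_d(hkl), rel=1e-12)

    def test_zero_index_rejected(self):
        with pytest.raises(ValueError):
            d_spacing(UnitCell(10, 10, 10), (0, 0, 0))

    @given(h=st.integers(-8, 8), k=st.integers(-8, 8), l=st.integers(-8, 8))
    @settings(deadline=None, max_examples=50)
    def test_friedel_symmetry_of_d(self, h, k, l):
        if (h, k, l) == (0, 0, 0):
            return
        cell = UnitCell(7, 8, 9, 80, 95, 100)
        assert d_spacing(cell, (h, k, l)) == pytest.approx(d_spacing(cell, (-h, -k, -l)))


class TestSymmetryOps:
    def test_identity_required(self):
        with pytest.raises(ValueError):
            SymmetryOps(-np.eye(3, dtype=int)[None], np.zeros((1, 3)))

    def test_p212121_expansion_preserves_site_set(self):
        ops = SymmetryOps.from_spacegroup("P 21 21 21")
        assert len(ops) == 4
        frac = np.array([[0.13, 0.27, 0.41]])
        expanded = ops.expand(frac)[:, 0, :] % 1.0
        # re-expanding any copy reproduces the same set of sites
        again = ops.expand(expanded[2][None])[:, 0, :] % 1.0
        d = np.linalg.norm(expanded[None] - again[:, None], axis=-1)
        assert np.all(d.min(axis=1) < 1e-12)


class TestModelIO:
    def test_three_atom_fixture(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(THREE_ATOM_PDB)
        model = read_model(p)
        assert len(model) == 3
        assert model.cell.a == pytest.approx(10.0)
        fe = model.atoms[0]
        assert fe.element == "Fe" and fe.b_iso == pytest.approx(42.27)
        assert model.atoms[2].occ == pytest.approx(0.5)

    def test_write_read_roundtrip(self, tmp_path, site_oh):
        p = tmp_path / "site.pdb"
        write_model(site_oh.model, p)
        back = read_model(p)
        assert len(back) == len(site_oh.model)
        np.testing.assert_allclose(back.positions, site_oh.model.positions, atol=1e-3)
        np.testing.assert_allclose(back.b_factors, site_oh.model.b_factors, atol=1e-2)
        assert [a.key for a in back.atoms] == [a.key for a in site_oh.model.atoms]

    def test_missing_cryst1_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("".join(THREE_ATOM_PDB.splitlines(keepends=True)[1:]))
        with pytest.raises(ValueError, match="CRYST1"):
            read_model(p)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="element"):
            Atom("A", 1, "BAD", "Q1", "Qq", np.zeros(3))


class TestReflectionIO:
    def _random_set(self, n, seed, cell):
        rng = np.random.default_rng(seed)
        hkl = rng.integers(-6, 7, size=(3 * n, 3))
        hkl = np.unique(hkl[np.any(hkl != 0, axis=1)], axis=0)[:n]
        return ReflectionSet(
            hkl=hkl,
            fobs=rng.uniform(0, 100, len(hkl)),
            sigma=rng.uniform(0.5, 5, len(hkl)),
            free=rng.random(len(hkl)) < 0.05,
            cell=cell,
        )

    def test_row_parse(self, tmp_path):
        p = tmp_path / "r.hkl"
        p.write_text("# comment\n1 2 3 10.0 1.0 0\n")
        rs = read_reflections(p, UnitCell(10, 10, 10))
        assert len(rs) == 1
        assert tuple(rs.hkl[0]) == (1, 2, 3)
        assert rs.fobs[0] == 10.0 and rs.sigma[0] == 1.0 and not rs.free[0]

    def test_n_rows(self, tmp_path):
        cell = UnitCell(30, 30, 30)
        rs = self._random_set(100, 1, cell)
        p = tmp_path / "n.hkl"
        write_reflections(rs, p)
        assert len(read_reflections(p, cell)) == 100

    def test_roundtrip_property(self, tmp_path):
        cell = UnitCell(30, 30, 30)
        for seed in (1, 2, 3):
            rs = self._random_set(64, seed, cell)
            p = tmp_path / f"rt{seed}.hkl"
            write_reflections(rs, p)
            back = read_reflections(p, cell)
            np.testing.assert_array_equal(back.hkl, rs.hkl)
            np.testing.assert_allclose(back.fobs, rs.fobs, atol=1e-6)
            np.testing.assert_allclose(back.sigma, rs.sigma, atol=1e-6)
            np.testing.assert_array_equal(back.free, rs.free)

    def test_nonpositive_sigma_rejected_with_count(self, tmp_path, caplog):
        p = tmp_path / "s.hkl"
        p.write_text("1 2 3 10.0 1.0 0\n1 2 4 10.0 -1.0 0\n1 2 5 10.0 0.0 0\n")
        with caplog.at_level("WARNING"):
            rs = read_reflections(p, UnitCell(10, 10, 10))
        assert len(rs) == 1
        assert "2" in caplog.text

    def test_extra_trailing_columns_tolerated(self, tmp_path):
        p = tmp_path / "x.hkl"
        p.write_text("1 2 3 10.0 1.0 1 99.9 extra\n")
        rs = read_reflections(p, UnitCell(10, 10, 10))
        assert rs.free[0]


class TestMergeFriedel:
    def _set(self, rows, cell=None):
        cell = cell or UnitCell(20, 20, 20)
        arr = np.array([r[:3] for r in rows], int)
        return ReflectionSet(
            hkl=arr,
            fobs=np.array([r[3] for r in rows], float),
            sigma=np.array([r[4] for r in rows], float),
            free=np.zeros(len(rows), bool),
            cell=cell,
        )

    def test_no_mates_passthrough(self):
        rs = self._set([(1, 2, 3, 10, 1), (2, 0, 1, 5, 2)])
        merged = merge_friedel(rs)
        assert merged.merged and len(merged) == 2
        assert sorted(map(tuple, merged.hkl)) == [(1, 2, 3), (2, 0, 1)]

    def test_equal_pair(self):
        merged = merge_friedel(self._set([(1, 2, 3, 10, 1), (-1, -2, -3, 10, 1)]))
        assert len(merged) == 1
        assert merged.fobs[0] == pytest.approx(10.0)
        assert merged.sigma[0] == pytest.approx(1 / np.sqrt(2))

    def test_inverse_variance_mean_by_hand(self):
        merged = merge_friedel(self._set([(1, 2, 3, 10, 1), (-1, -2, -3, 12, 2)]))
        assert merged.fobs[0] == pytest.approx(10.4)
        assert merged.sigma[0] == pytest.approx(0.8944, abs=1e-4)

    def test_canonical_representative_is_lexicographically_larger(self):
        merged = merge_friedel(self._set([(-1, 2, 3, 10, 1)]))
        assert tuple(merged.hkl[0]) == (1, -2, -3)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(40):
            h = tuple(rng.integers(-5, 6, 3))
            if h == (0, 0, 0):
                continue
            rows.append((*h, float(rng.uniform(1, 50)), float(rng.uniform(0.5, 3))))
        once = merge_friedel(self._set(rows))
        twice = merge_friedel(once)
        np.testing.assert_array_equal(once.hkl, twice.hkl)
        np.testing.assert_allclose(once.fobs, twice.fobs, rtol=1e-12)
        np.testing.assert_allclose(once.sigma, twice.sigma, rtol=1e-12)


class TestFreeSet:
    def _set(self, n=1000):
        hkl = np.column_stack([np.arange(1, n + 1), np.ones(n, int), np.ones(n, int)])
        return ReflectionSet(hkl, np.ones(n), np.ones(n), np.zeros(n, bool), UnitCell(2000, 10, 10))

    def test_exact_count(self):
        assert assign_free_set(self._set(), 0.05, seed=1).free.sum() == 50

    def test_seed_reproducible(self):
        a = assign_free_set(self._set(), 0.05, seed=9).free
        b = assign_free_set(self._set(), 0.05, seed=9).free
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_differ(self):
        a = assign_free_set(self._set(), 0.05, seed=1).free
        b = assign_free_set(self._set(), 0.05, seed=2).free
        assert np.any(a != b)

    @pytest.mark.parametrize("frac", [0.0, 0.5, -0.1, 0.9])
    def test_fraction_range_enforced(self, frac):
        with pytest.raises(ValueError):
            assign_free_set(self._set(100), frac, seed=0)


class TestMergingStats:
    def test_perfect_duplicates(self):
        cell = UnitCell(10, 10, 10)
        uniq = theoretical_reflections(cell, 2.5)
        vals = np.arange(1.0, len(uniq) + 1)
        obs = pd.DataFrame(
            np.vstack([np.column_stack([uniq, vals])] * 2), columns=["h", "k", "l", "value"]
        )
        stats = merging_stats(obs, cell, 2.5, seed=0)
        assert stats["r_meas"] == pytest.approx(0.0)
        assert stats["cc_half"] == pytest.approx(100.0)
        assert stats["multiplicity"] == pytest.approx(2.0)
        assert stats["completeness"] == pytest.approx(100.0)

    def test_rmeas_hand_evaluation(self):
        # one unique with observations {9, 11}: Rmeas = sqrt(2)*(1+1)/20 = 14.14%
        obs = pd.DataFrame({"h": [1, 1], "k": [2, 2], "l": [3, 3], "value": [9.0, 11.0]})
        stats = merging_stats(obs, UnitCell(10, 10, 10), 2.0, seed=0)
        assert stats["r_meas"] == pytest.approx(100 * np.sqrt(2) * 2 / 20, abs=1e-6)

    def test_completeness_counting(self):
        cell = UnitCell(10, 10, 10)
        uniq = theoretical_reflections(cell, 2.0)
        n = len(uniq)
        n_obs = int(round(0.88 * n))
        obs = pd.DataFrame(uniq[:n_obs], columns=["h", "k", "l"])
        obs["value"] = 1.0
        stats = merging_stats(obs, cell, 2.0, seed=0)
        assert stats["completeness"] == pytest.approx(100.0 * n_obs / n)

    def test_all_singletons_rmeas_absent(self):
        obs = pd.DataFrame({"h": [1, 2], "k": [0, 0], "l": [0, 0], "value": [5.0, 6.0]})
        stats = merging_stats(obs, UnitCell(10, 10, 10), 2.0, seed=0)
        assert stats["r_meas"] is None

    def test_friedel_mates_count_as_one_unique(self):
        obs = pd.DataFrame({"h": [1, -1], "k": [2, -2], "l": [3, -3], "value": [9.0, 11.0]})
        stats = merging_stats(obs, UnitCell(10, 10, 10), 2.0, seed=0)
        assert stats["multiplicity"] == pytest.approx(2.0)

    def test_theoretical_count_matches_brute_force(self):
        cell = UnitCell(10, 11, 12)
        d_min = 2.5
        count = 0
        for h in range(-5, 6):
            for k in range(-5, 6):
                for l in range(-5, 6):
                    if (h, k, l) <= (-h, -k, -l):
                        continue
                    if d_spacing(cell, (h, k, l)) >= d_min:
                        count += 1
        assert len(theoretical_reflections(cell, d_min)) == count
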