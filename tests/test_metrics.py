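"""Bilayer observables: per-lipid area/volume, compressibility, thickness,
electron density, deuterium order parameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bilayerlab import metrics
from bilayerlab.core import Selection, assign_leaflets
from bilayerlab.metrics import (
    BilayerMetricSeries,
    area_compressibility,
    area_per_lipid,
    bilayer_thickness,
    electron_density_profile,
    order_parameters,
    volume_per_lipid,
)
from bilayerlab.synthetic import GeneratorParams, generate_bilayer_trajectory

from conftest import make_trajectory


def boxes_only_traj(boxes):
    """Minimal 1-atom trajectory carrying the given per-frame boxes."""
    coords = [[[0.0, 0.0, 0.0]]] * len(boxes)
    return make_trajectory(coords, boxes)


class TestAreaPerLipid:
    def test_identity_case(self):
        traj = boxes_only_traj([(10.0, 10.0, 50.0)])
        assert area_per_lipid(traj, 1, discard_fraction=0.0).mean == pytest.approx(100.0)

    def test_hand_value(self):
        traj = boxes_only_traj([(8.0, 8.0, 50.0)])
        assert area_per_lipid(traj, 2, discard_fraction=0.0).mean == pytest.approx(32.0)

    def test_invalid_m_lipid(self):
        with pytest.raises(ValueError):
            area_per_lipid(boxes_only_traj([(8.0, 8.0, 50.0)]), 0)

    def test_product_reproduces_box_area_exactly(self):
        rng = np.random.default_rng(0)
        boxes = [(float(a), float(b), 50.0) for a, b in rng.uniform(30, 60, size=(20, 2))]
        traj = boxes_only_traj(boxes)
        series = area_per_lipid(traj, 7, discard_fraction=0.0)
        for v, (lx, ly, _) in zip(series.per_frame, boxes):
            assert v * 7 == pytest.approx(lx * ly, rel=1e-14)


class TestVolumePerLipid:
    def test_zero_when_waters_fill_box(self):
        # V_box = n_w * 30.53 exactly
        traj = boxes_only_traj([(10.0, 10.0, 30.53)])
        series = volume_per_lipid(traj, 100, 5, discard_fraction=0.0)
        assert series.mean == pytest.approx(0.0, abs=1e-9)

    def test_hand_value(self):
        traj = boxes_only_traj([(100.0, 100.0, 10.0)])  # V_box = 100000
        series = volume_per_lipid(traj, 2000, 64, discard_fraction=0.0)
        assert series.mean == pytest.approx(608.4375)

    def test_no_waters(self):
        traj = boxes_only_traj([(10.0, 10.0, 10.0)])
        series = volume_per_lipid(traj, 0, 4, discard_fraction=0.0)
        assert series.mean == pytest.approx(250.0)

    def test_negative_volume_warns_but_reports(self):
        traj = boxes_only_traj([(5.0, 5.0, 5.0)])
        with pytest.warns(UserWarning, match="negative V_L"):
            series = volume_per_lipid(traj, 100, 4, discard_fraction=0.0)
        assert series.mean < 0


class TestCompressibility:
    def _series(self, values):
        return BilayerMetricSeries.from_values("A_L", values, discard_fraction=0.0, n_blocks=1)

    def test_closed_form_on_known_series(self):
        values = np.array([60.0, 62.0, 64.0, 66.0])
        res = area_compressibility(self._series(values), T=313.0, m_lipid=10)
        expected = metrics.BOLTZMANN_mN_per_m * 313.0 * 63.0 / (10 * np.var(values, ddof=1))
        assert res.K_A == pytest.approx(expected, rel=1e-12)

    def test_doubling_temperature_doubles_ka(self):
        values = np.array([60.0, 62.0, 61.0, 64.0])
        k1 = area_compressibility(self._series(values), 300.0, 4).K_A
        k2 = area_compressibility(self._series(values), 600.0, 4).K_A
        assert k2 == pytest.approx(2 * k1)

    def test_doubling_variance_halves_ka(self):
        base = np.array([-1.0, 1.0, -1.0, 1.0])
        k1 = area_compressibility(self._series(100.0 + base), 313.0, 4).K_A
        k2 = area_compressibility(self._series(100.0 + base * math.sqrt(2)), 313.0, 4).K_A
        assert k1 / k2 == pytest.approx(2.0, rel=1e-9)

    def test_rigid_box_rejected(self):
        with pytest.raises(ValueError, match="rigid box"):
            area_compressibility(self._series([50.0, 50.0, 50.0]), 313.0, 4)

    def test_magnitude_matches_study_scale(self):
        # planted free-bilayer conditions give K_A in the fluid-membrane range
        p = GeneratorParams(n_lipids_per_leaflet=2, n_frames=4000, chain_length=2,
                            scd_targets=(0.2, 0.1), n_waters=0, seed=2)
        traj, _ = generate_bilayer_trajectory(p)
        areas = area_per_lipid(traj, 2, discard_fraction=0.0)
        res = area_compressibility(areas, 313.0, 2)
        assert 150 < res.K_A < 400  # mN/m, liquid-crystalline bilayer scale


class TestThickness:
    def _bilayer(self, z_upper, z_lower, extra=None):
        specs, coords = [], []
        for i, z in enumerate([z_upper] * 4 + [z_lower] * 4):
            specs.append(("P", "P", i))
            coords.append([float(i), 0.0, z])
        if extra is not None:
            specs.append(("X", "C", 8))
            coords.append(extra)
        return make_trajectory([coords], (100.0, 100.0, 100.0), specs)

    def test_planted_planes(self):
        traj = self._bilayer(18.0, -18.0)
        sel = Selection("p", tuple(range(8)))
        leaf = assign_leaflets(traj.frames[0], sel)
        h = bilayer_thickness(traj, sel, leaf, discard_fraction=0.0)
        assert h.mean == pytest.approx(36.0)

    def test_c2_scale_planes(self):
        traj = self._bilayer(13.0, -13.0)
        sel = Selection("p", tuple(range(8)))
        leaf = assign_leaflets(traj.frames[0], sel)
        assert bilayer_thickness(traj, sel, leaf, discard_fraction=0.0).mean == pytest.approx(26.0)

    def test_selection_scoped(self):
        # an extra non-selected atom leaves the thickness unchanged
        traj = self._bilayer(18.0, -18.0, extra=[0.0, 0.0, 3.0])
        sel = Selection("p", tuple(range(8)))
        leaf = assign_leaflets(traj.frames[0], sel)
        assert bilayer_thickness(traj, sel, leaf, discard_fraction=0.0).mean == pytest.approx(36.0)

    def test_empty_leaflet_rejected(self):
        traj = self._bilayer(18.0, -18.0)
        sel_p = Selection("p", tuple(range(8)))
        leaf = assign_leaflets(traj.frames[0], sel_p)
        upper_only = Selection("u", tuple(range(4)))
        with pytest.raises(Exception, match="leaflet"):
            bilayer_thickness(traj, upper_only, leaf)


class TestDensityProfile:
    def test_single_atom_hand_value(self):
        # Z = 15 at z = 5.0, area 100 A^2, bin 0.5 A -> 15/(100*0.5) = 0.30 e-/A^3
        specs = [("P", "P", 0)]
        traj = make_trajectory([[[0.0, 0.0, 5.0]]], (10.0, 10.0, 40.0), specs)
        prof = electron_density_profile(traj, {"p": Selection("p", (0,))}, bin_width=0.5)
        assert prof.densities["p"].max() == pytest.approx(0.30)
        assert (prof.densities["p"] > 0).sum() == 1

    def test_mirror_symmetric_fixture(self):
        specs = [("C1", "C", 0), ("C2", "C", 1)]
        traj = make_trajectory([[[0, 0, 7.0], [0, 0, -7.0]]], (20.0, 20.0, 40.0), specs)
        prof = electron_density_profile(traj, {"c": Selection("c", (0, 1))}, bin_width=0.5)
        np.testing.assert_allclose(prof.densities["c"], prof.densities["c"][::-1], atol=1e-12)

    def test_integral_conservation(self):
        rng = np.random.default_rng(4)
        n = 30
        coords = [rng.uniform(-15, 15, size=(n, 3)) for _ in range(3)]
        traj = make_trajectory(coords, (25.0, 25.0, 40.0))
        groups = {
            "a": Selection("a", tuple(range(10))),
            "b": Selection("b", tuple(range(10, n))),
        }
        prof = electron_density_profile(traj, groups, bin_width=0.5)
        assert prof.integral("a") == pytest.approx(10 * 6, rel=1e-9)
        assert prof.integral("b") == pytest.approx(20 * 6, rel=1e-9)
        assert prof.integral("total") == pytest.approx(30 * 6, rel=1e-9)

    def test_empty_group_warned_and_omitted(self):
        traj = make_trajectory([[[0.0, 0.0, 0.0]]], (10.0, 10.0, 10.0))
        with pytest.warns(UserWarning, match="empty"):
            prof = electron_density_profile(
                traj, {"x": Selection("x", ()), "y": Selection("y", (0,))}
            )
        assert "x" not in prof.densities and "y" in prof.densities


def ch_traj(directions):
    """One carbon at origin with one H per given unit direction (each molecule
    gets its own C to keep (C, H) pairing simple)."""
    specs, coords = [], []
    for i, d in enumerate(directions):
        specs += [(f"C{i}", "C", i), (f"H{i}", "H", i)]
        coords += [[0.0, 0.0, 0.0], list(np.asarray(d) * 1.09)]
    traj = make_trajectory([coords], (500.0, 500.0, 500.0), specs)
    triples = [[(2 * i, (2 * i + 1,)) for i in range(len(directions))]]
    return traj, {"chain": triples}


class TestOrderParameters:
    def test_parallel_gives_one(self):
        traj, chains = ch_traj([(0, 0, 1.0), (0, 0, -1.0)])
        prof = order_parameters(traj, chains)["chain"]
        assert prof.scd[0] == pytest.approx(1.0, abs=1e-12)

    def test_in_plane_gives_minus_half(self):
        traj, chains = ch_traj([(1.0, 0, 0), (0, 1.0, 0)])
        prof = order_parameters(traj, chains)["chain"]
        assert prof.scd[0] == pytest.approx(-0.5, abs=1e-12)

    def test_magic_angle_gives_zero(self):
        theta = math.radians(54.7356103)  # arccos(1/sqrt(3))
        traj, chains = ch_traj([(math.sin(theta), 0, math.cos(theta))])
        prof = order_parameters(traj, chains)["chain"]
        assert prof.scd[0] == pytest.approx(0.0, abs=1e-6)

    def test_isotropic_gives_zero(self, rng):
        n = 100_000
        z = rng.uniform(-1, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        r = np.sqrt(1 - z**2)
        dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        # single carbon with all n hydrogens attached: same average, tiny fixture
        specs = [("C1", "C", 0)] + [(f"H{i}", "H", 0) for i in range(n)]
        coords = np.vstack([[0.0, 0.0, 0.0], dirs * 1.09])
        traj = make_trajectory([coords], (500.0, 500.0, 500.0), specs)
        chains = {"chain": [[(0, tuple(range(1, n + 1)))]]}
        prof = order_parameters(traj, chains)["chain"]
        assert prof.scd[0] == pytest.approx(0.0, abs=0.01)

    def test_missing_hydrogens_rejected(self):
        traj, _ = ch_traj([(0, 0, 1.0)])
        with pytest.raises(Exception, match="hydrogen"):
            order_parameters(traj, {"chain": [[(0, ())]]})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 20))
    def test_scd_bounded(self, seed, n):
        r = np.random.default_rng(seed)
        dirs = r.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        traj, chains = ch_traj(dirs)
        prof = order_parameters(traj, chains)["chain"]
        assert -0.5 - 1e-9 <= prof.scd[0] <= 1.0 + 1e-9
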