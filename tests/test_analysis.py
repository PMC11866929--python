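"""Diagnostics: MAE metric, ADF geometry, diffusion, bond order."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rdfbias as rb
from rdfbias.analysis import (adf, classify_phase, diffusion_coefficient,
                              mae, mean_squared_displacement, qlbar)
from rdfbias.engine import EngineConfig, LJParams, MDEngine

from conftest import make_fcc_frame, make_random_frame


def hist(values, grid=None):
    grid = grid or rb.RDFGrid(len(values), 0.1)
    return rb.RDFHistogram(grid, np.asarray(values, dtype=float))


class TestMAE:
    def test_zero_iff_identical(self):
        a = hist([1.0, 2.0, 0.5])
        assert mae(a, a) == 0.0
        b = hist([1.0, 2.0, 0.6])
        assert mae(a, b) > 0.0

    def test_constant_offset(self):
        g = rb.RDFGrid(5, 0.1)
        a = hist(np.ones(5), g)
        b = hist(np.ones(5) + 0.1, g)
        assert mae(a, b) == pytest.approx(0.1)

    def test_symmetry_and_grid_mismatch(self):
        a, b = hist([1, 2, 3]), hist([0, 2, 5])
        assert mae(a, b) == mae(b, a)
        with pytest.raises(ValueError):
            mae(a, hist([1, 2], rb.RDFGrid(2, 0.1)))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 10), min_size=4, max_size=4),
           st.lists(st.floats(0, 10), min_size=4, max_size=4),
           st.lists(st.floats(0, 10), min_size=4, max_size=4))
    def test_triangle_inequality(self, x, y, z):
        g = rb.RDFGrid(4, 0.1)
        a, b, c = hist(x, g), hist(y, g), hist(z, g)
        assert mae(a, c) <= mae(a, b) + mae(b, c) + 1e-12


class TestADF:
    def test_collinear_atoms_peak_at_180(self):
        pos = np.array([[5.0, 5.0, 5.0], [6.0, 5.0, 5.0], [4.0, 5.0, 5.0]])
        frame = rb.Frame(pos, np.full(3, 10.0))
        h = adf(frame, cutoff=1.2, bin_width_deg=2.0)
        assert h.theta[np.argmax(h.density)] == pytest.approx(179.0)

    def test_right_angle_triad(self):
        pos = np.array([[5.0, 5.0, 5.0], [6.0, 5.0, 5.0], [5.0, 6.0, 5.0]])
        frame = rb.Frame(pos, np.full(3, 12.0))
        h = adf(frame, cutoff=1.2, bin_width_deg=2.0)
        assert h.theta[np.argmax(h.density)] == pytest.approx(91.0)

    def test_tetrahedral_shell_peaks_at_tetrahedral_angle(self):
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / np.sqrt(3.0)
        pos = np.vstack([[0.0, 0.0, 0.0], tet]) + 5.0
        frame = rb.Frame(pos, np.full(3, 10.0))
        h = adf(frame, cutoff=1.2, bin_width_deg=2.0)
        peak = h.theta[np.argmax(h.density)]
        assert abs(peak - 109.47) <= h.bin_width

    def test_density_integrates_to_one(self, rng):
        frame = make_random_frame(rng, n=60, box_len=5.0)
        h = adf(frame, cutoff=1.4, bin_width_deg=2.0)
        assert np.sum(h.density) * h.bin_width == pytest.approx(1.0)

    def test_no_neighbors_is_an_error(self):
        pos = np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0], [9.0, 9.0, 1.0]])
        frame = rb.Frame(pos, np.full(3, 12.0))
        with pytest.raises(ValueError):
            adf(frame, cutoff=0.5)


class TestDiffusion:
    def test_frozen_particles_have_zero_diffusion(self):
        pos = np.broadcast_to(np.zeros((1, 10, 3)), (50, 10, 3))
        res = diffusion_coefficient(pos, dt=0.1)
        assert res.d == 0.0

    def test_ballistic_motion_is_flagged(self):
        t = np.arange(100)[:, None, None]
        v = np.ones((1, 5, 3))
        res = diffusion_coefficient((0.5 * t**2) * v, dt=0.1)
        assert res.flagged  # MSD ∝ t⁴ here: clearly non-diffusive

    def test_msd_of_linear_motion_is_quadratic(self):
        t = np.arange(30, dtype=float)
        pos = np.zeros((30, 2, 3))
        pos[:, 0, 0] = 2.0 * t
        pos[:, 1, 1] = 2.0 * t
        msd = mean_squared_displacement(pos)
        assert np.allclose(msd, (2.0 * t) ** 2, rtol=1e-8, atol=1e-8)

    def test_langevin_free_particles_recover_input_diffusivity(self):
        """Overdamped free Langevin dynamics: D = k_BT·τ/m, recovered
        from the Einstein relation within 10%."""
        kt, tau = 1.0, 0.1
        cfg = EngineConfig(
            lj_params={("X", "X"): LJParams(epsilon=0.0)},
            temperature=kt, thermostat_damping=tau, dt=0.01, seed=4,
        )
        n, box_len = 500, 20.0
        rng = np.random.default_rng(0)
        frame = rb.Frame(rng.uniform(0, box_len, (n, 3)), np.full(3, box_len))
        engine = MDEngine(frame, cfg)
        unwrapped = [engine.state.frame.positions.copy()]
        prev = unwrapped[0].copy()
        for _ in range(2000):
            engine.step(5)
            cur = engine.state.frame.positions
            d = cur - prev
            d -= box_len * np.round(d / box_len)
            unwrapped.append(unwrapped[-1] + d)
            prev = cur.copy()
        res = diffusion_coefficient(np.asarray(unwrapped), dt=0.05)
        assert res.d == pytest.approx(kt * tau, rel=0.1)
        assert not res.flagged


class TestBondOrder:
    def test_fcc_q6bar_single_shared_value(self, fcc_frame):
        res = qlbar(fcc_frame, l=6, neighbor_rule={"knn": 12})
        assert res.q.std() < 1e-10
        assert res.q.mean() == pytest.approx(0.5745, abs=5e-4)

    def test_fcc_matches_independent_symbolic_summation(self, fcc_frame):
        """Closed-form spherical harmonics from sympy, summed by hand
        over the 12 nearest-neighbour bonds, agree to 1e−8."""
        import sympy as sp

        res = qlbar(fcc_frame, l=6, neighbor_rule={"knn": 12})
        # 12 NN bond directions of FCC
        dirs = []
        for u, v in [(0, 1), (0, 2), (1, 2)]:
            for su in (1, -1):
                for sv in (1, -1):
                    d = np.zeros(3)
                    d[u], d[v] = su, sv
                    dirs.append(d / np.sqrt(2.0))
        theta_s, phi_s = sp.symbols("theta phi")
        l = 6
        q_sq = 0.0
        for m in range(-l, l + 1):
            ylm = sp.lambdify((theta_s, phi_s),
                              sp.Ynm(l, m, theta_s, phi_s).expand(func=True),
                              "numpy")
            acc = 0.0 + 0.0j
            for d in dirs:
                th = np.arccos(d[2])
                ph = np.arctan2(d[1], d[0])
                acc += complex(ylm(th, ph))
            q_sq += abs(acc / len(dirs)) ** 2
        q6_expected = np.sqrt(4.0 * np.pi / (2 * l + 1) * q_sq)
        # perfect lattice: Lechner–Dellago averaging leaves q_lm unchanged
        assert res.q.mean() == pytest.approx(q6_expected, abs=1e-8)

    def test_rotation_invariance_open_cluster(self, rng):
        """q̄_6 of a finite cluster is unchanged by a global rotation.

        A random cluster avoids the equidistant-neighbour ties of
        lattice surfaces, which would let the k-nearest rule pick
        different (equally valid) neighbour sets after rotation.
        """
        from scipy.spatial.transform import Rotation

        pos = rng.uniform(-3.0, 3.0, size=(60, 3))
        big = np.full(3, 100.0)
        a = qlbar(rb.Frame(pos + 50.0, big), l=6, neighbor_rule={"knn": 12})
        rot = Rotation.random(random_state=7).as_matrix()
        b = qlbar(rb.Frame(pos @ rot.T + 50.0, big), l=6,
                  neighbor_rule={"knn": 12})
        assert np.allclose(a.q, b.q, atol=1e-10)

    def test_gas_and_lattice_separate_cleanly(self, rng, fcc_frame):
        lattice = qlbar(fcc_frame, l=6, neighbor_rule={"knn": 12})
        gas_frame = make_random_frame(rng, n=256, box_len=6.2)
        gas = qlbar(gas_frame, l=6, neighbor_rule={"knn": 12})
        assert np.median(lattice.q) > np.median(gas.q)
        assert gas.q.max() < lattice.q.min()  # zero overlap at 0.35

    def test_cutoff_rule_matches_knn_on_perfect_fcc(self, fcc_frame):
        by_knn = qlbar(fcc_frame, l=6, neighbor_rule={"knn": 12})
        by_cut = qlbar(fcc_frame, l=6, neighbor_rule={"cutoff": 1.3})
        assert np.allclose(by_knn.q, by_cut.q, atol=1e-12)

    def test_isolated_atoms_reported(self):
        pos = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0], [8.0, 8.0, 8.0]])
        frame = rb.Frame(pos, np.full(3, 10.0))
        res = qlbar(frame, l=6, neighbor_rule={"cutoff": 1.0})
        assert 2 in res.excluded
        assert res.q.shape[0] == 2


class TestClassify:
    def test_all_below_threshold_zero_solid(self, rng, fcc_frame):
        gas = qlbar(make_random_frame(rng, n=128, box_len=5.0), l=6,
                    neighbor_rule={"knn": 12})
        out = classify_phase(gas, 0.35)
        assert out["solid_fraction"] == 0.0

    def test_perfect_fcc_fully_solid_at_035(self, fcc_frame):
        res = qlbar(fcc_frame, l=6, neighbor_rule={"knn": 12})
        out = classify_phase(res, 0.35)
        assert out["solid_fraction"] == 1.0

    def test_preset_thresholds_accepted(self, fcc_frame):
        from rdfbias.analysis import PHASE_THRESHOLD_PRESETS

        res = qlbar(fcc_frame, l=6, neighbor_rule={"knn": 12})
        for name, thr in PHASE_THRESHOLD_PRESETS.items():
            out = classify_phase(res, thr)
            assert out["solid_fraction"] == 1.0  # perfect crystal

    def test_threshold_validated(self, fcc_frame):
        res = qlbar(fcc_frame, l=6, neighbor_rule={"knn": 12})
        with pytest.raises(ValueError):
            classify_phase(res, 1.5)
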