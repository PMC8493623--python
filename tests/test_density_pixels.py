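import math

import numpy as np
import pytest

from pixkit.density_pixels import (BOHR, COULOMB_K, DensityCube, LatticeInfo,
                                   PixelCloud, condense, coulomb_energy, prune,
                                   read_cube, write_cube)
from pixkit.errors import CubeFormatError, PixkitError
from pixkit.fixtures import analytic_coulomb, make_gaussian_cube


def random_cube(rng, shape=(5, 4, 3), nuclei=()):
    return DensityCube(origin=rng.uniform(-1, 1, 3),
                       axes=np.diag(rng.uniform(0.2, 0.5, 3)),
                       counts=shape, values=rng.uniform(0, 1, shape),
                       nuclei=list(nuclei))


class TestCubeIO:
    def test_value_ordering(self):
        # x slowest, z fastest in the text stream
        values = np.arange(8).reshape(2, 2, 2).astype(float)
        cube = DensityCube(origin=np.zeros(3), axes=np.eye(3) * 0.5,
                           counts=(2, 2, 2), values=values)
        body = write_cube(cube).splitlines()[6:]
        flat = [float(tok) / BOHR ** 3 for line in body for tok in line.split()]
        np.testing.assert_allclose(flat, values.reshape(-1), rtol=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        cube = random_cube(rng, nuclei=[("O", 8.0, np.array([0.3, 0.2, 0.1]))])
        back = read_cube(write_cube(cube))
        np.testing.assert_allclose(back.values, cube.values, atol=1e-12)
        np.testing.assert_allclose(back.origin, cube.origin, atol=1e-12)
        np.testing.assert_allclose(back.axes, cube.axes, atol=1e-12)
        assert back.counts == cube.counts
        assert back.nuclei[0][0] == "O"

    def test_independent_gaussian_agrees(self):
        # cube written by the fixture generator's analytic field: re-reading
        # reproduces the analytic values exactly
        cube = make_gaussian_cube([[0, 0, 0]], [0.8], [2.0],
                                  origin=(-2, -2, -2), spacing=0.1,
                                  shape=(41, 41, 41))
        back = read_cube(write_cube(cube))
        x = np.array([0.7, -0.3, 0.4])
        idx = tuple(int(round(v)) for v in (x - cube.origin) / 0.1)
        expected = 2.0 / ((2 * math.pi) ** 1.5 * 0.8 ** 3) * math.exp(
            -float(x @ x) / (2 * 0.8 ** 2))
        assert back.values[idx] == pytest.approx(expected, abs=1e-10)

    def test_count_mismatch_raises(self):
        rng = np.random.default_rng(1)
        text = write_cube(random_cube(rng))
        truncated = "\n".join(text.splitlines()[:-1])
        with pytest.raises(CubeFormatError):
            read_cube(truncated)

    def test_angstrom_convention_negative_counts(self):
        rng = np.random.default_rng(2)
        cube = random_cube(rng)
        text = write_cube(cube)
        lines = text.splitlines()
        # flip to Angstrom units: negate counts, rescale vectors and values
        out = lines[:3]
        for i in range(3, 6):
            parts = lines[i].split()
            vec = np.array([float(v) for v in parts[1:4]]) * BOHR
            out.append(f"{-int(parts[0]):5d} {vec[0]:.12E} {vec[1]:.12E} {vec[2]:.12E}")
        body = []
        for line in lines[6:]:
            body.append(" ".join(f"{float(t) / BOHR ** 3:.16E}"
                                 for t in line.split()))
        back = read_cube("\n".join(out + body))
        np.testing.assert_allclose(back.values, cube.values, rtol=1e-12)
        np.testing.assert_allclose(back.axes, cube.axes, rtol=1e-12)


class TestCondense:
    def test_n1_identity(self):
        rng = np.random.default_rng(3)
        cube = random_cube(rng)
        cloud = condense(cube, 1)
        assert len(cloud) == 5 * 4 * 3
        np.testing.assert_allclose(cloud.charges,
                                   -cube.values.reshape(-1) * cube.voxel_volume)
        # positions are the voxel sample points
        expected0 = cube.origin
        np.testing.assert_allclose(cloud.positions[0], expected0, atol=1e-12)

    def test_uniform_blocks(self):
        cube = DensityCube(origin=np.zeros(3), axes=np.eye(3) * 0.5,
                           counts=(4, 4, 4), values=np.full((4, 4, 4), 2.0))
        cloud = condense(cube, 2)
        assert len(cloud) == 8
        np.testing.assert_allclose(cloud.charges, -2.0 * 0.125 * 8)
        assert cloud.total_electron_charge == pytest.approx(-2.0 * 0.5 ** 3 * 64)

    def test_nonuniform_block_weighted_mean(self):
        values = np.zeros((2, 2, 2))
        values[0, 0, 0] = 1.0
        values[1, 1, 1] = 3.0
        cube = DensityCube(origin=np.zeros(3), axes=np.eye(3),
                           counts=(2, 2, 2), values=values)
        cloud = condense(cube, 2)
        assert len(cloud) == 1
        # weighted mean of corners (0,0,0) w1 and (1,1,1) w3
        np.testing.assert_allclose(cloud.positions[0], [0.75, 0.75, 0.75])
        assert cloud.charges[0] == pytest.approx(-4.0)

    def test_edge_remainders_kept(self):
        rng = np.random.default_rng(4)
        cube = random_cube(rng, shape=(5, 5, 5))
        cloud = condense(cube, 2)
        assert len(cloud) == 27    # ceil(5/2)^3
        assert cloud.total_electron_charge == pytest.approx(
            -cube.integrated_charge(), abs=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_charge_conservation(self, n):
        rng = np.random.default_rng(n)
        cube = random_cube(rng, shape=(7, 6, 5))
        cloud = condense(cube, n)
        assert abs(cloud.charges.sum() + cube.integrated_charge()) < 1e-10

    def test_zero_block_geometric_center(self):
        cube = DensityCube(origin=np.zeros(3), axes=np.eye(3),
                           counts=(2, 2, 2), values=np.zeros((2, 2, 2)))
        cloud = condense(cube, 2)
        np.testing.assert_allclose(cloud.positions[0], [0.5, 0.5, 0.5])

    def test_bad_level(self):
        rng = np.random.default_rng(5)
        with pytest.raises(PixkitError):
            condense(random_cube(rng), 0)


class TestPrune:
    def _cloud(self):
        rng = np.random.default_rng(6)
        return condense(random_cube(rng), 1)

    def test_qmin_zero_identity(self):
        cloud = self._cloud()
        pruned = prune(cloud, 0.0)
        assert len(pruned) == len(cloud)

    def test_all_below_threshold(self):
        cloud = self._cloud()
        pruned = prune(cloud, 1e6)
        assert len(pruned) == 0
        assert pruned.pruned_charge == pytest.approx(cloud.charges.sum())

    def test_matches_brute_filter(self):
        cloud = self._cloud()
        q_min = float(np.median(np.abs(cloud.charges)))
        pruned = prune(cloud, q_min)
        expected = [q for q in cloud.charges if abs(q) >= q_min]
        np.testing.assert_allclose(sorted(pruned.charges), sorted(expected))

    def test_nuclei_untouched(self):
        rng = np.random.default_rng(7)
        cloud = condense(random_cube(rng, nuclei=[("C", 6.0, np.zeros(3))]), 1)
        assert prune(cloud, 1e6).nuclei == cloud.nuclei


class TestCoulomb:
    def test_unit_charges_one_angstrom(self):
        a = PixelCloud(charges=[1.0], positions=[[0, 0, 0]], condensation_level=1)
        b = PixelCloud(charges=[-1.0], positions=[[1, 0, 0]], condensation_level=1)
        e = coulomb_energy(a, b, r_min=0.1)
        assert e == pytest.approx(-COULOMB_K)
        assert COULOMB_K == pytest.approx(1389.35, abs=0.01)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(8)
        a = PixelCloud(charges=rng.normal(size=30),
                       positions=rng.uniform(0, 3, (30, 3)),
                       condensation_level=1)
        b = PixelCloud(charges=rng.normal(size=25),
                       positions=rng.uniform(5, 8, (25, 3)),
                       condensation_level=1)
        assert coulomb_energy(a, b) == pytest.approx(coulomb_energy(b, a))

    def test_overlapping_nuclei_rejected(self):
        a = PixelCloud(charges=[], positions=np.empty((0, 3)),
                       condensation_level=1,
                       nuclei=[("C", 6.0, np.zeros(3))])
        b = PixelCloud(charges=[], positions=np.empty((0, 3)),
                       condensation_level=1,
                       nuclei=[("C", 6.0, np.array([0.05, 0, 0]))])
        with pytest.raises(PixkitError, match="not distinct"):
            coulomb_energy(a, b)

    def test_rmin_skip_counted(self):
        a = PixelCloud(charges=[1.0, 1.0], positions=[[0, 0, 0], [3, 0, 0]],
                       condensation_level=1)
        b = PixelCloud(charges=[1.0], positions=[[0.2, 0, 0]],
                       condensation_level=1)
        e, clash = coulomb_energy(a, b, r_min=0.5, return_clashes=True)
        assert clash.skipped_pairs == 1
        assert clash.min_distance == pytest.approx(0.2)
        assert e == pytest.approx(COULOMB_K / 2.8)

    def test_fft_equals_direct(self):
        """Dual route: lattice-aligned clouds through the FFT path must equal
        the direct double sum bit-for-bit (within float rounding)."""
        rng = np.random.default_rng(9)
        h = 0.25
        step = np.diag([h, h, h])
        ia = np.unique(rng.integers(0, 9, (250, 3)), axis=0)
        ib = np.unique(rng.integers(4, 14, (250, 3)), axis=0)
        qa = rng.normal(size=len(ia))
        qb = rng.normal(size=len(ib))
        oa = np.zeros(3)
        ob = np.array([3 * h, -2 * h, h])
        a = PixelCloud(qa, oa + ia * h, 1,
                       lattice=LatticeInfo(oa, step, ia))
        b_fft = PixelCloud(qb, ob + ib * h, 1,
                           lattice=LatticeInfo(ob, step, ib))
        b_dir = PixelCloud(qb, ob + ib * h, 1)
        e_fft, c_fft = coulomb_energy(a, b_fft, r_min=0.4, return_clashes=True)
        e_dir, c_dir = coulomb_energy(a, b_dir, r_min=0.4, return_clashes=True)
        assert e_fft == pytest.approx(e_dir, rel=1e-12)
        assert c_fft.skipped_pairs == c_dir.skipped_pairs

    def test_condensation_level_consistency(self):
        """Well-separated clouds: energies at n = 1..4 agree within 1%."""
        s, R = 0.8, 16.0   # separation = 20 voxel lengths
        h = s / 6.0
        half = 3.2
        npts = int(round(2 * half / h)) + 1
        cubes = []
        for cx in (0.0, R):
            cubes.append(make_gaussian_cube(
                [[cx, 0, 0]], [s], [1.0], origin=(cx - half, -half, -half),
                spacing=h, shape=(npts,) * 3))
        energies = []
        for n in (1, 2, 3, 4):
            a = condense(cubes[0], n)
            b = condense(cubes[1], n)
            if n >= 2:
                a, b = prune(a, 1e-9), prune(b, 1e-9)
            energies.append(coulomb_energy(a, b, r_min=0.05))
        ref = energies[0]
        for e in energies[1:]:
            assert abs(e - ref) / abs(ref) < 0.01

    def test_monopole_limit(self):
        s = 0.4
        h = s / 6.0
        half = 1.8
        npts = int(round(2 * half / h)) + 1
        R = 8.0     # > 10 x radius of gyration (sqrt(3)*0.4 = 0.69)
        clouds = []
        for cx in (0.0, R):
            cube = make_gaussian_cube([[cx, 0, 0]], [s], [1.0],
                                      origin=(cx - half, -half, -half),
                                      spacing=h, shape=(npts,) * 3)
            clouds.append(prune(condense(cube, 3), 1e-10))
        e = coulomb_energy(clouds[0], clouds[1], r_min=0.05)
        assert abs(e - COULOMB_K / R) / (COULOMB_K / R) < 0.001

    def test_neutral_decay_faster_than_1_over_r(self):
        """Two neutral clouds (blob + opposite nucleus): E falls off faster
        than monopole-monopole."""
        s = 0.5
        h = s / 6.0
        half = 2.25
        npts = int(round(2 * half / h)) + 1

        def cloud_at(cx):
            cube = make_gaussian_cube(
                [[cx, 0, 0]], [s], [1.0], origin=(cx - half, -half, -half),
                spacing=h, shape=(npts,) * 3,
                nuclei=[("H", 1.0, np.array([cx + h / 2, h / 2, h / 2]))])
            return prune(condense(cube, 2), 1e-10)

        a = cloud_at(0.0)
        e1 = abs(coulomb_energy(a, cloud_at(6.0), r_min=0.05))
        e2 = abs(coulomb_energy(a, cloud_at(12.0), r_min=0.05))
        assert e2 < e1 / 2.0   # strictly faster than 1/R


class TestAnalyticOracle:
    def test_single_gaussian_normalized(self):
        cube = make_gaussian_cube([[0, 0, 0]], [0.7], [1.0],
                                  origin=(-4.0, -4.0, -4.0), spacing=0.1,
                                  shape=(81, 81, 81))
        assert cube.integrated_charge() == pytest.approx(1.0, abs=1e-6)

    def test_under_resolved_grid_rejected(self):
        with pytest.raises(PixkitError, match="resolve"):
            make_gaussian_cube([[0, 0, 0]], [0.3], [1.0],
                               origin=(-2, -2, -2), spacing=0.1,
                               shape=(41, 41, 41))

    def test_far_apart_is_monopole(self):
        e = analytic_coulomb([(-1.0, 0.5, (0, 0, 0))],
                             [(-1.0, 0.5, (50, 0, 0))])
        assert e == pytest.approx(COULOMB_K / 50, rel=1e-4)

    def test_matches_quadrature(self):
        """Closed form vs dense-grid numerical quadrature for one blob pair."""
        sa, sb, R = 0.6, 0.9, 2.5
        exact = analytic_coulomb([(-1.0, sa, (0, 0, 0))],
                                 [(-1.0, sb, (R, 0, 0))])
        # quadrature: integrate rho_a(r) * phi_b(r), phi_b = K erf(d/sqrt(2)sb)/d
        from scipy.special import erf
        h = 0.06
        g = np.arange(-3.0, 3.0 + h / 2, h)
        gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
        rho = 1.0 / ((2 * math.pi) ** 1.5 * sa ** 3) * np.exp(
            -(gx ** 2 + gy ** 2 + gz ** 2) / (2 * sa ** 2))
        d = np.sqrt((gx - R) ** 2 + gy ** 2 + gz ** 2)
        phi = -COULOMB_K * erf(d / (math.sqrt(2) * sb)) / d
        quad = float((rho * phi).sum() * h ** 3) * -1.0
        assert exact == pytest.approx(quad, abs=abs(exact) * 1e-4)
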