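import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from chirsep.atom_density import (CUTOFF, SIGMA, SNAPSHOT_DIM, TRAJECTORY_DIM,
                                  RadialGrid, a2_profile, a3_profile,
                                  aggregate_trajectory, featurize_frameset,
                                  gaussian, snapshot_representation)
from chirsep.electronic_weights import CHANNELS
from chirsep.structures_io import FrameSet, StructuralError

GRID = RadialGrid()


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain loops, no shared code path)
# ---------------------------------------------------------------------------

def brute_a2(i, coords, w, centers, cutoff=CUTOFF):
    out = np.zeros(len(centers))
    for j in range(len(coords)):
        if j == i:
            continue
        d = np.linalg.norm(coords[j] - coords[i])
        if d > cutoff:
            continue
        for b, r in enumerate(centers):
            out[b] += w[i, j] * np.exp(-(d - r) ** 2 / (2 * SIGMA ** 2)) \
                / (SIGMA * np.sqrt(2 * np.pi))
    return out


def brute_a3(i, coords, w, centers, angle_fn, cutoff=CUTOFF):
    out = np.zeros(len(centers))
    n = len(coords)
    for j in range(n):
        for k in range(n):
            if i in (j, k) or j == k:
                continue
            dij = np.linalg.norm(coords[j] - coords[i])
            dik = np.linalg.norm(coords[k] - coords[i])
            if dij > cutoff or dik > cutoff:
                continue
            u = (coords[j] - coords[i]) / dij
            v = (coords[k] - coords[i]) / dik
            cos_t = np.clip(u @ v, -1.0, 1.0)
            phi = cos_t if angle_fn == "cos" else np.sqrt(1.0 - cos_t ** 2)
            wprod = w[i, j] * w[i, k] * w[j, k]
            for b, r in enumerate(centers):
                out[b] += wprod * phi \
                    * np.exp(-(dij - r) ** 2 / (2 * SIGMA ** 2)) \
                    / (SIGMA * np.sqrt(2 * np.pi))
    return out


class TestGaussian:
    def test_peak_value(self):
        expected = 1.0 / (0.0825 * np.sqrt(2 * np.pi))  # ~4.836
        assert gaussian(2.0, np.array([2.0]))[0] == pytest.approx(expected)
        assert expected == pytest.approx(4.836, abs=5e-3)

    def test_far_tail_vanishes(self):
        assert gaussian(2.0, np.array([7.9]))[0] < 1e-300

    def test_unit_integral(self):
        val, _ = quad(lambda r: gaussian(3.0, np.array([r]))[0], -np.inf,
                      np.inf)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestRadialGrid:
    def test_160_bins_inclusive_endpoints(self):
        c = GRID.centers
        assert len(c) == 160
        assert c[0] == 0.7 and c[-1] == 8.0
        assert np.allclose(np.diff(c), c[1] - c[0])


class TestProfiles:
    coords = np.array([[0.0, 0.0, 0.0], [1.1, 0.4, -0.2], [-0.9, 1.3, 0.5],
                       [0.3, -1.2, 1.6]])

    def _weights(self, seed=0):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.1, 2.0, size=(4, 4))
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        return w

    def test_a2_no_neighbours(self):
        coords = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        w = np.ones((2, 2))
        assert np.all(a2_profile(0, coords, w, GRID) == 0)

    def test_a2_single_neighbour_peak_and_norm(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        w = np.ones((2, 2))
        prof = a2_profile(0, coords, w, GRID)
        assert GRID.centers[np.argmax(prof)] == pytest.approx(3.0, abs=GRID.spacing)
        # Riemann sum over the grid approximates the unit Gaussian mass
        assert prof.sum() * GRID.spacing == pytest.approx(1.0, abs=1e-6)

    def test_a2_linearity_in_neighbours(self):
        one = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        two = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 3.0, 0.0]])
        w1 = np.ones((2, 2))
        w2 = np.ones((3, 3))
        np.testing.assert_allclose(a2_profile(0, two, w2, GRID),
                                   2 * a2_profile(0, one, w1, GRID))

    def test_a3_fewer_than_two_neighbours(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        assert np.all(a3_profile(0, coords, np.ones((2, 2)), "cos", GRID) == 0)

    def test_a3_collinear_sine_vanishes(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [-2.0, 0.0, 0.0]])
        prof = a3_profile(0, coords, np.ones((3, 3)), "sin", GRID)
        np.testing.assert_allclose(prof, 0.0, atol=1e-12)

    @pytest.mark.parametrize("angle_fn", ["cos", "sin"])
    def test_a3_matches_brute_force(self, angle_fn):
        w = self._weights()
        for i in range(4):
            np.testing.assert_allclose(
                a3_profile(i, self.coords, w, angle_fn, GRID),
                brute_a3(i, self.coords, w, GRID.centers, angle_fn),
                atol=1e-10)

    def test_a2_matches_brute_force(self):
        w = self._weights(1)
        for i in range(4):
            np.testing.assert_allclose(
                a2_profile(i, self.coords, w, GRID),
                brute_a2(i, self.coords, w, GRID.centers), atol=1e-10)

    def test_weight_scaling_laws(self):
        """A2 is linear in the weights; A3 is cubic."""
        w = self._weights(2)
        a2 = a2_profile(0, self.coords, w, GRID)
        a3 = a3_profile(0, self.coords, w, "cos", GRID)
        np.testing.assert_allclose(a2_profile(0, self.coords, 3 * w, GRID),
                                   3 * a2, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            a3_profile(0, self.coords, 3 * w, "cos", GRID), 27 * a3,
            rtol=1e-10, atol=1e-12)


class TestSnapshotRepresentation:
    def test_shape_and_centres(self, tiny_complex, provider):
        rep = snapshot_representation(tiny_complex, provider=provider)
        # 4 heavy atoms (C, O, N + O) -- hydrogens are not centres
        n_heavy = sum(1 for e in tiny_complex.elements if e != "H")
        assert rep.values.shape == (n_heavy, SNAPSHOT_DIM)
        assert SNAPSHOT_DIM == 7 + 7 * 160 + 14 * 160 == 3367

    def test_isometry_invariance(self, tiny_complex, provider):
        ref = snapshot_representation(tiny_complex, provider=provider).values
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7])
        for coords in (rot.apply(tiny_complex.coords) + [3.0, -1.0, 2.0],
                       tiny_complex.coords @ np.diag([-1.0, 1.0, 1.0])):
            other = snapshot_representation(tiny_complex, coords,
                                            provider=provider).values
            np.testing.assert_allclose(other, ref, atol=1e-9)

    def test_matches_brute_force_everywhere(self, tiny_complex, provider):
        """Full per-atom vector equals the naive double/triple-loop reference."""
        rep = snapshot_representation(tiny_complex, provider=provider)
        ch = provider.weight_channels(tiny_complex)
        coords = tiny_complex.coords
        for row, i in enumerate(rep.center_indices):
            vec = rep.values[row]
            for c_idx, c in enumerate(CHANNELS):
                seg = vec[7 + c_idx * 160: 7 + (c_idx + 1) * 160]
                np.testing.assert_allclose(
                    seg, brute_a2(i, coords, ch.matrix(c), GRID.centers),
                    atol=1e-10)
            for f_idx, fn in enumerate(("cos", "sin")):
                for c_idx, c in enumerate(CHANNELS):
                    off = 7 + 7 * 160 + (f_idx * 7 + c_idx) * 160
                    np.testing.assert_allclose(
                        vec[off: off + 160],
                        brute_a3(i, coords, ch.matrix(c), GRID.centers, fn),
                        atol=1e-10)


class TestTrajectoryAggregation:
    def _reps(self, tiny_complex, provider, frames):
        return [snapshot_representation(tiny_complex, f, provider)
                for f in frames]

    def test_identical_frames_zero_std(self, tiny_complex, provider):
        reps = self._reps(tiny_complex, provider, [tiny_complex.coords] * 3)
        traj = aggregate_trajectory(reps)
        assert traj.values.shape[1] == TRAJECTORY_DIM == 6734
        # population std of bit-identical frames: zero to rounding of the mean
        np.testing.assert_allclose(traj.values[:, SNAPSHOT_DIM:], 0.0,
                                   atol=1e-8)

    def test_two_frame_mean_std(self, tiny_complex, provider):
        rng = np.random.default_rng(3)
        frames = [tiny_complex.coords + rng.normal(scale=0.1, size=(5, 3))
                  for _ in range(2)]
        reps = self._reps(tiny_complex, provider, frames)
        traj = aggregate_trajectory(reps)
        a, b = reps[0].values, reps[1].values
        np.testing.assert_allclose(traj.values[:, :SNAPSHOT_DIM], (a + b) / 2)
        np.testing.assert_allclose(traj.values[:, SNAPSHOT_DIM:],
                                   np.abs(a - b) / 2, atol=1e-12)

    def test_frame_order_irrelevant(self, tiny_complex, provider):
        rng = np.random.default_rng(4)
        frames = [tiny_complex.coords + rng.normal(scale=0.1, size=(5, 3))
                  for _ in range(4)]
        reps = self._reps(tiny_complex, provider, frames)
        t1 = aggregate_trajectory(reps)
        t2 = aggregate_trajectory(reps[::-1])
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-12)

    def test_static_a1_fields_have_zero_std(self, tiny_complex, provider):
        rng = np.random.default_rng(5)
        frames = FrameSet(tiny_complex,
                          [tiny_complex.coords + rng.normal(scale=0.1,
                                                            size=(5, 3))
                           for _ in range(3)])
        traj = featurize_frameset(frames, provider)
        # nuclear charge, group, period never vary across frames
        assert np.all(traj.values[:, SNAPSHOT_DIM:SNAPSHOT_DIM + 3] == 0)

    def test_single_frame_rejected(self, tiny_complex, provider):
        reps = self._reps(tiny_complex, provider, [tiny_complex.coords])
        with pytest.raises(StructuralError):
            aggregate_trajectory(reps)
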