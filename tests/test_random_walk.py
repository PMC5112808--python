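import math

import numpy as np
import pytest

from flrw import ImageGrid, WalkConfig, build_laplacian, edge_weight, generate_phantom, segment, solve_walker
from flrw.boosted_classifier import ProbabilityMap
from flrw.phantom import PhantomSpec
from flrw.random_walk import _lattice_offsets, segment_with_result
from flrw.seed_selection import SeedMask, auto_seeds


def make_seed_mask(shape, liver_coords, background_coords):
    states = np.full(shape, -1, dtype=np.int8)
    for c in liver_coords:
        states[c] = 1
    for c in background_coords:
        states[c] = 0
    return SeedMask(states=states)


def oracle_dirichlet(T, p, seeds, config):
    """Independent dense assembly + solve over the 4-connected lattice."""
    H, W = T.shape
    n = H * W
    Wm = np.zeros((n, n))
    for i in range(H):
        for j in range(W):
            for di, dj in ((0, 1), (1, 0)):
                ii, jj = i + di, j + dj
                if ii < H and jj < W:
                    w = math.exp(
                        -config.beta
                        * (
                            (1 - config.alpha) * (T[i, j] - T[ii, jj]) ** 2
                            + config.alpha * (p[i, j] - p[ii, jj]) ** 2
                        )
                    )
                    w = max(w, config.weight_floor)
                    a, b = i * W + j, ii * W + jj
                    Wm[a, b] = Wm[b, a] = w
    L = np.diag(Wm.sum(axis=1)) - Wm
    flat = seeds.states.ravel()
    seeded = flat >= 0
    x = np.zeros(n)
    x[seeded] = (flat[seeded] == 1).astype(float)
    free = ~seeded
    x[free] = np.linalg.solve(L[np.ix_(free, free)], -L[np.ix_(free, seeded)] @ x[seeded])
    return x.reshape(H, W)


def oracle_absorbing_chain(T, p, seeds, config):
    """Potentials as absorption probabilities of the seeded Markov chain."""
    H, W = T.shape
    n = H * W
    Wm = np.zeros((n, n))
    for i in range(H):
        for j in range(W):
            for di, dj in ((0, 1), (1, 0)):
                ii, jj = i + di, j + dj
                if ii < H and jj < W:
                    w = max(
                        math.exp(
                            -config.beta
                            * (
                                (1 - config.alpha) * (T[i, j] - T[ii, jj]) ** 2
                                + config.alpha * (p[i, j] - p[ii, jj]) ** 2
                            )
                        ),
                        config.weight_floor,
                    )
                    a, b = i * W + j, ii * W + jj
                    Wm[a, b] = Wm[b, a] = w
    P = Wm / Wm.sum(axis=1, keepdims=True)
    flat = seeds.states.ravel()
    free = flat < 0
    Q = P[np.ix_(free, ~free)]  # transitions into absorbing states
    R = P[np.ix_(free, free)]
    absorb_liver = (flat[~free] == 1).astype(float)
    h = np.linalg.solve(np.eye(free.sum()) - R, Q @ absorb_liver)
    x = np.zeros(n)
    x[~free] = absorb_liver
    x[free] = h
    return x.reshape(H, W)


class TestEdgeWeight:
    def test_identical_nodes_weight_one(self):
        assert edge_weight(0.3, 0.3, 0.7, 0.7, WalkConfig()) == pytest.approx(1.0)

    def test_closed_form_value(self):
        cfg = WalkConfig(alpha=0.5, beta=150.0)
        w = edge_weight(0.0, 0.1, 0.0, 0.2, cfg)
        assert w == pytest.approx(math.exp(-3.75), rel=1e-12)

    def test_alpha_zero_ignores_probability(self, rng):
        cfg = WalkConfig(alpha=0.0, beta=90.0)
        t1, t2 = 0.2, 0.5
        for p1, p2 in rng.random((5, 2)):
            assert edge_weight(t1, t2, p1, p2, cfg) == pytest.approx(
                math.exp(-90.0 * (t1 - t2) ** 2)
            )

    def test_floor_applied(self):
        cfg = WalkConfig(alpha=0.0, beta=150.0, weight_floor=1e-6)
        assert edge_weight(0.0, 1.0, 0, 0, cfg) == 1e-6


class TestLaplacian:
    def test_row_sums_zero(self, rng):
        T = rng.random((6, 6))
        seeds = make_seed_mask((6, 6), [(0, 0)], [(5, 5)])
        system = build_laplacian(T, None, seeds, WalkConfig(alpha=0.0))
        rows = np.asarray(abs(system["L"]).sum(axis=1)).ravel()
        np.testing.assert_allclose(
            np.asarray(system["L"].sum(axis=1)).ravel(), 0.0, atol=1e-12
        )
        assert rows.max() > 0

    def test_three_node_chain_midpoint(self):
        T = np.zeros((3, 1))
        seeds = make_seed_mask((3, 1), [(0, 0)], [(2, 0)])
        system = build_laplacian(T, None, seeds, WalkConfig(alpha=0.0))
        res = solve_walker(system)
        assert res.potentials[1, 0] == pytest.approx(0.5)

    def test_reduced_solve_equals_dense_oracle(self, rng):
        T = rng.random((5, 5))
        p = rng.random((5, 5))
        cfg = WalkConfig(alpha=0.4, beta=40.0)
        seeds = make_seed_mask((5, 5), [(0, 0), (1, 2)], [(4, 4), (3, 0)])
        res = solve_walker(build_laplacian(T, p, seeds, cfg))
        np.testing.assert_allclose(res.potentials, oracle_dirichlet(T, p, seeds, cfg), atol=1e-8)


class TestSolveWalker:
    def test_markov_chain_oracle_small_grids(self, rng):
        for shape in [(3, 4), (4, 4), (5, 3)]:
            T = rng.random(shape)
            p = rng.random(shape)
            cfg = WalkConfig(alpha=0.5, beta=25.0)
            seeds = make_seed_mask(shape, [(0, 0)], [(shape[0] - 1, shape[1] - 1)])
            res = solve_walker(build_laplacian(T, p, seeds, cfg))
            np.testing.assert_allclose(
                res.potentials, oracle_absorbing_chain(T, p, seeds, cfg), atol=1e-6
            )

    def test_maximum_principle(self, rng):
        T = rng.random((8, 8))
        seeds = make_seed_mask((8, 8), [(0, 0)], [(7, 7)])
        res = solve_walker(build_laplacian(T, None, seeds, WalkConfig(alpha=0.0, beta=80)))
        assert res.potentials.min() >= 0.0 and res.potentials.max() <= 1.0
        assert res.potentials[0, 0] == 1.0 and res.potentials[7, 7] == 0.0

    def test_solution_is_unique_energy_minimizer(self, rng):
        T = rng.random((4, 4))
        seeds = make_seed_mask((4, 4), [(0, 0)], [(3, 3)])
        system = build_laplacian(T, None, seeds, WalkConfig(alpha=0.0, beta=30))
        res = solve_walker(system)
        L = system["L"].toarray()
        x = res.potentials.ravel().copy()
        base = x @ L @ x
        free = np.flatnonzero(system["unseeded"])
        for k in free[:5]:
            for eps in (0.01, -0.02):
                y = x.copy()
                y[k] += eps
                assert y @ L @ y > base

    def test_potentials_invariant_under_weight_scaling(self, rng):
        T = rng.random((5, 5))
        seeds = make_seed_mask((5, 5), [(1, 1)], [(4, 4)])
        system = build_laplacian(T, None, seeds, WalkConfig(alpha=0.0, beta=20))
        res = solve_walker(system)
        scaled = dict(system)
        scaled["L"] = system["L"] * 7.0
        scaled["L_uu"] = system["L_uu"] * 7.0
        scaled["rhs"] = system["rhs"] * 7.0
        res2 = solve_walker(scaled)
        np.testing.assert_allclose(res.potentials, res2.potentials, atol=1e-10)

    def test_beta_sharpens_transition_band(self):
        image, _ = generate_phantom(PhantomSpec(shape=(64, 64), liver_radius=16.0, confuser_radius=8.0, rng_seed=9))
        seeds = auto_seeds(image)
        from flrw.image_io import rescale_intensity

        T = rescale_intensity(image, (0, 1))
        counts = []
        for beta in (10.0, 150.0):
            res = solve_walker(build_laplacian(T, None, seeds, WalkConfig(alpha=0.0, beta=beta)))
            counts.append(int((np.abs(res.potentials - 0.5) < 0.1).sum()))
        assert counts[1] <= counts[0]


class TestSegment:
    def test_alpha_one_with_ground_truth_probability(self):
        image, gt = generate_phantom(PhantomSpec(shape=(64, 64), liver_radius=16.0, confuser_radius=8.0, rng_seed=2))
        prob = ProbabilityMap(values=gt.labels.astype(float), spacing=image.spacing)
        seeds = auto_seeds(image)
        out = segment(image, prob, seeds, WalkConfig(alpha=1.0, beta=150.0))
        agreement = (out.labels == gt.labels).mean()
        assert agreement > 0.995

    def test_alpha_zero_matches_probability_free_path(self, rng):
        image, _ = generate_phantom(PhantomSpec(shape=(64, 64), liver_radius=16.0, confuser_radius=8.0, rng_seed=6))
        seeds = auto_seeds(image)
        cfg = WalkConfig(alpha=0.0, beta=150.0)
        with_p = segment(image, ProbabilityMap(values=rng.random(image.shape)), seeds, cfg)
        without_p = segment(image, None, seeds, cfg)
        np.testing.assert_array_equal(with_p.labels, without_p.labels)

    def test_small_3d_volume(self, rng):
        vol = np.full((4, 8, 8), 70.0)
        vol[1:3, 2:6, 2:6] = 140.0
        vol += rng.normal(0, 1.0, size=vol.shape)
        grid = ImageGrid(vol, spacing=(2.0, 1.0, 1.0))
        states = np.full(vol.shape, -1, dtype=np.int8)
        states[2, 4, 4] = 1
        states[0, 0, 0] = 0
        mask, res = segment_with_result(grid, None, SeedMask(states), WalkConfig(alpha=0.0, beta=150))
        assert mask.labels[1:3, 3:5, 3:5].all()
        assert not mask.labels[0].any()
        assert res.potentials.min() >= 0 and res.potentials.max() <= 1

    def test_connectivity_offsets(self):
        assert set(_lattice_offsets(2, 4)) == {(0, 1), (1, 0)}
        assert set(_lattice_offsets(2, 8)) == {(0, 1), (1, 0), (1, 1), (1, -1)}
        assert len(_lattice_offsets(3, 6)) == 3
        assert len(_lattice_offsets(3, 26)) == 13
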