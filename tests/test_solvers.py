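"""Shrinkage, the Split Bregman sub-steps, and the two reconstruction drivers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.fft import fft2, ifft2

import nltvmri as nv
from nltvmri.graph import nl_gradient
from nltvmri.solvers import (
    SolverState,
    _nltv_rhs,
    _nltv_system,
    b_update,
    bregman_refresh,
    d_update,
    objective,
    shrink,
    u_update,
)

from conftest import random_symmetric_graph


def _random_state(rng, size=16, mu=10.0, gamma=1.0, mask_ratio=0.4):
    g = random_symmetric_graph((size, size), rng)
    mask = nv.make_vardens_mask(size, mask_ratio, 6.0, 0.05, 3)
    v = nv.forward_measure(rng.random((size, size)), mask)
    params = nv.SolverParams(mu=mu, gamma=gamma, gs_sweeps=1)
    state = SolverState(
        u=rng.standard_normal((size, size)),
        d=rng.standard_normal(g.nnz),
        b=rng.standard_normal(g.nnz),
        v_k=v,
        graph=g,
    )
    return state, params


def quadratic_subproblem_objective(state, params):
    """gamma/2 ||d - grad u - b||^2 + mu/2 ||K u - v^k||^2 (u-subproblem)."""
    r = state.d - nl_gradient(state.u, state.graph) - state.b
    ku = state.v_k.mask.selected * fft2(state.u, norm="ortho")
    return 0.5 * params.gamma * float(r @ r) + 0.5 * params.mu * float(
        np.sum(np.abs(ku - state.v_k.values) ** 2)
    )


class TestShrink:
    @pytest.mark.parametrize(
        "x,lam,expected",
        [(2.0, 0.5, 1.5), (0.3, 0.5, 0.0), (-2.0, 0.5, -1.5), (0.0, 0.5, 0.0)],
    )
    def test_closed_form(self, x, lam, expected):
        assert shrink(x, lam) == pytest.approx(expected)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            shrink(1.0, -0.1)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        x=st.floats(-1e6, 1e6, allow_nan=False),
        lam=st.floats(0, 1e6, allow_nan=False),
    )
    def test_properties(self, x, lam):
        out = shrink(x, lam)
        assert abs(out) == pytest.approx(max(abs(x) - lam, 0.0))
        assert out * x >= 0  # sign preserved (or zero)


class TestUUpdate:
    def test_single_sweep_decreases_quadratic(self, rng):
        state, params = _random_state(rng)
        before = quadratic_subproblem_objective(state, params)
        state.u = u_update(state, params)
        after = quadratic_subproblem_objective(state, params)
        assert after <= before

    def test_sweeps_monotone(self, rng):
        state, params = _random_state(rng)
        values = [quadratic_subproblem_objective(state, params)]
        for _ in range(10):
            state.u = u_update(state, params)
            values.append(quadratic_subproblem_objective(state, params))
        assert all(b <= a + 1e-12 for a, b in zip(values, values[1:]))

    def test_fixed_point_satisfies_normal_equations(self, rng):
        state, params = _random_state(rng)
        many = nv.SolverParams(mu=params.mu, gamma=params.gamma, gs_sweeps=400)
        u = u_update(state, many)
        state.u = u
        system = _nltv_system(state, many)
        res = system.residual(u, _nltv_rhs(state, many))
        assert np.abs(res).max() <= 1e-6

    def test_jacobi_mode_converges_to_same_fixed_point(self, rng):
        state, params = _random_state(rng)
        gs = nv.SolverParams(mu=10.0, gamma=1.0, gs_sweeps=400)
        jc = nv.SolverParams(
            mu=10.0, gamma=1.0, gs_sweeps=4000, sweep_mode="jacobi"
        )
        u_gs = u_update(state, gs)
        u_jc = u_update(state, jc)
        np.testing.assert_allclose(u_jc, u_gs, atol=1e-5)

    def test_full_sampling_small_gamma_gives_zero_fill(self, rng):
        size = 16
        g = random_symmetric_graph((size, size), rng)
        mask = nv.make_vardens_mask(size, 1.0, 6.0, 0.0, 0)
        v = nv.forward_measure(nv.make_phantom("piecewise", size, 0), mask)
        state = SolverState(
            u=np.zeros((size, size)), d=g.new_field(), b=g.new_field(),
            v_k=v, graph=g,
        )
        params = nv.SolverParams(mu=100.0, gamma=1e-8, gs_sweeps=50)
        u = u_update(state, params)
        np.testing.assert_allclose(u, nv.zero_fill_recon(v), atol=1e-8)


class TestDUpdate:
    def test_zero_argument(self, rng):
        state, params = _random_state(rng)
        state.u = np.full(state.graph.shape, 3.0)
        state.b = state.graph.new_field()
        np.testing.assert_array_equal(d_update(state, params), 0.0)

    def test_group_norm_equals_scalar_shrink(self, rng):
        state, params = _random_state(rng, gamma=2.5)
        g = state.graph
        d = d_update(state, params)
        s = nl_gradient(state.u, g) + state.b
        n_s = np.sqrt(np.bincount(g.rows, weights=s * s, minlength=g.n_pixels))
        n_d = np.sqrt(np.bincount(g.rows, weights=d * d, minlength=g.n_pixels))
        np.testing.assert_allclose(
            n_d, np.maximum(n_s - 1.0 / params.gamma, 0.0), atol=1e-12
        )

    def test_single_neighbor_reduces_to_scalar_shrink(self):
        from scipy import sparse
        from nltvmri.graph import _graph_from_csr

        # two pixels joined by one symmetric unit-weight edge
        W = sparse.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        g = _graph_from_csr(W, (1, 2))
        sel = np.ones((1, 2), dtype=bool)
        from nltvmri.kspace import SamplingMask, KSpaceMeasurement

        mask = SamplingMask(sel, 1.0, 0)
        v = KSpaceMeasurement(np.zeros((1, 2), complex), mask)
        u = np.array([[0.0, 0.9]])
        b = np.array([0.4, 0.0])
        state = SolverState(u=u, d=g.new_field(), b=b, v_k=v, graph=g)
        params = nv.SolverParams(mu=1.0, gamma=2.0)
        d = d_update(state, params)
        # pixel 0's only edge: s = (0.9 - 0) + 0.4 = 1.3
        assert d[0] == pytest.approx(shrink(1.3, 0.5))


class TestBUpdate:
    def test_matches_edge_loop_oracle(self, rng):
        state, _ = _random_state(rng, size=8)
        g = state.graph
        out = b_update(state)
        uf = state.u.ravel()
        expected = np.empty(g.nnz)
        for p in range(g.nnz):
            i, j = g.rows[p], g.indices[p]
            expected[p] = (
                state.b[p] + np.sqrt(g.weights[p]) * (uf[j] - uf[i]) - state.d[p]
            )
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_zero_inputs(self, rng):
        state, _ = _random_state(rng, size=8)
        state.u = np.zeros(state.graph.shape)
        state.d = state.graph.new_field()
        state.b = state.graph.new_field()
        np.testing.assert_array_equal(b_update(state), 0.0)

    def test_b_absorbed_exactly(self, rng):
        # d = grad u + b absorbs b entirely: b <- b + grad u - d = 0
        state, _ = _random_state(rng, size=8)
        state.d = nl_gradient(state.u, state.graph) + state.b
        np.testing.assert_allclose(b_update(state), 0.0, atol=1e-14)


class TestBregmanRefresh:
    def test_consistent_iterate_leaves_v_unchanged(self, rng):
        state, _ = _random_state(rng, size=8)
        v_obs = state.v_k
        sel = v_obs.mask.selected
        # make v_k equal to K u so that v + v_k - K u = v
        ku = np.where(sel, fft2(state.u, norm="ortho"), 0)
        import dataclasses

        state.v_k = dataclasses.replace(v_obs, values=ku)
        out = bregman_refresh(state, v_obs)
        np.testing.assert_allclose(out.values, v_obs.values + ku - ku + 0 * 1j, atol=1e-14)

    def test_first_refresh_with_zero_u(self, rng):
        state, _ = _random_state(rng, size=8)
        state.u = np.zeros(state.graph.shape)
        out = bregman_refresh(state, state.v_k)
        np.testing.assert_allclose(out.values, 2.0 * state.v_k.values, atol=1e-14)

    def test_masked_update_matches_dense_oracle(self, rng):
        state, _ = _random_state(rng, size=8)
        v_obs = state.v_k
        sel = v_obs.mask.selected
        out = bregman_refresh(state, v_obs)
        dense = state.v_k.values + v_obs.values - fft2(state.u, norm="ortho")
        np.testing.assert_allclose(out.values[sel], dense[sel], atol=1e-12)
        assert np.all(out.values[~sel] == 0)


class TestObjective:
    def test_zero_state(self, rng):
        g = random_symmetric_graph((8, 8), rng)
        sel = np.ones((8, 8), dtype=bool)
        from nltvmri.kspace import SamplingMask, KSpaceMeasurement

        v = KSpaceMeasurement(np.zeros((8, 8), complex), SamplingMask(sel, 1.0, 0))
        state = SolverState(
            u=np.zeros((8, 8)), d=g.new_field(), b=g.new_field(), v_k=v, graph=g
        )
        assert objective(state, nv.SolverParams()) == 0.0

    def test_l1_homogeneity(self, rng):
        state, params = _random_state(rng, size=8)
        state.u = np.zeros(state.graph.shape)
        state.b = state.graph.new_field()
        import dataclasses

        state.v_k = dataclasses.replace(
            state.v_k, values=np.zeros_like(state.v_k.values)
        )
        params = nv.SolverParams(mu=params.mu, gamma=1e-12)
        obj1 = objective(state, params)
        state.d = 2.0 * state.d
        obj2 = objective(state, params)
        assert obj2 == pytest.approx(2.0 * obj1, rel=1e-6)

    def test_matches_dense_oracle(self, rng):
        state, params = _random_state(rng, size=8)
        g = state.graph
        uf = state.u.ravel()
        # explicit per-pixel/per-edge evaluation
        l1 = 0.0
        for i in range(g.n_pixels):
            sl = slice(g.indptr[i], g.indptr[i + 1])
            l1 += np.sqrt(np.sum(state.d[sl] ** 2))
        quad = 0.0
        for p in range(g.nnz):
            i, j = g.rows[p], g.indices[p]
            grad = np.sqrt(g.weights[p]) * (uf[j] - uf[i])
            quad += (state.d[p] - grad - state.b[p]) ** 2
        ku = state.v_k.mask.selected * fft2(state.u, norm="ortho")
        fid = np.sum(np.abs(ku - state.v_k.values) ** 2)
        expected = l1 + 0.5 * params.gamma * quad + 0.5 * params.mu * fid
        assert objective(state, params) == pytest.approx(expected, rel=1e-12)


class TestReconstruction:
    def test_noiseless_full_mask_nltv(self):
        ref = nv.make_phantom("textured", 32, 0)
        mask = nv.make_vardens_mask(32, 1.0, 6.0, 0.0, 1)
        m = nv.forward_measure(ref, mask)
        g = nv.compute_weights(nv.zero_fill_recon(m))
        u, hist = nv.reconstruct_nltv(m, g, nv.SolverParams())
        assert nv.relative_error(ref, u) < 1.0
        assert len(hist) >= 1

    def test_noiseless_full_mask_tv(self):
        ref = nv.make_phantom("textured", 32, 0)
        mask = nv.make_vardens_mask(32, 1.0, 6.0, 0.0, 1)
        m = nv.forward_measure(ref, mask)
        u, _ = nv.reconstruct_tv(m, nv.TVParams())
        assert nv.relative_error(ref, u) < 1.0

    def test_deterministic(self):
        ref = nv.make_phantom("textured", 24, 0)
        mask = nv.make_vardens_mask(24, 0.4, 6.0, 0.05, 2)
        m = nv.add_noise(nv.forward_measure(ref, mask), "gaussian", 0.01, 3)
        g = nv.compute_weights(nv.zero_fill_recon(m), patch_radius=1, search_radius=2)
        p = nv.SolverParams(n_outer=5)
        u1, _ = nv.reconstruct_nltv(m, g, p)
        u2, _ = nv.reconstruct_nltv(m, g, p)
        np.testing.assert_array_equal(u1, u2)

    def test_objective_monotone_across_substeps(self, rng):
        """Within one sweep (b frozen), the u-step then the d-step each
        decrease the splitting objective."""
        ref = nv.make_phantom("textured", 16, 0)
        mask = nv.make_vardens_mask(16, 0.4, 6.0, 0.05, 2)
        m = nv.forward_measure(ref, mask)
        g = nv.compute_weights(nv.zero_fill_recon(m), patch_radius=1, search_radius=2)
        params = nv.SolverParams(gs_sweeps=4)
        state = SolverState(
            u=nv.zero_fill_recon(m), d=g.new_field(), b=g.new_field(),
            v_k=m, graph=g,
        )
        for _ in range(3):
            before = objective(state, params)
            state.u = u_update(state, params)
            after_u = objective(state, params)
            state.d = d_update(state, params)
            after_d = objective(state, params)
            assert after_u <= before + 1e-10
            assert after_d <= after_u + 1e-10
            state.b = b_update(state)

    def test_history_records_snr_when_ref_given(self):
        ref = nv.make_phantom("piecewise", 24, 0)
        mask = nv.make_vardens_mask(24, 0.4, 6.0, 0.05, 2)
        m = nv.forward_measure(ref, mask)
        u, hist = nv.reconstruct_tv(m, nv.TVParams(n_outer=3, tol=0.0), ref=ref)
        assert len(hist) == 3
        assert all(np.isfinite(h["snr"]) for h in hist)

    def test_tv_bridge(self):
        """NLTV on the unit forward-difference grid graph reproduces the
        independent TV implementation."""
        ref = nv.make_phantom("textured", 24, 0)
        mask = nv.make_vardens_mask(24, 0.35, 6.0, 0.05, 5)
        m = nv.forward_measure(ref, mask)
        g = nv.grid_forward_graph((24, 24))
        pn = nv.SolverParams(n_outer=8, tol=0.0)
        pt = nv.TVParams(n_outer=8, tol=0.0)
        u_nl, _ = nv.reconstruct_nltv(m, g, pn)
        u_tv, _ = nv.reconstruct_tv(m, pt)
        assert nv.relative_error(u_tv, u_nl) < 0.1
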