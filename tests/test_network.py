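import numpy as np
import pytest

from dtnn import (
    AtomicState,
    EnergyScaler,
    GaussianGrid,
    MoleculeGeometry,
    OracleTensorParams,
    atomic_energies,
    embed,
    gaussian_expand,
    init_params,
    interaction_factorized,
    interaction_full,
    load_checkpoint,
    molecular_energy,
    probe_energy,
    refine_pass,
    save_checkpoint,
)
from dtnn.data import distance_matrix
from dtnn.featurize import expand_all
from dtnn.network import forward_states, probe_energies

from conftest import random_isometry


def equivalent_oracle(params, block=0):
    """Contract the factorized weights into explicit tensor-layer form.

    With identity activation,
        W_fc[(W_cf c + b1) o (W_df d + b2)]
      = c^T V d  +  W_c c  +  W_d d  +  b
    with V_k[a,b] = sum_f W_fc[k,f] W_cf[f,a] W_df[f,b],
    W_c = W_fc diag(b2) W_cf, W_d = W_fc diag(b1) W_df, b = W_fc (b1 o b2).
    """
    W_cf, b1 = params.W_cf[block], params.b_f1[block]
    W_df, b2 = params.W_df[block], params.b_f2[block]
    W_fc = params.W_fc[block]
    V = np.einsum("kf,fa,fb->kab", W_fc, W_cf, W_df)
    return OracleTensorParams(
        V=V,
        W_c=W_fc @ (b2[:, None] * W_cf),
        W_d=W_fc @ (b1[:, None] * W_df),
        b=W_fc @ (b1 * b2),
    )


class TestEmbed:
    def test_identical_charges_identical_rows(self, tiny_params):
        state = embed([1, 1], tiny_params)
        np.testing.assert_array_equal(state.coeffs[0], state.coeffs[1])
        assert state.t == 0

    def test_different_charges_differ(self, tiny_params):
        state = embed([6, 1], tiny_params)
        assert not np.array_equal(state.coeffs[0], state.coeffs[1])

    @pytest.mark.parametrize("bad", [0, 99])
    def test_unseen_charge_errors_naming_z(self, tiny_params, bad):
        with pytest.raises(KeyError, match=str(bad)):
            embed([1, bad], tiny_params)


class TestInteractionFull:
    def test_zero_weights_give_g_of_zero(self):
        oracle = OracleTensorParams(
            V=np.zeros((3, 2, 4)), W_c=np.zeros((3, 2)), W_d=np.zeros((3, 4)),
            b=np.zeros(3),
        )
        out = interaction_full(np.ones(2), np.ones(4), oracle)
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_scalar_bilinear_arithmetic(self):
        oracle = OracleTensorParams(
            V=np.array([[[2.0]]]), W_c=np.zeros((1, 1)), W_d=np.zeros((1, 1)),
            b=np.zeros(1),
        )
        out = interaction_full(np.array([3.0]), np.array([4.0]), oracle, act="identity")
        assert out[0] == pytest.approx(24.0)

    def test_matches_triple_loop_contraction(self, rng):
        """The einsum bilinear form equals the brute-force triple loop."""
        B, G = 5, 7
        oracle = OracleTensorParams(
            V=rng.normal(size=(B, B, G)),
            W_c=rng.normal(size=(B, B)),
            W_d=rng.normal(size=(B, G)),
            b=rng.normal(size=B),
        )
        c, d = rng.normal(size=B), rng.normal(size=G)
        out = interaction_full(c, d, oracle, act="identity")
        expected = np.empty(B)
        for k in range(B):
            acc = oracle.b[k] + oracle.W_c[k] @ c + oracle.W_d[k] @ d
            for a in range(B):
                for bb in range(G):
                    acc += c[a] * oracle.V[k, a, bb] * d[bb]
            expected[k] = acc
        np.testing.assert_allclose(out, expected, atol=1e-12)


class TestInteractionFactorized:
    def test_zero_dhat_zero_biases_annihilates(self, tiny_grid):
        params = init_params([1], tiny_grid.n_features, B=4, F=6, T=1, seed=2)
        v = interaction_factorized(np.ones(4), np.zeros(tiny_grid.n_features), params)
        np.testing.assert_array_equal(v, np.zeros(4))

    def test_deterministic(self, tiny_params, rng):
        c = rng.normal(size=tiny_params.B)
        d = rng.normal(size=tiny_params.G)
        np.testing.assert_array_equal(
            interaction_factorized(c, d, tiny_params),
            interaction_factorized(c, d, tiny_params),
        )

    def test_equals_contracted_oracle(self, rng):
        """Low-rank factorization == explicit tensor layer on contracted weights."""
        params = init_params([1], 6, B=5, F=4, T=1, act="identity", seed=9)
        params.b_f1[0][:] = rng.normal(size=4)
        params.b_f2[0][:] = rng.normal(size=4)
        oracle = equivalent_oracle(params)
        for _ in range(10):
            c, d = rng.normal(size=5), rng.normal(size=6)
            np.testing.assert_allclose(
                interaction_factorized(c, d, params),
                interaction_full(c, d, oracle, act="identity"),
                atol=1e-10,
            )


class TestRefinePass:
    def test_single_atom_unchanged(self, tiny_params, tiny_grid):
        state = embed([6], tiny_params)
        D = np.zeros((1, 1))
        feats = expand_all(D, tiny_grid)
        out = refine_pass(state, D, feats, tiny_params)
        np.testing.assert_array_equal(out.coeffs, state.coeffs)
        assert out.t == 1

    def test_homonuclear_diatomic_exchange_symmetry(self, tiny_params, tiny_grid):
        mol = MoleculeGeometry(Z=[1, 1], R=[[0, 0, 0], [0, 0, 0.74]])
        D = distance_matrix(mol)
        out = refine_pass(embed(mol.Z, tiny_params), D, expand_all(D, tiny_grid), tiny_params)
        np.testing.assert_array_equal(out.coeffs[0], out.coeffs[1])

    def test_all_pairs_beyond_cutoff_unchanged(self, tiny_grid):
        params = init_params([1, 6], tiny_grid.n_features, B=4, F=6, T=1,
                             cutoff=1.0, seed=3)
        mol = MoleculeGeometry(Z=[1, 6], R=[[0, 0, 0], [0, 0, 2.5]])
        D = distance_matrix(mol)
        state = embed(mol.Z, params)
        out = refine_pass(state, D, expand_all(D, tiny_grid), params)
        np.testing.assert_array_equal(out.coeffs, state.coeffs)


class TestAtomicEnergies:
    def test_zero_output_layer_predicts_mean(self, tiny_params, scaler):
        state = embed([1, 6, 8], tiny_params)  # head_W2/b2 are zero-initialized
        E_i = atomic_energies(state, tiny_params, scaler)
        np.testing.assert_allclose(E_i, scaler.E_mu)

    def test_identity_scaler(self, tiny_params, rng):
        tiny_params.head_W2 = rng.normal(size=tiny_params.head_W2.shape)
        state = embed([1, 6], tiny_params)
        ehat = atomic_energies(state, tiny_params, EnergyScaler(0.0, 1.0))
        E_i = atomic_energies(state, tiny_params, EnergyScaler(0.0, 2.0))
        np.testing.assert_allclose(E_i, 2.0 * ehat, rtol=1e-12)


class TestMolecularEnergy:
    def _params(self, tiny_grid, rng, **kw):
        params = init_params([1, 6, 8], tiny_grid.n_features, B=6, F=8, T=2,
                             seed=4, **kw)
        params.head_W2 = rng.normal(size=params.head_W2.shape)  # non-degenerate head
        return params

    def test_permutation_invariance(self, tiny_grid, scaler, rng):
        params = self._params(tiny_grid, rng)
        mol = MoleculeGeometry(Z=[8, 1, 1, 6], R=rng.normal(scale=1.5, size=(4, 3)))
        E, E_i = molecular_energy(mol, params, tiny_grid, scaler)
        perm = rng.permutation(4)
        E_p, E_i_p = molecular_energy(
            MoleculeGeometry(Z=mol.Z[perm], R=mol.R[perm]), params, tiny_grid, scaler
        )
        assert E_p == pytest.approx(E, rel=1e-10)
        np.testing.assert_allclose(E_i_p, E_i[perm], rtol=1e-10)

    def test_isometry_invariance(self, tiny_grid, scaler, rng):
        params = self._params(tiny_grid, rng)
        mol = MoleculeGeometry(Z=[8, 1, 6], R=rng.normal(scale=1.5, size=(3, 3)))
        E, _ = molecular_energy(mol, params, tiny_grid, scaler)
        Q, t = random_isometry(rng)
        E_m, _ = molecular_energy(
            MoleculeGeometry(Z=mol.Z, R=mol.R @ Q.T + t), params, tiny_grid, scaler
        )
        assert E_m == pytest.approx(E, rel=1e-10)

    def test_size_extensivity_under_cutoff(self, tiny_grid, scaler, rng):
        """Two far-separated copies cost exactly twice one copy."""
        params = self._params(tiny_grid, rng, cutoff=3.0)
        mol = MoleculeGeometry(Z=[8, 1, 1], R=[[0, 0, 0], [0.96, 0, 0], [0, 0.96, 0]])
        E1, _ = molecular_energy(mol, params, tiny_grid, scaler)
        pair = MoleculeGeometry(
            Z=np.concatenate([mol.Z, mol.Z]),
            R=np.vstack([mol.R, mol.R + [0, 0, 30.0]]),  # 10x cutoff apart
        )
        E2, _ = molecular_energy(pair, params, tiny_grid, scaler)
        assert E2 == pytest.approx(2 * E1, rel=1e-9)

    def test_total_is_sum_of_atomic(self, tiny_grid, scaler, rng):
        params = self._params(tiny_grid, rng)
        mol = MoleculeGeometry(Z=[6, 1, 8], R=rng.normal(scale=1.5, size=(3, 3)))
        E, E_i = molecular_energy(mol, params, tiny_grid, scaler)
        assert E == np.sum(E_i)


class TestProbe:
    def test_one_way_coupling_bitwise(self, tiny_grid, scaler, rng, triatomic):
        params = init_params([1, 6, 8], tiny_grid.n_features, B=6, F=8, T=2, seed=5)
        params.head_W2 = rng.normal(size=params.head_W2.shape)
        E_before, E_i_before = molecular_energy(triatomic, params, tiny_grid, scaler)
        probe_energy(triatomic, 1, [0.5, 0.5, 1.0], params, tiny_grid, scaler)
        E_after, E_i_after = molecular_energy(triatomic, params, tiny_grid, scaler)
        assert E_before == E_after  # bitwise
        np.testing.assert_array_equal(E_i_before, E_i_after)

    def test_beyond_cutoff_gives_isolated_atom_energy(self, tiny_grid, scaler, rng):
        params = init_params([1, 6], tiny_grid.n_features, B=6, F=8, T=2,
                             cutoff=2.0, seed=6)
        params.head_W2 = rng.normal(size=params.head_W2.shape)
        mol = MoleculeGeometry(Z=[6, 6], R=[[0, 0, 0], [1.4, 0, 0]])
        omega = probe_energy(mol, 1, [100.0, 0, 0], params, tiny_grid, scaler)
        isolated = atomic_energies(embed([1], params), params, scaler)[0]
        assert omega == pytest.approx(isolated, rel=1e-12)

    def test_mirror_symmetric_positions_equal(self, tiny_grid, scaler, rng):
        params = init_params([1, 7], tiny_grid.n_features, B=6, F=8, T=2, seed=7)
        params.head_W2 = rng.normal(size=params.head_W2.shape)
        mol = MoleculeGeometry(Z=[7, 7], R=[[0, 0, -0.55], [0, 0, 0.55]])
        a = probe_energy(mol, 1, [0.8, 0.3, 0.9], params, tiny_grid, scaler)
        b = probe_energy(mol, 1, [0.8, 0.3, -0.9], params, tiny_grid, scaler)
        assert a == pytest.approx(b, rel=1e-10)

    def test_vectorized_matches_scalar(self, tiny_grid, scaler, rng, triatomic):
        params = init_params([1, 6, 8], tiny_grid.n_features, B=6, F=8, T=2, seed=8)
        params.head_W2 = rng.normal(size=params.head_W2.shape)
        pts = rng.normal(scale=2.0, size=(5, 3))
        vals = probe_energies(triatomic, 1, pts, params, tiny_grid, scaler)
        for p, v in zip(pts, vals):
            assert probe_energy(triatomic, 1, p, params, tiny_grid, scaler) == \
                pytest.approx(v, rel=1e-12)

    def test_unseen_probe_charge_errors(self, tiny_params, tiny_grid, scaler, triatomic):
        with pytest.raises(KeyError, match="17"):
            probe_energy(triatomic, 17, [0, 0, 1.0], tiny_params, tiny_grid, scaler)


def test_checkpoint_round_trip(tmp_path, tiny_grid, scaler, rng):
    params = init_params([1, 6, 8], tiny_grid.n_features, B=6, F=8, T=3,
                         cutoff=4.5, tied=False, seed=11)
    params.head_W2 = rng.normal(size=params.head_W2.shape)
    path = save_checkpoint(tmp_path / "ck.npz", params, tiny_grid, scaler, {"note": 1})
    p2, g2, s2, cfg = load_checkpoint(path)
    assert cfg == {"note": 1}
    assert (g2.mu_min, g2.mu_max, g2.delta_mu, g2.sigma) == (
        tiny_grid.mu_min, tiny_grid.mu_max, tiny_grid.delta_mu, tiny_grid.sigma
    )
    assert (s2.E_mu, s2.E_sigma) == (scaler.E_mu, scaler.E_sigma)
    assert p2.n_passes == 3 and p2.cutoff == 4.5 and not p2.tied
    mol = MoleculeGeometry(Z=[8, 1, 6], R=rng.normal(scale=1.5, size=(3, 3)))
    E1, _ = molecular_energy(mol, params, tiny_grid, scaler)
    E2, _ = molecular_energy(mol, p2, g2, s2)
    assert E1 == E2
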