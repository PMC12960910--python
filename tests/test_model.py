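"""GMVAE forward semantics: attention, inference heads, sampling, densities."""

import numpy as np

import spatialmix as sm
from spatialmix._tensor import Tensor
from spatialmix.graph import MiniBatch
from spatialmix.model import (
    MixtureModelState,
    decode,
    gat_encode,
    gaussian_log_density,
    infer,
    joint_log_prob,
    prior_log_prob,
    sample_all_components,
    sample_latent,
)


def toy_batch(X, neighbors):
    """MiniBatch where every unit is a target."""
    X = np.asarray(X, dtype=float)
    return MiniBatch(
        target_ids=np.arange(len(X)),
        member_ids=np.arange(len(X)),
        local_X=X,
        local_neighbors=np.asarray(neighbors, dtype=np.intp),
    )


def toy_state(m=3, K=2, **kw):
    return MixtureModelState(n_features=m, n_clusters=K, hidden_dim=5,
                             latent_dim=2, seed=1, **kw)


# -- GAT ----------------------------------------------------------------------


def test_self_loop_only_returns_transformed_features():
    state = toy_state()
    X = np.array([[1.0, -0.5, 2.0]])
    # no neighbor edges: softmax over the single self-loop gives weight 1
    batch = MiniBatch(
        target_ids=np.array([0]),
        member_ids=np.array([0]),
        local_X=X,
        local_neighbors=np.empty((1, 0), dtype=np.intp),
    )
    out = gat_encode(batch, state.gat)
    expected = X @ state.gat.weight.data + state.gat.bias.data
    np.testing.assert_allclose(out.data, expected, atol=1e-12)


def test_attention_weights_sum_to_one(rng):
    from spatialmix.model import _batch_edges

    state = toy_state()
    batch = toy_batch(rng.normal(size=(6, 3)), rng.integers(0, 6, size=(6, 2)))
    src, dst = _batch_edges(batch)
    h = Tensor(batch.local_X) @ state.gat.weight
    e = (
        (h * state.gat.att_src.reshape(1, -1)).sum(axis=1).take_rows(src)
        + (h * state.gat.att_dst.reshape(1, -1)).sum(axis=1).take_rows(dst)
    ).leaky_relu(0.2)
    alpha = e.segment_softmax(dst, 6)
    sums = alpha.segment_sum(dst, 6)
    np.testing.assert_allclose(sums.data, 1.0, atol=1e-6)


def test_identical_neighbor_features_give_uniform_attention():
    state = toy_state()
    X = np.tile([[0.3, -1.0, 0.7]], (4, 1))  # all members identical
    batch = toy_batch(X, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])
    out = gat_encode(batch, state.gat)
    # softmax of equal logits is uniform; the weighted mean of identical
    # transformed vectors is that vector again
    expected = X @ state.gat.weight.data + state.gat.bias.data
    np.testing.assert_allclose(out.data, expected, atol=1e-10)


# -- inference ----------------------------------------------------------------


def test_infer_rows_are_probability_vectors(rng):
    state = toy_state(m=4, K=3)
    batch = toy_batch(rng.normal(size=(8, 4)), rng.integers(0, 8, size=(8, 3)))
    out = infer(batch, state)
    np.testing.assert_allclose(out.Y_hat.data.sum(axis=1), 1.0, atol=1e-6)
    assert (out.Y_hat.data >= 0).all()
    assert (out.sigma_post.data >= state.sigma_floor).all()


def test_zeroed_head_gives_uniform_assignment(rng):
    state = toy_state(m=4, K=3)
    state.params["head_y.W"].data[:] = 0.0
    state.params["head_y.b"].data[:] = 0.0
    batch = toy_batch(rng.normal(size=(5, 4)), rng.integers(0, 5, size=(5, 2)))
    out = infer(batch, state)
    np.testing.assert_allclose(out.Y_hat.data, 1.0 / 3.0, atol=1e-12)


# -- sampling -----------------------------------------------------------------


def test_zero_noise_recovers_posterior_mean(rng):
    mu = Tensor(rng.normal(size=(4, 2, 3)))
    sig = Tensor(np.full((4, 2, 3), 1e-4))
    z = sample_all_components(mu, sig, seed=0, eps=np.zeros((4, 2, 3)))
    np.testing.assert_allclose(z.data, mu.data)


def test_sampling_deterministic_under_seed(rng):
    mu = Tensor(rng.normal(size=(4, 2, 3)))
    sig = Tensor(rng.uniform(0.5, 2.0, size=(4, 2, 3)))
    z1 = sample_all_components(mu, sig, seed=42)
    z2 = sample_all_components(mu, sig, seed=42)
    np.testing.assert_array_equal(z1.data, z2.data)


def test_sample_mean_approaches_posterior_mean():
    rng = np.random.default_rng(0)
    mu = np.array([[[1.0, -2.0]]])
    sig = np.array([[[0.5, 0.3]]])
    draws = np.stack(
        [
            sample_all_components(Tensor(mu), Tensor(sig), seed=s).data
            for s in range(10_000)
        ]
    )
    err = np.abs(draws.mean(axis=0) - mu)
    assert (err < 3.0 * sig / np.sqrt(10_000)).all()


def test_sample_latent_uses_most_probable_component(rng):
    post = sm.PosteriorParams(
        mu_post=np.array([[[0.0, 0.0], [5.0, 5.0]]]),
        sigma_post=np.full((1, 2, 2), 1e-6),
    )
    Y = sm.SoftAssignment(np.array([[0.1, 0.9]]))
    z = sample_latent(post, Y, seed=0, eps=np.zeros((1, 2, 2)))
    np.testing.assert_allclose(z, [[5.0, 5.0]])


# -- decoder & densities ------------------------------------------------------


def test_decoder_outputs_positive_sigma_and_is_deterministic(rng):
    state = toy_state()
    z = Tensor(np.vstack([rng.normal(size=(1, 2))] * 2))  # two identical rows
    mu_x, sigma_x = decode(z, state)
    assert (sigma_x.data > 0).all()
    np.testing.assert_array_equal(mu_x.data[0], mu_x.data[1])
    np.testing.assert_array_equal(sigma_x.data[0], sigma_x.data[1])


def test_decoder_density_matches_closed_form(rng):
    state = toy_state(m=2)
    z = Tensor(rng.normal(size=(3, 2)))
    mu_x, sigma_x = decode(z, state)
    x = rng.normal(size=(3, 2))
    got = gaussian_log_density(Tensor(x), mu_x, sigma_x).data
    expected = (
        -0.5 * np.log(2 * np.pi)
        - np.log(sigma_x.data)
        - (x - mu_x.data) ** 2 / (2 * sigma_x.data**2)
    ).sum(axis=1)
    np.testing.assert_allclose(got, expected, atol=1e-12)


def test_prior_log_prob_at_mean_is_normalizing_constant():
    state = toy_state()
    state.params["prior.s"].data[:] = np.log(np.expm1(1.0 - state.sigma_floor))
    z = state.mu_prior.data[0][None, :]  # at component 0's mean
    lp = prior_log_prob(z, state)
    np.testing.assert_allclose(lp[0, 0], -(2 / 2) * np.log(2 * np.pi), atol=1e-9)


def test_prior_log_prob_decreases_away_from_mean():
    state = toy_state()
    z0 = state.mu_prior.data[[0]]
    near = prior_log_prob(z0, state)[0, 0]
    far = prior_log_prob(z0 + 1.5, state)[0, 0]
    assert far < near


def test_prior_log_prob_matches_scipy_oracle(rng):
    from scipy.stats import norm

    state = MixtureModelState(n_features=4, n_clusters=3, latent_dim=2, seed=0)
    z = rng.normal(size=(5, 2))
    got = prior_log_prob(z, state)
    mu = state.mu_prior.data
    sig = state.sigma_prior.data
    expected = np.array(
        [
            [norm.logpdf(z[i], mu[j], sig[j]).sum() for j in range(3)]
            for i in range(5)
        ]
    )
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_joint_factorization_matches_direct_sum(rng):
    """log p(y, z, x) assembled from its three factors equals the direct
    closed-form evaluation."""
    from scipy.stats import norm

    state = toy_state(m=3, K=2)
    z = rng.normal(size=(4, 2))
    x = rng.normal(size=(4, 3))
    got = joint_log_prob(z, x, state)
    mu_x, sigma_x = decode(Tensor(z), state)
    expected = (
        -np.log(2)
        + prior_log_prob(z, state)
        + norm.logpdf(x, mu_x.data, sigma_x.data).sum(axis=1)[:, None]
    )
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_component_permutation_symmetry(rng):
    """Permuting mixture components permutes assignment columns and prior
    rows consistently."""
    state = toy_state(m=4, K=3)
    batch = toy_batch(rng.normal(size=(6, 4)), rng.integers(0, 6, size=(6, 2)))
    out = infer(batch, state)
    perm = np.array([2, 0, 1])
    # permute all per-component parameter blocks
    K, dz, h = 3, state.latent_dim, state.hidden_dim
    state.params["head_y.W"].data = state.params["head_y.W"].data[:, perm]
    state.params["head_y.b"].data = state.params["head_y.b"].data[perm]
    for name in ("head_mu", "head_sig"):
        W = state.params[f"{name}.W"].data.reshape(h, K, dz)
        b = state.params[f"{name}.b"].data.reshape(K, dz)
        state.params[f"{name}.W"].data = W[:, perm].reshape(h, K * dz)
        state.params[f"{name}.b"].data = b[perm].reshape(K * dz)
    state.params["prior.mu"].data = state.params["prior.mu"].data[perm]
    state.params["prior.s"].data = state.params["prior.s"].data[perm]
    out2 = infer(batch, state)
    np.testing.assert_allclose(out2.Y_hat.data, out.Y_hat.data[:, perm], atol=1e-12)
    np.testing.assert_allclose(out2.mu_post.data, out.mu_post.data[:, perm], atol=1e-12)


def test_outputs_finite_for_finite_inputs(rng):
    state = toy_state(m=5, K=4)
    X = rng.normal(size=(10, 5)) * 100  # large but finite
    batch = toy_batch(X, rng.integers(0, 10, size=(10, 3)))
    out = infer(batch, state)
    z = sample_all_components(out.mu_post, out.sigma_post, seed=0)
    mu_x, sigma_x = decode(z, state)
    for t in (out.Y_hat, out.mu_post, out.sigma_post, mu_x, sigma_x):
        assert np.isfinite(t.data).all()


def test_checkpoint_roundtrip(tmp_path, rng):
    state = toy_state()
    path = tmp_path / "model.npz"
    state.save(path)
    back = MixtureModelState.load(path)
    assert back.n_clusters == state.n_clusters
    for k in state.params:
        np.testing.assert_array_equal(back.params[k].data, state.params[k].data)
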