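import math

import numpy as np
import pytest

from mevae import (
    ModelSpec,
    PopulationSpec,
    build_decoder,
    build_encoder,
    encode,
    fuse_latents,
    generate_population,
    kl_closed_form,
    load_model,
    loss_beta_vae,
    loss_denoising_ae,
    loss_invariant_cvae,
    loss_me_vae,
    loss_output_corrected,
    loss_standard_vae,
    make_identity_dataset,
    make_paired_dataset,
    save_model,
    train,
)
from mevae.exceptions import ConfigurationError, InvalidInputError, ProvenanceError


# ---------------------------------------------------------------------------
# scalar-loop oracles (independent of the vectorized implementation)
# ---------------------------------------------------------------------------

def oracle_bce(target, recon):
    eps = 1e-7
    t = target.reshape(target.shape[0], -1) if target.ndim > 1 else target.reshape(1, -1)
    r = recon.reshape(recon.shape[0], -1) if recon.ndim > 1 else recon.reshape(1, -1)
    per_sample = []
    for i in range(t.shape[0]):
        s = 0.0
        for j in range(t.shape[1]):
            rv = min(max(r[i, j], eps), 1 - eps)
            s -= t[i, j] * math.log(rv) + (1 - t[i, j]) * math.log(1 - rv)
        per_sample.append(s)
    return sum(per_sample) / len(per_sample)


def oracle_kl(mu, logvar):
    mu = np.atleast_2d(mu)
    lv = np.atleast_2d(logvar)
    per_sample = []
    for i in range(mu.shape[0]):
        s = 0.0
        for j in range(mu.shape[1]):
            s += 0.5 * (mu[i, j] ** 2 + math.exp(lv[i, j]) - 1.0 - lv[i, j])
        per_sample.append(s)
    return sum(per_sample) / len(per_sample)


def oracle_gauss_kl(mu1, lv1, mu2, lv2):
    s = 0.0
    for j in range(len(mu1)):
        s += 0.5 * (lv2[j] - lv1[j] + (math.exp(lv1[j]) + (mu1[j] - mu2[j]) ** 2) / math.exp(lv2[j]) - 1.0)
    return s


@pytest.fixture
def small_tensors():
    rng = np.random.default_rng(3)
    target = rng.uniform(0.05, 0.95, (3, 2, 2, 1))
    recon = rng.uniform(0.05, 0.95, (3, 2, 2, 1))
    mu = rng.normal(0, 1, (3, 4))
    lv = rng.normal(0, 0.5, (3, 4))
    return target, recon, mu, lv


# ---------------------------------------------------------------------------
# KL and fusion
# ---------------------------------------------------------------------------

def test_kl_zero_at_standard_normal():
    assert kl_closed_form(np.zeros(4), np.zeros(4)) == 0.0


def test_kl_hand_value():
    assert abs(kl_closed_form(np.array([1.0]), np.array([0.0])) - 0.5) < 1e-12


def test_kl_matches_monte_carlo():
    """Closed form within 1% of a 1e6-sample MC estimate of E_q[log q - log p]."""
    rng = np.random.default_rng(7)
    mu = np.array([0.7, -1.2, 0.3])
    lv = np.array([0.4, -0.6, 0.1])
    sd = np.exp(0.5 * lv)
    z = mu + sd * rng.standard_normal((1_000_000, 3))
    log_q = -0.5 * (((z - mu) / sd) ** 2 + np.log(2 * np.pi) + lv).sum(axis=1)
    log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
    mc = (log_q - log_p).mean()
    assert abs(kl_closed_form(mu, lv) - mc) / mc < 0.01


def test_kl_nonnegative_property():
    rng = np.random.default_rng(0)
    for _ in range(50):
        mu = rng.normal(0, 2, 5)
        lv = rng.normal(0, 1, 5)
        assert kl_closed_form(mu, lv) >= 0.0


def test_kl_rejects_nonfinite():
    with pytest.raises(InvalidInputError):
        kl_closed_form(np.array([np.nan]), np.array([0.0]))


def test_fuse_latents_contracts():
    z = np.array([1.0, 2.0])
    np.testing.assert_array_equal(fuse_latents([z]), z)
    np.testing.assert_array_equal(fuse_latents([np.array([1.0, 2.0]), np.array([3.0, -1.0])]),
                                  np.array([3.0, -2.0]))
    np.testing.assert_array_equal(fuse_latents([z, np.zeros(2)]), np.zeros(2))
    with pytest.raises(InvalidInputError):
        fuse_latents([np.zeros(2), np.zeros(3)])


# ---------------------------------------------------------------------------
# loss oracle equivalence and reduction identities
# ---------------------------------------------------------------------------

def test_standard_vae_loss_matches_scalar_oracle(small_tensors):
    target, recon, mu, lv = small_tensors
    got = loss_standard_vae(target, recon, mu, lv)
    expected = oracle_bce(target, recon) + oracle_kl(mu, lv)
    assert abs(got - expected) < 1e-6


def test_perfect_reconstruction_zero_loss():
    t = np.array([[1e-7, 1 - 1e-7], [1 - 1e-7, 1e-7]])
    assert loss_standard_vae(t, t, np.zeros(2), np.zeros(2)) < 1e-4


def test_kl_monotonicity_in_mu(small_tensors):
    target, recon, _, _ = small_tensors
    base = loss_standard_vae(target, recon, np.zeros((3, 4)), np.zeros((3, 4)))
    shifted = loss_standard_vae(target, recon, np.ones((3, 4)), np.zeros((3, 4)))
    assert shifted > base


def test_output_corrected_reduces_to_standard(small_tensors):
    target, recon, mu, lv = small_tensors
    assert loss_output_corrected(target, recon, mu, lv) == loss_standard_vae(target, recon, mu, lv)


def test_output_corrected_provenance_check(small_tensors):
    target, recon, mu, lv = small_tensors
    with pytest.raises(ProvenanceError):
        loss_output_corrected(target, recon, mu, lv, provenance={"target_is_canonical": False})


def test_me_vae_loss_reductions_and_oracle(small_tensors):
    target, recon, mu, lv = small_tensors
    # n=1 reduces exactly to the output-corrected arithmetic
    assert loss_me_vae(target, recon, [mu], [lv]) == loss_output_corrected(target, recon, mu, lv)
    # identical posteriors: KL term equals the single-encoder KL
    assert abs(loss_me_vae(target, recon, [mu] * 3, [lv] * 3) - loss_me_vae(target, recon, [mu], [lv])) < 1e-10
    # n=2 against the scalar oracle
    mu2, lv2 = mu * 0.5, lv * -0.3
    got = loss_me_vae(target, recon, [mu, mu2], [lv, lv2])
    expected = oracle_bce(target, recon) + 0.5 * (oracle_kl(mu, lv) + oracle_kl(mu2, lv2))
    assert abs(got - expected) < 1e-6
    with pytest.raises(InvalidInputError):
        loss_me_vae(target, recon, [], [])


def test_beta_vae_loss(small_tensors):
    target, recon, mu, lv = small_tensors
    assert loss_beta_vae(target, recon, mu, lv, 1.0) == loss_standard_vae(target, recon, mu, lv)
    kl = kl_closed_form(mu, lv)
    diff = loss_beta_vae(target, recon, mu, lv, 2.0) - loss_beta_vae(target, recon, mu, lv, 0.5)
    assert abs(diff - 1.5 * kl) < 1e-9
    got = loss_beta_vae(target, recon, mu, lv, 4.0)
    assert abs(got - (oracle_bce(target, recon) + 4.0 * oracle_kl(mu, lv))) < 1e-6
    with pytest.raises(ConfigurationError):
        loss_beta_vae(target, recon, mu, lv, 0.0)


def test_invariant_cvae_loss(small_tensors):
    target, recon, mu, lv = small_tensors
    t0, r0 = target[0], recon[0]
    # lambda=0 reduces to standard arithmetic
    got0 = loss_invariant_cvae(t0, r0, mu[0], lv[0], mu, lv, lam=0.0)
    assert abs(got0 - loss_standard_vae(t0, r0, mu[0], lv[0])) < 1e-9
    # identical posteriors -> marginal term zero
    same_mu = np.tile(mu[0], (3, 1))
    same_lv = np.tile(lv[0], (3, 1))
    got_same = loss_invariant_cvae(t0, r0, mu[0], lv[0], same_mu, same_lv, lam=1.0)
    assert abs(got_same - (2.0 * oracle_bce(t0, r0) + oracle_kl(mu[0], lv[0]))) < 1e-6
    # brute-force pairwise KL for a batch of 3
    got = loss_invariant_cvae(t0, r0, mu[0], lv[0], mu, lv, lam=1.0)
    pair = [oracle_gauss_kl(mu[0], lv[0], mu[j], lv[j]) for j in (1, 2)]
    expected = 2.0 * oracle_bce(t0, r0) + oracle_kl(mu[0], lv[0]) + np.mean(pair)
    assert abs(got - expected) < 1e-6
    with pytest.raises(InvalidInputError):
        loss_invariant_cvae(t0, r0, mu[0], lv[0], mu[:1], lv[:1], lam=1.0)


def test_denoising_loss_is_bce_only(small_tensors):
    target, recon, mu, lv = small_tensors
    got = loss_denoising_ae(target, recon)
    assert abs(got - oracle_bce(target, recon)) < 1e-6
    assert abs(got - (loss_standard_vae(target, recon, mu, lv) - kl_closed_form(mu, lv))) < 1e-9


def test_bce_rejects_out_of_range_reconstruction(small_tensors):
    target, _, _, _ = small_tensors
    with pytest.raises(InvalidInputError):
        loss_denoising_ae(target, target + 1.5)


# ---------------------------------------------------------------------------
# network components
# ---------------------------------------------------------------------------

def test_encoder_shapes_and_determinism():
    enc = build_encoder((8, 8, 1), 6, hidden=(16, 12, 8), seed=0)
    enc2 = build_encoder((8, 8, 1), 6, hidden=(16, 12, 8), seed=0)
    x = np.zeros((2, 64))
    mu, lv = enc.forward(x)
    assert mu.shape == (2, 6) and lv.shape == (2, 6)
    assert np.all(np.isfinite(mu)) and np.all(np.isfinite(lv))
    np.testing.assert_array_equal(enc.trunk.W[0], enc2.trunk.W[0])


def test_decoder_output_range_and_saturation():
    dec = build_decoder(6, (8, 8, 1), hidden=(16, 12, 8), seed=1)
    out = dec.forward(np.zeros((2, 6)))
    assert out.shape == (2, 64)
    assert np.all((out > 0) & (out < 1))
    extreme = dec.forward(np.full((1, 6), 100.0))
    assert np.all(np.isfinite(extreme))


def test_builders_reject_bad_shapes():
    with pytest.raises(ConfigurationError):
        build_encoder((0, 8, 1), 4)
    with pytest.raises(ConfigurationError):
        build_decoder(0, (8, 8, 1))


# ---------------------------------------------------------------------------
# training behaviour (desk scale)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_records():
    spec = PopulationSpec(n_cells=60, image_size=24, ellipse_axes=((5.0, 0.6), (3.2, 0.4)),
                          staining_pattern="uniform", hotspot_fraction=0.3, noise_sd=0.02)
    return generate_population(spec, seed=2)


def test_training_decreases_loss(tiny_records):
    dataset = make_identity_dataset(tiny_records)
    spec = ModelSpec(variant="standard_vae", latent_dim=8, input_shape=(24, 24, 1),
                     corrections=(), hidden=(64, 32, 16), batch_size=20)
    model = train(spec, dataset, epochs=5, seed=0)
    totals = [h["total"] for h in model.history]
    assert len(totals) == 5
    assert all(np.isfinite(totals))
    assert totals[-1] <= totals[0]
    drops = sum(b <= a for a, b in zip(totals, totals[1:]))
    assert drops >= 3


def test_training_reproducible_and_zero_epochs(tiny_records):
    dataset = make_identity_dataset(tiny_records)
    spec = ModelSpec(variant="standard_vae", latent_dim=8, input_shape=(24, 24, 1),
                     corrections=(), hidden=(64, 32, 16), batch_size=20)
    m1 = train(spec, dataset, epochs=2, seed=5)
    m2 = train(spec, dataset, epochs=2, seed=5)
    assert m1.history[-1]["total"] == m2.history[-1]["total"]
    m0 = train(spec, dataset, epochs=0, seed=5)
    assert m0.history == []


def test_me_dae_and_me_vae_train(tiny_records):
    dataset = make_paired_dataset(tiny_records, ("rotation",), seed=1)
    for variant in ("me_vae", "me_dae"):
        spec = ModelSpec(variant=variant, latent_dim=8, input_shape=(24, 24, 1),
                         corrections=("rotation",), hidden=(64, 32, 16), batch_size=20)
        model = train(spec, dataset, epochs=2, seed=0)
        assert all(np.isfinite(h["total"]) for h in model.history)
        if variant == "me_dae":
            assert all(h["kl"] == 0.0 for h in model.history)


def test_invariant_cvae_trains_with_condition(tiny_records):
    from mevae.transforms import nuisance_condition_matrix

    dataset = make_identity_dataset(tiny_records)
    C = nuisance_condition_matrix(tiny_records)
    for s, c in zip(dataset, C):
        s.condition = c
    spec = ModelSpec(variant="invariant_cvae", latent_dim=8, input_shape=(24, 24, 1),
                     corrections=(), hidden=(64, 32, 16), batch_size=20,
                     condition_dim=C.shape[1], lam=1.0)
    model = train(spec, dataset, epochs=2, seed=0)
    assert all(np.isfinite(h["total"]) for h in model.history)


def test_encode_deterministic_and_shaped(tiny_records):
    dataset = make_paired_dataset(tiny_records, ("rotation",), seed=1)
    spec = ModelSpec(variant="me_vae", latent_dim=8, input_shape=(24, 24, 1),
                     corrections=("rotation",), hidden=(64, 32, 16), batch_size=20)
    model = train(spec, dataset, epochs=1, seed=0)
    emb1 = encode(model, tiny_records[:10])
    emb2 = encode(model, tiny_records[:10])
    assert emb1.values.shape == (10, 8)
    np.testing.assert_array_equal(emb1.values, emb2.values)
    assert np.all(np.isfinite(emb1.values))


def test_single_encoder_me_vae_encode_equals_output_corrected(tiny_records):
    """With identical weights, me_vae(n=1) and output_corrected encode agree."""
    dataset = make_paired_dataset(tiny_records, ("rotation",), seed=1)
    spec_me = ModelSpec(variant="me_vae", latent_dim=8, input_shape=(24, 24, 1),
                        corrections=("rotation",), hidden=(64, 32, 16), batch_size=20)
    model = train(spec_me, dataset, epochs=1, seed=3)
    import dataclasses

    model_oc = dataclasses.replace(model, spec=dataclasses.replace(spec_me, variant="output_corrected_vae"))
    a = encode(model, tiny_records[:8]).values
    b = encode(model_oc, tiny_records[:8]).values
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_model_save_load_round_trip(tiny_records, tmp_path):
    dataset = make_paired_dataset(tiny_records[:20], ("rotation",), seed=1)
    spec = ModelSpec(variant="me_vae", latent_dim=8, input_shape=(24, 24, 1),
                     corrections=("rotation",), hidden=(64, 32, 16), batch_size=10)
    model = train(spec, dataset, epochs=1, seed=0)
    path = tmp_path / "model.npz"
    save_model(model, str(path))
    loaded = load_model(str(path))
    a = encode(model, tiny_records[:5]).values
    b = encode(loaded, tiny_records[:5]).values
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_spec_validation():
    with pytest.raises(ConfigurationError):
        ModelSpec(variant="gan").validate()
    with pytest.raises(ConfigurationError):
        ModelSpec(latent_dim=0).validate()
    with pytest.raises(ConfigurationError):
        ModelSpec(variant="me_vae", corrections=()).validate()
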