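import numpy as np
import pytest
from hypothesis import given, strategies as st

from content_ehr.corpus import PatientRecord, Visit, split_corpus
from content_ehr.model import init_content_params, zero_content_params
from content_ehr.recognition import init_recognition_params, zero_recognition_params
from content_ehr.training import (
    TrainConfig,
    elbo_grads,
    elbo_loss,
    fit,
    named_arrays,
    predict,
)
from content_ehr.checkpoint import load_checkpoint, save_checkpoint

from conftest import random_record

SMALL_CFG = TrainConfig(
    embed_dim=6, hidden_dim=8, n_topics=3, rec_hidden1=8, rec_hidden2=8,
    max_epochs=3, patience=3, seed=5,
)


def _one_visit_record(label=1):
    return PatientRecord("p", (Visit((0,), label=label),), (True,))


def test_elbo_zero_params_single_visit():
    p = zero_content_params(3, 4, 5, 2)
    rp = zero_recognition_params(3, 2, 4, 4)
    assert elbo_loss(_one_visit_record(1), p, rp, np.zeros(2)) == pytest.approx(
        np.log(0.5)
    )


def test_elbo_zero_params_two_visits():
    p = zero_content_params(3, 4, 5, 2)
    rp = zero_recognition_params(3, 2, 4, 4)
    rec = PatientRecord(
        "p", (Visit((0,), label=1), Visit((1,), label=0)), (True, True)
    )
    assert elbo_loss(rec, p, rp, np.zeros(2)) == pytest.approx(2 * np.log(0.5))


def test_elbo_requires_a_supervised_visit():
    p = zero_content_params(3, 4, 5, 2)
    rec = PatientRecord("p", (Visit((0,)),), (False,))
    with pytest.raises(ValueError, match="supervised"):
        elbo_loss(rec, p, None)


def test_masked_out_visits_contribute_no_likelihood():
    rng = np.random.default_rng(0)
    p = init_content_params(5, 4, 5, 2, rng)
    rp = init_recognition_params(5, 2, 4, 4, rng)
    eps = rng.standard_normal(2)
    rec_a = PatientRecord(
        "p", (Visit((0,), label=1), Visit((1,), label=0)), (True, False)
    )
    rec_b = PatientRecord(
        "p", (Visit((0,), label=1), Visit((1,), label=1)), (True, False)
    )
    # flipping the label of a masked-out visit changes nothing
    assert elbo_loss(rec_a, p, rp, eps) == elbo_loss(rec_b, p, rp, eps)


def test_gru_baseline_objective_is_pure_likelihood():
    p = zero_content_params(3, 4, 5, 2)
    # without the recognition network there is no KL, so two fair-coin visits
    # give exactly the Bernoulli log-likelihood
    rec = PatientRecord(
        "p", (Visit((0,), label=1), Visit((1,), label=0)), (True, True)
    )
    assert elbo_loss(rec, p, None) == pytest.approx(2 * np.log(0.5))


@given(st.integers(0, 10_000))
def test_single_sample_elbo_is_nonpositive(seed):
    rng = np.random.default_rng(seed)
    p = init_content_params(6, 4, 5, 3, rng)
    rp = init_recognition_params(6, 3, 5, 5, rng)
    rec = random_record(rng, 6, int(rng.integers(1, 6)))
    assert elbo_loss(rec, p, rp, rng.standard_normal(3)) <= 0.0


def test_elbo_grads_value_matches_elbo_loss():
    rng = np.random.default_rng(1)
    p = init_content_params(6, 4, 5, 3, rng)
    rp = init_recognition_params(6, 3, 5, 5, rng)
    rec = random_record(rng, 6, 4)
    eps = rng.standard_normal(3)
    value, grads = elbo_grads(rec, p, rp, eps)
    assert value == pytest.approx(elbo_loss(rec, p, rp, eps), rel=1e-12)
    assert set(grads) == set(named_arrays(p, rp))


def test_gradients_match_finite_differences_small_model():
    rng = np.random.default_rng(2)
    p = init_content_params(8, 4, 4, 2, rng)
    rp = init_recognition_params(8, 2, 5, 5, rng)
    rec = random_record(rng, 8, 4)
    eps = rng.standard_normal(2)
    _, grads = elbo_grads(rec, p, rp, eps)
    arrays = named_arrays(p, rp)
    step = 1e-5
    for name, arr in arrays.items():
        flat = arr.reshape(-1)
        gflat = np.atleast_1d(grads[name]).reshape(-1)
        for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + step
            up = elbo_loss(rec, p, rp, eps)
            flat[i] = orig - step
            down = elbo_loss(rec, p, rp, eps)
            flat[i] = orig
            fd = -(up - down) / (2 * step)
            assert abs(fd - gflat[i]) <= 1e-4 * max(abs(fd), abs(gflat[i]), 1e-6), name


def _small_fit(corpus, **kw):
    from dataclasses import replace

    return fit(corpus, replace(SMALL_CFG, **kw))


def test_training_elbo_improves_on_synthetic_corpus(small_sim):
    corpus, _ = small_sim
    result = _small_fit(corpus, max_epochs=5, patience=5)
    hist = result.history
    assert len(hist) == 5
    assert hist[4]["train_elbo"] >= hist[0]["train_elbo"]


def test_fit_is_deterministic_given_seed(small_sim):
    corpus, _ = small_sim
    a = _small_fit(corpus, max_epochs=2)
    b = _small_fit(corpus, max_epochs=2)
    assert a.history == b.history
    assert a.best_epoch == b.best_epoch
    for k, arr in named_arrays(a.params, a.rec_params).items():
        np.testing.assert_array_equal(arr, named_arrays(b.params, b.rec_params)[k])


def test_gru_baseline_fit_has_no_recognition_params(small_sim):
    corpus, _ = small_sim
    result = _small_fit(corpus, max_epochs=1, model_variant="gru_baseline")
    assert result.rec_params is None


def test_predict_all_zero_checkpoint_gives_half(small_sim):
    corpus, _ = small_sim
    result = _small_fit(corpus, max_epochs=1)
    result.params = zero_content_params(
        corpus.vocabulary.size, SMALL_CFG.embed_dim, SMALL_CFG.hidden_dim,
        SMALL_CFG.n_topics,
    )
    result.rec_params = zero_recognition_params(
        corpus.vocabulary.size, SMALL_CFG.n_topics, 8, 8
    )
    for _, probs in predict(corpus, result, records=corpus.records[:3]):
        assert np.all(probs == 0.5)


def test_predict_mean_mode_is_deterministic(small_sim):
    corpus, _ = small_sim
    result = _small_fit(corpus, max_epochs=1)
    a = predict(corpus, result, records=corpus.records[:5])
    b = predict(corpus, result, records=corpus.records[:5])
    for (_, pa), (_, pb) in zip(a, b):
        np.testing.assert_array_equal(pa, pb)


def test_predict_rejects_vocabulary_mismatch(small_sim, tiny_corpus):
    corpus, _ = small_sim
    result = _small_fit(corpus, max_epochs=1)
    with pytest.raises(ValueError, match="vocabulary"):
        predict(tiny_corpus, result)


def test_causal_theta_context_runs_and_differs_from_full(small_sim):
    from dataclasses import replace

    corpus, _ = small_sim
    result = _small_fit(corpus, max_epochs=2)
    full = predict(corpus, result, records=corpus.records[:2])
    result_causal = result
    result_causal.config = replace(result.config, theta_context="causal")
    causal = predict(corpus, result_causal, records=corpus.records[:2])
    assert any(
        not np.allclose(pf, pc) for (_, pf), (_, pc) in zip(full, causal)
    )


def test_checkpoint_round_trip(small_sim, tmp_path):
    corpus, _ = small_sim
    result = _small_fit(corpus, max_epochs=1)
    path = tmp_path / "ck.npz"
    save_checkpoint(result, path)
    back = load_checkpoint(path)
    assert back.config == result.config
    assert back.vocab_hash == result.vocab_hash
    assert back.history == result.history
    for k, arr in named_arrays(result.params, result.rec_params).items():
        np.testing.assert_array_equal(arr, named_arrays(back.params, back.rec_params)[k])
    a = predict(corpus, result, records=corpus.records[:3])
    b = predict(corpus, back, records=corpus.records[:3])
    for (_, pa), (_, pb) in zip(a, b):
        np.testing.assert_array_equal(pa, pb)
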