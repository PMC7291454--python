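import numpy as np
import pytest

from mmtraj import hmm
from mmtraj.hmm import EVENT_DEATH, EVENT_DROPOUT, EVENT_NONE

from conftest import (align_full_transition, brute_force_path,
                      random_small_model, three_state_model)


# ----------------------------------------------------------------------
# fuzzy c-means initialisation
# ----------------------------------------------------------------------

def test_fuzzy_separated_clouds_have_crisp_membership():
    rng = np.random.default_rng(0)
    sd = 0.5
    a = rng.normal([0, 0], sd, size=(50, 2))
    b = rng.normal([10 * sd * np.sqrt(2), 0], sd, size=(50, 2))
    U = hmm.fuzzy_init(np.vstack([a, b]), 2, seed=1)
    own = np.maximum(U[:50].max(axis=1), U[50:].max(axis=1))
    # own-cloud membership: clouds separated by 10x the within-cloud SD
    labels = U.argmax(axis=1)
    assert (labels[:50] == labels[0]).all()
    assert (labels[50:] == labels[-1]).all()
    assert labels[0] != labels[-1]
    assert (U.max(axis=1) >= 0.9).all()


def test_fuzzy_identical_points_uniform_membership():
    X = np.ones((20, 3))
    U = hmm.fuzzy_init(X, 4, seed=0)
    assert np.allclose(U, 0.25)


def test_fuzzy_same_seed_identical():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(60, 2))
    assert np.array_equal(hmm.fuzzy_init(X, 3, seed=9),
                          hmm.fuzzy_init(X, 3, seed=9))
    assert (hmm.fuzzy_init(X, 3, seed=9).sum(axis=1)
            == pytest.approx(np.ones(60)))


def test_fuzzy_more_clusters_than_points_rejected():
    with pytest.raises(hmm.HmmError):
        hmm.fuzzy_init(np.zeros((3, 2)), 5)


# ----------------------------------------------------------------------
# Viterbi vs exhaustive enumeration
# ----------------------------------------------------------------------

@pytest.mark.parametrize("K", [1, 2, 3])
@pytest.mark.parametrize("T", [1, 3, 5])
@pytest.mark.parametrize("event", [EVENT_NONE, EVENT_DEATH, EVENT_DROPOUT])
def test_viterbi_equals_brute_force(K, T, event):
    rng = np.random.default_rng(K * 100 + T * 10 + event)
    model = random_small_model(K, 2, rng)
    T_alive = T if event == EVENT_NONE else max(T - 1, 1)
    scores = rng.normal(scale=3, size=(T_alive, 2))
    expected = brute_force_path(model, scores, event)
    got = hmm.viterbi(model, scores, event=event)
    assert np.array_equal(got, expected)


def test_viterbi_single_state_constant_path():
    rng = np.random.default_rng(0)
    model = random_small_model(1, 2, rng)
    path = hmm.viterbi(model, rng.normal(size=(4, 2)))
    assert np.array_equal(path, np.zeros(4))


def test_decoded_death_at_event_wave():
    model = three_state_model()
    scores = np.zeros((2, 2))  # alive waves 0-1, dies at wave 2
    path = hmm.viterbi(model, scores, event=EVENT_DEATH)
    assert path[-1] == model.death_state
    assert (path[:-1] < model.K_live).all()


# ----------------------------------------------------------------------
# Baum-Welch
# ----------------------------------------------------------------------

def test_single_state_mle_equals_sample_moments():
    rng = np.random.default_rng(4)
    n, T, d = 200, 5, 2
    scores = rng.normal(1.5, 2.0, size=(n, T, d))
    data = hmm.SeqData(patient_ids=np.arange(n), scores=scores,
                       lengths=np.full(n, T), event=np.zeros(n, dtype=int))
    fit = hmm.baum_welch(data, 1, seed=0, max_iter=50)
    X = scores.reshape(-1, d)
    assert np.allclose(fit.means[0], X.mean(axis=0), atol=1e-8)
    assert np.allclose(fit.variances[0], X.var(axis=0), atol=1e-8)


def test_log_likelihood_trace_nondecreasing():
    truth = three_state_model()
    data = hmm.sample_sequences(truth, 500, 5, seed=8)
    fit = hmm.baum_welch(data, 3, seed=2, max_iter=100)
    trace = np.array(fit.log_likelihood_trace)
    assert (np.diff(trace) >= -1e-9 * np.abs(trace[:-1])).all()


def test_transition_recovery_three_states():
    truth = three_state_model()
    data = hmm.sample_sequences(truth, 2000, 5, seed=30)
    fit = hmm.select_model(data, [3], restarts=10, seed=30)
    aligned = align_full_transition(fit, truth)
    assert np.abs(aligned - truth.A).max() <= 0.05


def test_absorption_hazard_tracks_truth():
    """Estimated death-transition mass per cluster tracks the simulated
    cluster-specific mortality."""
    truth = three_state_model()
    data = hmm.sample_sequences(truth, 5000, 5, seed=13)
    fit = hmm.select_model(data, [3], restarts=5, seed=13)
    aligned = align_full_transition(fit, truth)
    death = truth.death_state
    assert np.abs(aligned[:3, death] - truth.A[:3, death]).max() <= 0.05


def test_gamma_rows_sum_to_one_and_event_decoding():
    truth = three_state_model()
    data = hmm.sample_sequences(truth, 300, 5, seed=21)
    fit = hmm.baum_welch(data, 3, seed=1, max_iter=60)
    traj = hmm.decode(fit, data)
    g = traj[[c for c in traj.columns if c.startswith("gamma_")]].to_numpy()
    assert np.allclose(g.sum(axis=1), 1.0, atol=1e-9)
    # decoded absorbing states appear exactly at recorded event waves
    ev = data.event != EVENT_NONE
    for pid, length, event in zip(data.patient_ids[ev], data.lengths[ev],
                                  data.event[ev]):
        rows = traj[traj["patient_id"] == pid].sort_values("year_index")
        expected = fit.death_state if event == EVENT_DEATH else fit.dropout_state
        assert rows["decoded_state"].iloc[-1] == expected
        assert (rows["decoded_state"].iloc[:-1] < fit.K_live).all()


def test_select_model_single_candidate_unconditional():
    truth = three_state_model()
    data = hmm.sample_sequences(truth, 200, 5, seed=3)
    fit = hmm.select_model(data, [2], restarts=2, seed=0)
    assert fit.K_live == 2


def test_select_model_deterministic():
    truth = three_state_model()
    data = hmm.sample_sequences(truth, 300, 5, seed=6)
    a = hmm.select_model(data, [2, 3], restarts=2, seed=5)
    b = hmm.select_model(data, [2, 3], restarts=2, seed=5)
    assert a.K_live == b.K_live
    assert np.array_equal(a.A, b.A)


def test_heldout_criterion_runs():
    truth = three_state_model()
    data = hmm.sample_sequences(truth, 400, 5, seed=17)
    fit = hmm.select_model(data, [2, 3], criterion="heldout", restarts=2, seed=1)
    assert fit.K_live in (2, 3)


def test_model_json_roundtrip(tmp_path):
    truth = three_state_model()
    truth.to_json(tmp_path / "m.json")
    back = hmm.HmmModel.from_json(tmp_path / "m.json")
    data = hmm.sample_sequences(truth, 50, 5, seed=2)
    assert hmm.log_likelihood(data, back) == pytest.approx(
        hmm.log_likelihood(data, truth))
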