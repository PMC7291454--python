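import numpy as np
import pytest

from mmtraj import config, hmm, phenotypes, simulate


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = config.default_config("tiny", seed=7)
    return simulate.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_phenotypes(tiny_cohort):
    return phenotypes.phenotype_cohort(tiny_cohort)


def three_state_model() -> hmm.HmmModel:
    """Known 3-state chain with absorbing death/drop-out, well-separated
    Gaussian emissions; ground truth for recovery and selection studies."""
    A = np.array([
        [0.70, 0.10, 0.10, 0.07, 0.03],
        [0.10, 0.72, 0.08, 0.06, 0.04],
        [0.05, 0.10, 0.70, 0.10, 0.05],
        [0.00, 0.00, 0.00, 1.00, 0.00],
        [0.00, 0.00, 0.00, 0.00, 1.00],
    ])
    return hmm.HmmModel(
        K_live=3, d=2, pi=np.array([0.5, 0.3, 0.2]), A=A,
        means=np.array([[0.0, 0.0], [4.0, 4.0], [-4.0, 4.0]]),
        variances=np.ones((3, 2)),
    )


def align_full_transition(fit: hmm.HmmModel, truth: hmm.HmmModel) -> np.ndarray:
    """Relabel a fitted transition matrix onto the truth's state order."""
    perm = hmm.align_states(fit.means, truth.means)
    S = truth.n_states
    full = np.concatenate([perm, [truth.death_state, truth.dropout_state]])
    out = np.zeros((S, S))
    for i in range(S):
        for j in range(S):
            out[full[i], full[j]] = fit.A[i, j]
    return out


def brute_force_path(model: hmm.HmmModel, scores: np.ndarray,
                     event: int) -> np.ndarray:
    """Exhaustive-enumeration Viterbi oracle for small K and T.

    Scores cover the alive waves; if the sequence ends in an event the
    admissible paths place the corresponding absorbing state last.
    Independent of the dynamic-programming implementation.
    """
    from itertools import product

    K = model.K_live
    T_alive = len(scores)

    def emis(t, k):
        v = model.variances[k]
        return float(-0.5 * np.sum(np.log(2 * np.pi * v)
                                   + (scores[t] - model.means[k]) ** 2 / v))

    best, best_lp = None, -np.inf
    for path in product(range(K), repeat=T_alive):
        lp = np.log(model.pi[path[0]]) + emis(0, path[0])
        for t in range(1, T_alive):
            lp += np.log(model.A[path[t - 1], path[t]]) + emis(t, path[t])
        full = list(path)
        if event != hmm.EVENT_NONE:
            s_ev = model.death_state if event == hmm.EVENT_DEATH \
                else model.dropout_state
            lp += np.log(model.A[path[-1], s_ev])
            full.append(s_ev)
        if lp > best_lp:
            best_lp, best = lp, full
    return np.array(best)


def random_small_model(K: int, d: int, rng: np.random.Generator) -> hmm.HmmModel:
    """Random valid small HMM for oracle-equivalence checks."""
    S = K + 2
    A = rng.dirichlet(np.ones(S), size=K)
    A = np.vstack([A, np.eye(S)[K:]])
    pi = rng.dirichlet(np.ones(K))
    means = rng.normal(scale=3.0, size=(K, d))
    variances = rng.uniform(0.5, 2.0, size=(K, d))
    return hmm.HmmModel(K_live=K, d=d, pi=pi, A=A, means=means,
                        variances=variances)
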