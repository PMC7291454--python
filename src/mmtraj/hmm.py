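"""Hidden Markov model over patient trajectories in factor-score space.

States are K_live multimorbidity-pattern clusters plus two observed
absorbing states (death, drop-out). Living states emit diagonal-covariance
Gaussians on the PCAmix factor scores; the absorbing states are observed —
their emission likelihood is a point mass on the recorded event and their
transition rows are frozen to the identity. Parameters are estimated by
Baum-Welch (EM, log-space), trajectories decoded by Viterbi, and the number
of clusters selected by BIC or held-out likelihood over seeded restarts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


def _lse(x: np.ndarray, axis: int) -> np.ndarray:
    """log-sum-exp tolerating all -inf slices (returns -inf there)."""
    m = np.max(x, axis=axis, keepdims=True)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.exp(x - m_safe).sum(axis=axis)) + np.squeeze(m_safe, axis)
    return out

from .config import ALIVE, DEATH, DROPOUT

logger = logging.getLogger(__name__)

EVENT_NONE, EVENT_DEATH, EVENT_DROPOUT = 0, 1, 2


class HmmError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# Sequence container
# ----------------------------------------------------------------------

@dataclass
class SeqData:
    """Padded per-patient observation sequences.

    ``scores`` is (n, T, d) with NaN beyond each patient's last row and at
    the (unscored) event row; ``lengths`` counts rows per patient including
    the event row; ``event`` records how each sequence ends.
    """

    patient_ids: np.ndarray
    scores: np.ndarray
    lengths: np.ndarray
    event: np.ndarray  # EVENT_NONE / EVENT_DEATH / EVENT_DROPOUT

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def T(self) -> int:
        return self.scores.shape[1]

    @property
    def d(self) -> int:
        return self.scores.shape[2]

    def alive_mask(self) -> np.ndarray:
        """(n, T) True where the row exists and the patient is alive."""
        t = np.arange(self.T)[None, :]
        exists = t < self.lengths[:, None]
        last_is_event = self.event[:, None] != EVENT_NONE
        event_row = t == (self.lengths[:, None] - 1)
        return exists & ~(last_is_event & event_row)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, score_cols) -> "SeqData":
        """Build from a long table with patient_id, year_index, status, scores.

        Waves must be contiguous from 0; the event row, if any, is last.
        """
        df = df.sort_values(["patient_id", "year_index"])
        pids = df["patient_id"].unique()
        idx = {p: i for i, p in enumerate(pids)}
        n = len(pids)
        T = int(df["year_index"].max()) + 1
        d = len(score_cols)
        scores = np.full((n, T, d), np.nan)
        lengths = np.zeros(n, dtype=np.int64)
        event = np.zeros(n, dtype=np.int64)
        rows = df["patient_id"].map(idx).to_numpy()
        waves = df["year_index"].to_numpy()
        scores[rows, waves] = df[list(score_cols)].to_numpy(dtype=float)
        np.maximum.at(lengths, rows, waves + 1)
        status = df["status"].to_numpy()
        event_rows = status != ALIVE
        event[rows[event_rows]] = np.where(
            status[event_rows] == DEATH, EVENT_DEATH, EVENT_DROPOUT)
        return cls(patient_ids=pids, scores=scores, lengths=lengths, event=event)


# ----------------------------------------------------------------------
# Model container
# ----------------------------------------------------------------------

@dataclass
class HmmModel:
    K_live: int
    d: int
    pi: np.ndarray  # (K_live,), initial distribution over living states
    A: np.ndarray  # (K_live+2, K_live+2) with frozen absorbing rows
    means: np.ndarray  # (K_live, d)
    variances: np.ndarray  # (K_live, d)
    log_likelihood_trace: list = field(default_factory=list)
    seed: int | None = None

    @property
    def n_states(self) -> int:
        return self.K_live + 2

    @property
    def death_state(self) -> int:
        return self.K_live

    @property
    def dropout_state(self) -> int:
        return self.K_live + 1

    def n_parameters(self) -> int:
        K, S, d = self.K_live, self.n_states, self.d
        return (K - 1) + K * (S - 1) + 2 * K * d

    def to_json(self, path) -> None:
        obj = {
            "K_live": self.K_live, "d": self.d,
            "pi": self.pi.tolist(), "A": self.A.tolist(),
            "means": self.means.tolist(), "variances": self.variances.tolist(),
            "log_likelihood_trace": list(self.log_likelihood_trace),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "HmmModel":
        with open(path) as fh:
            obj = json.load(fh)
        for k in ("pi", "A", "means", "variances"):
            obj[k] = np.asarray(obj[k])
        return cls(**obj)


# ----------------------------------------------------------------------
# Fuzzy c-means initialisation
# ----------------------------------------------------------------------

def fuzzy_init(X: np.ndarray, K_live: int, seed: int = 0, m: float = 2.0,
               max_iter: int = 200, tol: float = 1e-7) -> np.ndarray:
    """Fuzzy c-means memberships (fuzzifier ``m``) over living clusters.

    Returns an (n, K_live) row-stochastic responsibility matrix. Points
    coinciding with several centres split their membership equally among
    the zero-distance centres.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if K_live > n:
        raise HmmError(f"K_live={K_live} exceeds number of points {n}")
    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=K_live, replace=False)]
    power = 2.0 / (m - 1.0)
    U = np.full((n, K_live), 1.0 / K_live)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", over="ignore"):
            inv = d2 ** (-power / 2.0)
        U_new = np.where(np.isfinite(inv), inv, 0.0)
        U_new[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        U_new = U_new / U_new.sum(axis=1, keepdims=True)
        W = U_new ** m
        denom = W.sum(axis=0)
        centers_new = np.where(denom[:, None] > 0,
                               (W.T @ X) / np.maximum(denom, 1e-300)[:, None],
                               centers)
        shift = np.abs(U_new - U).max()
        U, centers = U_new, centers_new
        if shift < tol:
            break
    return U


# ----------------------------------------------------------------------
# Emission likelihoods and message passing
# ----------------------------------------------------------------------

def _log_emissions(data: SeqData, model: HmmModel) -> np.ndarray:
    """(n, T, S) log-emission matrix with observed absorbing states."""
    n, T, S, K = data.n, data.T, model.n_states, model.K_live
    logB = np.full((n, T, S), -np.inf)
    alive = data.alive_mask()
    X = data.scores[alive]  # (N, d)
    var = model.variances
    const = -0.5 * (model.d * np.log(2 * np.pi) + np.log(var).sum(axis=1)
                    + (model.means ** 2 / var).sum(axis=1))
    # Gaussian-diagonal loglik expanded into two matrix products
    ll = const[None, :] + X @ (model.means / var).T - 0.5 * (X ** 2) @ (1.0 / var).T
    if np.any(np.isnan(ll)):
        raise HmmError("NaN emission log-likelihood (check factor scores)")
    live_block = np.full((n, T, K), -np.inf)
    live_block[alive] = ll
    logB[:, :, :K] = live_block
    # event rows: point mass on the recorded absorbing state
    has_event = data.event != EVENT_NONE
    i = np.where(has_event)[0]
    t_ev = data.lengths[i] - 1
    s_ev = np.where(data.event[i] == EVENT_DEATH, K, K + 1)
    logB[i, t_ev, :] = -np.inf
    logB[i, t_ev, s_ev] = 0.0
    return logB


def _forward(data: SeqData, model: HmmModel, logB: np.ndarray):
    n, T, S = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logpi = np.concatenate([np.log(model.pi), [-np.inf, -np.inf]])
    alpha = np.full((n, T, S), -np.inf)
    alpha[:, 0] = logpi[None, :] + logB[:, 0]
    for t in range(1, T):
        act = data.lengths > t
        if not act.any():
            break
        prev = alpha[act, t - 1]
        alpha[act, t] = _lse(prev[:, :, None] + logA[None, :, :], axis=1) \
            + logB[act, t]
    loglik = _lse(alpha[np.arange(n), data.lengths - 1], axis=1)
    if np.any(np.isnan(loglik)) or np.any(loglik == -np.inf):
        bad = int(np.where(~np.isfinite(loglik))[0][0])
        raise HmmError(f"non-finite forward likelihood for patient index {bad}")
    return alpha, loglik


def _backward(data: SeqData, model: HmmModel, logB: np.ndarray) -> np.ndarray:
    n, T, S = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
    beta = np.full((n, T, S), -np.inf)
    beta[np.arange(n), data.lengths - 1] = 0.0
    for t in range(T - 2, -1, -1):
        act = data.lengths > t + 1
        if not act.any():
            continue
        nxt = logB[act, t + 1] + beta[act, t + 1]
        beta[act, t] = _lse(logA[None, :, :] + nxt[:, None, :], axis=2)
    return beta


def log_likelihood(data: SeqData, model: HmmModel) -> float:
    logB = _log_emissions(data, model)
    _, ll = _forward(data, model, logB)
    return float(ll.sum())


# ----------------------------------------------------------------------
# Baum-Welch
# ----------------------------------------------------------------------

def _init_model(data: SeqData, K_live: int, seed: int,
                var_floor: float) -> HmmModel:
    baseline = data.scores[:, 0, :]
    resp = fuzzy_init(baseline, K_live, seed=seed)
    S = K_live + 2
    pi = resp.mean(axis=0)
    pi = pi / pi.sum()
    w = resp.sum(axis=0)
    means = (resp.T @ baseline) / w[:, None]
    var = (resp.T @ baseline ** 2) / w[:, None] - means ** 2
    var = np.maximum(var, var_floor)
    # empirical per-transition event hazards
    trans_total = max(int((data.lengths - 1).sum()), 1)
    p_death = (data.event == EVENT_DEATH).sum() / trans_total
    p_drop = (data.event == EVENT_DROPOUT).sum() / trans_total
    stay = 0.7 * (1 - p_death - p_drop)
    A = np.zeros((S, S))
    for k in range(K_live):
        A[k, :K_live] = (1 - p_death - p_drop - stay) / max(K_live - 1, 1)
        A[k, k] = stay if K_live > 1 else 1 - p_death - p_drop
        A[k, K_live] = p_death
        A[k, K_live + 1] = p_drop
        A[k] /= A[k].sum()
    A[K_live, K_live] = 1.0
    A[K_live + 1, K_live + 1] = 1.0
    return HmmModel(K_live=K_live, d=data.d, pi=pi, A=A, means=means,
                    variances=var, seed=seed)


def baum_welch(data: SeqData, K_live: int, init: HmmModel | None = None,
               seed: int = 0, tol: float = 1e-6, max_iter: int = 500,
               var_floor: float = 1e-6) -> HmmModel:
    """Fit HMM parameters by EM in log space.

    Death and drop-out are observed absorbing states: their transition rows
    stay frozen to the identity and no emission parameters are estimated for
    them. The log-likelihood trace is nondecreasing up to numerical
    tolerance; a degenerate emission variance is floored with a warning.
    """
    model = init if init is not None else _init_model(data, K_live, seed, var_floor)
    K, S = model.K_live, model.n_states
    alive = data.alive_mask()
    X = data.scores[alive]
    trace = []
    prev_ll = -np.inf
    for it in range(max_iter):
        logB = _log_emissions(data, model)
        try:
            alpha, ll_i = _forward(data, model, logB)
        except HmmError as exc:
            raise HmmError(f"numerical failure at EM iteration {it}: {exc}") from exc
        beta = _backward(data, model, logB)
        ll = float(ll_i.sum())
        trace.append(ll)

        log_gamma = alpha + beta - ll_i[:, None, None]
        gamma = np.exp(log_gamma)
        t_idx = np.arange(data.T)[None, :]
        exists = t_idx < data.lengths[:, None]
        gamma[~exists] = 0.0

        # transition expectations
        with np.errstate(divide="ignore"):
            logA = np.log(model.A)
        xi_sum = np.zeros((S, S))
        for t in range(data.T - 1):
            act = data.lengths > t + 1
            if not act.any():
                continue
            log_xi = (alpha[act, t, :, None] + logA[None, :, :]
                      + logB[act, t + 1, None, :] + beta[act, t + 1, None, :]
                      - ll_i[act, None, None])
            xi_sum += np.exp(log_xi).sum(axis=0)

        # M-step
        pi = gamma[:, 0, :K].sum(axis=0)
        model.pi = pi / pi.sum()
        A = model.A.copy()
        for k in range(K):
            mass = xi_sum[k].sum()
            if mass > 0:
                A[k] = xi_sum[k] / mass
        A[K] = 0.0
        A[K, K] = 1.0
        A[K + 1] = 0.0
        A[K + 1, K + 1] = 1.0
        model.A = A

        w = gamma[:, :, :K][alive]  # (N, K)
        wsum = w.sum(axis=0)
        ok = wsum > 1e-12
        means = model.means.copy()
        var = model.variances.copy()
        means[ok] = (w.T @ X)[ok] / wsum[ok, None]
        var[ok] = (w.T @ X ** 2)[ok] / wsum[ok, None] - means[ok] ** 2
        if np.any(var[ok] < var_floor):
            logger.warning("EM iteration %d: emission variance floored at %g",
                           it, var_floor)
        var[ok] = np.maximum(var[ok], var_floor)
        model.means, model.variances = means, var

        if prev_ll > -np.inf and (ll - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = ll
    model.log_likelihood_trace = trace
    return model


# ----------------------------------------------------------------------
# Decoding
# ----------------------------------------------------------------------

def viterbi(model: HmmModel, scores, event: int = EVENT_NONE) -> np.ndarray:
    """Most probable state path for one patient's sequence.

    ``scores`` is (T_i, d) for the alive waves; if ``event`` is death or
    drop-out an additional terminal event row is appended to the path.
    """
    data = SeqData(
        patient_ids=np.array([0]),
        scores=_pad_single(np.asarray(scores, dtype=float), event, model.d),
        lengths=np.array([len(scores) + (1 if event != EVENT_NONE else 0)]),
        event=np.array([event]),
    )
    return viterbi_batch(model, data)[0, :data.lengths[0]]


def _pad_single(scores: np.ndarray, event: int, d: int) -> np.ndarray:
    T = len(scores) + (1 if event != EVENT_NONE else 0)
    out = np.full((1, T, d), np.nan)
    out[0, :len(scores)] = scores
    return out


def viterbi_batch(model: HmmModel, data: SeqData) -> np.ndarray:
    """Viterbi paths for all patients; -1 beyond each patient's length."""
    logB = _log_emissions(data, model)
    n, T, S = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logpi = np.concatenate([np.log(model.pi), [-np.inf, -np.inf]])
    delta = np.full((n, T, S), -np.inf)
    psi = np.zeros((n, T, S), dtype=np.int64)
    delta[:, 0] = logpi[None, :] + logB[:, 0]
    for t in range(1, T):
        act = data.lengths > t
        if not act.any():
            break
        cand = delta[act, t - 1][:, :, None] + logA[None, :, :]
        psi[act, t] = cand.argmax(axis=1)
        delta[act, t] = cand.max(axis=1) + logB[act, t]
    paths = np.full((n, T), -1, dtype=np.int64)
    last = data.lengths - 1
    paths[np.arange(n), last] = delta[np.arange(n), last].argmax(axis=1)
    for t in range(T - 1, 0, -1):
        act = data.lengths > t
        paths[act, t - 1] = psi[act, t, paths[act, t]]
    return paths


def decode(model: HmmModel, data: SeqData) -> pd.DataFrame:
    """Viterbi path plus posterior (gamma) memberships per patient-wave."""
    paths = viterbi_batch(model, data)
    logB = _log_emissions(data, model)
    alpha, ll_i = _forward(data, model, logB)
    beta = _backward(data, model, logB)
    gamma = np.exp(alpha + beta - ll_i[:, None, None])
    rows = []
    n, T = paths.shape
    exists = np.arange(T)[None, :] < data.lengths[:, None]
    pid, wave = np.nonzero(exists)
    out = pd.DataFrame({
        "patient_id": data.patient_ids[pid],
        "year_index": wave,
        "decoded_state": paths[pid, wave],
    })
    g = gamma[pid, wave]
    g = g / g.sum(axis=1, keepdims=True)
    for s in range(model.n_states):
        out[f"gamma_{s}"] = g[:, s]
    baseline = pd.Series(paths[:, 0], index=data.patient_ids)
    out["baseline_cluster"] = out["patient_id"].map(baseline)
    return out


# ----------------------------------------------------------------------
# Sampling (parameter-recovery harnesses, simulation studies)
# ----------------------------------------------------------------------

def sample_sequences(model: HmmModel, n: int, T: int, seed: int = 0) -> SeqData:
    """Draw sequences from a known model (Gaussian emissions, absorbing ends).

    Useful as ground truth in parameter-recovery and model-selection
    studies: latent paths follow ``model.A`` from ``model.pi``; an absorbing
    state terminates the sequence at the wave it is entered.
    """
    rng = np.random.default_rng(seed)
    K, S = model.K_live, model.n_states
    states = np.empty((n, T), dtype=np.int64)
    states[:, 0] = rng.choice(K, size=n, p=model.pi)
    cum = np.cumsum(model.A, axis=1)
    for t in range(1, T):
        u = rng.random(n)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
    alive = states < K
    absorbed = np.where(alive.all(axis=1), T, np.argmin(alive, axis=1))
    lengths = np.minimum(absorbed + 1, T)
    scores = np.full((n, T, model.d), np.nan)
    for t in range(T):
        live = alive[:, t]
        st = states[live, t]
        scores[live, t] = (model.means[st]
                           + np.sqrt(model.variances[st])
                           * rng.standard_normal((live.sum(), model.d)))
    event = np.zeros(n, dtype=np.int64)
    ev = absorbed < T
    event[ev] = np.where(states[np.arange(n), absorbed.clip(max=T - 1)][ev]
                         == model.death_state, EVENT_DEATH, EVENT_DROPOUT)
    data = SeqData(patient_ids=np.arange(n), scores=scores,
                   lengths=lengths, event=event)
    data.true_states = states  # ground truth, for recovery tests
    return data


# ----------------------------------------------------------------------
# Model selection and label alignment
# ----------------------------------------------------------------------

def select_model(data: SeqData, candidates, criterion: str = "bic",
                 restarts: int = 10, seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 500, heldout_frac: float = 0.2):
    """Fit each candidate K_live from seeded restarts; return the winner.

    ``criterion``: "bic" (default) or "heldout" (mean per-row log-likelihood
    on a seeded 20% patient split). Restart ties on the criterion break
    deterministically toward the lowest restart seed.
    """
    candidates = list(candidates)
    if not candidates:
        raise HmmError("no candidate models given")
    rng = np.random.default_rng(seed)
    if criterion == "heldout":
        n = data.n
        test = np.zeros(n, dtype=bool)
        test[rng.choice(n, size=max(1, int(round(heldout_frac * n))),
                        replace=False)] = True
        train_data = _subset(data, ~test)
        test_data = _subset(data, test)
    else:
        train_data, test_data = data, None

    results, failures = [], []
    for K in candidates:
        best = None
        for r in range(restarts):
            try:
                fit = baum_welch(train_data, K, seed=seed * 1000 + r,
                                 tol=tol, max_iter=max_iter)
            except HmmError as exc:
                failures.append((K, r, str(exc)))
                continue
            ll = fit.log_likelihood_trace[-1]
            if best is None or ll > best[0] + 1e-12:
                best = (ll, r, fit)
        if best is None:
            continue
        ll, _, fit = best
        n_obs = int(data.lengths.sum())
        if criterion == "bic":
            score = -2.0 * ll + fit.n_parameters() * np.log(n_obs)
        elif criterion == "heldout":
            score = -log_likelihood(test_data, fit) / int(test_data.lengths.sum())
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        results.append((score, K, fit))
    if not results:
        raise HmmError(f"all candidate fits failed: {failures}")
    results.sort(key=lambda r: (r[0], r[1]))
    score, K, fit = results[0]
    logger.info("selected K_live=%d by %s=%.2f", K, criterion, score)
    return fit


def _subset(data: SeqData, mask: np.ndarray) -> SeqData:
    return SeqData(patient_ids=data.patient_ids[mask],
                   scores=data.scores[mask], lengths=data.lengths[mask],
                   event=data.event[mask])


def align_states(means_est: np.ndarray, means_true: np.ndarray) -> np.ndarray:
    """Permutation mapping estimated state k to the nearest true state.

    Minimum-cost bipartite matching on Euclidean emission-mean distances;
    ``perm[k]`` is the true label of estimated state k.
    """
    cost = np.linalg.norm(means_est[:, None, :] - means_true[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(means_est), dtype=np.int64)
    perm[rows] = cols
    return perm
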