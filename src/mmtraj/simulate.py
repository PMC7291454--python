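"""Synthetic longitudinal cohort generator.

Draws an elderly primary-care cohort following a latent Markov chain over K
multimorbidity clusters with absorbing death and drop-out states. Disease
flags are chronic (monotone within patient), drug packages are
negative-binomial counts, labs are log-normal per cluster, and the
deprivation quintile (MEDEA) is missing completely at random at a
configurable rate.

Output is one long table with one row per patient per observed wave, up to
and including the wave at which death or drop-out occurs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ALIVE, DEATH, DROPOUT, MEDEA_LEVELS, MEDEA_PROBS, SimConfig

DISEASE_PREFIX = "disease_"
DRUG_PREFIX = "drug_"


def disease_columns(n: int) -> list[str]:
    return [f"{DISEASE_PREFIX}{i:02d}" for i in range(n)]


def drug_columns(n: int) -> list[str]:
    return [f"{DRUG_PREFIX}{i:02d}" for i in range(n)]


def _sample_states(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent state path (n_patients, n_years) from the configured chain."""
    n, T, K = config.n_patients, config.n_years, config.n_clusters
    states = np.empty((n, T), dtype=np.int64)
    states[:, 0] = rng.choice(K, size=n, p=config.initial_distribution)
    cum = np.cumsum(config.transition_matrix, axis=1)
    for t in range(1, T):
        u = rng.random(n)
        rows = cum[states[:, t - 1]]
        states[:, t] = (u[:, None] > rows).sum(axis=1)
    return states


def _negbin(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; mean given, size=dispersion."""
    lam = rng.gamma(shape=size_param, scale=np.maximum(mean, 1e-12) / size_param)
    return rng.poisson(lam)


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Simulate a cohort table from a validated configuration.

    Returns a long DataFrame with one row per patient per wave until (and
    including) the wave of death or drop-out. Columns: patient_id,
    year_index, age_baseline, sex, medea, disease_00.., drug_00..,
    creatinine, alp, alt, ggt, visits, status, true_state.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T, K = config.n_patients, config.n_years, config.n_clusters
    death, dropout = config.death_state, config.dropout_state

    states = _sample_states(config, rng)
    alive = states < K
    # first wave at which the patient is absorbed, T if never
    absorbed = np.where(alive.all(axis=1), T, np.argmin(alive, axis=1))
    # rows exist for waves 0 .. min(absorbed, T-1); event wave keeps one row
    last_wave = np.minimum(absorbed, T - 1)

    lo, hi = config.age_range
    age = lo + (hi - lo) * rng.beta(1.5, 3.5, size=n)
    female = rng.random(n) < config.sex_ratio
    medea = rng.choice(len(MEDEA_LEVELS), size=n, p=MEDEA_PROBS / MEDEA_PROBS.sum())
    medea_missing = rng.random(n) < config.medea_missing_rate

    dis_cols = disease_columns(config.n_diseases)
    drug_cols = drug_columns(config.n_drugs)

    # Per-wave draws; chronic-disease flags made persistent by running max.
    flags = np.zeros((n, T, config.n_diseases), dtype=np.int8)
    packages = np.zeros((n, T, config.n_drugs), dtype=np.int64)
    labs = {name: np.full((n, T), np.nan) for name in config.lab_params}
    visits = np.zeros((n, T), dtype=np.int64)

    for t in range(T):
        live = alive[:, t]
        st = states[live, t]
        draw = rng.random((live.sum(), config.n_diseases)) < config.disease_prevalence[st]
        flags[live, t] = draw
        if t > 0:
            flags[:, t] = np.maximum(flags[:, t], flags[:, t - 1])
        packages[live, t] = _negbin(rng, config.package_mean[st],
                                    config.package_dispersion)
        for name, lp in config.lab_params.items():
            labs[name][live, t] = np.exp(
                np.log(lp.median[st]) + lp.sigma[st] * rng.standard_normal(live.sum())
            )
        visits[live, t] = rng.poisson(config.visit_mean[st]) if config.visit_mean is not None \
            else rng.poisson(8.0, size=live.sum())

    keep = np.arange(T)[None, :] <= last_wave[:, None]
    pid, wave = np.nonzero(keep)

    status = np.where(states[pid, wave] == death, DEATH,
                      np.where(states[pid, wave] == dropout, DROPOUT, ALIVE))

    cols = {
        "patient_id": pid,
        "year_index": wave,
        "age_baseline": np.round(age[pid], 1),
        "sex": np.where(female[pid], "female", "male"),
        "medea": pd.array(
            [None if medea_missing[p] else MEDEA_LEVELS[medea[p]] for p in pid],
            dtype="string"),
        "status": status,
        "true_state": states[pid, wave],
        "visits": visits[pid, wave],
    }
    for j, c in enumerate(dis_cols):
        cols[c] = flags[pid, wave, j]
    for j, c in enumerate(drug_cols):
        cols[c] = packages[pid, wave, j]
    for name in ("creatinine", "alp", "alt", "ggt"):
        cols[name] = labs[name][pid, wave]
    return pd.DataFrame(cols)
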