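import numpy as np
import pandas as pd
import pytest

from mmtraj import config, simulate
from mmtraj.config import ALIVE, ConfigError, LabParams, default_config


def _single_state_config(n=300, death=0.0, dropout=0.0, seed=0):
    K = 1
    A = np.array([[1.0 - death - dropout, death, dropout],
                  [0, 1, 0], [0, 0, 1.0]])
    return config.SimConfig(
        n_patients=n, n_clusters=K, n_diseases=4, n_drugs=3,
        disease_prevalence=np.full((K, 4), 0.3),
        package_mean=np.full((K, 3), 1.0),
        transition_matrix=A, initial_distribution=np.array([1.0]),
        lab_params={k: LabParams(np.full(K, m), np.full(K, 0.2))
                    for k, m in (("creatinine", 0.8), ("alp", 80.0),
                                 ("alt", 20.0), ("ggt", 25.0))},
        visit_mean=np.array([8.0]), seed=seed,
    )


def test_single_state_chain_stays_in_state_zero():
    cohort = simulate.simulate_cohort(_single_state_config())
    assert (cohort["true_state"] == 0).all()
    assert (cohort["status"] == ALIVE).all()
    # every patient observed for all five waves
    assert cohort.groupby("patient_id")["year_index"].count().eq(5).all()


def test_medea_missing_fraction_close_to_configured():
    cfg = default_config("paperlike", n_patients=10000, seed=11)
    cohort = simulate.simulate_cohort(cfg)
    base = cohort[cohort["year_index"] == 0]
    frac = base["medea"].isna().mean()
    se = np.sqrt(0.07 * 0.93 / len(base))
    assert abs(frac - 0.07) < 3 * se


def test_per_wave_death_hazard_matches_binomial_oracle():
    cfg = _single_state_config(n=5000, death=0.2, seed=3)
    cohort = simulate.simulate_cohort(cfg)
    # per-wave hazard: deaths observed at wave t among those alive at t-1
    for t in range(1, 5):
        at_risk = cohort[(cohort["year_index"] == t - 1)
                         & (cohort["status"] == ALIVE)]["patient_id"]
        now = cohort[(cohort["year_index"] == t)
                     & cohort["patient_id"].isin(at_risk)]
        hazard = (now["status"] == "dead").mean()
        se = np.sqrt(0.2 * 0.8 / len(at_risk))
        assert abs(hazard - 0.2) < 3 * se, f"wave {t}: hazard {hazard:.3f}"


def test_no_rows_after_absorption_and_absorption_probability():
    cfg = default_config("tiny", n_patients=5000, seed=5)
    cohort = simulate.simulate_cohort(cfg)
    last = cohort.sort_values("year_index").groupby("patient_id").tail(1)
    events = last[last["status"] != ALIVE]
    # closure: the event row is each absorbed patient's final row
    merged = cohort.merge(events[["patient_id", "year_index"]],
                          on="patient_id", suffixes=("", "_event"))
    assert (merged["year_index"] <= merged["year_index_event"]).all()
    # analytic absorption probability after T-1 transitions
    A = cfg.transition_matrix
    p = np.zeros(cfg.n_states)
    p[:cfg.n_clusters] = cfg.initial_distribution
    for _ in range(cfg.n_years - 1):
        p = p @ A
    expected = p[cfg.n_clusters:].sum()
    observed = len(events) / cfg.n_patients
    se = np.sqrt(expected * (1 - expected) / cfg.n_patients)
    assert abs(observed - expected) < 3 * se


def test_baseline_prevalence_converges_to_configured():
    cfg = default_config("tiny", n_patients=8000, seed=2)
    cohort = simulate.simulate_cohort(cfg)
    base = cohort[cohort["year_index"] == 0]
    dis = simulate.disease_columns(cfg.n_diseases)
    for k in range(cfg.n_clusters):
        grp = base[base["true_state"] == k]
        emp = grp[dis].mean().to_numpy()
        truth = cfg.disease_prevalence[k]
        se = np.sqrt(truth * (1 - truth) / len(grp))
        assert np.all(np.abs(emp - truth) < 3 * np.maximum(se, 1e-6)), \
            f"cluster {k}: max dev {np.abs(emp - truth).max():.4f}"


def test_same_seed_byte_identical():
    cfg = default_config("tiny", seed=42)
    a = simulate.simulate_cohort(cfg).to_csv(index=False)
    b = simulate.simulate_cohort(default_config("tiny", seed=42)).to_csv(index=False)
    assert a == b


def test_disease_flags_monotone_within_patient(tiny_cohort):
    dis = [c for c in tiny_cohort.columns if c.startswith("disease_")]
    for _, grp in tiny_cohort.sort_values("year_index").groupby("patient_id"):
        arr = grp[dis].to_numpy()
        assert (np.diff(arr, axis=0) >= 0).all()


def test_unknown_scenario_lists_registry():
    with pytest.raises(ConfigError, match="paperlike"):
        default_config("nonexistent")


def test_non_stochastic_transition_row_named():
    cfg = _single_state_config()
    cfg.transition_matrix = np.array([[0.5, 0.2, 0.2], [0, 1, 0], [0, 0, 1.0]])
    with pytest.raises(ConfigError, match="row 0"):
        simulate.simulate_cohort(cfg)


def test_paperlike_dimensions():
    cfg = default_config("paperlike", n_patients=10, seed=0)
    assert cfg.n_diseases == 60
    assert cfg.n_clusters == 10
    assert cfg.n_drugs == 40
    tiny = default_config("tiny", seed=0)
    assert (tiny.n_clusters, tiny.n_diseases, tiny.n_drugs,
            tiny.n_patients) == (3, 6, 4, 200)
    null = default_config("null", seed=0)
    assert np.unique(null.disease_prevalence).size == 1
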