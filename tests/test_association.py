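import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mmtraj import association
from mmtraj.association import AssociationError
from mmtraj.config import MEDEA_LEVELS


def _fit_frame(estimates, ses):
    return pd.DataFrame({"term": [f"b{i}" for i in range(len(estimates))],
                         "estimate": estimates, "se": ses, "n": 100})


def _analysis_frame(n=400, seed=0, missing_rate=0.0, effect=0.0, K=3):
    """Synthetic analysis table with known medea margins."""
    rng = np.random.default_rng(seed)
    cluster = rng.integers(0, K, n)
    age = rng.uniform(65, 95, n)
    sex = rng.choice(["female", "male"], n)
    packs = rng.poisson(20, n)
    logit = -1.0 + effect * (cluster == K - 1)
    p = 1 / (1 + np.exp(-logit))
    medea = rng.choice(MEDEA_LEVELS, n, p=[0.3, 0.2, 0.15, 0.15, 0.1, 0.1])
    medea = pd.array(medea, dtype="string")
    miss = rng.random(n) < missing_rate
    medea[miss] = pd.NA
    return pd.DataFrame({
        "patient_id": np.arange(n), "baseline_cluster": cluster,
        "age": age, "sex": sex, "medea": medea,
        "total_packages_2012": packs,
        "outcome_kidney": rng.random(n) < p,
        "outcome_liver": rng.random(n) < p,
    }).astype({"outcome_kidney": int, "outcome_liver": int})


# ----------------------------------------------------------------------
# Rubin pooling
# ----------------------------------------------------------------------

def test_rubin_hand_arithmetic():
    fits = [_fit_frame([e], [0.2]) for e in (1.0, 1.2, 1.4)]
    pooled = association.pool_rubin(fits)
    assert pooled["pooled_log_odds"].iloc[0] == pytest.approx(1.2)
    assert pooled["between_variance"].iloc[0] == pytest.approx(0.04)
    assert pooled["within_variance"].iloc[0] == pytest.approx(0.04)
    assert pooled["total_variance"].iloc[0] == pytest.approx(0.04 + (4 / 3) * 0.04)
    assert pooled["ci_low"].iloc[0] < pooled["OR"].iloc[0] < pooled["ci_high"].iloc[0]
    assert pooled["total_variance"].iloc[0] >= pooled["within_variance"].iloc[0]


def test_rubin_identical_fits_collapse_to_single_fit_ci():
    fit = _fit_frame([0.7, -0.3], [0.1, 0.25])
    pooled = association.pool_rubin([fit.copy() for _ in range(5)])
    z = stats.norm.ppf(0.975)
    for i in range(2):
        est, se = fit["estimate"][i], fit["se"][i]
        assert pooled["between_variance"].iloc[i] == 0
        assert pooled["total_variance"].iloc[i] == pytest.approx(se ** 2)
        assert pooled["OR"].iloc[i] == pytest.approx(np.exp(est))
        assert pooled["ci_low"].iloc[i] == pytest.approx(np.exp(est - z * se))
        assert pooled["ci_high"].iloc[i] == pytest.approx(np.exp(est + z * se))


def test_rubin_pooled_estimate_is_mean_of_fits():
    rng = np.random.default_rng(1)
    fits = [_fit_frame(rng.normal(size=3), rng.uniform(0.1, 0.3, 3))
            for _ in range(7)]
    pooled = association.pool_rubin(fits)
    expected = np.mean([f["estimate"] for f in fits], axis=0)
    assert pooled["pooled_log_odds"].to_numpy() == pytest.approx(expected)


def test_rubin_mismatched_terms_rejected():
    a, b = _fit_frame([1.0], [0.1]), _fit_frame([1.0, 2.0], [0.1, 0.1])
    with pytest.raises(AssociationError, match="mismatch"):
        association.pool_rubin([a, b])
    with pytest.raises(AssociationError, match="m >= 2"):
        association.pool_rubin([a])


# ----------------------------------------------------------------------
# Logistic regression
# ----------------------------------------------------------------------

def test_two_by_two_odds_ratio_closed_form():
    """(a,b,c,d) = (30,70,10,90): OR must equal (30*90)/(70*10) exactly."""
    rows = []
    for cluster, outcome, count in ((1, 1, 30), (1, 0, 70), (0, 1, 10), (0, 0, 90)):
        rows += [{"patient_id": len(rows) + i, "baseline_cluster": cluster,
                  "outcome_kidney": outcome, "age": 70.0, "sex": "male",
                  "medea": "R", "total_packages_2012": 5}
                 for i in range(count)]
    df = pd.DataFrame(rows)
    df["patient_id"] = np.arange(len(df))
    fit = association.fit_logistic(df, "outcome_kidney", reference_cluster=0)
    est = fit.set_index("term").loc["cluster_1", "estimate"]
    assert np.exp(est) == pytest.approx((30 * 90) / (70 * 10), abs=1e-6)
    # constant covariates were dropped from the design
    assert "age" not in set(fit["term"])


def test_constant_outcome_rejected():
    df = _analysis_frame(100, seed=3)
    df["outcome_kidney"] = 1
    with pytest.raises(AssociationError, match="constant"):
        association.fit_logistic(df, "outcome_kidney")


# ----------------------------------------------------------------------
# MICE
# ----------------------------------------------------------------------

def test_mice_no_missing_returns_identical_copies():
    df = _analysis_frame(200, seed=4)
    out = association.mice_impute(df, m=3, seed=1)
    assert len(out) == 3
    for c in out:
        pd.testing.assert_frame_equal(c, df.reset_index(drop=True))


def test_mice_same_seed_identical():
    df = _analysis_frame(400, seed=5, missing_rate=0.07)
    a = association.mice_impute(df, m=2, seed=11)
    b = association.mice_impute(df, m=2, seed=11)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)


def test_mice_recovers_mcar_category_frequencies():
    truth = np.array([0.3, 0.2, 0.15, 0.15, 0.1, 0.1])
    df = _analysis_frame(3000, seed=6, missing_rate=0.07)
    completed = association.mice_impute(df, m=7, seed=2)
    freqs = np.mean([
        [float((c["medea"] == lev).mean()) for lev in MEDEA_LEVELS]
        for c in completed], axis=0)
    se = np.sqrt(truth * (1 - truth) / len(df))
    assert np.all(np.abs(freqs - truth) < 3 * se)


def test_mice_input_validation():
    df = _analysis_frame(100, seed=7)
    df["medea"] = pd.NA
    with pytest.raises(AssociationError, match="every patient"):
        association.mice_impute(df, m=2, seed=0)
    df2 = _analysis_frame(100, seed=8, missing_rate=0.07)
    df2.loc[0, "age"] = np.nan
    with pytest.raises(AssociationError, match="age"):
        association.mice_impute(df2, m=2, seed=0)


# ----------------------------------------------------------------------
# End-to-end association on synthetic tables
# ----------------------------------------------------------------------

def test_effect_direction_recovered_with_imputation():
    df = _analysis_frame(3000, seed=9, missing_rate=0.07, effect=1.2, K=3)
    completed = association.mice_impute(df, m=7, seed=3)
    fits = [association.fit_logistic(c, "outcome_kidney", reference_cluster=0)
            for c in completed]
    pooled = association.pool_rubin(fits).set_index("term")
    row = pooled.loc["cluster_2"]
    assert row["OR"] > 1
    assert row["ci_low"] > 1  # CI excludes the null
    assert row["ci_low"] < row["OR"] < row["ci_high"]


def test_small_clusters_excluded_from_analysis(tiny_phenotypes, caplog):
    import logging
    traj = tiny_phenotypes[tiny_phenotypes["year_index"] == 0][
        ["patient_id"]].copy()
    rng = np.random.default_rng(0)
    traj["baseline_cluster"] = rng.integers(0, 2, len(traj))
    traj.loc[traj.index[:3], "baseline_cluster"] = 99  # 3-patient cluster
    with caplog.at_level(logging.WARNING):
        rows = association.build_analysis_table(tiny_phenotypes, traj)
    assert 99 not in set(rows["baseline_cluster"])
    assert "excluding" in caplog.text
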