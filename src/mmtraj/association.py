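"""Baseline pattern vs abnormal kidney/liver function.

Builds one analysis row per patient (baseline decoded cluster, post-baseline
kidney/liver abnormality flags, age, sex, deprivation quintile, baseline
total packages), imputes the partially missing deprivation quintile with a
proportional-odds model inside a chained-equations sweep (m=7 datasets by
default), fits per-imputation logistic regressions, and pools log-odds with
Rubin's rules (Barnard-Rubin degrees of freedom, 95% CIs on the OR scale).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import ALIVE, MEDEA_LEVELS

logger = logging.getLogger(__name__)


class AssociationError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# Analysis table
# ----------------------------------------------------------------------

def build_analysis_table(phenotypes: pd.DataFrame,
                         trajectories: pd.DataFrame,
                         min_cluster_size: int = 30) -> pd.DataFrame:
    """One row per patient with baseline cluster, outcomes and covariates.

    Patients whose baseline cluster holds fewer than ``min_cluster_size``
    members are excluded with a warning: a near-empty pattern cannot support
    a stable cluster-level odds ratio and only induces separation.
    """
    base = phenotypes[phenotypes["year_index"] == 0][
        ["patient_id", "age_baseline", "sex", "medea",
         "kidney_abnormal_ever", "liver_abnormal_ever",
         "total_packages_baseline"]].copy()
    clusters = trajectories.drop_duplicates("patient_id")[
        ["patient_id", "baseline_cluster"]]
    out = base.merge(clusters, on="patient_id", how="inner")
    out = out.rename(columns={"kidney_abnormal_ever": "outcome_kidney",
                              "liver_abnormal_ever": "outcome_liver",
                              "age_baseline": "age",
                              "total_packages_baseline": "total_packages_2012"})
    if out.duplicated("patient_id").any():
        raise AssociationError("duplicate patients in analysis table")
    sizes = out["baseline_cluster"].value_counts()
    small = sizes[sizes < min_cluster_size]
    if len(small):
        logger.warning("excluding %d patients in %d baseline clusters smaller "
                       "than %d members: %s", small.sum(), len(small),
                       min_cluster_size, dict(small))
        out = out[~out["baseline_cluster"].isin(small.index)]
    return out.reset_index(drop=True)


# ----------------------------------------------------------------------
# Multiple imputation (chained equations)
# ----------------------------------------------------------------------

def _medea_codes(series: pd.Series) -> np.ndarray:
    codes = pd.Categorical(series, categories=MEDEA_LEVELS, ordered=True).codes
    return codes.astype(float)


def _imputation_design(df: pd.DataFrame) -> np.ndarray:
    """Predictors for the deprivation-quintile conditional model."""
    cols = [df["age"].to_numpy(dtype=float),
            (df["sex"] == "female").to_numpy(dtype=float),
            df["total_packages_2012"].to_numpy(dtype=float),
            df["outcome_kidney"].to_numpy(dtype=float),
            df["outcome_liver"].to_numpy(dtype=float)]
    dummies = pd.get_dummies(df["baseline_cluster"], drop_first=True)
    X = np.column_stack(cols + [dummies.to_numpy(dtype=float)])
    # standardise continuous columns for optimizer stability
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def mice_impute(rows: pd.DataFrame, m: int = 7, seed: int = 0,
                n_sweeps: int = 10) -> list:
    """Return ``m`` completed copies of the analysis table.

    Only the deprivation quintile (medea) may be missing. The conditional
    model is a proportional-odds (ordinal logistic) regression of medea on
    every other analysis variable; draws are taken from the fitted category
    probabilities. With a single incomplete variable the chained sweep is
    idempotent, so the model is fit once regardless of ``n_sweeps``. Falls
    back to predictive-mean matching on the integer coding if the ordinal
    fit fails. Fully seeded and deterministic.
    """
    df = rows.reset_index(drop=True)
    other = df.drop(columns=["medea", "patient_id"])
    if other.isna().any().any():
        bad = other.columns[other.isna().any()][0]
        raise AssociationError(f"only medea may be missing; {bad!r} has NaNs")
    codes = _medea_codes(df["medea"])
    miss = codes < 0
    if not miss.any():
        return [df.copy() for _ in range(m)]
    if miss.all():
        raise AssociationError("medea is missing for every patient")
    rate = miss.mean()
    if rate >= 0.5:
        raise AssociationError(f"medea missingness {rate:.0%} exceeds 50%")

    X = _imputation_design(df)
    obs = ~miss
    y_obs = codes[obs]
    rng = np.random.default_rng(seed)
    try:
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        mod = OrderedModel(y_obs, X[obs], distr="logit")
        res = mod.fit(method="bfgs", maxiter=200, disp=False)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("ordinal model did not converge")
        probs = res.model.predict(res.params, exog=X[miss])
        # guard rows: renormalise fitted category probabilities
        probs = np.clip(probs, 1e-12, None)
        probs = probs / probs.sum(axis=1, keepdims=True)
        draws_fn = lambda: np.array(
            [rng.choice(len(MEDEA_LEVELS), p=p) for p in probs])
    except Exception as exc:  # pragma: no cover - fallback path
        logger.warning("ordinal imputation model failed (%s); falling back "
                       "to predictive-mean matching", exc)
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(obs.sum()), X[obs]]), y_obs, rcond=None)
        pred_obs = np.column_stack([np.ones(obs.sum()), X[obs]]) @ beta
        pred_mis = np.column_stack([np.ones(miss.sum()), X[miss]]) @ beta

        def draws_fn():
            noisy = pred_mis + rng.normal(0, pred_obs.std() * 0.1, miss.sum())
            idx = np.abs(noisy[:, None] - pred_obs[None, :]).argmin(axis=1)
            return y_obs[idx].astype(int)

    completed = []
    for _ in range(m):
        imp = df.copy()
        new = codes.copy()
        new[miss] = draws_fn()
        imp["medea"] = pd.array([MEDEA_LEVELS[int(c)] for c in new],
                                dtype="string")
        completed.append(imp)
    return completed


# ----------------------------------------------------------------------
# Logistic regression
# ----------------------------------------------------------------------

def _model_design(df: pd.DataFrame, reference_cluster,
                  medea_as: str = "dummies"):
    """Design matrix: cluster dummies (ref dropped) + adjustment covariates."""
    parts, names = [], []
    clusters = sorted(df["baseline_cluster"].unique())
    for k in clusters:
        if k == reference_cluster:
            continue
        parts.append((df["baseline_cluster"] == k).to_numpy(dtype=float))
        names.append(f"cluster_{k}")
    parts.append(df["age"].to_numpy(dtype=float))
    names.append("age")
    parts.append((df["sex"] == "female").to_numpy(dtype=float))
    names.append("sex_female")
    if medea_as == "dummies":
        for lev in MEDEA_LEVELS[1:]:
            parts.append((df["medea"] == lev).to_numpy(dtype=float))
            names.append(f"medea_{lev}")
    elif medea_as == "ordinal":
        parts.append(_medea_codes(df["medea"]))
        names.append("medea")
    else:
        raise ValueError(f"unknown medea coding {medea_as!r}")
    parts.append(df["total_packages_2012"].to_numpy(dtype=float))
    names.append("total_packages_2012")
    X = np.column_stack(parts)
    return X, names


def fit_logistic(completed: pd.DataFrame, outcome: str,
                 reference_cluster=None, medea_as: str = "dummies") -> pd.DataFrame:
    """Maximum-likelihood logit of an outcome flag on the adjusted design.

    Returns a table of terms, coefficients and standard errors for one
    completed dataset. Zero-variance covariates are dropped with a warning;
    separation or non-convergence raise with the offending detail.
    """
    y = completed[outcome].to_numpy(dtype=float)
    if y.min() == y.max():
        raise AssociationError(f"outcome {outcome!r} is constant")
    if reference_cluster is None:
        reference_cluster = (completed["baseline_cluster"]
                             .value_counts().idxmax())
    X, names = _model_design(completed, reference_cluster, medea_as)
    keep = X.std(axis=0) > 0
    for nm in np.array(names)[~keep]:
        logger.warning("dropping zero-variance covariate %r", nm)
    X, names = X[:, keep], list(np.array(names)[keep])
    Xc = sm.add_constant(X, has_constant="add")
    try:
        try:
            res = sm.Logit(y, Xc).fit(disp=False, maxiter=200)
        except np.linalg.LinAlgError:
            # singular Hessian under Newton (boundary estimate); BFGS copes
            res = sm.Logit(y, Xc).fit(method="bfgs", disp=False, maxiter=500)
    except Exception as exc:
        raise AssociationError(
            f"logistic fit failed for outcome {outcome!r} "
            f"(terms {names}): {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        # A flat score at the boundary signals quasi-separation (e.g. a tiny
        # cluster with no events): accept the boundary estimate with a
        # warning. A genuinely unconverged fit is an error.
        grad = np.abs(res.model.score(res.params)).max()
        if grad < 1e-4:
            sep = [nm for nm, b in zip(["intercept"] + names, res.params)
                   if abs(b) > 15]
            logger.warning("quasi-separation for outcome %r in terms %s; "
                           "boundary estimates kept", outcome, sep)
        else:
            raise AssociationError(
                f"logit for {outcome!r} did not converge "
                f"(max |score| {grad:.3g}): {res.mle_retvals['warnflag']}")
    return pd.DataFrame({
        "term": ["intercept"] + names,
        "estimate": res.params,
        "se": res.bse,
        "n": int(res.nobs),
    })


# ----------------------------------------------------------------------
# Rubin's rules
# ----------------------------------------------------------------------

def pool_rubin(fits: list, nu_com: float = np.inf) -> pd.DataFrame:
    """Pool per-imputation estimates with Rubin's rules.

    Total variance T = W̄ + (1 + 1/m)B; degrees of freedom by Barnard-Rubin
    given a complete-data df ``nu_com`` (default infinite, appropriate for a
    large-sample logit, in which case the classic Rubin df is recovered and
    B = 0 collapses exactly to the single-fit normal CI). ORs and 95% CIs
    are reported on the exponentiated scale.
    """
    if len(fits) < 2:
        raise AssociationError("Rubin pooling needs m >= 2 fits")
    terms = list(fits[0]["term"])
    for f in fits[1:]:
        if list(f["term"]) != terms:
            raise AssociationError("imputation fits have mismatched terms")
    m = len(fits)
    Q = np.column_stack([f["estimate"].to_numpy() for f in fits])
    U = np.column_stack([f["se"].to_numpy() ** 2 for f in fits])
    qbar = Q.mean(axis=1)
    wbar = U.mean(axis=1)
    B = Q.var(axis=1, ddof=1)
    T = wbar + (1 + 1 / m) * B

    lam = (1 + 1 / m) * B / T
    df = np.empty(len(terms))
    for i, l in enumerate(lam):
        if l <= 0:
            df[i] = np.inf
            continue
        nu_old = (m - 1) / l ** 2
        if np.isinf(nu_com):
            df[i] = nu_old
        else:
            nu_obs = (nu_com + 1) / (nu_com + 3) * nu_com * (1 - l)
            df[i] = 1 / (1 / nu_old + 1 / nu_obs)
    tcrit = np.where(np.isinf(df), stats.norm.ppf(0.975),
                     stats.t.ppf(0.975, np.where(np.isinf(df), 1, df)))
    half = tcrit * np.sqrt(T)
    return pd.DataFrame({
        "term": terms,
        "pooled_log_odds": qbar,
        "within_variance": wbar,
        "between_variance": B,
        "total_variance": T,
        "df": df,
        "OR": np.exp(qbar),
        "ci_low": np.exp(qbar - half),
        "ci_high": np.exp(qbar + half),
        "m": m,
    })


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------

def run_association(phenotypes: pd.DataFrame, trajectories: pd.DataFrame,
                    m: int = 7, seed: int = 0, reference_cluster=None,
                    medea_as: str = "dummies") -> dict:
    """Pooled OR tables for kidney and liver outcomes.

    The reference cluster defaults to the largest baseline cluster (the
    analogue of a non-specific majority pattern). Returns a dict with keys
    ``kidney`` and ``liver``.
    """
    rows = build_analysis_table(phenotypes, trajectories)
    if reference_cluster is None:
        reference_cluster = rows["baseline_cluster"].value_counts().idxmax()
    logger.info("association: n=%d patients, reference cluster %s, m=%d",
                len(rows), reference_cluster, m)
    completed = mice_impute(rows, m=m, seed=seed)
    out = {}
    for outcome, key in (("outcome_kidney", "kidney"), ("outcome_liver", "liver")):
        fits = [fit_logistic(c, outcome, reference_cluster, medea_as)
                for c in completed]
        out[key] = pool_rubin(fits)
    return out
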