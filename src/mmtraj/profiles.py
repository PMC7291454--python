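"""Per-cluster, per-year pattern profiles.

For diseases the cluster statistic is prevalence; for drugs it is the mean
number of annual packages over all cluster members. O/E ratios divide the
cluster statistic by the same statistic in the overall population of alive,
decoded patients that year. Exclusivity is the cluster's share of all
patients with the disease (or of all packages of the drug). An item belongs
to a pattern when its O/E ratio is >= 2; drugs have a secondary membership
flag when their exclusivity strictly exceeds the cluster's population share.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import ALIVE
from .simulate import DISEASE_PREFIX, DRUG_PREFIX

logger = logging.getLogger(__name__)

OE_MEMBER_MIN = 2.0  # inclusive


def _frame_at_year(table: pd.DataFrame, trajectories: pd.DataFrame, year: int,
                   include_absorbed: bool = False) -> pd.DataFrame:
    """Rows at a wave joined with decoded cluster; default alive-only."""
    traj = trajectories[trajectories["year_index"] == year][
        ["patient_id", "decoded_state"]]
    df = table[table["year_index"] == year].merge(traj, on="patient_id",
                                                  how="inner")
    if not include_absorbed:
        df = df[df["status"] == ALIVE]
    missing = df["decoded_state"].isna()
    if missing.any():
        raise ValueError(f"{missing.sum()} patients at year {year} lack a "
                         "decoded cluster")
    return df


def disease_profile(cohort: pd.DataFrame, trajectories: pd.DataFrame,
                    year: int, include_absorbed: bool = False) -> pd.DataFrame:
    """Prevalence, O/E ratio and exclusivity per cluster for every disease.

    The overall population is, by default, the alive decoded patients at the
    given wave; an item whose overall prevalence is zero has no defined O/E
    and is emitted as missing with a warning.
    """
    df = _frame_at_year(cohort, trajectories, year, include_absorbed)
    items = [c for c in cohort.columns if c.startswith(DISEASE_PREFIX)]
    return _profile(df, items, year, statistic="prevalence")


def drug_profile(cohort: pd.DataFrame, trajectories: pd.DataFrame,
                 year: int, include_absorbed: bool = False) -> pd.DataFrame:
    """Mean packages, O/E ratio and package-share exclusivity per cluster.

    Means are taken over all cluster members including non-users. Drugs with
    zero packages dispensed overall are skipped with a warning. The
    ``member_by_exclusivity`` flag is set when the cluster's share of all
    packages strictly exceeds its share of the population.
    """
    df = _frame_at_year(cohort, trajectories, year, include_absorbed)
    items = [c for c in cohort.columns if c.startswith(DRUG_PREFIX)]
    return _profile(df, items, year, statistic="mean_packages")


def _profile(df: pd.DataFrame, items: list, year: int, statistic: str) -> pd.DataFrame:
    n_total = len(df)
    clusters = np.sort(df["decoded_state"].unique())
    sizes = df.groupby("decoded_state").size()
    vals = df[items].to_numpy(dtype=float)
    overall = vals.mean(axis=0)
    totals = vals.sum(axis=0)

    rows = []
    for k in clusters:
        in_k = (df["decoded_state"] == k).to_numpy()
        cl_vals = vals[in_k]
        cl_stat = cl_vals.mean(axis=0)
        cl_share = sizes[k] / n_total
        for j, item in enumerate(items):
            if totals[j] == 0:
                if k == clusters[0]:
                    logger.warning("item %s has zero overall %s at year %d; "
                                   "O/E undefined", item, statistic, year)
                continue
            oe = cl_stat[j] / overall[j]
            excl = cl_vals[:, j].sum() / totals[j]
            rows.append({
                "cluster": int(k), "year_index": year, "item": item,
                "cluster_size": int(sizes[k]), "cluster_share": cl_share,
                "cluster_value": cl_stat[j], "overall_value": overall[j],
                "oe_ratio": oe, "exclusivity": excl,
                "member": int(oe >= OE_MEMBER_MIN),
                "member_by_exclusivity": int(excl > cl_share),
            })
    out = pd.DataFrame(rows)
    out.attrs["statistic"] = statistic
    out.attrs["n_population"] = n_total
    return out


def profile_evolution(profiles: pd.DataFrame) -> pd.DataFrame:
    """Tidy per-cluster, per-item time series with year-over-year deltas."""
    years = sorted(profiles["year_index"].unique())
    if len(years) < 2:
        raise ValueError("profile evolution needs at least two profiled years")
    out = profiles.sort_values(["cluster", "item", "year_index"]).copy()
    grp = out.groupby(["cluster", "item"])
    out["delta_oe"] = grp["oe_ratio"].diff()
    out["delta_value"] = grp["cluster_value"].diff()
    return out
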