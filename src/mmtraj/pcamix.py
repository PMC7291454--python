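"""Factor analysis of mixed data (PCAmix).

Generalized-SVD construction that reduces a mix of quantitative columns and
qualitative (categorical) columns to orthogonal factor scores. With only
quantitative columns it coincides with standard PCA of the standardized
matrix; with only qualitative columns its eigenvalues are the MCA principal
inertias scaled by the number of qualitative variables.

Construction: quantitative columns are standardized (population SD);
each qualitative variable is indicator-coded, each indicator column centred
by its category frequency p_s and weighted by 1/sqrt(p_s). The SVD of the
resulting matrix divided by sqrt(n) yields eigenvalues summing to the total
inertia p_quant + (total categories − n_qual).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PcamixError(ValueError):
    pass


@dataclass
class FactorModel:
    """Fitted PCAmix model: loadings, eigenvalues and preprocessing constants."""

    d: int
    quant_names: list
    qual_names: list
    quant_mean: np.ndarray  # per quantitative column
    quant_sd: np.ndarray
    categories: dict  # qual name -> list of category labels
    cat_probs: dict  # qual name -> array of category frequencies
    loadings: np.ndarray  # (n_weighted_columns, d), right singular vectors
    eigenvalues: np.ndarray  # length d, nonincreasing
    total_inertia: float
    n_fit: int

    def to_json(self, path) -> None:
        obj = {
            "d": self.d,
            "quant_names": list(self.quant_names),
            "qual_names": list(self.qual_names),
            "quant_mean": self.quant_mean.tolist(),
            "quant_sd": self.quant_sd.tolist(),
            "categories": {k: list(v) for k, v in self.categories.items()},
            "cat_probs": {k: np.asarray(v).tolist() for k, v in self.cat_probs.items()},
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "total_inertia": self.total_inertia,
            "n_fit": self.n_fit,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "FactorModel":
        with open(path) as fh:
            obj = json.load(fh)
        obj["quant_mean"] = np.asarray(obj["quant_mean"])
        obj["quant_sd"] = np.asarray(obj["quant_sd"])
        obj["cat_probs"] = {k: np.asarray(v) for k, v in obj["cat_probs"].items()}
        obj["loadings"] = np.asarray(obj["loadings"])
        obj["eigenvalues"] = np.asarray(obj["eigenvalues"])
        return cls(**obj)


def _weighted_matrix(quant: pd.DataFrame | None, qual: pd.DataFrame | None,
                     model: FactorModel | None = None):
    """Build the column-weighted matrix Z; fit constants when model is None."""
    blocks = []
    if model is None:
        quant_mean = quant.mean(axis=0).to_numpy() if quant is not None else np.empty(0)
        quant_sd = quant.std(axis=0, ddof=0).to_numpy() if quant is not None else np.empty(0)
        if quant is not None and np.any(quant_sd == 0):
            bad = quant.columns[quant_sd == 0][0]
            raise PcamixError(f"quantitative variable {bad!r} is constant")
    else:
        quant_mean, quant_sd = model.quant_mean, model.quant_sd

    if quant is not None and len(quant.columns):
        blocks.append((quant.to_numpy(dtype=float) - quant_mean) / quant_sd)

    categories, cat_probs = {}, {}
    if qual is not None:
        for col in qual.columns:
            vals = qual[col].astype(str)
            if model is None:
                cats = sorted(vals.unique())
                if len(cats) < 2:
                    raise PcamixError(
                        f"qualitative variable {col!r} has a single category")
                p = np.array([(vals == c).mean() for c in cats])
                categories[col], cat_probs[col] = cats, p
            else:
                cats = model.categories[col]
                p = model.cat_probs[col]
                unseen = set(vals.unique()) - set(cats)
                if unseen:
                    logger.warning(
                        "variable %r: unseen categories %s mapped to zero weight",
                        col, sorted(unseen))
            G = np.zeros((len(vals), len(cats)))
            arr = vals.to_numpy()
            for j, c in enumerate(cats):
                G[:, j] = arr == c
            seen = G.sum(axis=1) > 0
            # rows with unseen categories contribute zero after centering
            Z = (G - p) / np.sqrt(p)
            Z[~seen] = 0.0
            blocks.append(Z)
    Zfull = np.hstack(blocks) if blocks else np.empty((0, 0))
    return Zfull, quant_mean, quant_sd, categories, cat_probs


def fit_pcamix(quant: pd.DataFrame | None, qual: pd.DataFrame | None,
               d="auto", inertia_target: float = 0.80):
    """Fit a PCAmix model and return (model, scores).

    ``d`` may be an integer or ``"auto"``, in which case the smallest number
    of components whose cumulative inertia reaches ``inertia_target`` is
    retained. Scores are centred on the fitting data; the sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    n = len(quant) if quant is not None else len(qual)
    Z, qmean, qsd, cats, probs = _weighted_matrix(quant, qual)
    p_quant = len(qmean)
    m_categories = sum(len(c) for c in cats.values())
    total_inertia = p_quant + (m_categories - len(cats))

    U, s, Vt = np.linalg.svd(Z / np.sqrt(n), full_matrices=False)
    eig = s ** 2
    rank = int(np.sum(eig > 1e-12 * max(eig[0], 1.0)))
    if d == "auto":
        cum = np.cumsum(eig[:rank]) / eig[:rank].sum()
        d = int(np.searchsorted(cum, inertia_target) + 1)
    d = int(d)
    if d > rank:
        raise PcamixError(f"d={d} exceeds matrix rank {rank}")

    V = Vt[:d].T
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(d):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]

    model = FactorModel(
        d=d, quant_names=list(quant.columns) if quant is not None else [],
        qual_names=list(qual.columns) if qual is not None else [],
        quant_mean=qmean, quant_sd=qsd, categories=cats, cat_probs=probs,
        loadings=V, eigenvalues=eig[:d], total_inertia=float(total_inertia),
        n_fit=n,
    )
    scores = Z @ V
    return model, scores


def transform(model: FactorModel, quant: pd.DataFrame | None,
              qual: pd.DataFrame | None) -> np.ndarray:
    """Project new rows onto the fitted axes (deterministic)."""
    if model.quant_names:
        quant = quant[model.quant_names]
    else:
        quant = None
    if model.qual_names:
        qual = qual[model.qual_names]
    else:
        qual = None
    Z, *_ = _weighted_matrix(quant, qual, model=model)
    return Z @ model.loadings


def split_blocks(df: pd.DataFrame, quant_cols, qual_cols):
    """Convenience accessor returning the two typed blocks of a table."""
    quant = df[list(quant_cols)] if quant_cols else None
    qual = df[list(qual_cols)] if qual_cols else None
    return quant, qual
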