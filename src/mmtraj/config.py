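"""Simulation configuration for synthetic elderly primary-care cohorts.

A :class:`SimConfig` fully determines a cohort draw: K latent multimorbidity
clusters with cluster-specific chronic-disease prevalences, drug-package
means and lab distributions, a Markov transition matrix over the K living
states plus two absorbing states (death, drop-out), and demographic margins.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

# Absorbing-state labels appended after the K living cluster states.
DEATH = "dead"
DROPOUT = "dropped"
ALIVE = "alive"

MEDEA_LEVELS = ["R", "U1", "U2", "U3", "U4", "U5"]
#: Overall MEDEA quintile margins (rural + urban quintiles, least to most
#: deprived), used by every scenario.
MEDEA_PROBS = np.array([0.214, 0.170, 0.160, 0.162, 0.156, 0.138])

LAB_NAMES = ("creatinine", "alp", "alt", "ggt")


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class LabParams:
    """Per-cluster log-normal parameters for one analyte.

    ``median`` is the per-cluster median on the natural scale (mg/dL for
    creatinine, IU/L for the liver enzymes); ``sigma`` the log-scale SD.
    """

    median: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.median = np.asarray(self.median, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)


@dataclass
class SimConfig:
    n_patients: int
    n_years: int = 5
    n_clusters: int = 10
    n_diseases: int = 60
    n_drugs: int = 40
    disease_prevalence: np.ndarray = None  # (K, n_diseases)
    package_mean: np.ndarray = None  # (K, n_drugs)
    transition_matrix: np.ndarray = None  # (K+2, K+2)
    initial_distribution: np.ndarray = None  # (K,)
    lab_params: dict = None  # analyte -> LabParams
    visit_mean: np.ndarray = None  # (K,)
    age_range: tuple = (65, 99)
    sex_ratio: float = 0.578  # probability female
    medea_missing_rate: float = 0.07
    package_dispersion: float = 1.0  # negative-binomial size parameter
    seed: int = 0
    scenario: str = "custom"
    # indices of clusters with shifted renal / hepatic lab distributions
    renal_cluster: int | None = None
    hepatic_cluster: int | None = None

    # ------------------------------------------------------------------
    @property
    def n_states(self) -> int:
        """Living clusters plus the two absorbing states."""
        return self.n_clusters + 2

    @property
    def death_state(self) -> int:
        return self.n_clusters

    @property
    def dropout_state(self) -> int:
        return self.n_clusters + 1

    def validate(self) -> None:
        K = self.n_clusters
        if self.disease_prevalence.shape != (K, self.n_diseases):
            raise ConfigError(
                f"disease_prevalence shape {self.disease_prevalence.shape} "
                f"!= ({K}, {self.n_diseases})"
            )
        if np.any(self.disease_prevalence < 0) or np.any(self.disease_prevalence > 1):
            raise ConfigError("disease prevalences must lie in [0, 1]")
        if self.package_mean.shape != (K, self.n_drugs):
            raise ConfigError("package_mean has wrong shape")
        if np.any(self.package_mean < 0):
            raise ConfigError("package means must be nonnegative")
        A = self.transition_matrix
        if A.shape != (K + 2, K + 2):
            raise ConfigError(f"transition matrix must be {(K + 2, K + 2)}")
        row_sums = A.sum(axis=1)
        bad = np.where(~np.isclose(row_sums, 1.0, atol=1e-8))[0]
        if bad.size:
            raise ConfigError(
                f"transition matrix row {bad[0]} sums to {row_sums[bad[0]]:.6f}, not 1"
            )
        if np.any(A < 0):
            raise ConfigError("transition probabilities must be nonnegative")
        for absorbing in (self.death_state, self.dropout_state):
            if not np.isclose(A[absorbing, absorbing], 1.0):
                raise ConfigError(
                    f"row {absorbing} (absorbing state) must have 1 on the diagonal"
                )
        pi = self.initial_distribution
        if pi.shape != (K,) or not np.isclose(pi.sum(), 1.0) or np.any(pi < 0):
            raise ConfigError("initial_distribution must be a length-K simplex")
        lo, hi = self.age_range
        if not (65 <= lo < hi <= 99):
            raise ConfigError("age_range must lie within [65, 99]")
        if not 0 <= self.medea_missing_rate <= 1:
            raise ConfigError("medea_missing_rate must be a probability")
        for name in LAB_NAMES:
            lp = self.lab_params[name]
            if lp.median.shape != (K,) or lp.sigma.shape != (K,):
                raise ConfigError(f"lab_params[{name}] must have one entry per cluster")

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("disease_prevalence", "package_mean", "transition_matrix",
                    "initial_distribution", "visit_mean"):
            d[key] = np.asarray(d[key]).tolist()
        d["lab_params"] = {
            k: {"median": v["median"].tolist(), "sigma": v["sigma"].tolist()}
            for k, v in d["lab_params"].items()
        }
        d["age_range"] = list(d["age_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("disease_prevalence", "package_mean", "transition_matrix",
                    "initial_distribution", "visit_mean"):
            d[key] = np.asarray(d[key], dtype=float)
        d["lab_params"] = {k: LabParams(**v) for k, v in d["lab_params"].items()}
        d["age_range"] = tuple(d["age_range"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


# ----------------------------------------------------------------------
# Scenario registry
# ----------------------------------------------------------------------

def _transition_matrix(pi: np.ndarray, stay: float, death_hazard: np.ndarray,
                       dropout_hazard: float) -> np.ndarray:
    """Row-stochastic matrix with per-cluster self-stay and event hazards.

    Mass not kept in place or absorbed is spread over the other living
    clusters proportionally to their stationary share ``pi``.
    """
    K = len(pi)
    A = np.zeros((K + 2, K + 2))
    for k in range(K):
        move = 1.0 - stay - death_hazard[k] - dropout_hazard
        if move < 0:
            raise ConfigError(f"hazards of cluster {k} exceed 1 - stay probability")
        others = np.delete(np.arange(K), k)
        w = pi[others] / pi[others].sum()
        A[k, k] = stay
        A[k, others] = move * w
        A[k, K] = death_hazard[k]
        A[k, K + 1] = dropout_hazard
    A[K, K] = 1.0
    A[K + 1, K + 1] = 1.0
    return A


def _flat_labs(K: int) -> dict:
    return {
        "creatinine": LabParams(np.full(K, 0.75), np.full(K, 0.15)),
        "alp": LabParams(np.full(K, 80.0), np.full(K, 0.30)),
        "alt": LabParams(np.full(K, 20.0), np.full(K, 0.40)),
        "ggt": LabParams(np.full(K, 22.0), np.full(K, 0.45)),
    }


def _paperlike(n_patients: int, seed: int) -> SimConfig:
    K, n_dis, n_drug = 10, 60, 40
    # Baseline cluster shares shaped like a typical elderly primary-care
    # population: one large non-specific cluster, a long tail of organ
    # system patterns.
    pi = np.array([0.420, 0.193, 0.079, 0.066, 0.059,
                   0.046, 0.045, 0.039, 0.036, 0.017])
    pi = pi / pi.sum()

    # Six signature diseases per cluster, concentrated enough that the
    # planted O/E ratio exceeds 2 even for the largest cluster.
    prev = np.full((K, n_dis), 0.04)
    for k in range(K):
        prev[k, 6 * k:6 * (k + 1)] = 0.65

    # Drugs 0-9 are population-wide staples (PPIs, statins, analgesics);
    # drugs 10-39 are cluster signatures, three per cluster.
    pkg = np.full((K, n_drug), 0.2)
    pkg[:, :10] = 2.0
    for k in range(K):
        pkg[k, 10 + 3 * k:10 + 3 * (k + 1)] = 5.0

    # Mortality hazard rises in the cardio-renal and multisystem clusters.
    death_hazard = np.array([0.015, 0.02, 0.02, 0.08, 0.04,
                             0.05, 0.025, 0.03, 0.02, 0.06])
    A = _transition_matrix(pi, stay=0.86, death_hazard=death_hazard,
                           dropout_hazard=0.015)

    labs = _flat_labs(K)
    renal, hepatic = 3, 7
    labs["creatinine"].median[renal] = 1.25
    labs["ggt"].median[hepatic] = 52.0
    labs["alp"].median[hepatic] = 150.0
    labs["alt"].median[hepatic] = 45.0

    visit_mean = np.array([7., 10., 10., 20., 14., 12., 12., 11., 12., 15.])

    return SimConfig(
        n_patients=n_patients, n_clusters=K, n_diseases=n_dis, n_drugs=n_drug,
        disease_prevalence=prev, package_mean=pkg, transition_matrix=A,
        initial_distribution=pi, lab_params=labs, visit_mean=visit_mean,
        seed=seed, scenario="paperlike", renal_cluster=renal,
        hepatic_cluster=hepatic,
    )


def _tiny(n_patients: int, seed: int) -> SimConfig:
    K, n_dis, n_drug = 3, 6, 4
    pi = np.array([0.5, 0.3, 0.2])
    prev = np.full((K, n_dis), 0.05)
    for k in range(K):
        prev[k, 2 * k:2 * (k + 1)] = 0.7
    pkg = np.full((K, n_drug), 0.3)
    for k in range(K):
        pkg[k, k % n_drug] = 4.0
    A = _transition_matrix(pi, stay=0.85, death_hazard=np.array([0.02, 0.05, 0.08]),
                           dropout_hazard=0.02)
    labs = _flat_labs(K)
    labs["creatinine"].median[2] = 1.25
    labs["ggt"].median[1] = 52.0
    return SimConfig(
        n_patients=n_patients, n_clusters=K, n_diseases=n_dis, n_drugs=n_drug,
        disease_prevalence=prev, package_mean=pkg, transition_matrix=A,
        initial_distribution=pi, lab_params=labs,
        visit_mean=np.array([8.0, 10.0, 14.0]), seed=seed, scenario="tiny",
        renal_cluster=2, hepatic_cluster=1,
    )


def _null(n_patients: int, seed: int) -> SimConfig:
    """Exchangeable clusters: identical prevalences, packages and labs."""
    cfg = _tiny(n_patients, seed)
    cfg.disease_prevalence = np.full_like(cfg.disease_prevalence, 0.2)
    cfg.package_mean = np.full_like(cfg.package_mean, 1.0)
    cfg.lab_params = _flat_labs(cfg.n_clusters)
    cfg.scenario = "null"
    cfg.renal_cluster = None
    cfg.hepatic_cluster = None
    return cfg


_SCENARIOS = {"paperlike": _paperlike, "tiny": _tiny, "null": _null}
_DEFAULT_N = {"paperlike": 5000, "tiny": 200, "null": 200}


def default_config(scenario_name: str, n_patients: int | None = None,
                   seed: int = 0) -> SimConfig:
    """Return a fully populated, seedable configuration from the registry.

    Known scenarios: ``paperlike`` (10 clusters, 60 disease groups, 40
    ATC-level-4 drug codes, planted renal and hepatic clusters), ``tiny``
    (3 clusters, fast smoke tests) and ``null`` (no cluster structure).
    """
    if scenario_name not in _SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario_name!r}; known scenarios: "
            f"{sorted(_SCENARIOS)}"
        )
    n = n_patients if n_patients is not None else _DEFAULT_N[scenario_name]
    cfg = _SCENARIOS[scenario_name](n, seed)
    cfg.validate()
    return cfg
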