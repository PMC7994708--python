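"""Synthetic ordinal symptom panels with known network structure.

Generates latent-Gaussian VAR(1) panels and discretizes them to 0-4 ordinal
scores, so every estimator in the package can be exercised against a known
truth.  The generative model per subject i is

    y_0  = m_0 + mu_i + x_0,            x_0 ~ stationary dist. of the VAR
    y_t  = m_t + mu_i + B (y_{t-1} - m_{t-1} - mu_i) + eps_t
    eps_t ~ N(0, Sigma),  Sigma implied by the contemporaneous partial
                          correlations with unit partial variances
    mu_i ~ N(0, diag(between_sd^2))     stable person effect

with ``m_t`` the population wave means — by default high at admission and
declining by discharge, mimicking an acute treated episode (so the panel is
deliberately mean-nonstationary, like the real setting).  The latent array
is returned alongside the ordinal panel so closed-form oracles stay
available; discretization attenuates correlations, which is part of what
the ordinal pipeline has to cope with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .gvar import check_stationarity
from .panel import DEFAULT_SYMPTOMS, SymptomPanel

#: default threshold cut-points mapping latent position to scores 0..4
DEFAULT_THRESHOLDS = (0.5, 1.5, 2.5, 3.5)

#: default admission-wave latent means (acute mania: high mood/energy/insight
#: loss, lower sexual-interest item), declining linearly to ~25% by discharge
_T0_MEANS = np.array([3.6, 2.9, 0.8, 2.7, 2.6, 2.9, 2.3, 2.6, 2.1, 1.6, 3.2])


def default_wave_means(waves: int = 3, decline: float = 0.75) -> np.ndarray:
    """Linearly declining wave means: wave 0 at the acute profile, the last
    wave at ``(1 - decline)`` of it."""
    frac = np.linspace(1.0, 1.0 - decline, waves)
    return np.outer(frac, _T0_MEANS)


def ring_pcor(p: int = 11, weight: float = 0.25, extra_edges=((0, 4), (1, 5), (2, 7)),
              extra_weight: float = 0.2) -> np.ndarray:
    """Sparse partial-correlation matrix: a ring plus a few cross edges.

    A deterministic, diagnosable ground-truth contemporaneous network; the
    defaults give a comfortably positive-definite implied precision.
    """
    P = np.zeros((p, p))
    for i in range(p):
        j = (i + 1) % p
        P[i, j] = P[j, i] = weight
    for i, j in extra_edges:
        if i < p and j < p:
            P[i, j] = P[j, i] = extra_weight
    np.fill_diagonal(P, 0.0)
    return P


def hub_chain_pcor(p: int = 11, base: float = 0.35, step: float = 0.025,
                   hub_targets=(4, 6, 8), hub_weight: float = 0.15) -> np.ndarray:
    """Sparse partial-correlation matrix with heterogeneous node strengths.

    A chain with linearly decaying edge weights plus a hub node connected to
    a few distant nodes, so the strength-centrality ranking is well separated
    — the regime in which centrality stability is diagnosable (a network with
    near-tied strengths has an unstable ranking by construction).
    """
    P = np.zeros((p, p))
    for i in range(p - 1):
        w = base - step * i
        P[i, i + 1] = P[i + 1, i] = w
    for j in hub_targets:
        if j < p:
            P[0, j] = P[j, 0] = hub_weight
    np.fill_diagonal(P, 0.0)
    return P


def sparse_temporal_matrix(p: int = 11, diag: float = 0.4,
                           cross=((3, 0, 0.25), (0, 1, 0.2), (5, 6, -0.2), (8, 4, 0.2)),
                           ) -> np.ndarray:
    """Sparse temporal matrix: autoregressive diagonal plus a few cross-lags.

    ``cross`` entries are (outcome, predictor, coefficient). The default has
    spectral radius < 1.
    """
    B = np.eye(p) * diag
    for j, k, v in cross:
        if j < p and k < p:
            B[j, k] = v
    return B


@dataclass
class GeneratorConfig:
    """Ground truth and design for a synthetic panel."""

    n_subjects: int = 100
    waves: int = 3
    p: int = 11
    B_true: np.ndarray | None = None
    contemporaneous_pcor: np.ndarray | None = None
    between_sd: np.ndarray | float = 0.5
    wave_means: np.ndarray | None = None
    thresholds: tuple = DEFAULT_THRESHOLDS
    seed: int = 0
    symptom_names: tuple = DEFAULT_SYMPTOMS
    wave_labels: tuple | None = None

    def __post_init__(self):
        if self.B_true is None:
            self.B_true = sparse_temporal_matrix(self.p)
        if self.contemporaneous_pcor is None:
            self.contemporaneous_pcor = ring_pcor(self.p)
        if self.wave_means is None:
            self.wave_means = default_wave_means(self.waves)[:, :self.p]
        self.B_true = np.asarray(self.B_true, dtype=float)
        self.contemporaneous_pcor = np.asarray(self.contemporaneous_pcor, dtype=float)
        self.wave_means = np.asarray(self.wave_means, dtype=float)
        self.between_sd = np.broadcast_to(
            np.asarray(self.between_sd, dtype=float), (self.p,)).copy()
        if self.wave_labels is None:
            self.wave_labels = tuple(f"t{i}" for i in range(self.waves))
        if len(self.symptom_names) != self.p:
            self.symptom_names = tuple(f"V{i}" for i in range(self.p))
        self.validate()

    def validate(self) -> None:
        p = self.p
        if self.B_true.shape != (p, p):
            raise ValueError("B_true must be p x p")
        radius, stable = check_stationarity(self.B_true)
        if not stable:
            raise ValueError(f"B_true spectral radius {radius:.3f} >= 1; dynamics explosive")
        P = self.contemporaneous_pcor
        if P.shape != (p, p) or not np.allclose(P, P.T, atol=1e-10):
            raise ValueError("contemporaneous_pcor must be symmetric p x p")
        if not np.allclose(np.diag(P), 0.0):
            raise ValueError("contemporaneous_pcor must have zero diagonal")
        if np.any(np.abs(P) >= 1.0):
            raise ValueError("partial correlations must lie in (-1, 1)")
        if np.linalg.eigvalsh(self.implied_precision())[0] <= 0:
            raise ValueError("contemporaneous_pcor does not imply a positive-definite precision")
        if self.wave_means.shape != (self.waves, p):
            raise ValueError("wave_means must be waves x p")
        th = np.asarray(self.thresholds, dtype=float)
        if th.size != 4 or np.any(np.diff(th) <= 0):
            raise ValueError("thresholds must be 4 strictly increasing cut-points")
        if np.any(self.between_sd < 0):
            raise ValueError("between_sd must be nonnegative")

    def implied_precision(self) -> np.ndarray:
        """Innovation precision with unit partial variances: K = I - P off-diagonal."""
        K = -self.contemporaneous_pcor.copy()
        np.fill_diagonal(K, 1.0)
        return K

    def innovation_covariance(self) -> np.ndarray:
        return np.linalg.inv(self.implied_precision())

    def to_json(self, path) -> None:
        obj = {
            "n_subjects": self.n_subjects, "waves": self.waves, "p": self.p,
            "B_true": self.B_true.tolist(),
            "contemporaneous_pcor": self.contemporaneous_pcor.tolist(),
            "between_sd": self.between_sd.tolist(),
            "wave_means": self.wave_means.tolist(),
            "thresholds": list(self.thresholds), "seed": self.seed,
            "symptom_names": list(self.symptom_names),
            "wave_labels": list(self.wave_labels),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            obj = json.load(fh)
        obj["thresholds"] = tuple(obj["thresholds"])
        obj["symptom_names"] = tuple(obj["symptom_names"])
        obj["wave_labels"] = tuple(obj["wave_labels"])
        for key in ("B_true", "contemporaneous_pcor", "between_sd", "wave_means"):
            obj[key] = np.asarray(obj[key], dtype=float)
        return cls(**obj)


def study_config(seed: int = 0, n_subjects: int = 100) -> GeneratorConfig:
    """The study-mimicking default: 100 subjects, 3 waves, 11 named symptoms,
    high admission means declining by discharge."""
    return GeneratorConfig(n_subjects=n_subjects, seed=seed)


def discretize(latent: np.ndarray, thresholds=DEFAULT_THRESHOLDS) -> np.ndarray:
    """Map latent values to ordinal scores: the score is the number of
    cut-points lying below the value, so output is in {0..4}."""
    th = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(th) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return np.searchsorted(th, np.asarray(latent, dtype=float), side="left").astype(float)


def generate_panel(config: GeneratorConfig, return_latent: bool = False):
    """Draw a synthetic ordinal panel (and optionally the latent array).

    Returns a validated :class:`SymptomPanel`; with ``return_latent=True``
    also the (n, waves, p) continuous latent array for oracle checks.
    Identical seeds give identical panels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, w, p = config.n_subjects, config.waves, config.p
    B = config.B_true
    Sigma = config.innovation_covariance()
    stat_cov = solve_discrete_lyapunov(B, Sigma)

    mu = rng.normal(0.0, 1.0, size=(n, p)) * config.between_sd
    latent = np.empty((n, w, p))
    x = rng.multivariate_normal(np.zeros(p), stat_cov, size=n, method="cholesky")
    latent[:, 0, :] = config.wave_means[0] + mu + x
    for t in range(1, w):
        eps = rng.multivariate_normal(np.zeros(p), Sigma, size=n, method="cholesky")
        x = x @ B.T + eps
        latent[:, t, :] = config.wave_means[t] + mu + x

    scores = discretize(latent, config.thresholds)
    ids = [f"S{i:04d}" for i in range(n)]
    panel = SymptomPanel(scores, ids, config.wave_labels, config.symptom_names)
    return (panel, latent) if return_latent else panel
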