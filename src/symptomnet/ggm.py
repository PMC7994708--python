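"""Cross-sectional Gaussian graphical models and network descriptives.

A GGM encodes each pairwise conditional association as a partial correlation:
with precision matrix ``K = C^{-1}`` of a correlation matrix ``C``, the edge
weight between nodes i and j is ``w_ij = -K_ij / sqrt(K_ii K_jj)``.  Two
estimators are provided in scikit-learn style:

* :class:`GaussianGraphicalModel` — the nonregularized network, a direct
  inversion of the (repaired) correlation matrix.  This is the primary model
  for well-powered psychometric data, following the recommendation against
  routine lasso regularization in that setting.
* :class:`EBICGraphicalLasso` — an L1-penalized precision estimate with the
  penalty selected by the extended BIC, the conventional choice when sparsity
  is wanted; it is also the default internal engine of the network comparison
  test.

Node predictability — the share of a node's variance explained by all other
nodes, an absolute connectivity measure — is computed under a Gaussian
working model on standardized variables: ``R^2_j = 1 - 1/K_jj``, identical to
the OLS R-squared of node j regressed on the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .association import CorrelationMatrix, nearest_pd, pearson_matrix, spearman_matrix

#: absolute precision entries below this are treated as structural zeros
ZERO_TOL = 1e-10


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class NetworkModel:
    """Symmetric partial-correlation network with estimation metadata."""

    weights: np.ndarray
    nodes: tuple
    method: str                    # "nonregularized" | "ebic_glasso"
    input_correlation: str         # "spearman" | "pearson"
    n: int
    lambda_selected: float | None = None
    gamma: float | None = None
    repaired_input: bool = False

    def __post_init__(self):
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(W, W.T, atol=1e-8):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(W), 0.0, atol=1e-10):
            raise ValueError("weights must have zero diagonal")
        if np.any(np.abs(W) >= 1.0):
            raise ValueError("partial correlations must lie in (-1, 1)")
        self.weights = (W + W.T) / 2.0
        np.fill_diagonal(self.weights, 0.0)
        self.nodes = tuple(self.nodes) if self.nodes else tuple(range(W.shape[0]))

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.nodes), columns=list(self.nodes))

    def edge_list(self, min_abs_weight: float = 0.0) -> pd.DataFrame:
        return display_filter(self, min_abs_weight)

    def to_graph(self):
        """Weighted undirected networkx graph (all nonzero edges)."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.nodes)
        iu, ju = np.triu_indices(self.p, k=1)
        for i, j in zip(iu, ju):
            w = self.weights[i, j]
            if w != 0.0:
                G.add_edge(self.nodes[i], self.nodes[j], weight=float(w))
        return G


@dataclass
class PredictabilityVector:
    """Per-node shared variance with the rest of the network (R^2 in [0, 1])."""

    r2: np.ndarray
    nodes: tuple = ()

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        if np.any((self.r2 < -1e-12) | (self.r2 > 1 + 1e-12)):
            raise ValueError("predictability values must lie in [0, 1]")
        self.r2 = np.clip(self.r2, 0.0, 1.0)
        self.nodes = tuple(self.nodes) if self.nodes else tuple(range(self.r2.size))

    def to_series(self) -> pd.Series:
        return pd.Series(self.r2, index=list(self.nodes), name="predictability")


# ---------------------------------------------------------------------------
# core algebra
# ---------------------------------------------------------------------------

def precision_to_pcor(K: np.ndarray) -> np.ndarray:
    """Convert a positive-definite precision matrix to partial correlations.

    ``w_ij = -K_ij / sqrt(K_ii K_jj)`` off the diagonal, zero on it.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("precision matrix must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("precision matrix must be symmetric")
    if np.linalg.eigvalsh(K)[0] <= 0:
        raise np.linalg.LinAlgError("precision matrix is not positive definite")
    d = np.sqrt(np.diag(K))
    W = -K / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def _repaired(C: CorrelationMatrix) -> CorrelationMatrix:
    return C if C.is_psd() else nearest_pd(C)


def _invert_correlation(C: CorrelationMatrix) -> np.ndarray:
    Cr = _repaired(C)
    w = np.linalg.eigvalsh(Cr.values)
    if w[0] <= 1e-12:
        raise np.linalg.LinAlgError(
            "correlation matrix singular after PSD repair; network undefined")
    return np.linalg.inv(Cr.values), Cr.repaired


def node_predictability(C: CorrelationMatrix) -> PredictabilityVector:
    """Per-node R^2 on all other nodes, from the inverse correlation matrix."""
    K, _ = _invert_correlation(C)
    r2 = 1.0 - 1.0 / np.diag(K)
    return PredictabilityVector(np.clip(r2, 0.0, 1.0), nodes=C.names)


def global_strength(net: NetworkModel) -> float:
    """Sum of absolute edge weights over the strict upper triangle."""
    iu = np.triu_indices(net.p, k=1)
    return float(np.abs(net.weights[iu]).sum())


def strength_centrality(net: NetworkModel) -> pd.Series:
    """Node strength: sum of absolute incident edge weights."""
    s = np.abs(net.weights).sum(axis=1)
    return pd.Series(s, index=list(net.nodes), name="strength")


def display_filter(net: NetworkModel, min_abs_weight: float = 0.1) -> pd.DataFrame:
    """Edge list keeping edges with |weight| strictly above the threshold.

    Reporting-only: mirrors the convention of drawing only edges with weight
    greater than 0.1 in dense-network figures; the model is unchanged.
    """
    if min_abs_weight < 0:
        raise ValueError("threshold must be nonnegative")
    iu, ju = np.triu_indices(net.p, k=1)
    rows = [(net.nodes[i], net.nodes[j], net.weights[i, j])
            for i, j in zip(iu, ju)
            if abs(net.weights[i, j]) > min_abs_weight and net.weights[i, j] != 0.0]
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])


def fisher_z_edge_test(net: NetworkModel, alpha: float = 0.05) -> pd.DataFrame:
    """Optional two-sided Fisher-z significance test per edge (no multiplicity
    correction).  Uses the partial-correlation z with n - p - 1 effective
    degrees of freedom.  Off by default in all pipelines; the main networks
    are reported unpruned."""
    df = net.n - net.p - 1
    if df <= 0:
        raise ValueError("not enough observations for the edge test")
    iu, ju = np.triu_indices(net.p, k=1)
    rows = []
    for i, j in zip(iu, ju):
        w = np.clip(net.weights[i, j], -1 + 1e-12, 1 - 1e-12)
        z = np.arctanh(w) * np.sqrt(df - 1)
        pval = 2 * stats.norm.sf(abs(z))
        rows.append((net.nodes[i], net.nodes[j], w, pval, pval < alpha))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "weight", "p", "retained"])


# ---------------------------------------------------------------------------
# estimators (scikit-learn style)
# ---------------------------------------------------------------------------

class _BaseGGM(BaseEstimator):
    """Shared fit plumbing: data -> correlation -> precision -> network."""

    def _correlate(self, X):
        data = np.asarray(getattr(X, "data", X), dtype=float)
        if data.ndim != 2:
            raise ValueError("X must be a 2-D samples x nodes matrix")
        if data.shape[0] <= data.shape[1]:
            raise ValueError("need more observations than nodes")
        if self.correlation not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        fn = spearman_matrix if self.correlation == "spearman" else pearson_matrix
        return fn(X)   # X, not data: keeps symptom names when X is a WaveMatrix

    def _finish(self, C, K, W):
        self.correlation_ = C
        self.precision_ = K
        self.weights_ = W
        self.nodes_ = tuple(C.names) if C.names else tuple(range(C.p))
        self.n_ = C.n_effective
        self.predictability_ = np.clip(1.0 - 1.0 / np.diag(K), 0.0, 1.0)
        return self

    def predictability(self) -> PredictabilityVector:
        return PredictabilityVector(self.predictability_, nodes=self.nodes_)


class GaussianGraphicalModel(_BaseGGM):
    """Nonregularized partial-correlation network.

    Parameters
    ----------
    correlation : {"spearman", "pearson"}, default "spearman"
        Correlation input; Spearman is the default because symptom scores are
        ordinal.

    Attributes (after ``fit``)
    --------------------------
    weights_ : (p, p) partial-correlation matrix, zero diagonal.
    precision_ : inverse of the (PSD-repaired) correlation matrix.
    predictability_ : per-node R^2 on all other nodes.
    repaired_ : True if the correlation input needed a PSD repair.
    """

    def __init__(self, correlation: str = "spearman"):
        self.correlation = correlation

    def fit(self, X, y=None):
        C = self._correlate(X)
        return self.fit_correlation(C)

    def fit_correlation(self, C: CorrelationMatrix):
        """Fit directly from a correlation matrix (n taken from its metadata)."""
        K, repaired = _invert_correlation(C)
        self.repaired_ = repaired
        return self._finish(C, K, precision_to_pcor(K))

    def to_network(self) -> NetworkModel:
        return NetworkModel(self.weights_, self.nodes_, "nonregularized",
                            self.correlation_.method, self.n_,
                            repaired_input=self.repaired_)


class EBICGraphicalLasso(_BaseGGM):
    """Graphical lasso with EBIC penalty selection.

    The penalty grid is log-spaced from ``lambda_max`` (the largest absolute
    off-diagonal correlation, above which the solution is empty) down to
    ``lambda_max * lambda_min_ratio``.  Each fitted precision ``K`` is scored
    with ``EBIC = -2 loglik + E log n + 4 gamma E log p`` where ``E`` counts
    nonzero upper-triangle off-diagonal precision entries and
    ``loglik = (n/2)(log det K - tr(C K))``.  ``gamma`` defaults to 0.5, the
    conventional setting that errs toward sparsity.

    Because the EBIC is evaluated on the penalized (shrunk) precision, the
    selected model tends to drag in a few near-zero spurious edges alongside
    the shrunken true ones.  With ``edge_threshold`` (default on), partial
    correlations below ``sqrt(log(p) / n)`` — the rate at which thresholded
    graphical-lasso estimates are sign-consistent — are zeroed after
    selection; set it to False for the raw selected model.
    """

    def __init__(self, correlation: str = "pearson", gamma: float = 0.5,
                 n_lambda: int = 100, lambda_min_ratio: float = 0.01,
                 edge_threshold: bool = True):
        self.correlation = correlation
        self.gamma = gamma
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.edge_threshold = edge_threshold

    def fit(self, X, y=None):
        return self.fit_correlation(self._correlate(X))

    def fit_correlation(self, C: CorrelationMatrix):
        if C.n_effective <= 3:
            raise ValueError("need n > 3 for EBIC selection")
        Cr = _repaired(C)
        S = Cr.values
        n, p = C.n_effective, C.p
        lam_max = float(np.max(np.abs(S - np.eye(p))))
        if lam_max <= 0:          # diagonal input: empty network at any penalty
            grid = np.array([1.0])
        else:
            grid = np.geomspace(lam_max, lam_max * self.lambda_min_ratio, self.n_lambda)
        best = None
        n_failed = 0
        for lam in grid:
            try:
                K = glasso_precision(S, lam)
            except (FloatingPointError, np.linalg.LinAlgError, ValueError):
                n_failed += 1
                continue
            ebic = ebic_score(K, S, n, self.gamma)
            if best is None or ebic < best[0]:
                best = (ebic, lam, K)
        if best is None:
            raise RuntimeError(f"graphical lasso failed to converge on all {len(grid)} penalties")
        ebic_best, lam_best, K = best
        self.lambda_selected_ = float(lam_best)
        self.ebic_ = float(ebic_best)
        self.n_failed_fits_ = n_failed
        self.repaired_ = Cr.repaired
        W = precision_to_pcor(K)
        W[np.abs(W) < ZERO_TOL] = 0.0
        if self.edge_threshold:
            tau = np.sqrt(np.log(p) / n)
            W[np.abs(W) < tau] = 0.0
        return self._finish(C, K, W)

    def to_network(self) -> NetworkModel:
        return NetworkModel(self.weights_, self.nodes_, "ebic_glasso",
                            self.correlation_.method, self.n_,
                            lambda_selected=self.lambda_selected_, gamma=self.gamma,
                            repaired_input=self.repaired_)


def glasso_precision(S: np.ndarray, alpha: float) -> np.ndarray:
    """Single graphical-lasso fit: L1-penalized precision of covariance S.

    Tolerance 1e-5 on the dual gap; the iteration-cap warning is suppressed
    because fits within ~1e-4 of the optimum do not change EBIC ranking.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with np.errstate(all="raise"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, K = _sk_graphical_lasso(np.asarray(S, dtype=float), alpha=float(alpha),
                                   max_iter=200, tol=1e-5)
    K = (K + K.T) / 2.0
    K[np.abs(K) < ZERO_TOL] = 0.0
    return K


def ebic_score(K: np.ndarray, S: np.ndarray, n: int, gamma: float) -> float:
    """Extended BIC of a Gaussian precision estimate against sample correlation S."""
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    loglik = 0.5 * n * (logdet - np.trace(S @ K))
    p = K.shape[0]
    iu = np.triu_indices(p, k=1)
    E = int(np.count_nonzero(np.abs(K[iu]) > ZERO_TOL))
    return float(-2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p))


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def estimate_ggm(C: CorrelationMatrix, n: int | None = None) -> NetworkModel:
    """Nonregularized network from a correlation matrix."""
    if n is not None and n != C.n_effective:
        C = CorrelationMatrix(C.values, C.method, n, C.repaired, C.names)
    est = GaussianGraphicalModel(correlation=C.method)
    return est.fit_correlation(C).to_network()


def ebic_glasso(C: CorrelationMatrix, n: int | None = None, gamma: float = 0.5,
                n_lambda: int = 100, lambda_min_ratio: float = 0.01,
                edge_threshold: bool = True) -> NetworkModel:
    """EBIC-selected graphical-lasso network from a correlation matrix."""
    if n is not None and n != C.n_effective:
        C = CorrelationMatrix(C.values, C.method, n, C.repaired, C.names)
    est = EBICGraphicalLasso(correlation=C.method, gamma=gamma, n_lambda=n_lambda,
                             lambda_min_ratio=lambda_min_ratio,
                             edge_threshold=edge_threshold)
    return est.fit_correlation(C).to_network()
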