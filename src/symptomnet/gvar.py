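"""Panel graphical vector autoregression: temporal + contemporaneous networks.

With a few measurement waves per subject, lag-1 dynamics are estimated by
pooling all consecutive wave transitions (t0->t1, t1->t2, ...) under a
stationarity assumption and running a multivariate least-squares regression
of each wave on the previous one.  The coefficient matrix ``B`` is the
temporal (Granger-causal) network: ``B[j, k]`` is the effect of symptom k at
the previous wave on symptom j at the current wave, so a nonzero entry means
k's past improves the prediction of j beyond j's own past.  The partial
correlations of the same-wave regression residuals form the contemporaneous
network.

This is a pooled least-squares formulation of the panel GVAR — closed-form
and directly testable — rather than a latent-variable maximum-likelihood fit;
the Granger-regression reading of the temporal matrix is identical.
Subject-mean centering is available to remove stable between-person level,
but note it induces Nickell-type bias with very few waves, so the default is
no centering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .association import CorrelationMatrix, nearest_pd
from .ggm import precision_to_pcor
from .panel import SymptomPanel


@dataclass
class TemporalModel:
    """Fitted panel GVAR: temporal matrix B, intercepts, residual networks."""

    B: np.ndarray                     # [outcome, predictor]
    intercepts: np.ndarray
    contemporaneous: np.ndarray       # partial correlations of residuals
    residual_covariance: np.ndarray
    n_transitions: int
    nodes: tuple
    centering: str = "none"
    standardized: bool = False
    se: np.ndarray | None = None      # standard errors of [intercept; B rows]
    df_resid: int = 0

    @property
    def p(self) -> int:
        return self.B.shape[0]

    def temporal_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.B, index=list(self.nodes), columns=list(self.nodes))

    def to_digraph(self):
        """Directed networkx graph of the temporal matrix (edge k -> j for B[j, k] != 0)."""
        import networkx as nx

        G = nx.DiGraph()
        G.add_nodes_from(self.nodes)
        for j in range(self.p):
            for k in range(self.p):
                if self.B[j, k] != 0.0:
                    G.add_edge(self.nodes[k], self.nodes[j], weight=float(self.B[j, k]))
        return G


class PanelGVAR(BaseEstimator):
    """Pooled least-squares panel graphical VAR(1).

    Parameters
    ----------
    centering : {"none", "subject_mean"}, default "none"
        "subject_mean" removes each subject's across-wave mean before
        stacking (within-subject dynamics only; Nickell-biased at few waves).
    standardize : bool, default False
        Z-score each symptom on the pooled used scores before fitting; makes
        ``B`` invariant to per-symptom affine rescaling of the input.

    Attributes (after ``fit``)
    --------------------------
    B_ : (p, p) temporal coefficient matrix, [outcome, predictor].
    intercepts_ : per-symptom intercepts.
    contemporaneous_ : (p, p) residual partial-correlation matrix.
    residual_covariance_ : (p, p) residual covariance.
    n_transitions_ : pooled number of wave-to-wave transitions used.
    se_ : (p+1, p) least-squares standard errors ([intercept; predictors] x outcome).
    """

    def __init__(self, centering: str = "none", standardize: bool = False):
        self.centering = centering
        self.standardize = standardize

    def fit(self, panel, y=None):
        """Fit from a :class:`SymptomPanel` or an (n, waves, p) latent array."""
        if self.centering not in ("none", "subject_mean"):
            raise ValueError(f"unknown centering {self.centering!r}")
        scores, nodes = _panel_scores(panel)
        n, w, p = scores.shape
        if w < 2:
            raise ValueError("panel GVAR needs at least 2 waves")

        prev, curr = _stack_transitions(scores, self.centering)
        if prev.shape[0] <= p + 2:
            raise ValueError(
                f"only {prev.shape[0]} pooled transitions for p={p}; need more than p + 2")
        if self.standardize:
            mu = np.nanmean(scores.reshape(-1, p), axis=0)
            sd = np.nanstd(scores.reshape(-1, p), axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("cannot standardize a constant symptom")
            prev = (prev - mu) / sd
            curr = (curr - mu) / sd

        X = np.column_stack([np.ones(prev.shape[0]), prev])
        XtX = X.T @ X
        if np.linalg.matrix_rank(XtX) < X.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient predictor matrix")
        coef, *_ = np.linalg.lstsq(X, curr, rcond=None)
        resid = curr - X @ coef
        df = X.shape[0] - X.shape[1]
        sigma2 = (resid ** 2).sum(axis=0) / df
        XtX_inv = np.linalg.inv(XtX)
        se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))

        rc = resid.T @ resid / df
        d = np.sqrt(np.diag(rc))
        if np.any(d <= 0):
            raise np.linalg.LinAlgError("degenerate residual variance")
        R = CorrelationMatrix(np.clip(rc / np.outer(d, d), -1, 1), "pearson", X.shape[0],
                              names=nodes)
        Rv = R if R.is_psd() else nearest_pd(R)
        contemporaneous = precision_to_pcor(np.linalg.inv(Rv.values))

        self.B_ = coef[1:].T
        self.intercepts_ = coef[0]
        self.contemporaneous_ = contemporaneous
        self.residual_covariance_ = rc
        self.n_transitions_ = int(X.shape[0])
        self.nodes_ = nodes
        self.se_ = se
        self.df_resid_ = int(df)
        return self

    def to_model(self) -> TemporalModel:
        return TemporalModel(B=self.B_, intercepts=self.intercepts_,
                             contemporaneous=self.contemporaneous_,
                             residual_covariance=self.residual_covariance_,
                             n_transitions=self.n_transitions_, nodes=self.nodes_,
                             centering=self.centering, standardized=self.standardize,
                             se=self.se_, df_resid=self.df_resid_)


def _panel_scores(panel):
    if isinstance(panel, SymptomPanel):
        return panel.scores, tuple(panel.symptom_names)
    arr = np.asarray(panel, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a SymptomPanel or an (n, waves, p) array")
    return arr, tuple(range(arr.shape[2]))


def _stack_transitions(scores: np.ndarray, centering: str):
    """Stack complete consecutive wave pairs over subjects (valid pairs only)."""
    n, w, p = scores.shape
    if centering == "subject_mean":
        with np.errstate(invalid="ignore"):
            scores = scores - np.nanmean(scores, axis=1, keepdims=True)
    prev_rows, curr_rows = [], []
    for t in range(1, w):
        a, b = scores[:, t - 1, :], scores[:, t, :]
        ok = np.isfinite(a).all(axis=1) & np.isfinite(b).all(axis=1)
        prev_rows.append(a[ok])
        curr_rows.append(b[ok])
    return np.vstack(prev_rows), np.vstack(curr_rows)


def estimate_panel_gvar(panel, centering: str = "none",
                        standardize: bool = False) -> TemporalModel:
    """Functional wrapper over :class:`PanelGVAR`."""
    return PanelGVAR(centering=centering, standardize=standardize).fit(panel).to_model()


def check_stationarity(B: np.ndarray) -> tuple[float, bool]:
    """Spectral radius of the temporal matrix and whether the VAR(1) is stable.

    The pooled estimator assumes constant means, variances and dynamics over
    waves; a radius >= 1 means the fitted dynamics are explosive and the
    stationarity reading of B is not tenable.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("B must be square")
    radius = float(np.max(np.abs(np.linalg.eigvals(B))))
    return radius, radius < 1.0


def temporal_edge_test(model: TemporalModel, alpha: float = 0.05,
                       holm: bool = False) -> pd.DataFrame:
    """Wald test per temporal coefficient from least-squares standard errors.

    Returns a directed edge list (from = predictor, to = outcome) with
    two-sided p-values and retain flags at ``alpha``; Holm correction
    optional, off by default.
    """
    if model.se is None:
        raise ValueError("model was estimated without stored standard errors")
    if np.any(model.se[1:] <= 0):
        raise ValueError("degenerate residual variance; Wald test undefined")
    p = model.p
    rows = []
    for j in range(p):          # outcome
        for k in range(p):      # predictor
            b = model.B[j, k]
            se = model.se[1 + k, j]
            t = b / se
            pval = 2 * stats.t.sf(abs(t), model.df_resid)
            rows.append((model.nodes[k], model.nodes[j], b, se, pval))
    out = pd.DataFrame(rows, columns=["from", "to", "coefficient", "se", "p"])
    if holm:
        m = len(out)
        order = np.argsort(out["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_adjusted"] = adj
        out["retained"] = out["p_adjusted"] < alpha
    else:
        out["retained"] = out["p"] < alpha
    return out
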