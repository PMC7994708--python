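"""Bootstrap accuracy and case-drop stability for cross-sectional networks.

Follows the standard resampling guidelines used for psychometric networks:

* edge-weight accuracy — nonparametric bootstrap over subjects, reporting a
  2.5%/97.5% quantile interval per edge;
* centrality stability — case-drop subsampling: for a grid of drop
  proportions, node strength is recomputed on subsamples and correlated with
  the full-sample strength; the CS-coefficient is the largest proportion at
  which that correlation stays >= 0.7 in at least 95% of resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .ggm import strength_centrality
from .nct import EstimatorConfig

#: default case-drop grid, 5% steps up to the conventional 75% ceiling
DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))

CS_CORRELATION = 0.7
CS_PROBABILITY = 0.95


@dataclass
class BootstrapResult:
    kind: str                     # "edge_ci" | "case_drop"
    n_boot: int
    seed: int
    estimator_config: EstimatorConfig
    # edge_ci fields
    edge_table: pd.DataFrame | None = None
    # case_drop fields
    drop_curve: pd.DataFrame | None = None
    cs_coefficient: float | None = None
    cs_label: str | None = None   # "<0.05", numeric string, or ">0.75"
    n_redrawn: int = 0
    skipped_proportions: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return self.edge_table if self.kind == "edge_ci" else self.drop_curve


def _data_of(X) -> np.ndarray:
    return np.asarray(getattr(X, "data", X), dtype=float)


def _names_of(X, p):
    names = tuple(getattr(X, "symptom_names", ()))
    return names if names else tuple(range(p))


def edge_ci_bootstrap(X, n_boot: int = 1000, seed: int = 0,
                      estimator: EstimatorConfig | None = None) -> BootstrapResult:
    """Nonparametric bootstrap confidence intervals for every edge weight.

    Subjects are resampled with replacement ``n_boot`` times and the network
    re-estimated per resample; a resample on which estimation fails (e.g. a
    zero-variance column) is redrawn and the redraw counted. Reproducible
    given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    estimator = estimator or EstimatorConfig(method="nonregularized", correlation="spearman")
    data = _data_of(X)
    n, p = data.shape
    names = _names_of(X, p)
    point = estimator.build().fit(data).to_network().weights
    iu, ju = np.triu_indices(p, k=1)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, iu.size))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            W = estimator.build().fit(data[idx]).to_network().weights
        except (ValueError, np.linalg.LinAlgError, RuntimeError):
            n_redrawn += 1
            if n_redrawn > 100 * n_boot:
                raise RuntimeError("bootstrap estimation failing persistently")
            continue
        boots[b] = W[iu, ju]
        b += 1

    lo, hi = np.quantile(boots, [0.025, 0.975], axis=0)
    est = point[iu, ju]
    table = pd.DataFrame({
        "node_a": [names[i] for i in iu],
        "node_b": [names[j] for j in ju],
        "estimate": est,
        "lower": np.minimum(lo, est),
        "upper": np.maximum(hi, est),
        "boot_mean": boots.mean(axis=0),
    })
    return BootstrapResult(kind="edge_ci", n_boot=n_boot, seed=seed,
                           estimator_config=estimator, edge_table=table,
                           n_redrawn=n_redrawn)


def case_drop_stability(X, statistic: str = "strength",
                        drop_grid=DEFAULT_DROP_GRID, n_boot: int = 250, seed: int = 0,
                        estimator: EstimatorConfig | None = None) -> BootstrapResult:
    """Case-drop subsampling stability of strength centrality.

    For each drop proportion, subjects are subsampled without replacement,
    node strength recomputed, and Spearman-correlated with the full-sample
    strength (Spearman because centrality vectors are short and tied). The
    CS-coefficient is reported on the grid, as "<min" when even the smallest
    proportion fails the 0.7/95% rule, and as ">max" when the largest passes.
    """
    if statistic != "strength":
        raise ValueError("only strength centrality is supported")
    drop_grid = tuple(float(d) for d in drop_grid)
    if not all(0 < d <= 0.75 for d in drop_grid):
        raise ValueError("drop proportions must lie in (0, 0.75]")
    estimator = estimator or EstimatorConfig(method="nonregularized", correlation="spearman")
    data = _data_of(X)
    n, p = data.shape
    full = strength_centrality(estimator.build().fit(data).to_network()).to_numpy()

    rng = np.random.default_rng(seed)
    rows = []
    skipped = []
    for d in sorted(drop_grid):
        m = int(round(n * (1 - d)))
        if m < p + 2:
            skipped.append(d)
            continue
        cors = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.choice(n, size=m, replace=False)
            try:
                sub = strength_centrality(estimator.build().fit(data[idx]).to_network()).to_numpy()
                with warnings.catch_warnings():
                    # constant strength vectors (empty networks) yield an
                    # undefined correlation, handled as a failure below
                    warnings.simplefilter("ignore")
                    rho = spearmanr(full, sub).statistic
            except (ValueError, np.linalg.LinAlgError, RuntimeError):
                rho = np.nan
            cors[b] = rho
        ok = np.isfinite(cors)
        # an undefined correlation (e.g. an empty network with constant zero
        # strength) cannot certify stability, so it counts as a failure
        prop_ok = float(np.mean(ok & (np.nan_to_num(cors, nan=-np.inf) >= CS_CORRELATION)))
        rows.append({"drop": d, "n_sub": m, "mean_correlation": float(np.nanmean(cors)) if ok.any() else np.nan,
                     "prop_above_0.7": prop_ok, "n_valid": int(ok.sum())})
    curve = pd.DataFrame(rows)

    passing = curve.loc[curve["prop_above_0.7"] >= CS_PROBABILITY, "drop"]
    if passing.empty:
        cs, label = 0.0, f"<{min(drop_grid):g}"
    else:
        # CS = largest proportion such that it and every smaller one pass
        cs = 0.0
        for _, row in curve.iterrows():
            if row["prop_above_0.7"] >= CS_PROBABILITY:
                cs = row["drop"]
            else:
                break
        label = f">{max(drop_grid):g}" if cs == max(drop_grid) else f"{cs:g}"
    return BootstrapResult(kind="case_drop", n_boot=n_boot, seed=seed,
                           estimator_config=estimator, drop_curve=curve,
                           cs_coefficient=float(cs), cs_label=label,
                           skipped_proportions=tuple(skipped))
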