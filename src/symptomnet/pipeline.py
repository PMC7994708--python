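"""End-to-end study workflow and report export.

Runs, in order: per-wave descriptives, per-wave cross-sectional networks
(Spearman, nonregularized by default) with node predictability, optional
bootstrap stability, all pairwise network comparison tests on global
strength, and the panel GVAR temporal network.  The report is a pure
function of (panel, config): identical inputs give identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ggm import (GaussianGraphicalModel, EBICGraphicalLasso, NetworkModel,
                  PredictabilityVector, global_strength, strength_centrality,
                  display_filter)
from .gvar import PanelGVAR, TemporalModel, check_stationarity, temporal_edge_test
from .nct import EstimatorConfig, NCTResult, nct_global_strength
from .panel import SymptomPanel, summarize, wave_matrix
from .stability import BootstrapResult, case_drop_stability, edge_ci_bootstrap


@dataclass
class StudyConfig:
    """Everything the pipeline needs; echoed into the report for audit."""

    correlation: str = "spearman"
    method: str = "nonregularized"      # cross-sectional estimator
    gamma: float = 0.5
    nct_estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    n_perm: int = 1000
    paired: bool | None = None          # None = auto (paired when ids match)
    run_stability: bool = False
    n_boot: int = 250
    gvar_centering: str = "none"
    gvar_standardize: bool = False
    alpha: float = 0.05
    display_threshold: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["nct_estimator"] = self.nct_estimator.to_dict()
        return d


@dataclass
class StudyReport:
    config: StudyConfig
    descriptives: dict[str, pd.DataFrame]
    networks: dict[str, NetworkModel]
    predictability: dict[str, PredictabilityVector]
    nct_results: dict[str, NCTResult]
    temporal: TemporalModel | None
    stability: dict[str, dict[str, BootstrapResult]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def global_strengths(self) -> dict[str, float]:
        return {w: global_strength(net) for w, net in self.networks.items()}

    def predictability_table(self) -> pd.DataFrame:
        """Symptoms x waves table of node predictability."""
        return pd.DataFrame({w: v.to_series() for w, v in self.predictability.items()})

    def summary(self) -> dict:
        out = {
            "version": self.version,
            "config": self.config.to_dict(),
            "waves": list(self.networks.keys()),
            "global_strength": self.global_strengths(),
            "nct": {pair: r.summary() for pair, r in self.nct_results.items()},
            "failures": self.failures,
        }
        if self.temporal is not None:
            radius, stable = check_stationarity(self.temporal.B)
            out["temporal"] = {
                "n_transitions": self.temporal.n_transitions,
                "spectral_radius": radius,
                "stable": stable,
                "centering": self.temporal.centering,
            }
        if self.stability:
            out["stability"] = {
                w: {"cs_coefficient": r["case_drop"].cs_label}
                for w, r in self.stability.items() if "case_drop" in r
            }
        return out


def _cross_sectional_estimator(config: StudyConfig):
    if config.method == "nonregularized":
        return GaussianGraphicalModel(correlation=config.correlation)
    if config.method == "ebic_glasso":
        return EBICGraphicalLasso(correlation=config.correlation, gamma=config.gamma)
    raise ValueError(f"unknown method {config.method!r}")


def run_full_study(panel: SymptomPanel, config: StudyConfig | None = None) -> StudyReport:
    """Execute the full workflow on a panel; stages fail independently."""
    config = config or StudyConfig()
    if panel.n_waves < 2:
        raise ValueError("study pipeline needs at least 2 waves")

    descriptives, networks, predictability, stability, failures = {}, {}, {}, {}, {}
    matrices = {}
    for wave in panel.wave_labels:
        try:
            descriptives[wave] = summarize(panel, wave)
            X = wave_matrix(panel, wave)
            matrices[wave] = X
            est = _cross_sectional_estimator(config).fit(X)
            networks[wave] = est.to_network()
            predictability[wave] = est.predictability()
        except Exception as exc:   # stage isolation: later stages still run
            failures[f"cross_sectional[{wave}]"] = f"{type(exc).__name__}: {exc}"

    if config.run_stability:
        boot_est = EstimatorConfig(method=config.method, correlation=config.correlation,
                                   gamma=config.gamma)
        for wave, X in matrices.items():
            try:
                stability[wave] = {
                    "edge_ci": edge_ci_bootstrap(X, n_boot=max(100, config.n_boot),
                                                 seed=config.seed, estimator=boot_est),
                    "case_drop": case_drop_stability(X, n_boot=config.n_boot,
                                                     seed=config.seed, estimator=boot_est),
                }
            except Exception as exc:
                failures[f"stability[{wave}]"] = f"{type(exc).__name__}: {exc}"

    nct_results = {}
    for w1, w2 in combinations(panel.wave_labels, 2):
        if w1 not in matrices or w2 not in matrices:
            continue
        key = f"{w1}-{w2}"
        try:
            nct_results[key] = nct_global_strength(
                matrices[w1], matrices[w2], paired=config.paired,
                n_perm=config.n_perm, seed=config.seed,
                estimator=config.nct_estimator)
        except Exception as exc:
            failures[f"nct[{key}]"] = f"{type(exc).__name__}: {exc}"

    temporal = None
    try:
        temporal = PanelGVAR(centering=config.gvar_centering,
                             standardize=config.gvar_standardize).fit(panel).to_model()
    except Exception as exc:
        failures["temporal"] = f"{type(exc).__name__}: {exc}"

    return StudyReport(config=config, descriptives=descriptives, networks=networks,
                       predictability=predictability, nct_results=nct_results,
                       temporal=temporal, stability=stability, failures=failures)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_network(net: NetworkModel, directory: Path, stem: str,
                   display_threshold: float = 0.0) -> None:
    import networkx as nx

    net.to_frame().to_csv(directory / f"{stem}_weights.csv")
    display_filter(net, display_threshold).to_csv(directory / f"{stem}_edges.csv", index=False)
    nx.write_graphml(net.to_graph(), directory / f"{stem}.graphml")


def export_report(report: StudyReport, directory) -> list[str]:
    """Write every report artifact to a directory; returns the file names.

    Weight-matrix CSVs, display-thresholded edge lists and GraphML per wave,
    a symptoms x waves predictability CSV, per-pair NCT JSON, the directed
    temporal edge list and GraphML, stability CSVs when run, and a single
    summary JSON.
    """
    import networkx as nx

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not directory.is_dir():
        raise NotADirectoryError(str(directory))

    for wave, net in report.networks.items():
        export_network(net, directory, f"network_{wave}",
                       report.config.display_threshold)
        report.descriptives[wave].to_csv(directory / f"descriptives_{wave}.csv")
    if report.predictability:
        report.predictability_table().to_csv(directory / "predictability.csv")
    for pair, res in report.nct_results.items():
        res.to_json(directory / f"nct_{pair}.json")
    if report.temporal is not None:
        edges = temporal_edge_test(report.temporal, alpha=report.config.alpha)
        edges.to_csv(directory / "temporal_edges.csv", index=False)
        report.temporal.temporal_frame().to_csv(directory / "temporal_B.csv")
        nx.write_graphml(report.temporal.to_digraph(), directory / "temporal.graphml")
    for wave, boots in report.stability.items():
        boots["edge_ci"].edge_table.to_csv(directory / f"stability_edge_ci_{wave}.csv", index=False)
        boots["case_drop"].drop_curve.to_csv(directory / f"stability_case_drop_{wave}.csv", index=False)
    with open(directory / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, default=_json_default)
    return sorted(p.name for p in directory.iterdir())


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
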