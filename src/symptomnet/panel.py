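"""Ordinal symptom panel data: container, readers, descriptives.

The raw material for every estimator in this package is a subjects x waves x
symptoms array of clinician-rated ordinal scores (0-4 Likert scale, as on the
Young Mania Rating Scale rescaled to a common 0-4 range).  Panels are stored
dense with NaN marking a missing administration; per-wave matrices used by the
cross-sectional estimators are extracted with an explicit missing-data policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default symptom labels, matching the eleven YMRS items.
DEFAULT_SYMPTOMS = (
    "Mood", "Motor", "Sexual", "Sleep", "Irritable", "Speech",
    "LgTtAbn", "Content", "Aggressive", "Appearance", "Insight",
)

DEFAULT_WAVES = ("t0", "t1", "t2")

SCORE_MIN = 0
SCORE_MAX = 4


class PanelSchemaError(ValueError):
    """A panel file does not have the required columns."""


class PanelValidationError(ValueError):
    """Panel content violates the score invariants (range, integrality, duplicates)."""


@dataclass
class SymptomPanel:
    """Subjects x waves x symptoms ordinal score array.

    Parameters
    ----------
    scores : ndarray of shape (n_subjects, n_waves, n_symptoms)
        Float array; NaN marks a missing score, every non-missing entry must
        be an integer in [0, 4].
    subject_ids : sequence
        Unique subject identifiers, one per row of ``scores``.
    wave_labels : sequence of str
        Time-ordered wave labels.
    symptom_names : sequence of str
        Symptom labels, no duplicates.
    """

    scores: np.ndarray
    subject_ids: list = field(default_factory=list)
    wave_labels: tuple = DEFAULT_WAVES
    symptom_names: tuple = DEFAULT_SYMPTOMS

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.subject_ids = list(self.subject_ids)
        self.wave_labels = tuple(self.wave_labels)
        self.symptom_names = tuple(self.symptom_names)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.scores.ndim != 3:
            raise PanelValidationError("scores must be a 3-way array (subject, wave, symptom)")
        n, w, p = self.scores.shape
        if len(self.subject_ids) != n:
            raise PanelValidationError(f"{len(self.subject_ids)} subject ids for {n} score rows")
        if len(self.wave_labels) != w:
            raise PanelValidationError(f"{len(self.wave_labels)} wave labels for {w} waves")
        if len(self.symptom_names) != p:
            raise PanelValidationError(f"{len(self.symptom_names)} symptom names for {p} columns")
        if len(set(self.subject_ids)) != n:
            raise PanelValidationError("duplicate subject ids")
        if len(set(self.symptom_names)) != p:
            raise PanelValidationError("duplicate symptom names")
        if len(set(self.wave_labels)) != w:
            raise PanelValidationError("duplicate wave labels")
        bad = self._offending_cells()
        if bad:
            cells = ", ".join(
                f"(subject={s}, wave={wl}, symptom={sym}, value={v:g})" for s, wl, sym, v in bad[:10]
            )
            more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
            raise PanelValidationError(
                f"scores must be integers in [{SCORE_MIN}, {SCORE_MAX}]; offending cells: {cells}{more}"
            )

    def _offending_cells(self):
        bad = []
        finite = np.isfinite(self.scores)
        ok = np.zeros_like(finite)
        ok[finite] = (
            (self.scores[finite] >= SCORE_MIN)
            & (self.scores[finite] <= SCORE_MAX)
            & (self.scores[finite] == np.round(self.scores[finite]))
        )
        for i, j, k in zip(*np.nonzero(finite & ~ok)):
            bad.append((self.subject_ids[i], self.wave_labels[j], self.symptom_names[k],
                        self.scores[i, j, k]))
        return bad

    # -- convenience -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_waves(self) -> int:
        return self.scores.shape[1]

    @property
    def n_symptoms(self) -> int:
        return self.scores.shape[2]

    def wave_index(self, wave: str) -> int:
        try:
            return self.wave_labels.index(wave)
        except ValueError:
            raise KeyError(f"unknown wave label {wave!r}; panel has {list(self.wave_labels)}") from None

    def to_long(self) -> pd.DataFrame:
        """Long-format frame: one row per (subject, wave), symptom columns."""
        rows = []
        for i, sid in enumerate(self.subject_ids):
            for j, wl in enumerate(self.wave_labels):
                row = {"subject": sid, "wave": wl}
                row.update({sym: self.scores[i, j, k] for k, sym in enumerate(self.symptom_names)})
                rows.append(row)
        return pd.DataFrame(rows)

    def to_wide(self) -> pd.DataFrame:
        """Wide-format frame: one row per subject, wave-index-suffixed columns (Mood0, Mood1, ...)."""
        cols = {"subject": self.subject_ids}
        for j in range(self.n_waves):
            for k, sym in enumerate(self.symptom_names):
                cols[f"{sym}{j}"] = self.scores[:, j, k]
        return pd.DataFrame(cols)


@dataclass
class WaveMatrix:
    """Complete-case score matrix for one wave (rows sorted by subject id)."""

    wave: str
    data: np.ndarray  # n x p, no missing entries
    subject_ids: list
    symptom_names: tuple = DEFAULT_SYMPTOMS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("WaveMatrix data must be 2-D")
        if np.isnan(self.data).any():
            raise ValueError("WaveMatrix must not contain missing entries")
        if self.data.shape[0] != len(self.subject_ids):
            raise ValueError("row count does not match subject ids")
        if self.data.shape[1] != len(self.symptom_names):
            raise ValueError("column count does not match symptom names")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_panel(path, dialect: str = "long", symptom_names=None) -> SymptomPanel:
    """Read a CSV symptom panel.

    ``long`` dialect: columns ``subject, wave, <symptom>...``; one row per
    subject x wave. ``wide`` dialect: columns ``subject, Mood0, ..., Insight2``
    with the integer wave index appended to the symptom name; wave labels
    become ``t0, t1, ...``.

    Out-of-range or non-integer scores raise :class:`PanelValidationError`
    naming the offending cells; they are never silently clipped.
    """
    df = pd.read_csv(path)
    if dialect == "long":
        return _panel_from_long(df, symptom_names)
    if dialect == "wide":
        return _panel_from_wide(df, symptom_names)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")


def _panel_from_long(df: pd.DataFrame, symptom_names=None) -> SymptomPanel:
    required = {"subject", "wave"}
    if not required.issubset(df.columns):
        raise PanelSchemaError(f"long dialect requires columns {sorted(required)}; got {list(df.columns)}")
    symptoms = tuple(symptom_names) if symptom_names else tuple(
        c for c in df.columns if c not in ("subject", "wave"))
    missing = [s for s in symptoms if s not in df.columns]
    if missing:
        raise PanelSchemaError(f"missing symptom columns: {missing}")
    if not symptoms:
        raise PanelSchemaError("no symptom columns found")
    dup = df.duplicated(subset=["subject", "wave"])
    if dup.any():
        pairs = df.loc[dup, ["subject", "wave"]].values.tolist()
        raise PanelValidationError(f"duplicate (subject, wave) rows: {pairs[:5]}")
    subjects = sorted(df["subject"].unique().tolist(), key=str)
    waves = _ordered_waves(df["wave"].unique().tolist())
    scores = np.full((len(subjects), len(waves), len(symptoms)), np.nan)
    si = {s: i for i, s in enumerate(subjects)}
    wi = {w: j for j, w in enumerate(waves)}
    for _, row in df.iterrows():
        scores[si[row["subject"]], wi[row["wave"]], :] = [row[s] for s in symptoms]
    return SymptomPanel(scores, subjects, tuple(waves), symptoms)


def _panel_from_wide(df: pd.DataFrame, symptom_names=None) -> SymptomPanel:
    if "subject" not in df.columns:
        raise PanelSchemaError("wide dialect requires a 'subject' column")
    symptoms = tuple(symptom_names) if symptom_names else _infer_wide_symptoms(df)
    wave_idx = sorted({int(c[len(s):]) for c in df.columns for s in symptoms
                       if c.startswith(s) and c[len(s):].isdigit()})
    if not wave_idx:
        raise PanelSchemaError("no wave-suffixed symptom columns (e.g. Mood0) found")
    for s in symptoms:
        for j in wave_idx:
            if f"{s}{j}" not in df.columns:
                raise PanelSchemaError(f"missing column {s}{j}")
    df = df.sort_values("subject", key=lambda c: c.astype(str)).reset_index(drop=True)
    subjects = df["subject"].tolist()
    scores = np.full((len(subjects), len(wave_idx), len(symptoms)), np.nan)
    for j, w in enumerate(wave_idx):
        for k, s in enumerate(symptoms):
            scores[:, j, k] = df[f"{s}{w}"].to_numpy(dtype=float)
    waves = tuple(f"t{w}" for w in wave_idx)
    return SymptomPanel(scores, subjects, waves, symptoms)


def _infer_wide_symptoms(df: pd.DataFrame):
    """Strip trailing digits from wave-suffixed columns, preserving order."""
    seen = []
    for c in df.columns:
        if c == "subject":
            continue
        base = c.rstrip("0123456789")
        if base and base != c and base not in seen:
            seen.append(base)
    if not seen:
        raise PanelSchemaError("could not infer symptom names from wide columns")
    return tuple(seen)


def _ordered_waves(labels):
    """Wave labels sorted by trailing integer when present, else lexically."""
    def key(w):
        s = str(w)
        digits = "".join(ch for ch in s if ch.isdigit())
        return (0, int(digits)) if digits else (1, s)
    return sorted(labels, key=key)


def write_panel(panel: SymptomPanel, path, dialect: str = "long") -> None:
    """Write a panel back to CSV in either dialect (NaN cells left empty)."""
    frame = panel.to_long() if dialect == "long" else panel.to_wide()
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# descriptives and extraction
# ---------------------------------------------------------------------------

def summarize(panel: SymptomPanel, wave: str) -> pd.DataFrame:
    """Per-symptom descriptive statistics at one wave.

    Returns a frame indexed by symptom with columns ``mean, sd, min, max``;
    the standard deviation uses the n-1 denominator and missing scores are
    excluded per symptom.
    """
    j = panel.wave_index(wave)
    out = {}
    for k, sym in enumerate(panel.symptom_names):
        col = panel.scores[:, j, k]
        col = col[np.isfinite(col)]
        if col.size == 0:
            out[sym] = dict(mean=np.nan, sd=np.nan, min=np.nan, max=np.nan)
        else:
            sd = float(np.std(col, ddof=1)) if col.size > 1 else np.nan
            out[sym] = dict(mean=float(np.mean(col)), sd=sd,
                            min=float(np.min(col)), max=float(np.max(col)))
    return pd.DataFrame(out).T[["mean", "sd", "min", "max"]]


def wave_matrix(panel: SymptomPanel, wave: str, missing_policy: str = "listwise") -> WaveMatrix:
    """Extract the complete-case n x p score matrix at one wave.

    Under the (only) ``listwise`` policy, subjects missing any score at the
    wave are dropped. Rows are ordered by subject id so downstream estimates
    are independent of input row order. Raises if fewer than p+2 complete
    subjects remain, since the network estimators are undefined there.
    """
    if missing_policy != "listwise":
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    j = panel.wave_index(wave)
    block = panel.scores[:, j, :]
    keep = np.isfinite(block).all(axis=1)
    order = np.argsort(np.array([str(s) for s in panel.subject_ids], dtype=object))
    order = order[keep[order]]
    p = panel.n_symptoms
    if order.size < p + 2:
        raise ValueError(
            f"wave {wave!r} has {order.size} complete subjects; need at least {p + 2}")
    return WaveMatrix(wave=wave, data=block[order], subject_ids=[panel.subject_ids[i] for i in order],
                      symptom_names=panel.symptom_names)
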