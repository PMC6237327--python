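"""The "stroke clock": estimating hours since stroke onset from a gene panel.

A panel of genes with stereotyped, temporally overlapping expression
profiles is trained by (1) recording each panel gene's mean and SD over
all training samples, and (2) averaging the standardized values per
design timepoint into a per-gene centroid curve. A new sample is placed
in time by standardizing its panel values with the *training* statistics
(a single sample cannot standardize itself) and finding the point on a
dense time grid where the mean squared deviation from the interpolated
centroid curves is smallest. Interpolation is piecewise-linear in
log(1 + t): the sampling grid (0, 1, 2, 3, 6, 24 h) is roughly uniform
on that axis, whereas linear-in-hours interpolation would let the
6-24 h gap dominate. Ties in the score break toward the earliest time
(clinically conservative: favors treating). The estimate is labeled
"within" or "beyond" a decision window (default 4.5 h, the thrombolysis
eligibility horizon).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import UserInputError

DEFAULT_TAU_WINDOW_H = 4.5
DEFAULT_GRID_STEP_H = 0.1
ARCHETYPE_ORDER = ("A", "B", "C", "D", "E", "F", "G", "H")


def select_panel(
    ranked: pd.DataFrame,
    archetypes: pd.Series,
    k_per_archetype: int = 3,
) -> list[str]:
    """Top-k most significant genes from each archetype present.

    ``ranked`` is the output of rank_and_threshold (indexed by gene, with
    a ``rank`` column); ``archetypes`` maps gene -> label. Labels OTHER /
    NULL are ignored. Deterministic: archetypes are visited in A..H
    order and genes in rank order.
    """
    if k_per_archetype < 1:
        raise UserInputError("k_per_archetype must be >= 1")
    labels = archetypes.reindex(ranked.index)
    usable = labels[labels.isin(ARCHETYPE_ORDER)]
    if usable.empty:
        raise UserInputError("no archetype-labeled genes to select from")
    panel: list[str] = []
    for label in ARCHETYPE_ORDER:
        members = usable[usable == label].index
        if len(members) == 0:
            continue
        by_rank = ranked.loc[members].sort_values("rank").index.tolist()
        if len(by_rank) < k_per_archetype:
            warnings.warn(
                f"archetype {label} has only {len(by_rank)} genes "
                f"(requested {k_per_archetype})", stacklevel=2,
            )
        panel.extend(by_rank[:k_per_archetype])
    return panel


@dataclass
class TimeEstimate:
    """One sample's estimated hours-since-onset."""

    t_hat: float
    score: float                    # mean squared deviation at t_hat
    window: str                     # "within" or "beyond"
    n_genes_used: int


@dataclass
class EvaluationReport:
    """Leave-one-animal-out evaluation of a clock panel."""

    estimates: pd.DataFrame         # sample_id, animal, time_h, t_hat, ...
    median_abs_error_h: float
    window_accuracy: float
    tau_window_h: float
    settings: dict = field(default_factory=dict)


class StrokeClock(RegressorMixin, BaseEstimator):
    """Nearest-temporal-profile estimator of hours since stroke onset.

    ``fit(X, t)`` takes X of shape (n_samples, n_panel_genes) — a
    DataFrame preserves gene names — and t the per-sample time in hours.
    ``predict(X)`` returns the estimated hours for each row.

    Parameters
    ----------
    grid_step_h : float
        Resolution of the candidate-time grid on [0, max design time].
    tau_window_h : float
        Decision window separating "within" from "beyond".

    Attributes
    ----------
    panel_ : gene names; gene_means_, gene_sds_ : training statistics;
    timepoints_ : design hours; centroids_ : standardized per-timepoint
    means (timepoints x genes); time_grid_ : candidate times.
    """

    def __init__(self, grid_step_h: float = DEFAULT_GRID_STEP_H,
                 tau_window_h: float = DEFAULT_TAU_WINDOW_H):
        self.grid_step_h = grid_step_h
        self.tau_window_h = tau_window_h

    # -- fitting -----------------------------------------------------------

    def fit(self, X, t):
        if isinstance(X, pd.DataFrame):
            panel = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            panel = [f"g{i}" for i in range(values.shape[1])]
        t = np.asarray(t, dtype=float)
        if values.ndim != 2 or values.shape[0] != t.shape[0]:
            raise UserInputError("X must be samples x genes matching len(t)")
        if values.shape[1] == 0:
            raise UserInputError("panel is empty")
        if np.isnan(values).any():
            raise UserInputError("panel matrix contains missing values")
        timepoints = np.array(sorted(set(t)))
        if len(timepoints) < 2:
            raise UserInputError("training data must span >= 2 timepoints")
        max_t = float(timepoints[-1])
        if not (0 < self.tau_window_h < max_t):
            raise UserInputError("tau_window_h must lie inside the design span")

        means = values.mean(axis=0)
        sds = values.std(axis=0, ddof=1)
        if np.any(sds <= 0):
            bad = panel[int(np.argmin(sds))]
            raise UserInputError(f"panel gene {bad!r} has zero variance in training")
        z = (values - means) / sds
        centroids = np.vstack([z[t == tp].mean(axis=0) for tp in timepoints])

        grid = np.arange(0.0, max_t + self.grid_step_h / 2, self.grid_step_h)
        grid = np.unique(np.round(np.concatenate([grid, timepoints]), 9))

        self.panel_ = panel
        self.gene_means_ = means
        self.gene_sds_ = sds
        self.timepoints_ = timepoints
        self.centroids_ = centroids
        self.time_grid_ = grid
        # centroid curves sampled on the grid, linear in log1p(time)
        u_design = np.log1p(timepoints)
        u_grid = np.log1p(grid)
        self.curve_ = np.column_stack([
            np.interp(u_grid, u_design, centroids[:, j])
            for j in range(centroids.shape[1])
        ])
        return self

    # -- estimation --------------------------------------------------------

    def _scores(self, z: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Mean squared deviation from the centroid curves, per grid time."""
        diff = self.curve_[:, cols] - z[None, :]
        return (diff ** 2).mean(axis=1)

    def estimate(self, X) -> list[TimeEstimate]:
        """Per-sample time estimates with scores and window labels.

        Panel genes missing from a DataFrame input are dropped with a
        warning; fewer than 2 usable genes is an error.
        """
        if not hasattr(self, "curve_"):
            raise UserInputError("StrokeClock is not fitted")
        if isinstance(X, pd.DataFrame):
            present = [g for g in self.panel_ if g in X.columns]
            absent = [g for g in self.panel_ if g not in X.columns]
            if absent:
                warnings.warn(f"panel genes missing from input: {absent}", stacklevel=2)
            if len(present) < 2:
                raise UserInputError(
                    f"need >= 2 usable panel genes, have {len(present)}"
                )
            cols = np.array([self.panel_.index(g) for g in present])
            values = X[present].to_numpy(dtype=float)
        else:
            values = np.atleast_2d(np.asarray(X, dtype=float))
            if values.shape[1] != len(self.panel_):
                raise UserInputError(
                    f"expected {len(self.panel_)} panel genes, got {values.shape[1]}"
                )
            cols = np.arange(len(self.panel_))
        out = []
        for row in values:
            z = (row - self.gene_means_[cols]) / self.gene_sds_[cols]
            scores = self._scores(z, cols)
            i = int(np.argmin(scores))      # ties -> earliest grid time
            t_hat = float(self.time_grid_[i])
            out.append(TimeEstimate(
                t_hat=t_hat,
                score=float(scores[i]),
                window="within" if t_hat <= self.tau_window_h else "beyond",
                n_genes_used=len(cols),
            ))
        return out

    def predict(self, X) -> np.ndarray:
        return np.array([e.t_hat for e in self.estimate(X)])

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        if not hasattr(self, "curve_"):
            raise UserInputError("StrokeClock is not fitted")
        payload = {
            "grid_step_h": self.grid_step_h,
            "tau_window_h": self.tau_window_h,
            "panel": self.panel_,
            "gene_means": self.gene_means_.tolist(),
            "gene_sds": self.gene_sds_.tolist(),
            "timepoints_h": self.timepoints_.tolist(),
            "centroids": self.centroids_.tolist(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StrokeClock":
        payload = json.loads(text)
        model = cls(grid_step_h=payload["grid_step_h"],
                    tau_window_h=payload["tau_window_h"])
        model.panel_ = list(payload["panel"])
        model.gene_means_ = np.array(payload["gene_means"])
        model.gene_sds_ = np.array(payload["gene_sds"])
        model.timepoints_ = np.array(payload["timepoints_h"])
        model.centroids_ = np.array(payload["centroids"])
        max_t = float(model.timepoints_[-1])
        grid = np.arange(0.0, max_t + model.grid_step_h / 2, model.grid_step_h)
        model.time_grid_ = np.unique(np.round(np.concatenate([grid, model.timepoints_]), 9))
        u_design = np.log1p(model.timepoints_)
        u_grid = np.log1p(model.time_grid_)
        model.curve_ = np.column_stack([
            np.interp(u_grid, u_design, model.centroids_[:, j])
            for j in range(model.centroids_.shape[1])
        ])
        return model


# ---------------------------------------------------------------------------
# functional wrappers on the genes x samples file layout


def _panel_matrix(matrix: pd.DataFrame, sample_sheet: pd.DataFrame,
                  panel: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    missing = [g for g in panel if g not in matrix.index]
    if missing:
        raise UserInputError(f"panel genes absent from matrix: {missing}")
    sheet = sample_sheet.set_index("sample_id").loc[list(matrix.columns)]
    X = matrix.loc[panel].T
    return X, sheet["time_h"].to_numpy(dtype=float)


def train_clock(matrix: pd.DataFrame, sample_sheet: pd.DataFrame,
                panel: list[str], **settings) -> StrokeClock:
    """Fit a :class:`StrokeClock` from a genes x samples matrix."""
    X, t = _panel_matrix(matrix, sample_sheet, panel)
    return StrokeClock(**settings).fit(X, t)


def estimate_time(model: StrokeClock, sample_vector: pd.Series | np.ndarray) -> TimeEstimate:
    """Estimate one sample's hours-since-onset from its panel values."""
    if isinstance(sample_vector, pd.Series):
        X = sample_vector.to_frame().T
    else:
        X = np.atleast_2d(sample_vector)
    return model.estimate(X)[0]


def evaluate_loao(matrix: pd.DataFrame, sample_sheet: pd.DataFrame,
                  panel: list[str], **settings) -> EvaluationReport:
    """Leave-one-animal-out evaluation: per-fold training excludes every
    sample of the held-out animal; each held-out sample is then timed."""
    animals = sample_sheet["animal"].unique()
    if len(animals) < 2:
        raise UserInputError("leave-one-animal-out needs >= 2 animals")
    tau = settings.get("tau_window_h", DEFAULT_TAU_WINDOW_H)
    rows = []
    for animal in animals:
        train_sheet = sample_sheet[sample_sheet["animal"] != animal]
        test_sheet = sample_sheet[sample_sheet["animal"] == animal]
        model = train_clock(matrix[train_sheet["sample_id"].tolist()],
                            train_sheet, panel, **settings)
        X_test, t_test = _panel_matrix(matrix[test_sheet["sample_id"].tolist()],
                                       test_sheet, panel)
        for (sid, t_true, est) in zip(test_sheet["sample_id"], t_test,
                                      model.estimate(X_test)):
            rows.append({
                "sample_id": sid, "animal": animal, "time_h": t_true,
                "t_hat": est.t_hat, "score": est.score, "window": est.window,
                "abs_error_h": abs(est.t_hat - t_true),
                "true_window": "within" if t_true <= tau else "beyond",
            })
    estimates = pd.DataFrame(rows)
    return EvaluationReport(
        estimates=estimates,
        median_abs_error_h=float(estimates["abs_error_h"].median()),
        window_accuracy=float((estimates["window"] == estimates["true_window"]).mean()),
        tau_window_h=float(tau),
        settings=dict(settings),
    )
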