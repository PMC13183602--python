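"""Validation metrics for trained surrogates.

The accuracy measure is the fractional mean square error, a scale-free
percentage

    fMSE = 100 * sum_i (y_hat_i - y_i)^2 / sum_i y_i^2,

computed per output variable; an aggregate report averages the per-variable
values.  ``validate`` builds a fresh design, solves the mechanistic model
for ground truth, and compares against surrogate predictions, returning
both the metric report and the paired actual/predicted scatter table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from episurf.cellmodel import DomainError, ModelVariant
from episurf.datagen import (Dataset, build_design, default_ranges,
                             generate_dataset)
from episurf.surrogate import TrainedSurrogate, predict

__all__ = [
    "MetricsReport",
    "fractional_mse",
    "metrics_from_frames",
    "scatter_table",
    "validate",
    "ValidationError",
]


class ValidationError(RuntimeError):
    """Ground-truth generation failed too often to trust the validation."""


@dataclass(frozen=True)
class MetricsReport:
    per_output: Mapping[str, float]      # fractional MSE, percent
    aggregate: float                     # arithmetic mean of per-output values
    n_samples: int
    direction: str
    scenario: str = ""
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {"per_output": dict(self.per_output),
                "aggregate": self.aggregate, "n_samples": self.n_samples,
                "direction": self.direction, "scenario": self.scenario,
                "n_excluded": self.n_excluded}


def fractional_mse(actual, predicted) -> float:
    """Fractional MSE in percent: 100 * SSE / sum(actual^2)."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.size == 0:
        raise DomainError("actual and predicted must be equal-length, non-empty")
    denom = float(np.sum(a * a))
    if denom == 0.0:
        raise DomainError("actual vector is identically zero")
    return 100.0 * float(np.sum((p - a) ** 2)) / denom


def metrics_from_frames(actual: pd.DataFrame, predicted: pd.DataFrame,
                        direction: str, scenario: str = "",
                        n_excluded: int = 0) -> MetricsReport:
    """Per-column fractional MSE of two aligned frames, plus their mean."""
    per = {c: fractional_mse(actual[c], predicted[c]) for c in actual.columns}
    return MetricsReport(per_output=per,
                         aggregate=float(np.mean(list(per.values()))),
                         n_samples=len(actual), direction=direction,
                         scenario=scenario, n_excluded=n_excluded)


def scatter_table(actual: pd.DataFrame, predicted: pd.DataFrame,
                  scenario: str) -> pd.DataFrame:
    """Long-format (variable, actual, predicted, scenario) pairs."""
    frames = []
    for c in actual.columns:
        frames.append(pd.DataFrame({
            "variable": c,
            "actual": actual[c].to_numpy(),
            "predicted": predicted[c].to_numpy(),
            "scenario": scenario}))
    return pd.concat(frames, ignore_index=True)


def validate(surrogate: TrainedSurrogate, variant: ModelVariant,
             n: int = 250, seed: int = 0, design_mode: str = "random",
             inhibition: Mapping | None = None,
             nuisance: Mapping | None = None,
             scenario: str = "",
             truth: Dataset | None = None,
             max_unconverged_frac: float = 0.05
             ) -> tuple[MetricsReport, pd.DataFrame]:
    """Validate a surrogate against freshly solved mechanistic ground truth.

    Builds an ``n``-point design (random within the training ranges by
    default, or an inhibition design), solves the mechanistic model at every
    point, and scores surrogate predictions.  Unconverged ground-truth rows
    are excluded and counted; more than ``max_unconverged_frac`` of them
    aborts the validation, since that indicates a solver regression rather
    than a surrogate problem.  A pre-generated ``truth`` dataset bypasses
    design construction.
    """
    if truth is None:
        design = build_design(default_ranges(variant), design_mode, n,
                              seed=seed, inhibition=inhibition,
                              nuisance=nuisance)
        truth = generate_dataset(variant, design)
    table = truth.table
    conv = table["converged"].astype(bool)
    n_excluded = int((~conv).sum())
    if n_excluded > max_unconverged_frac * len(table):
        raise ValidationError(
            f"{n_excluded}/{len(table)} ground-truth solves failed")
    table = table[conv].reset_index(drop=True)

    feats = table.loc[:, list(surrogate.feature_names)]
    pred = predict(surrogate, feats)
    actual = table.loc[:, list(surrogate.target_names)]
    tag = scenario or design_mode
    report = metrics_from_frames(actual, pred, surrogate.direction,
                                 scenario=tag, n_excluded=n_excluded)
    return report, scatter_table(actual, pred, tag)
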