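"""Logistic masking-risk model with stepwise-AIC feature selection.

The masking score is the inverse-logit of a linear predictor over
z-standardized features; the shipped feature set is the standard
deviation of the detectability map, the GLCM correlation of the density
map, and age.  Candidate predictors are selected by bidirectional
stepwise search on the Akaike Information Criterion (AIC = 2k - 2 logL)
starting from the intercept-only model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .errors import MaskScopeError, ParameterError
from .features import FEATURE_NAMES

try:  # raised (as error) by some statsmodels versions on separation
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass

__all__ = [
    "ModelParams",
    "MaskingScore",
    "fit_logistic",
    "stepwise_aic",
    "predict_masking_score",
    "score_exam",
    "save_model",
    "load_model",
    "load_default_model",
]


@dataclass
class ModelParams:
    """Fitted logistic model on both the standardized and raw scales."""

    intercept: float                      # raw scale
    coefficients: dict                    # raw scale, per selected feature
    selected_feature_names: list
    log_likelihood: float
    aic: float
    n_fit: int
    feature_means: dict = field(default_factory=dict)
    feature_stds: dict = field(default_factory=dict)
    intercept_std: float = 0.0            # standardized scale
    coefficients_std: dict = field(default_factory=dict)
    standard_errors_std: dict = field(default_factory=dict)
    separation_flag: bool = False
    converged: bool = True
    seed: int | None = None


@dataclass(frozen=True)
class MaskingScore:
    exam_id: str
    score: float


def _design(table: pd.DataFrame, names: list, means: dict, stds: dict):
    cols = [(table[n].to_numpy(float) - means[n]) / stds[n] for n in names]
    X = np.column_stack([np.ones(len(table))] + cols) if cols else np.ones(
        (len(table), 1)
    )
    return X


def fit_logistic(
    feature_table: pd.DataFrame,
    labels: np.ndarray,
    feature_names: list | None = None,
) -> ModelParams:
    """Maximum-likelihood logistic fit (Newton/IRLS) on z-scored features.

    Standardization constants are estimated on the training table and
    stored so the model can be applied to raw-scale feature vectors.
    Complete separation is flagged rather than raised; the returned
    coefficients are then unreliable and ``separation_flag`` is set.
    """
    names = list(feature_names if feature_names is not None else FEATURE_NAMES)
    names = [n for n in names if n in feature_table.columns]
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ParameterError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ParameterError("labels must contain both classes")
    n, k = len(y), len(names) + 1
    if n < 10 * k:
        warnings.warn(f"n={n} below 10 cases per parameter (k={k})", stacklevel=2)
    means = {m: float(feature_table[m].mean()) for m in names}
    stds = {
        m: float(s) if (s := feature_table[m].std(ddof=0)) > 0 else 1.0
        for m in names
    }
    X = _design(feature_table, names, means, stds)
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=100, tol=1e-10, disp=0
            )
            converged = bool(res.mle_retvals.get("converged", True))
            params = res.params
            llf = float(res.llf)
            bse = res.bse
        except (
            PerfectSeparationError,
            PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ):
            # singular Hessian under (quasi-)separation: small-ridge refit
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit_regularized(
                    alpha=1e-6, disp=0, maxiter=200
                )
            params = np.asarray(res.params)
            llf = float(sm.Logit(y, X).loglike(params))
            bse = np.full(len(params), np.nan)
    b0_std = float(params[0])
    coef_std = {m: float(params[i + 1]) for i, m in enumerate(names)}
    se_std = {m: float(bse[i + 1]) for i, m in enumerate(names)}
    # back-transform to raw scale: b_raw = b_std / sd, b0 -= sum(b_std*mu/sd)
    coef_raw = {m: coef_std[m] / stds[m] for m in names}
    b0_raw = b0_std - sum(coef_std[m] * means[m] / stds[m] for m in names)
    return ModelParams(
        intercept=b0_raw,
        coefficients=coef_raw,
        selected_feature_names=names,
        log_likelihood=llf,
        aic=2.0 * k - 2.0 * llf,
        n_fit=n,
        feature_means=means,
        feature_stds=stds,
        intercept_std=b0_std,
        coefficients_std=coef_std,
        standard_errors_std=se_std,
        separation_flag=separation,
        converged=converged,
    )


def stepwise_aic(
    candidate_names: list,
    feature_table: pd.DataFrame,
    labels: np.ndarray,
) -> ModelParams:
    """Bidirectional stepwise AIC selection from the intercept-only model.

    At each step every single addition and removal is scored; the move
    with the largest AIC decrease is applied (ties broken by candidate
    order, additions before removals); the search stops when no move
    lowers the AIC.
    """
    candidates = list(candidate_names)
    current: list = []
    best = fit_logistic(feature_table, labels, feature_names=current)
    while True:
        moves = []
        for name in candidates:
            if name not in current:
                moves.append(current + [name])
        for name in current:
            moves.append([m for m in current if m != name])
        best_move, best_fit = None, None
        for trial in moves:
            fit = fit_logistic(feature_table, labels, feature_names=trial)
            if fit.aic < best.aic - 1e-12 and (
                best_fit is None or fit.aic < best_fit.aic - 1e-12
            ):
                best_move, best_fit = trial, fit
        if best_move is None:
            return best
        current, best = best_move, best_fit


def predict_masking_score(
    model: ModelParams, features: dict | pd.Series, exam_id: str = ""
) -> MaskingScore:
    """Inverse-logit of the linear predictor; score in (0, 1)."""
    eta = model.intercept
    for name in model.selected_feature_names:
        if name not in features:
            raise ParameterError(f"missing feature: {name}")
        eta += model.coefficients[name] * float(features[name])
    score = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    return MaskingScore(exam_id=exam_id or str(features.get("exam_id", "")),
                        score=float(score))


def score_exam(view_scores) -> float:
    """Arithmetic mean of the available per-view masking scores."""
    arr = np.asarray(list(view_scores), dtype=float)
    if arr.size == 0:
        raise ParameterError("need at least one view score")
    return float(arr.mean())


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: ModelParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(model), indent=2))


def load_model(path: str | Path) -> ModelParams:
    return ModelParams(**json.loads(Path(path).read_text()))


def load_default_model() -> ModelParams:
    """Shipped default weights, fitted on the default synthetic cohort.

    The fit seed and cohort size are recorded in the model metadata.
    """
    text = (
        resources.files("maskscope").joinpath("data/default_model.json").read_text()
    )
    return ModelParams(**json.loads(text))
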