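"""Brain-age model: CV selection of component count, regularized linear
regression, brain-age gap (BAG) and its age-bias adjustment.

The BAG of a scan is delta1 = predicted age - chronological age. Because a
least-squares age predictor shrinks toward the mean age, delta1 is
negatively correlated with age by construction; the adjusted BAG delta2
removes this regression-to-the-mean bias by residualizing delta1 on age
with an OLS line (slope/intercept ``beta2``) and is the quantity entered
into the mixed-effects motion models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold

from .exceptions import FitError, InputError

__all__ = [
    "Beta2",
    "AgeModel",
    "CVCurve",
    "WithinSessionResult",
    "cv_select_components",
    "train_age_model",
    "predict_age",
    "compute_bag",
    "fit_bag_adjustment",
    "adjust_bag",
    "train_within_session",
    "select_lambda",
]

REGULARIZATIONS = ("none", "l1", "l2")

#: default grid for the inner regularization-strength search
LAMBDA_GRID = np.logspace(-4, 2, 20)


class Beta2(NamedTuple):
    """Age-bias line fitted to (delta1, age) pairs: delta1 ~ slope*age + intercept."""

    slope: float
    intercept: float


@dataclass(frozen=True)
class AgeModel:
    """Linear age predictor on the first ``k`` PC scores."""

    k: int
    regularization: str
    lam: float
    coef: np.ndarray  # years per score-unit, length k
    intercept: float  # years

    def __post_init__(self):
        if len(self.coef) != self.k:
            raise FitError(f"coefficient length {len(self.coef)} != k={self.k}")
        if self.lam < 0:
            raise FitError("lam must be >= 0")


@dataclass(frozen=True)
class CVCurve:
    """Cross-validation curve over the number of components.

    ``k_star`` is the smallest k attaining the minimum mean out-of-fold
    RMSE. ``oof_pred`` holds the out-of-fold predictions at ``k_star``
    (same row order as the score matrix used for selection) and
    ``fold_ids`` the fold each row was held out in — these back the
    age-bias fit without any self-prediction.
    """

    ks: np.ndarray
    rmse: np.ndarray  # mean per-fold RMSE, years
    k_star: int
    folds: int
    seed: int
    fold_ids: np.ndarray
    oof_pred: np.ndarray
    lam_star: float


def _as_matrix(scores) -> np.ndarray:
    m = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, dtype=float)
    if m.ndim != 2:
        raise InputError("scores must be a 2-D matrix")
    return m


def _fit_linear(S: np.ndarray, y: np.ndarray, regularization: str, lam: float):
    """Return (coef, intercept). Intercept is never penalized."""
    if regularization == "none":
        design = np.column_stack([np.ones(len(S)), S])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            raise FitError(
                "singular unregularized design (rank "
                f"{rank} < {design.shape[1]}); consider l2 regularization"
            )
        return coef[1:], float(coef[0])
    if regularization == "l2":
        est = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
    elif regularization == "l1":
        est = Lasso(alpha=lam, fit_intercept=True, max_iter=50000)
    else:
        raise InputError(f"regularization must be one of {REGULARIZATIONS}")
    est.fit(S, y)
    return est.coef_.copy(), float(est.intercept_)


def train_age_model(scores, ages, k: int, regularization: str = "none", lam: float = 0.0) -> AgeModel:
    """Least-squares (optionally L1/L2-penalized) fit of age on the first k scores.

    For ridge, ``lam`` multiplies the squared-norm penalty as in the
    closed form ``(S'S + lam*I)^-1 S'y`` on centered data; for lasso it is
    the scikit-learn ``alpha`` of ``(1/2n)||y - Sw||^2 + alpha*||w||_1``.
    """
    S = _as_matrix(scores)
    y = np.asarray(ages, dtype=float)
    if S.shape[0] != len(y):
        raise InputError("scores and ages disagree in length")
    if k < 1 or k > S.shape[1]:
        raise InputError(f"k must be in [1, {S.shape[1]}], got {k}")
    if regularization == "none" and S.shape[0] <= k:
        raise FitError(f"need more rows than k={k} for an unregularized fit")
    if regularization not in REGULARIZATIONS:
        raise InputError(f"regularization must be one of {REGULARIZATIONS}")
    coef, intercept = _fit_linear(S[:, :k], y, regularization, lam)
    return AgeModel(k=k, regularization=regularization, lam=float(lam), coef=coef, intercept=intercept)


def predict_age(model: AgeModel, scores) -> np.ndarray:
    """Predicted ages ``S[:, :k] @ coef + intercept`` in years."""
    S = _as_matrix(scores)
    if S.shape[1] < model.k:
        raise InputError(f"score matrix has {S.shape[1]} columns; model needs {model.k}")
    return S[:, : model.k] @ model.coef + model.intercept


def select_lambda(
    S: np.ndarray,
    y: np.ndarray,
    regularization: str,
    folds: int = 5,
    grid: Sequence[float] = LAMBDA_GRID,
    seed: int = 0,
) -> float:
    """Inner-CV grid search for the regularization strength (RMSE loss)."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    best = (np.inf, float(grid[0]))
    for lam in grid:
        errs = []
        for tr, va in kf.split(S):
            coef, b0 = _fit_linear(S[tr], y[tr], regularization, lam)
            pred = S[va] @ coef + b0
            errs.append(np.sqrt(np.mean((pred - y[va]) ** 2)))
        m = float(np.mean(errs))
        if m < best[0]:
            best = (m, float(lam))
    return best[1]


def cv_select_components(
    scores,
    ages,
    k_range: Sequence[int],
    folds: int = 10,
    regularization: str = "none",
    lam: Optional[float] = None,
    seed: int = 0,
) -> CVCurve:
    """Mean out-of-fold RMSE for each candidate component count.

    The fold partition is a single seeded shuffle shared by every k, so the
    curve compares models on identical splits. Ties in the minimum are
    broken toward the smallest k (parsimony). When a penalized fit is
    requested without a strength, an inner 5-fold grid search picks it per
    training fold.
    """
    S = _as_matrix(scores)
    y = np.asarray(ages, dtype=float)
    ks = np.asarray(sorted(set(int(k) for k in k_range)))
    if len(ks) == 0:
        raise InputError("k_range is empty")
    if ks[0] < 1 or ks[-1] > S.shape[1]:
        raise InputError(f"k_range must lie within [1, {S.shape[1]}]")
    if folds < 2:
        raise InputError("folds must be >= 2")
    if len(y) < folds:
        raise InputError(f"need at least {folds} rows for {folds}-fold CV")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(S))
    fold_ids = np.empty(len(y), dtype=int)
    for f, (_, va) in enumerate(splits):
        fold_ids[va] = f

    mean_rmse = np.empty(len(ks))
    oof_by_k = {}
    for i, k in enumerate(ks):
        oof = np.empty(len(y))
        errs = []
        for tr, va in splits:
            Sk = S[tr, :k]
            lam_f = lam
            if regularization != "none" and lam_f is None:
                lam_f = select_lambda(Sk, y[tr], regularization, seed=seed)
            coef, b0 = _fit_linear(Sk, y[tr], regularization, lam_f or 0.0)
            pred = S[va, :k] @ coef + b0
            oof[va] = pred
            errs.append(np.sqrt(np.mean((pred - y[va]) ** 2)))
        mean_rmse[i] = np.mean(errs)
        oof_by_k[int(k)] = oof

    # parsimony tie-break: smallest k whose RMSE is numerically at the minimum
    best = float(np.min(mean_rmse))
    tied = mean_rmse <= best * (1.0 + 1e-9) + 1e-12
    k_star = int(ks[int(np.argmax(tied))])
    lam_star = lam
    if regularization != "none" and lam_star is None:
        lam_star = select_lambda(S[:, :k_star], y, regularization, seed=seed)
    return CVCurve(
        ks=ks,
        rmse=mean_rmse,
        k_star=k_star,
        folds=folds,
        seed=int(seed),
        fold_ids=fold_ids,
        oof_pred=oof_by_k[k_star],
        lam_star=float(lam_star or 0.0),
    )


def compute_bag(predicted, chronological) -> np.ndarray:
    """BAG delta1 = predicted - chronological age, per scan, in years."""
    p = np.asarray(predicted, dtype=float)
    c = np.asarray(chronological, dtype=float)
    if p.shape != c.shape:
        raise InputError(f"length mismatch: predicted {p.shape} vs chronological {c.shape}")
    return p - c


def fit_bag_adjustment(delta1, ages) -> Beta2:
    """OLS of delta1 on chronological age (with intercept).

    The fitted line captures the share of BAG explained by age itself;
    subtracting it (see :func:`adjust_bag`) yields residuals with zero mean
    and zero age-correlation on the fitting sample.
    """
    d = np.asarray(delta1, dtype=float)
    y = np.asarray(ages, dtype=float)
    if d.shape != y.shape:
        raise InputError("delta1 and ages disagree in length")
    if len(d) < 3:
        raise InputError("need at least 3 scans to fit the age-bias line")
    if np.var(y) == 0:
        raise InputError("ages are constant; age-bias line is unidentifiable")
    slope, intercept = np.polyfit(y, d, 1)
    return Beta2(slope=float(slope), intercept=float(intercept))


def adjust_bag(delta1, ages, beta2: Beta2) -> np.ndarray:
    """Adjusted BAG delta2 = delta1 - (slope*age + intercept)."""
    d = np.asarray(delta1, dtype=float)
    y = np.asarray(ages, dtype=float)
    if d.shape != y.shape:
        raise InputError("delta1 and ages disagree in length")
    return d - (beta2.slope * y + beta2.intercept)


@dataclass(frozen=True)
class WithinSessionResult:
    """Within-session training protocol output.

    Scans of the training session carry out-of-fold predictions (no scan is
    predicted by a model fitted on itself); all other scans are predicted by
    the model refit on the full training session. ``fold_ids`` maps each
    training-session scan_id to its held-out fold, and ``fold_train_ids``
    lists the scan_ids each fold's model was fitted on, so the no-leakage
    protocol is auditable.
    """

    train_session: str
    predictions: pd.Series  # predicted age per scan_id, all sessions
    model: AgeModel
    fold_ids: dict
    fold_train_ids: dict


def train_within_session(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    train_session: str,
    k: int,
    folds: int = 10,
    seed: int = 0,
    regularization: str = "none",
    lam: Optional[float] = None,
) -> WithinSessionResult:
    """Train the age model on one session of a repeated-session cohort.

    Emulates the validation in which the predictor is trained with CV on
    the no-motion session and applied to the motion sessions (or trained on
    the high-motion session, symmetrically).
    """
    meta = meta.set_index("scan_id") if "scan_id" in meta.columns else meta
    if not scores.index.equals(meta.index):
        meta = meta.loc[scores.index]
    sess = meta["session"]
    in_train = sess == train_session
    if in_train.sum() == 0:
        raise InputError(f"no scans in session {train_session!r}")
    sub = meta.loc[in_train, "subject_id"]
    if sub.duplicated().any():
        dup = sub[sub.duplicated()].unique().tolist()
        raise InputError(f"duplicate subject(s) within session {train_session!r}: {dup[:5]}")

    S = scores.to_numpy(dtype=float)
    y = meta["age"].to_numpy(dtype=float)
    tr_idx = np.where(in_train.to_numpy())[0]
    if len(tr_idx) < folds:
        raise InputError(f"need at least {folds} training-session scans for {folds}-fold CV")

    lam_fit = lam
    if regularization != "none" and lam_fit is None:
        lam_fit = select_lambda(S[tr_idx, :k], y[tr_idx], regularization, seed=seed)
    lam_fit = lam_fit or 0.0

    pred = np.empty(len(y))
    fold_ids, fold_train_ids = {}, {}
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for f, (tr, va) in enumerate(kf.split(tr_idx)):
        rows_tr, rows_va = tr_idx[tr], tr_idx[va]
        coef, b0 = _fit_linear(S[rows_tr, :k], y[rows_tr], regularization, lam_fit)
        pred[rows_va] = S[rows_va, :k] @ coef + b0
        for r in rows_va:
            fold_ids[scores.index[r]] = f
        fold_train_ids[f] = [scores.index[r] for r in rows_tr]

    model = train_age_model(S[tr_idx], y[tr_idx], k, regularization, lam_fit)
    out_idx = np.where(~in_train.to_numpy())[0]
    if len(out_idx):
        pred[out_idx] = predict_age(model, S[out_idx])

    return WithinSessionResult(
        train_session=train_session,
        predictions=pd.Series(pred, index=scores.index, name="predicted_age"),
        model=model,
        fold_ids=fold_ids,
        fold_train_ids=fold_train_ids,
    )
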