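"""Random-intercept mixed-effects models for motion effects, per-component
FDR screening, and intra-rater agreement.

Every model has the form ``outcome ~ predictor + (1 | subject)`` where the
outcome is the adjusted brain-age gap, the normalized Euler number, or a
single PC score, and the predictor is the motion session (categorical,
STAND reference), the 0-5 visual rating (one continuous slope), or the
normalized Euler number. The random intercept absorbs the within-subject
correlation of the three repeated sessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .exceptions import FitError, InputError, SchemaError

__all__ = [
    "LMMResult",
    "FDRReport",
    "AgreementResult",
    "fit_lmm",
    "bh_fdr",
    "pc_motion_tests",
    "rater_agreement",
    "PREDICTORS",
]

#: predictor name -> model formula right-hand side
PREDICTORS = {
    "session": "C(session, Treatment('STAND'))",
    "rating": "rating",
    "euler": "euler_norm",
}

_TERM_LABELS = {
    "C(session, Treatment('STAND'))[T.HM1]": "HM1",
    "C(session, Treatment('STAND'))[T.HM2]": "HM2",
    "rating": "rating",
    "euler_norm": "euler_norm",
    "Intercept": "Intercept",
}


@dataclass(frozen=True)
class LMMResult:
    """Fixed effects and variance components of one random-intercept fit.

    ``terms`` has one row per fixed effect with columns
    estimate/se/t/p/df; Wald t-tests use residual degrees of freedom
    (n_obs - n_fixed). Two R-squared flavours are reported: marginal
    (fixed effects only) and conditional (fixed plus predicted random
    intercepts), both adjusted for the number of fixed slopes.
    """

    outcome: str
    predictor: str
    terms: pd.DataFrame
    group_var: float
    resid_var: float
    r2_adj_conditional: float
    r2_adj_marginal: float
    n_obs: int
    n_groups: int
    converged: bool

    def term(self, label: str) -> pd.Series:
        return self.terms.loc[label]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "terms": {
                lab: {k: float(v) for k, v in row.items()}
                for lab, row in self.terms.iterrows()
            },
            "group_var": self.group_var,
            "resid_var": self.resid_var,
            "r2_adj_conditional": self.r2_adj_conditional,
            "r2_adj_marginal": self.r2_adj_marginal,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
        }


def _adjusted_r2(y: np.ndarray, fitted: np.ndarray, n_slopes: int) -> float:
    if np.var(y) == 0 or np.var(fitted) == 0:
        return float("nan")
    r2 = np.corrcoef(y, fitted)[0, 1] ** 2
    n = len(y)
    if n - n_slopes - 1 <= 0:
        return float("nan")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - n_slopes - 1))


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    group: str = "subject_id",
) -> LMMResult:
    """REML fit of ``outcome ~ predictor + (1 | group)``.

    ``predictor`` is one of ``session`` (two treatment contrasts vs STAND),
    ``rating`` or ``euler`` (one continuous slope). Raises on a single
    subject (the random intercept is then unidentifiable) and propagates
    non-convergence as an error.
    """
    if predictor not in PREDICTORS:
        raise InputError(f"predictor must be one of {sorted(PREDICTORS)}, got {predictor!r}")
    col = {"session": "session", "rating": "rating", "euler": "euler_norm"}[predictor]
    for c in (outcome, col, group):
        if c not in data.columns:
            raise SchemaError(f"column {c!r} missing from model data")
    sub = data[[outcome, col, group]].copy()
    num_cols = [outcome] + ([col] if predictor != "session" else [])
    if not np.all(np.isfinite(sub[num_cols].to_numpy(dtype=float))):
        raise InputError(f"non-finite values in columns {num_cols}")
    if sub[group].nunique() < 2:
        raise FitError("need at least 2 subjects for a random-intercept model")
    if predictor == "session" and sub[col].nunique() < 2:
        raise FitError("session predictor requires at least 2 distinct sessions")

    formula = f"{outcome} ~ {PREDICTORS[predictor]}"
    model = smf.mixedlm(formula, sub, groups=sub[group])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = model.fit(reml=True)
        except np.linalg.LinAlgError:
            # boundary cases (zero residual variance) defeat the default
            # lbfgs path; Powell is derivative-free and robust there
            try:
                res = model.fit(reml=True, method="powell")
            except Exception as exc:  # pragma: no cover - diagnostic path
                raise FitError(f"mixed model failed to converge: {exc}") from exc

    fe = res.fe_params
    se = res.bse_fe
    n_obs = len(sub)
    n_fixed = len(fe)
    df = n_obs - n_fixed
    tvals = fe / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)

    rows = {}
    for i, name in enumerate(fe.index):
        label = _TERM_LABELS.get(name, name)
        rows[label] = {
            "estimate": float(fe.iloc[i]),
            "se": float(se.iloc[i]),
            "t": float(tvals.iloc[i]),
            "p": float(pvals[i]),
            "df": float(df),
        }
    terms = pd.DataFrame(rows).T[["estimate", "se", "t", "p", "df"]]

    y = sub[outcome].to_numpy(dtype=float)
    fixed_fitted = model.exog @ fe.to_numpy()
    # statsmodels fittedvalues are conditional (fixed + predicted random
    # effects); with a zero random-intercept variance the prediction is
    # singular and the conditional fit collapses to the marginal one
    try:
        cond_fitted = np.asarray(res.fittedvalues, dtype=float)
    except (ValueError, np.linalg.LinAlgError):
        cond_fitted = fixed_fitted
    n_slopes = n_fixed - 1

    return LMMResult(
        outcome=outcome,
        predictor=predictor,
        terms=terms,
        group_var=float(res.cov_re.iloc[0, 0]),
        resid_var=float(res.scale),
        r2_adj_conditional=_adjusted_r2(y, cond_fitted, n_slopes),
        r2_adj_marginal=_adjusted_r2(y, fixed_fitted, n_slopes),
        n_obs=n_obs,
        n_groups=int(sub[group].nunique()),
        converged=bool(getattr(res, "converged", True)),
    )


def bh_fdr(pvalues, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, rejected flags).

    Rejects hypotheses 1..k* in sorted order where
    k* = max{k : p_(k) <= k*q/m}; adjusted p-values are the standard
    monotone min over j >= k of m*p_(j)/j, capped at 1, returned in the
    original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise InputError("pvalues must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise InputError(f"FDR level q must lie in (0, 1), got {q}")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass(frozen=True)
class FDRReport:
    """Per-component motion screening after BH correction.

    ``table`` has one row per component. For the session predictor the BH
    step-up runs separately within each contrast (HM1 vs STAND, HM2 vs
    STAND) across components, mirroring separately reported counts per
    contrast; a component is flagged ``rejected`` when any of its contrasts
    survives. ``explained_variance_rejected`` maps each contrast (and
    "any") to the training explained-variance mass of its significant
    components, when variance fractions were supplied.
    """

    predictor: str
    q: float
    table: pd.DataFrame
    contrasts: list[str]
    explained_variance_rejected: dict = field(default_factory=dict)

    @property
    def n_rejected(self) -> dict:
        out = {c: int(self.table[f"rejected_{c}"].sum()) for c in self.contrasts}
        out["any"] = int(self.table["rejected"].sum())
        return out


def pc_motion_tests(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    predictor: str = "session",
    q: float = 0.05,
    explained_variance: Optional[Sequence[float]] = None,
) -> FDRReport:
    """Fit ``PC_i ~ predictor + (1|subject)`` for every component, BH-correct.

    ``scores`` is the scans x k score matrix aligned with ``meta`` rows
    (by scan_id index). ``explained_variance`` optionally supplies the
    training-cohort variance fraction of each component so the report can
    state how much training variance the motion-affected components carry.
    """
    if scores.shape[1] < 1:
        raise InputError("need at least one component")
    meta = meta.set_index("scan_id") if "scan_id" in meta.columns else meta
    meta = meta.loc[scores.index]
    if explained_variance is not None and len(explained_variance) != scores.shape[1]:
        raise InputError("explained_variance length must match number of components")

    contrasts = ["HM1", "HM2"] if predictor == "session" else [predictor if predictor != "euler" else "euler_norm"]
    rows = []
    for j, pc in enumerate(scores.columns):
        data = meta.copy()
        data["pc_score"] = scores[pc].to_numpy()
        data = data.reset_index()
        try:
            res = fit_lmm(data, "pc_score", predictor)
        except FitError as exc:
            raise FitError(f"component {pc} (index {j}): {exc}") from exc
        row = {"component": pc}
        for c in contrasts:
            t = res.term(c)
            row[f"estimate_{c}"] = t["estimate"]
            row[f"t_{c}"] = t["t"]
            row[f"p_{c}"] = t["p"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("component")

    for c in contrasts:
        p_adj, rej = bh_fdr(table[f"p_{c}"].to_numpy(), q)
        table[f"p_adj_{c}"] = p_adj
        table[f"rejected_{c}"] = rej
    table["rejected"] = np.logical_or.reduce(
        [table[f"rejected_{c}"].to_numpy() for c in contrasts]
    )

    ev_rejected = {}
    if explained_variance is not None:
        ev = np.asarray(explained_variance, dtype=float)
        for c in contrasts:
            ev_rejected[c] = float(ev[table[f"rejected_{c}"].to_numpy()].sum())
        ev_rejected["any"] = float(ev[table["rejected"].to_numpy()].sum())

    return FDRReport(
        predictor=predictor,
        q=q,
        table=table,
        contrasts=contrasts,
        explained_variance_rejected=ev_rejected,
    )


@dataclass(frozen=True)
class AgreementResult:
    """Intra-rater agreement on the 6-point motion-rating scale."""

    percent_agreement: float
    kappa: Optional[float]  # linearly weighted Cohen's kappa; None if undefined
    n: int

    @property
    def kappa_undefined(self) -> bool:
        return self.kappa is None


def rater_agreement(ratings_a, ratings_b) -> AgreementResult:
    """Exact agreement (%) and linearly weighted Cohen's kappa.

    When both rating vectors are constant and identical the kappa
    denominator vanishes; the result then reports 100% agreement with an
    undefined kappa rather than a number.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("rating vectors must be 1-D and of equal length")
    if len(a) < 2:
        raise InputError("need at least 2 rated scans")
    for name, v in (("ratings_a", a), ("ratings_b", b)):
        vi = v.astype(int)
        if np.any(vi != v) or vi.min() < 0 or vi.max() > 5:
            raise InputError(f"{name} must contain integers in 0..5")
    a = a.astype(int)
    b = b.astype(int)
    pct = 100.0 * float(np.mean(a == b))
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1 and a[0] == b[0]:
        return AgreementResult(percent_agreement=pct, kappa=None, n=len(a))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kappa = float(
            cohen_kappa_score(a, b, labels=list(range(6)), weights="linear")
        )
    return AgreementResult(percent_agreement=pct, kappa=kappa, n=len(a))
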