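"""End-to-end synthetic experiment: simulate -> train -> predict -> adjust
-> mixed models -> FDR screen -> report.

:func:`run_experiment` performs the whole analysis in memory and returns an
:class:`ExperimentResult`; :func:`run_pipeline` additionally writes every
artifact (model bundle, predictions, per-model JSON, FDR tables, markdown
report) to an output directory. All randomness descends from one root seed
split per stage, so a rerun with the same configuration reproduces every
number.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import brainage, features, io, mixedmodels, synthetic
from .config import SimConfig
from .exceptions import ConfigError
from .records import records_to_frame

__all__ = ["RunConfig", "ExperimentResult", "run_experiment", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full experiment.

    Either a :class:`SimConfig` (synthetic cohorts) or paths to real
    feature/metadata tables for training and test cohorts — exactly one of
    the two. ``beta2_sample`` chooses where the age-bias line is fitted:
    ``"train_cv"`` (out-of-fold training predictions; default) or
    ``"test"`` (refit on the test sample, for sensitivity checks).
    """

    sim: Optional[SimConfig] = None
    train_features: Optional[str] = None
    train_meta: Optional[str] = None
    test_features: Optional[str] = None
    test_meta: Optional[str] = None
    k_min: int = 1
    k_max: int = 20
    folds: int = 10
    regularization: str = "none"
    lam: Optional[float] = None
    q: float = 0.05
    beta2_sample: str = "train_cv"
    within_session: bool = True
    within_session_train: str = "STAND"
    seed: int = 0

    def validate(self) -> None:
        has_sim = self.sim is not None
        paths = (self.train_features, self.train_meta, self.test_features, self.test_meta)
        has_real = any(p is not None for p in paths)
        if has_sim == has_real:
            raise ConfigError("supply exactly one of: a sim config, or real table paths")
        if has_real and any(p is None for p in paths):
            raise ConfigError("real-data runs need all four table paths")
        if not 1 <= self.k_min <= self.k_max:
            raise ConfigError(f"need 1 <= k_min <= k_max, got ({self.k_min}, {self.k_max})")
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")
        if not 0 < self.q < 1:
            raise ConfigError("q must lie in (0, 1)")
        if self.beta2_sample not in ("train_cv", "test"):
            raise ConfigError("beta2_sample must be 'train_cv' or 'test'")
        if self.regularization not in brainage.REGULARIZATIONS:
            raise ConfigError(f"regularization must be one of {brainage.REGULARIZATIONS}")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["sim"] = self.sim.to_dict() if self.sim is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    """Everything the pipeline computes, in memory."""

    config: RunConfig
    scaler: features.ScalerModel
    pca: features.PCAModel
    cv_curve: brainage.CVCurve
    age_model: brainage.AgeModel
    beta2: brainage.Beta2
    predictions: pd.DataFrame  # scan_id, age, session, rating, euler_*, predicted_age, delta1, delta2
    train_cv_rmse: float
    train_cv_corr: float
    lmm: dict = field(default_factory=dict)  # name -> LMMResult
    fdr: dict = field(default_factory=dict)  # predictor -> FDRReport
    agreement: Optional[mixedmodels.AgreementResult] = None
    within: Optional[dict] = None  # within-session protocol results
    truth: Optional[synthetic.GroundTruth] = None


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _bag_chain(pred, ages, beta2):
    delta1 = brainage.compute_bag(pred, ages)
    delta2 = brainage.adjust_bag(delta1, ages, beta2)
    return delta1, delta2


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Run the full analysis chain and return all results in memory."""
    config.validate()
    s_train, s_test, s_cv, s_rerate, s_within, _ = _stage_seeds(config.seed)

    truth_test = None
    if config.sim is not None:
        # both cohorts share the latent structure stream of one seed but
        # draw subjects from cohort-specific streams (see synthetic._spawn)
        sim = config.sim.replace(seed=s_train)
        train_X, train_recs, _ = synthetic.generate_training_cohort(sim)
        test_X, test_recs, truth_test = synthetic.generate_motion_cohort(sim)
        train_meta = records_to_frame(train_recs)
        test_meta = records_to_frame(test_recs)
    else:
        train_X, train_meta = io.load_scan_table(config.train_features, config.train_meta)
        test_X, test_meta = io.load_scan_table(config.test_features, config.test_meta)

    # --- training-anchored normalization and PCA
    scaler = features.fit_feature_scaler(train_X)
    train_scaled = features.apply_scaler(train_X, scaler)
    max_k = min(config.k_max, train_scaled.shape[0] - 1, train_scaled.shape[1])
    pca = features.fit_pca(train_scaled, max_k)
    train_scores = features.project(train_X, scaler, pca, max_k)

    # --- component count by 10-fold CV (RMSE cost), then final fit
    ages_train = train_meta["age"].to_numpy(dtype=float)
    curve = brainage.cv_select_components(
        train_scores,
        ages_train,
        range(config.k_min, max_k + 1),
        folds=config.folds,
        regularization=config.regularization,
        lam=config.lam,
        seed=s_cv,
    )
    age_model = brainage.train_age_model(
        train_scores, ages_train, curve.k_star, config.regularization, curve.lam_star
    )
    train_cv_rmse = float(np.sqrt(np.mean((curve.oof_pred - ages_train) ** 2)))
    train_cv_corr = float(np.corrcoef(curve.oof_pred, ages_train)[0, 1])

    # --- BAG and age-bias adjustment
    delta1_train_cv = brainage.compute_bag(curve.oof_pred, ages_train)
    test_scores = features.project(test_X, scaler, pca, max_k)
    ages_test = test_meta["age"].to_numpy(dtype=float)
    pred_test = brainage.predict_age(age_model, test_scores)
    if config.beta2_sample == "train_cv":
        beta2 = brainage.fit_bag_adjustment(delta1_train_cv, ages_train)
    else:
        beta2 = brainage.fit_bag_adjustment(
            brainage.compute_bag(pred_test, ages_test), ages_test
        )
    delta1, delta2 = _bag_chain(pred_test, ages_test, beta2)

    predictions = test_meta.copy()
    predictions["euler_norm"] = features.normalize_euler(predictions["euler_raw"].to_numpy())
    predictions["predicted_age"] = pred_test
    predictions["delta1"] = delta1
    predictions["delta2"] = delta2

    # --- mixed-effects motion models
    lmm = {}
    for name, outcome, predictor in [
        ("bag_session", "delta2", "session"),
        ("bag_rating", "delta2", "rating"),
        ("bag_euler", "delta2", "euler"),
        ("euler_session", "euler_norm", "session"),
        ("euler_rating", "euler_norm", "rating"),
    ]:
        lmm[name] = mixedmodels.fit_lmm(predictions, outcome, predictor)

    # --- per-component motion screen: the components used by the model,
    # widened to a minimum panel so the BH correction is exercised
    k_screen = min(max(curve.k_star, 10), max_k)
    screen_scores = test_scores.iloc[:, :k_screen]
    ev = pca.explained_variance_ratio[:k_screen]
    fdr = {
        "session": mixedmodels.pc_motion_tests(
            screen_scores, test_meta, "session", config.q, ev
        ),
        "rating": mixedmodels.pc_motion_tests(
            screen_scores, test_meta, "rating", config.q, ev
        ),
    }

    # --- intra-rater agreement (synthetic runs: simulate an independent re-rating)
    agreement = None
    if truth_test is not None:
        rerated = synthetic.assign_visual_ratings(
            truth_test.severities, config.sim.rating_noise_sd, s_rerate
        )
        agreement = mixedmodels.rater_agreement(test_meta["rating"].to_numpy(), rerated)

    # --- within-session training protocol
    within = None
    if config.within_session:
        ws = brainage.train_within_session(
            test_scores,
            test_meta,
            config.within_session_train,
            k=curve.k_star,
            folds=config.folds,
            seed=s_within,
            regularization=config.regularization,
            lam=curve.lam_star if config.regularization != "none" else None,
        )
        pred_ws = ws.predictions.to_numpy()
        in_train = (test_meta["session"] == config.within_session_train).to_numpy()
        d1_ws = brainage.compute_bag(pred_ws, ages_test)
        beta2_ws = brainage.fit_bag_adjustment(d1_ws[in_train], ages_test[in_train])
        d2_ws = brainage.adjust_bag(d1_ws, ages_test, beta2_ws)
        ws_table = predictions.copy()
        ws_table["delta2"] = d2_ws
        within = {
            "result": ws,
            "beta2": beta2_ws,
            "delta2": d2_ws,
            "lmm_session": mixedmodels.fit_lmm(ws_table, "delta2", "session"),
            "lmm_rating": mixedmodels.fit_lmm(ws_table, "delta2", "rating"),
        }

    return ExperimentResult(
        config=config,
        scaler=scaler,
        pca=pca,
        cv_curve=curve,
        age_model=age_model,
        beta2=beta2,
        predictions=predictions,
        train_cv_rmse=train_cv_rmse,
        train_cv_corr=train_cv_corr,
        lmm=lmm,
        fdr=fdr,
        agreement=agreement,
        within=within,
        truth=truth_test,
    )


def _report_markdown(res: ExperimentResult) -> str:
    c = res.config
    lines = [
        "# Motion / brain-age experiment report",
        "",
        f"- config hash: `{c.config_hash()}`",
        f"- seed: {c.seed}",
        f"- components: k* = {res.cv_curve.k_star} "
        f"(searched {res.cv_curve.ks[0]}..{res.cv_curve.ks[-1]}, {res.cv_curve.folds}-fold CV)",
        f"- regularization: {c.regularization} (lambda = {res.cv_curve.lam_star:g})",
        f"- training CV: RMSE = {res.train_cv_rmse:.3f} years, r = {res.train_cv_corr:.3f}",
        f"- age-bias line beta2: slope = {res.beta2.slope:.4f}, intercept = {res.beta2.intercept:.3f}",
        "",
        "## Mixed-effects models",
        "",
    ]
    for name, r in res.lmm.items():
        lines.append(f"### {name}: {r.outcome} ~ {r.predictor} + (1|subject)")
        lines.append("")
        lines.append("| term | estimate | SE | t | p |")
        lines.append("|---|---|---|---|---|")
        for lab, row in r.terms.iterrows():
            lines.append(
                f"| {lab} | {row['estimate']:.4f} | {row['se']:.4f} | "
                f"{row['t']:.2f} | {row['p']:.3g} |"
            )
        lines.append(
            f"\nadjusted R2: conditional {r.r2_adj_conditional:.3f}, "
            f"marginal {r.r2_adj_marginal:.3f}; "
            f"var(subject) = {r.group_var:.4f}, var(resid) = {r.resid_var:.4f}\n"
        )
    lines.append("## Per-component FDR screen")
    lines.append("")
    for pred_name, rep in res.fdr.items():
        nrej = rep.n_rejected
        ev = rep.explained_variance_rejected
        lines.append(
            f"- predictor `{pred_name}` (q = {rep.q}): rejected {nrej} "
            f"of {len(rep.table)} components; "
            f"explained-variance mass of rejected set: "
            + ", ".join(f"{k}: {v:.3f}" for k, v in ev.items())
        )
    if res.agreement is not None:
        a = res.agreement
        kap = "undefined" if a.kappa is None else f"{a.kappa:.3f}"
        lines.append("")
        lines.append("## Intra-rater agreement")
        lines.append("")
        lines.append(
            f"- exact agreement {a.percent_agreement:.1f}% on n = {a.n}; "
            f"linearly weighted kappa = {kap}"
        )
    if res.within is not None:
        lines.append("")
        lines.append(
            f"## Within-session protocol (trained on {res.within['result'].train_session})"
        )
        lines.append("")
        for key in ("lmm_session", "lmm_rating"):
            r = res.within[key]
            for lab, row in r.terms.iterrows():
                if lab == "Intercept":
                    continue
                lines.append(
                    f"- {key} {lab}: {row['estimate']:.3f} "
                    f"(t = {row['t']:.2f}, p = {row['p']:.3g})"
                )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig, out_dir) -> ExperimentResult:
    """Run :func:`run_experiment` and write the full artifact bundle."""
    res = run_experiment(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    io.save_model_bundle(
        out / "model",
        res.scaler,
        res.pca,
        res.age_model,
        res.beta2,
        res.cv_curve,
        extra={"config": config.to_dict(), "config_hash": config.config_hash()},
    )
    res.predictions.to_csv(out / "predictions.csv", index=False)
    for name, r in res.lmm.items():
        (out / f"lmm_{name}.json").write_text(json.dumps(r.to_dict(), indent=2))
    for pred_name, rep in res.fdr.items():
        rep.table.to_csv(out / f"fdr_{pred_name}.csv")
    if res.agreement is not None:
        (out / "agreement.json").write_text(
            json.dumps(
                {
                    "percent_agreement": res.agreement.percent_agreement,
                    "kappa": res.agreement.kappa,
                    "n": res.agreement.n,
                }
            )
        )
    if res.within is not None:
        (out / "within_session.json").write_text(
            json.dumps(
                {
                    "train_session": res.within["result"].train_session,
                    "beta2": list(res.within["beta2"]),
                    "lmm_session": res.within["lmm_session"].to_dict(),
                    "lmm_rating": res.within["lmm_rating"].to_dict(),
                }
            )
        )
    (out / "report.md").write_text(_report_markdown(res))
    return res
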