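"""Reading/writing feature tables, scan metadata, and fitted-model bundles.

Feature matrices travel as TSV (``scan_id`` first column, one column per
feature); metadata as CSV with the fixed column set of
:data:`motionbag.records.META_COLUMNS`. Model components are serialized to
JSON with full-precision floats (Python's float repr round-trips exactly).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .brainage import AgeModel, Beta2, CVCurve
from .config import SESSIONS
from .exceptions import SchemaError
from .features import PCAModel, ScalerModel
from .records import META_COLUMNS

__all__ = [
    "write_features",
    "read_features",
    "write_meta",
    "read_meta",
    "load_scan_table",
    "save_model_bundle",
    "load_model_bundle",
]


def write_features(features: pd.DataFrame, path) -> None:
    df = features.copy()
    df.index.name = "scan_id"
    df.to_csv(path, sep="\t")


def read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "scan_id":
        raise SchemaError(f"{path}: first column must be scan_id, got {df.columns[0]!r}")
    return df.set_index("scan_id")


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def read_meta(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: metadata is missing columns {missing}")
    return df


def _validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    dup = meta["scan_id"][meta["scan_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate scan_id(s): {dup.tolist()[:5]}")
    bad_age = meta[~(meta["age"] > 0)]
    if len(bad_age):
        raise SchemaError(f"non-positive ages for scan_id(s): {bad_age['scan_id'].tolist()[:5]}")
    has_session = meta["session"].notna() & (meta["session"].astype(str) != "")
    bad_sess = meta[has_session & ~meta["session"].isin(SESSIONS)]
    if len(bad_sess):
        raise SchemaError(
            f"session must be one of {SESSIONS}; offending scan_id(s): "
            f"{bad_sess['scan_id'].tolist()[:5]}"
        )
    has_rating = meta["rating"].notna()
    r = meta.loc[has_rating, "rating"]
    bad_rating = meta.loc[has_rating].loc[(r < 0) | (r > 5) | (r != r.astype(int))]
    if len(bad_rating):
        raise SchemaError(
            f"ratings must be integers in 0..5; offending scan_id(s): "
            f"{bad_rating['scan_id'].tolist()[:5]}"
        )
    return meta


def load_scan_table(features_path, meta_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and merge a feature table with its metadata.

    Validates that scan_id keys match 1:1 and that ages, sessions and
    ratings obey the schema. Returns (features indexed by scan_id, metadata
    frame in feature order).
    """
    features = read_features(features_path)
    meta = _validate_meta(read_meta(meta_path))
    fset = set(features.index)
    mset = set(meta["scan_id"])
    only_f = sorted(fset - mset)
    only_m = sorted(mset - fset)
    if only_f or only_m:
        raise SchemaError(
            f"scan_id mismatch: {len(only_f)} only in features (e.g. {only_f[:3]}), "
            f"{len(only_m)} only in metadata (e.g. {only_m[:3]})"
        )
    meta = meta.set_index("scan_id").loc[features.index].reset_index()
    return features, meta


# --- model bundle serialization -------------------------------------------


def _arr(x) -> list:
    return np.asarray(x).tolist()


def save_model_bundle(
    out_dir,
    scaler: ScalerModel,
    pca: PCAModel,
    age_model: AgeModel,
    beta2: Beta2,
    cv_curve: Optional[CVCurve] = None,
    extra: Optional[dict] = None,
) -> None:
    """Write every fitted component of a brain-age model to ``out_dir``.

    One JSON file per component; floats round-trip exactly through repr.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "scaler.json").write_text(
        json.dumps(
            {
                "feature_names": scaler.feature_names,
                "means": _arr(scaler.means),
                "sds": _arr(scaler.sds),
                "dropped": scaler.dropped,
            }
        )
    )
    (out / "pca.json").write_text(
        json.dumps(
            {
                "feature_names": pca.feature_names,
                "loadings": _arr(pca.loadings),
                "singular_values": _arr(pca.singular_values),
                "explained_variance_ratio": _arr(pca.explained_variance_ratio),
                "n_samples": pca.n_samples,
            }
        )
    )
    (out / "age_model.json").write_text(
        json.dumps(
            {
                "k": age_model.k,
                "regularization": age_model.regularization,
                "lam": age_model.lam,
                "coef": _arr(age_model.coef),
                "intercept": age_model.intercept,
            }
        )
    )
    (out / "beta2.json").write_text(
        json.dumps({"slope": beta2.slope, "intercept": beta2.intercept})
    )
    if cv_curve is not None:
        (out / "cv_curve.json").write_text(
            json.dumps(
                {
                    "ks": _arr(cv_curve.ks),
                    "rmse": _arr(cv_curve.rmse),
                    "k_star": cv_curve.k_star,
                    "folds": cv_curve.folds,
                    "seed": cv_curve.seed,
                    "fold_ids": _arr(cv_curve.fold_ids),
                    "oof_pred": _arr(cv_curve.oof_pred),
                    "lam_star": cv_curve.lam_star,
                }
            )
        )
    if extra is not None:
        (out / "run_metadata.json").write_text(json.dumps(extra, indent=2, sort_keys=True))


def load_model_bundle(model_dir) -> dict:
    """Inverse of :func:`save_model_bundle`; returns a dict of components."""
    d = Path(model_dir)
    sc = json.loads((d / "scaler.json").read_text())
    scaler = ScalerModel(
        feature_names=sc["feature_names"],
        means=np.array(sc["means"]),
        sds=np.array(sc["sds"]),
        dropped=sc["dropped"],
    )
    pc = json.loads((d / "pca.json").read_text())
    pca = PCAModel(
        feature_names=pc["feature_names"],
        loadings=np.array(pc["loadings"]),
        singular_values=np.array(pc["singular_values"]),
        explained_variance_ratio=np.array(pc["explained_variance_ratio"]),
        n_samples=pc["n_samples"],
    )
    am = json.loads((d / "age_model.json").read_text())
    age_model = AgeModel(
        k=am["k"],
        regularization=am["regularization"],
        lam=am["lam"],
        coef=np.array(am["coef"]),
        intercept=am["intercept"],
    )
    b2 = json.loads((d / "beta2.json").read_text())
    beta2 = Beta2(slope=b2["slope"], intercept=b2["intercept"])
    bundle = {"scaler": scaler, "pca": pca, "age_model": age_model, "beta2": beta2}
    cv_path = d / "cv_curve.json"
    if cv_path.exists():
        cv = json.loads(cv_path.read_text())
        bundle["cv_curve"] = CVCurve(
            ks=np.array(cv["ks"]),
            rmse=np.array(cv["rmse"]),
            k_star=cv["k_star"],
            folds=cv["folds"],
            seed=cv["seed"],
            fold_ids=np.array(cv["fold_ids"]),
            oof_pred=np.array(cv["oof_pred"]),
            lam_star=cv["lam_star"],
        )
    return bundle
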