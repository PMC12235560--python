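"""Seeded synthetic cohorts for the motion / brain-age experiment.

Two generators share one latent feature model (see :class:`~motionbag.config.SimConfig`):

* :func:`generate_training_cohort` — one scan per subject, no motion; the
  stand-in for a large single-session training sample used to fit the
  brain-age model.
* :func:`generate_motion_cohort` — three scans per subject (STAND/HM1/HM2)
  with increasing latent motion severity, motion-biased features, 0-5
  visual ratings derived from severity, and a skew-distributed raw Euler
  surrogate decreasing with severity.

Because every quantity is generated from known loadings and severities, the
returned :class:`GroundTruth` lets downstream stages be tested by parameter
recovery rather than against opaque fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import MAX_RATING, RATING_SLOPE, SESSIONS, SimConfig
from .exceptions import InputError
from .records import ScanRecord

__all__ = [
    "GroundTruth",
    "generate_training_cohort",
    "generate_motion_cohort",
    "assign_visual_ratings",
    "synthesize_euler",
]


@dataclass(frozen=True)
class GroundTruth:
    """Latent quantities behind a generated cohort.

    ``age_loadings`` is the per-feature age slope (feature-units/year);
    ``motion_direction`` the unit vector along which motion shifts features
    (the full motion loading is ``motion_bias * motion_direction``);
    ``subject_effects`` the (n_subjects, n_latent) random-effect draws;
    ``severities`` the per-scan latent motion severity (all zero for the
    training cohort).
    """

    age_loadings: np.ndarray
    motion_direction: np.ndarray
    subject_effects: np.ndarray
    severities: np.ndarray
    latent_directions: np.ndarray
    feature_means: np.ndarray

    def bag_inflation_per_severity(self, config: SimConfig) -> float:
        """Years of brain-age inflation induced per unit latent severity.

        A scan shifted by ``motion_bias * b * m`` moves the ideal age
        read-out ``(a . x) / ||a||^2`` by
        ``motion_bias * (a . b) / ||a||^2`` years per severity unit; with
        the default negative bias and negative age slope this is positive.
        """
        a = self.age_loadings
        return float(config.motion_bias * (a @ self.motion_direction) / (a @ a))


def _directions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Orthonormal feature-space directions: column 0 is the aging direction,
    column 1 the motion-orthogonal complement, columns 0..n_latent-1 the
    latent subject-effect directions."""
    n_dir = max(config.n_latent, 2)
    if n_dir > config.n_features:
        raise InputError(
            f"n_features={config.n_features} too small for {n_dir} latent directions"
        )
    g = rng.standard_normal((config.n_features, n_dir))
    q, r = np.linalg.qr(g)
    # fix the sign so the decomposition is unique given the draw
    q = q * np.sign(np.diag(r))
    return q


def _feature_rows(
    config: SimConfig,
    ages: np.ndarray,
    subject_effects: np.ndarray,
    severities: np.ndarray,
    scan_subject_idx: np.ndarray,
    directions: np.ndarray,
    feature_means: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble the scans x features matrix from the latent model."""
    mid = 0.5 * (config.age_range[0] + config.age_range[1])
    q_age = directions[:, 0]
    a = config.age_effect_scale * q_age
    overlap = config.motion_overlap
    b = overlap * q_age + np.sqrt(max(0.0, 1.0 - overlap**2)) * directions[:, 1]

    n_scans = len(scan_subject_idx)
    x = np.tile(feature_means, (n_scans, 1))
    x += np.outer(ages[scan_subject_idx] - mid, a)
    if config.n_latent > 0:
        w = directions[:, : config.n_latent].T  # (n_latent, n_features)
        x += subject_effects[scan_subject_idx] @ w
    x += config.motion_bias * np.outer(severities, b)
    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=x.shape)
    return x, a, b


def _spawn(seed: int, stream: int, n: int) -> list[np.random.Generator]:
    """Independent generators for stream ``stream`` of root ``seed``.

    Stream 0 holds the latent structure (directions, feature means) so that
    training and motion cohorts built from the same seed describe the same
    underlying population; cohort-specific draws use separate streams.
    """
    ss = np.random.SeedSequence([int(seed), int(stream)])
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def generate_training_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, list[ScanRecord], GroundTruth]:
    """One motion-free scan per subject; ages uniform on ``age_range``.

    Returns the scans x features matrix (indexed by ``scan_id``), the scan
    records, and the generating ground truth. Deterministic in
    ``(config, config.seed)``.
    """
    config.validate()
    (rng_struct,) = _spawn(config.seed, 0, 1)
    rng_sub, rng_noise, rng_euler = _spawn(config.seed, 1, 3)

    n = config.n_train
    directions = _directions(config, rng_struct)
    feature_means = rng_struct.normal(0.0, 1.0, config.n_features)

    ages = rng_sub.uniform(*config.age_range, size=n)
    sexes = np.where(rng_sub.random(n) < 0.5, "F", "M")
    subject_effects = (
        rng_sub.normal(0.0, config.subject_sd, size=(n, config.n_latent))
        if config.n_latent > 0
        else np.zeros((n, 0))
    )
    severities = np.zeros(n)
    idx = np.arange(n)
    x, a, b = _feature_rows(
        config, ages, subject_effects, severities, idx, directions, feature_means, rng_noise
    )

    euler_raw = synthesize_euler(
        severities,
        config.euler_intercept,
        config.euler_slope,
        config.euler_noise_sd,
        rng_euler,
    )
    scan_ids = [f"train{i:04d}" for i in range(n)]
    records = [
        ScanRecord(
            scan_id=scan_ids[i],
            subject_id=f"T{i:04d}",
            age=float(ages[i]),
            sex=str(sexes[i]),
            session=None,
            rating=0,
            euler_raw=float(euler_raw[i]),
        )
        for i in range(n)
    ]
    features = pd.DataFrame(
        x, index=pd.Index(scan_ids, name="scan_id"),
        columns=[f"f{j:03d}" for j in range(config.n_features)],
    )
    truth = GroundTruth(a, b, subject_effects, severities, directions, feature_means)
    return features, records, truth


def generate_motion_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, list[ScanRecord], GroundTruth]:
    """Three scans per subject, one per session STAND/HM1/HM2.

    Within a subject the three scans share age, sex and subject random
    effect; they differ by the per-scan latent severity (truncated normal at
    zero around the session's mean), the induced feature bias
    ``motion_bias * b * severity``, fresh measurement noise, the visual
    rating and the Euler surrogate.
    """
    config.validate()
    (rng_struct,) = _spawn(config.seed, 0, 1)
    rng_sub, rng_noise, rng_sev, rng_rate, rng_euler = _spawn(config.seed, 2, 5)

    n_sub = config.n_test_subjects
    directions = _directions(config, rng_struct)
    feature_means = rng_struct.normal(0.0, 1.0, config.n_features)

    ages = rng_sub.uniform(*config.age_range, size=n_sub)
    sexes = np.where(rng_sub.random(n_sub) < 0.5, "F", "M")
    subject_effects = (
        rng_sub.normal(0.0, config.subject_sd, size=(n_sub, config.n_latent))
        if config.n_latent > 0
        else np.zeros((n_sub, 0))
    )

    # scan order: all subjects x (STAND, HM1, HM2)
    scan_subject_idx = np.repeat(np.arange(n_sub), len(SESSIONS))
    sessions = np.tile(np.array(SESSIONS), n_sub)
    means = np.array([config.severity_means[SESSIONS.index(s)] for s in sessions])
    lo = (0.0 - means) / config.severity_sd
    severities = stats.truncnorm.rvs(
        lo, np.inf, loc=means, scale=config.severity_sd, random_state=rng_sev
    )
    # a zero session mean denotes no induced motion at all, not a
    # half-normal wobble around zero
    severities = np.where(means == 0.0, 0.0, severities)

    x, a, b = _feature_rows(
        config, ages, subject_effects, severities, scan_subject_idx,
        directions, feature_means, rng_noise,
    )

    ratings = assign_visual_ratings(severities, config.rating_noise_sd, rng_rate)
    euler_raw = synthesize_euler(
        severities, config.euler_intercept, config.euler_slope,
        config.euler_noise_sd, rng_euler,
    )

    records = []
    scan_ids = []
    for k in range(len(scan_subject_idx)):
        i = scan_subject_idx[k]
        sid = f"sub{i:04d}"
        scan_id = f"{sid}_{sessions[k]}"
        scan_ids.append(scan_id)
        records.append(
            ScanRecord(
                scan_id=scan_id,
                subject_id=sid,
                age=float(ages[i]),
                sex=str(sexes[i]),
                session=str(sessions[k]),
                rating=int(ratings[k]),
                euler_raw=float(euler_raw[k]),
            )
        )
    features = pd.DataFrame(
        x, index=pd.Index(scan_ids, name="scan_id"),
        columns=[f"f{j:03d}" for j in range(config.n_features)],
    )
    truth = GroundTruth(a, b, subject_effects, severities, directions, feature_means)
    return features, records, truth


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def assign_visual_ratings(severities, rating_noise_sd: float, seed) -> np.ndarray:
    """Map latent severities to integer 0-5 visual motion ratings.

    The map is piecewise linear with rounding:
    ``clamp(round(RATING_SLOPE * severity + noise), 0, 5)`` — monotone in
    expectation, saturating at the ends of the 6-point scale.

    ``seed`` may be an int or an existing :class:`numpy.random.Generator`.
    """
    severities = np.asarray(severities, dtype=float)
    if not np.all(np.isfinite(severities)):
        raise InputError("severities must be finite")
    if np.any(severities < 0):
        raise InputError("severities must be non-negative")
    if rating_noise_sd < 0:
        raise InputError("rating_noise_sd must be non-negative")
    rng = _as_rng(seed)
    latent = RATING_SLOPE * severities
    if rating_noise_sd > 0:
        latent = latent + rng.normal(0.0, rating_noise_sd, size=severities.shape)
    return np.clip(np.rint(latent), 0, MAX_RATING).astype(int)


def synthesize_euler(
    severities, euler_intercept: float, euler_slope: float, noise_sd: float, seed
) -> np.ndarray:
    """Raw average-Euler surrogate, left-skewed and decreasing with severity.

    A latent value ``e = euler_intercept - euler_slope * severity + noise``
    lives on the normalized-Euler scale; the returned raw value is
    ``1 - exp(-e)``, the exact inverse of the ``-ln(-raw + 1)``
    normalization, so normalizing the output recovers the latent exactly
    and the raw values inherit the heavy left tail seen in real Euler
    numbers.
    """
    severities = np.asarray(severities, dtype=float)
    if not np.all(np.isfinite(severities)):
        raise InputError("severities must be finite")
    if np.any(severities < 0):
        raise InputError("severities must be non-negative")
    if noise_sd < 0:
        raise InputError("noise_sd must be non-negative")
    rng = _as_rng(seed)
    latent = euler_intercept - euler_slope * severities
    if noise_sd > 0:
        latent = latent + rng.normal(0.0, noise_sd, size=severities.shape)
    return 1.0 - np.exp(-latent)
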