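"""Simulation configuration for the synthetic motion cohorts.

The synthetic design mirrors a repeated-session motion study: a training
cohort of young adults (one scan each, no induced motion) used to fit the
brain-age model, and a test cohort in which every participant is scanned
three times — once still (STAND), once with low induced head motion (HM1)
and once with high induced motion (HM2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

from .exceptions import ConfigError

SESSIONS = ("STAND", "HM1", "HM2")

MAX_RATING = 5
#: slope of the piecewise-linear severity -> rating map (rating levels per
#: severity unit); chosen so the high-motion session peaks near rating 4-5.
RATING_SLOPE = 1.6


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Features are generated from a low-rank latent model: a unit "aging
    direction" in feature space carries a linear age effect of
    ``age_effect_scale`` feature-units per year (negative by default, like
    grey-matter density decreasing with age); ``n_latent`` orthonormal latent
    directions carry subject-level random effects of SD ``subject_sd``;
    motion adds ``motion_bias`` feature-units per unit latent severity along
    a direction whose cosine with the aging direction is ``motion_overlap``.
    With the default negative ``motion_bias`` (grey-matter underestimation)
    and ``motion_overlap = 1``, motion pushes scans along the aging
    direction, i.e. makes brains look older.
    """

    n_train: int = 600
    n_test_subjects: int = 200
    n_features: int = 100
    n_latent: int = 12
    age_range: tuple[float, float] = (18.0, 50.0)
    age_effect_scale: float = -0.05  # feature-units / year along the aging direction
    subject_sd: float = 0.25  # SD of subject random effects per latent direction
    noise_sd: float = 0.10  # per-feature measurement noise SD
    motion_bias: float = -0.05  # feature-units per unit severity (<= 0: GM loss)
    motion_overlap: float = 1.0  # cosine between motion and aging directions
    severity_means: tuple[float, float, float] = (0.05, 1.5, 2.5)  # STAND, HM1, HM2
    severity_sd: float = 0.4
    rating_noise_sd: float = 0.5
    euler_intercept: float = -3.9  # latent normalized-Euler at zero severity
    euler_slope: float = 0.5  # normalized-Euler units lost per severity unit
    euler_noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_train", "n_test_subjects", "n_features"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_latent < 0:
            raise ConfigError(f"n_latent must be >= 0, got {self.n_latent}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError(f"age_range must be increasing, got {self.age_range}")
        if len(self.severity_means) != 3:
            raise ConfigError("severity_means needs one entry per session (STAND, HM1, HM2)")
        s0, s1, s2 = self.severity_means
        if not (s0 <= s1 <= s2):
            raise ConfigError(
                f"severity_means must be non-decreasing across sessions, got {self.severity_means}"
            )
        if min(self.severity_means) < 0:
            raise ConfigError("severity_means must be non-negative")
        if self.severity_sd <= 0:
            raise ConfigError(f"severity_sd must be positive, got {self.severity_sd}")
        if self.rating_noise_sd < 0:
            raise ConfigError("rating_noise_sd must be non-negative")
        if self.euler_noise_sd < 0:
            raise ConfigError("euler_noise_sd must be non-negative")
        if not -1.0 <= self.motion_overlap <= 1.0:
            raise ConfigError(f"motion_overlap must lie in [-1, 1], got {self.motion_overlap}")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ConfigError("noise_sd and subject_sd must be non-negative")

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimConfig fields: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("age_range", "severity_means"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)
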