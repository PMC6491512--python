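"""Cohort-simulation configuration.

The synthetic cohort emulates a community study of older adults who wear a
wristband sensor for several days per quarter. Ground-truth structure is
explicit: each lifestyle feature has a population mean/SD, participant-level
means are shifted by confounders (age, education, gender), and the MMSE
outcome is assembled from linear and inverted-U contributions of the true
lifestyle means plus direct confounder effects and Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .variables import LIFESTYLE_VARIABLES


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the offending field."""


#: Lifestyle features that carry their own generator distribution. Sleep
#: efficiency and awakening count are derived from TST/WASO structure.
GENERATED_FEATURES = [
    "walking_steps",
    "conversation_time",
    "heart_rate",
    "tst",
    "waso",
    "nap_time",
]

EFFECT_SHAPES = ("linear", "inverted_u")


@dataclass
class EffectSpec:
    """One ground-truth contribution of a lifestyle feature to MMSE.

    ``strength`` is MMSE points per between-person SD for ``linear`` effects,
    or the peak height in MMSE points for ``inverted_u`` effects (a Gaussian
    bump ``strength * exp(-(x - peak_location)^2 / (2 * peak_width^2))``).
    """

    variable: str
    shape: str
    strength: float
    peak_location: float | None = None
    peak_width: float | None = None

    def validate(self) -> None:
        if self.variable not in GENERATED_FEATURES:
            raise ConfigurationError(
                f"effect_specs: unknown variable {self.variable!r}; "
                f"expected one of {GENERATED_FEATURES}"
            )
        if self.shape not in EFFECT_SHAPES:
            raise ConfigurationError(
                f"effect_specs[{self.variable}].shape must be one of {EFFECT_SHAPES}"
            )
        if not math.isfinite(self.strength):
            raise ConfigurationError(f"effect_specs[{self.variable}].strength must be finite")
        if self.shape == "inverted_u":
            if self.peak_location is None:
                raise ConfigurationError(
                    f"effect_specs[{self.variable}]: peak_location required for inverted_u"
                )
            if self.peak_width is None or self.peak_width <= 0:
                raise ConfigurationError(
                    f"effect_specs[{self.variable}]: peak_width must be > 0 for inverted_u"
                )


@dataclass
class FeatureSpec:
    """Marginal distribution of one lifestyle feature.

    ``sd`` is the between-person SD of period-averaged values (what a summary
    table of per-participant means reports); ``daily_sd`` is the within-person
    day-to-day SD around the participant's own mean.
    """

    mean: float
    sd: float
    daily_sd: float
    minimum: float = 0.0
    maximum: float = math.inf


def _default_features() -> dict[str, FeatureSpec]:
    return {
        "walking_steps": FeatureSpec(5452.9, 2778.0, 1200.0, 0.0, 25000.0),
        "conversation_time": FeatureSpec(219.7, 86.3, 45.0, 0.0, 700.0),
        "heart_rate": FeatureSpec(64.7, 6.3, 2.5, 45.0, 110.0),
        "tst": FeatureSpec(408.4, 69.1, 35.0, 180.0, 660.0),
        "waso": FeatureSpec(22.1, 14.1, 8.0, 0.0, 120.0),
        "nap_time": FeatureSpec(48.7, 39.3, 20.0, 0.0, 300.0),
    }


def _default_effects() -> list[EffectSpec]:
    # Qualitative target structure: steps and heart rate linearly protective,
    # sleep duration and conversation time inverted-U with interior peaks, and
    # WASO carrying a weak positive direct term whose crude association is
    # sign-flipped by age confounding (the overshoot pattern the confounding
    # screen is built to catch).
    return [
        EffectSpec("walking_steps", "linear", 1.0),
        EffectSpec("heart_rate", "linear", 0.7),
        EffectSpec("waso", "linear", 0.22),
        EffectSpec("tst", "inverted_u", 1.8, peak_location=450.0, peak_width=90.0),
        EffectSpec("conversation_time", "inverted_u", 1.5, peak_location=300.0, peak_width=100.0),
    ]


def _default_confounding() -> dict[str, dict[str, float]]:
    # Per-unit effects of each (centred) confounder on lifestyle means and on
    # MMSE. Older age lowers daily steps, lengthens WASO and sleep, and lowers
    # MMSE; education raises conversation and MMSE; women talk somewhat more.
    return {
        "age": {"mmse": -0.12, "walking_steps": -80.0, "waso": 1.8, "tst": 0.5},
        "education": {"mmse": 0.15, "conversation_time": 3.0},
        "gender": {"conversation_time": 15.0},
    }


def _default_demographics() -> dict[str, Any]:
    return {
        "age_mean": 73.8,
        "age_sd": 5.8,
        "female_prob": 0.629,
        "education_mean": 11.8,
        "education_sd": 2.1,
        "education_min": 6.0,
        "education_max": 20.0,
        "bmi_mean": 23.2,
        "bmi_sd": 3.1,
        "bmi_min": 15.0,
        "bmi_max": 40.0,
        # Codes: 0 = every day, 1 = none, 2 = sometimes.
        "smoking_probs": {0: 0.021, 1: 0.958, 2: 0.021},
        "alcohol_probs": {0: 0.200, 1: 0.586, 2: 0.214},
        "hypertension_prev": 0.502,
        "diabetes_prev": 0.133,
        "hypercholesterolemia_prev": 0.329,
    }


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_participants: int = 855
    days_per_cycle: int = 8
    cycles: int = 4
    seed: int = 0
    effect_specs: list[EffectSpec] = field(default_factory=_default_effects)
    confounding_strengths: dict[str, dict[str, float]] = field(default_factory=_default_confounding)
    noise_sd: float = 1.5
    mmse_base: float = 26.0
    demographics: dict[str, Any] = field(default_factory=_default_demographics)
    features: dict[str, FeatureSpec] = field(default_factory=_default_features)
    #: Probability per participant-day of an inserted non-wear block.
    nonwear_prob: float = 0.0
    nonwear_minutes: int = 90

    @property
    def n_days(self) -> int:
        return self.days_per_cycle * self.cycles

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if self.days_per_cycle < 1:
            raise ConfigurationError("days_per_cycle must be >= 1")
        if self.cycles < 1:
            raise ConfigurationError("cycles must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0.0 <= self.nonwear_prob <= 1.0:
            raise ConfigurationError("nonwear_prob must be in [0, 1]")
        for key in ("hypertension_prev", "diabetes_prev", "hypercholesterolemia_prev", "female_prob"):
            p = self.demographics[key]
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"demographics[{key!r}] must be in [0, 1]")
        for name, spec in self.features.items():
            if name not in GENERATED_FEATURES:
                raise ConfigurationError(f"features: unknown feature {name!r}")
            if spec.sd < 0 or spec.daily_sd < 0:
                raise ConfigurationError(f"features[{name!r}]: SDs must be >= 0")
        for eff in self.effect_specs:
            eff.validate()
        for conf, strengths in self.confounding_strengths.items():
            for target in strengths:
                if target != "mmse" and target not in GENERATED_FEATURES:
                    raise ConfigurationError(
                        f"confounding_strengths[{conf!r}]: unknown target {target!r}"
                    )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["effect_specs"] = [dataclasses.asdict(e) for e in self.effect_specs]
        d["features"] = {k: dataclasses.asdict(v) for k, v in self.features.items()}
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "CohortConfig":
        data = dict(data)
        if "effect_specs" in data:
            data["effect_specs"] = [
                e if isinstance(e, EffectSpec) else EffectSpec(**e) for e in data["effect_specs"]
            ]
        if "features" in data:
            data["features"] = {
                k: v if isinstance(v, FeatureSpec) else FeatureSpec(**v)
                for k, v in data["features"].items()
            }
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


#: Nominal centring value of each confounder (so confounding contributions are
#: mean-zero and marginal feature means stay at their configured values).
def confounder_centers(demographics: dict[str, Any]) -> dict[str, float]:
    return {
        "age": demographics["age_mean"],
        "education": demographics["education_mean"],
        "gender": demographics["female_prob"],
        "bmi": demographics["bmi_mean"],
        "hypertension": demographics["hypertension_prev"],
        "diabetes": demographics["diabetes_prev"],
        "hypercholesterolemia": demographics["hypercholesterolemia_prev"],
    }


def confounder_sds(demographics: dict[str, Any]) -> dict[str, float]:
    """Marginal SD of each confounder (used to budget feature variance)."""

    def bern(p: float) -> float:
        return math.sqrt(p * (1.0 - p))

    return {
        "age": demographics["age_sd"],
        "education": demographics["education_sd"],
        "gender": bern(demographics["female_prob"]),
        "bmi": demographics["bmi_sd"],
        "hypertension": bern(demographics["hypertension_prev"]),
        "diabetes": bern(demographics["diabetes_prev"]),
        "hypercholesterolemia": bern(demographics["hypercholesterolemia_prev"]),
    }
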