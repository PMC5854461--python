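"""Survey measurement-error model.

Observed proportions are moved to the logit scale, where the latent process
lives.  The total error variance of an observation is the sum of its
survey-specific sampling variance (delta-method transform of the reported
proportion-scale standard error) and a squared source-specific non-sampling
standard deviation.  Sampling standard errors missing from the input are
imputed as the median of the observed standard errors for the same source
type and indicator, falling back to a configured default.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

from .data_io import Dataset, SOURCE_TYPES, SurveyObservation

__all__ = [
    "ErrorModelConfig",
    "TransformedObservation",
    "logit",
    "expit",
    "transform_observation",
    "impute_sampling_se",
    "total_variance",
    "prepare_observations",
]


def logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ValueError(f"logit undefined at {p}")
    return math.log(p / (1.0 - p))


def expit(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass
class ErrorModelConfig:
    """Source-specific biases and non-sampling error, all on the logit scale.

    ``bias`` is an additive logit-scale shift per source type with DHS fixed
    at zero as the reference category.  ``nonsampling_sd`` may hold fixed
    values (for simulation or a frozen fit); during estimation these are
    parameters with half-normal priors of scale ``nonsampling_prior_scale``.
    ``default_se`` (proportion scale) is the imputation fallback when no
    same-source, same-indicator standard errors are observed at all.
    ``emu_variance`` is the residual variance of one first-differenced
    logit-scale service-statistic observation.
    """

    nonsampling_sd: dict[str, float] = field(
        default_factory=lambda: {s: 0.1 for s in SOURCE_TYPES}
    )
    bias: dict[str, float] = field(default_factory=lambda: {s: 0.0 for s in SOURCE_TYPES})
    default_se: float = 0.015
    nonsampling_prior_scale: float = 0.2
    bias_prior_sd: float = 0.2
    emu_variance: float = 0.005

    def __post_init__(self) -> None:
        if self.bias.get("DHS", 0.0) != 0.0:
            raise ValueError("DHS is the reference source; its bias must be 0")
        for s, sd in self.nonsampling_sd.items():
            if sd < 0:
                raise ValueError(f"non-sampling SD for {s} must be >= 0")


@dataclass(frozen=True)
class TransformedObservation:
    """A survey observation on the modelling (logit) scale."""

    base: SurveyObservation
    z: float
    v_sampling: float
    v_total: float
    imputed: bool


def transform_observation(obs: SurveyObservation) -> tuple[float, float]:
    """Map a proportion-scale observation to logit scale.

    Returns ``(z, v_sampling)`` where ``z = logit(value)`` and the sampling
    variance is the delta-method image of the proportion-scale variance:
    ``se^2 / (value * (1 - value))^2``.
    """
    if obs.sampling_se is None:
        raise ValueError("sampling_se must be present (impute first)")
    z = logit(obs.value)
    d = obs.value * (1.0 - obs.value)
    return z, (obs.sampling_se / d) ** 2


def impute_sampling_se(pool: Sequence[float], default_se: float) -> float:
    """Median of the observed standard errors, or the configured fallback."""
    pool = [s for s in pool if s is not None]
    se = median(pool) if pool else default_se
    if not se > 0:
        raise ValueError(f"imputed sampling SE must be positive, got {se}")
    return se


def total_variance(v_sampling: float, source_type: str, cfg: ErrorModelConfig) -> float:
    """Total logit-scale variance: sampling plus squared non-sampling SD."""
    if v_sampling <= 0:
        raise ValueError(f"sampling variance must be positive, got {v_sampling}")
    return v_sampling + cfg.nonsampling_sd[source_type] ** 2


def prepare_observations(
    dataset: Dataset, cfg: ErrorModelConfig
) -> list[TransformedObservation]:
    """Transform every survey row to the modelling scale, imputing missing SEs.

    The imputation pool for an observation is the set of reported standard
    errors sharing its source type and indicator across the whole dataset.
    """
    pools: dict[tuple[str, str], list[float]] = {}
    for s in dataset.surveys:
        if s.sampling_se is not None:
            pools.setdefault((s.source_type, s.indicator), []).append(s.sampling_se)

    out: list[TransformedObservation] = []
    for s in dataset.surveys:
        if s.sampling_se is None:
            se = impute_sampling_se(pools.get((s.source_type, s.indicator), []), cfg.default_se)
            s_eff = SurveyObservation(
                s.country_code, s.indicator, s.value, s.source_type,
                s.period_start, s.period_end, se,
            )
            imputed = True
        else:
            s_eff, imputed = s, False
        z, v_sampling = transform_observation(s_eff)
        out.append(
            TransformedObservation(
                base=s_eff,
                z=z,
                v_sampling=v_sampling,
                v_total=total_variance(v_sampling, s.source_type, cfg),
                imputed=imputed,
            )
        )
    return out
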