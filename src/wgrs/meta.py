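"""Fixed-effect inverse-variance meta-analysis of log odds ratios.

Pooling is on the log-OR scale: each study contributes weight
``w_i = 1 / se_i**2``, the pooled estimate is the weighted mean and the
pooled SE is ``(sum w_i)**-0.5``.  Cochran's Q and I^2 are reported for
information only — the model is fixed-effect by design.

:func:`se_from_ci` back-transforms a published OR with its 95% Wald CI to a
log-OR and SE, so printed study results can be pooled directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = ["Z_95", "StudyEstimate", "MetaResult", "fixed_effect_meta", "se_from_ci"]

Z_95 = 1.959964


@dataclass(frozen=True)
class StudyEstimate:
    label: str
    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ConfigError(f"study {self.label!r}: se must be > 0, got {self.se}")


@dataclass(frozen=True)
class MetaResult:
    pooled_log_or: float
    pooled_se: float
    ci_low: float  # OR scale
    ci_high: float
    z: float
    p: float
    weights: tuple[float, ...]  # normalised, sum to 1
    labels: tuple[str, ...]
    q: float
    i2: float

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "log_or": self.pooled_log_or,
                    "se": self.pooled_se,
                    "or": self.pooled_or,
                    "ci_low": self.ci_low,
                    "ci_high": self.ci_high,
                    "z": self.z,
                    "p": self.p,
                    "q": self.q,
                    "i2": self.i2,
                }
            ]
        )


def fixed_effect_meta(studies: Sequence[StudyEstimate]) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study log-ORs."""
    studies = list(studies)
    if not studies:
        raise ConfigError("meta-analysis requires at least one study")
    log_or = np.array([s.log_or for s in studies])
    w = np.array([1.0 / s.se**2 for s in studies])
    pooled = float((w * log_or).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = pooled / se
    q = float((w * (log_or - pooled) ** 2).sum())
    dfq = len(studies) - 1
    i2 = float(max(0.0, (q - dfq) / q)) if q > 0 and dfq > 0 else 0.0
    return MetaResult(
        pooled_log_or=pooled,
        pooled_se=se,
        ci_low=math.exp(pooled - Z_95 * se),
        ci_high=math.exp(pooled + Z_95 * se),
        z=float(z),
        p=float(2.0 * stats.norm.sf(abs(z))),
        weights=tuple((w / w.sum()).tolist()),
        labels=tuple(s.label for s in studies),
        q=q,
        i2=i2,
    )


def se_from_ci(
    or_value: float, ci_low: float, ci_high: float, label: str = "", asym_tol: float = 0.02
) -> StudyEstimate:
    """Recover a log-OR and SE from a published OR with 95% Wald CI.

    ``se = (ln ci_high - ln ci_low) / (2 * 1.959964)``.  Warns when the CI is
    asymmetric about the log-OR beyond ``asym_tol`` (rounded tables often
    are, mildly; gross asymmetry suggests a non-Wald interval).
    """
    if not (0 < ci_low < or_value < ci_high):
        raise ConfigError(
            f"require 0 < ci_low < or < ci_high, got ({ci_low}, {or_value}, {ci_high})"
        )
    log_or = math.log(or_value)
    half_up = math.log(ci_high) - log_or
    half_down = log_or - math.log(ci_low)
    width = half_up + half_down
    if width > 0 and abs(half_up - half_down) / width > asym_tol:
        logger.warning(
            "CI for %s is asymmetric on the log scale (%.4f vs %.4f); "
            "SE recovered from the full width",
            label or or_value, half_down, half_up,
        )
    se = width / (2.0 * Z_95)
    return StudyEstimate(label=label, log_or=log_or, se=se)
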