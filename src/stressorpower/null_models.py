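"""Additive and multiplicative null-model effect sizes for factorial
two-stressor experiments.

A factorial experiment has four arms — control (C), stressor A alone,
stressor B alone, and both stressors together (I) — each summarised by a
mean, a standard deviation, and a replicate count.  The additive null model
expects the combined response to equal the sum of the individual stressor
effects; its interaction effect size is a four-arm Hedges' d,

    ES_add = J · (X̄_I − X̄_A − X̄_B + X̄_C) / s,

where ``s`` is the four-group pooled SD and ``J`` the small-sample bias
correction.  The multiplicative null model works on the log scale (a
factorial log response ratio) and expects the combined response ratio to
equal the product of the individual ratios.

Positive additive effect sizes mean the combined response sits *above* the
additive expectation; the sign carries no synergism/antagonism meaning on
its own — classification (see :mod:`stressorpower.inference`) is
direction-aware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.stats import norm

from .exceptions import (
    DegenerateExperimentError,
    NonPositiveMeanError,
    ZeroPooledSDError,
)

ADDITIVE = "additive"
MULTIPLICATIVE = "multiplicative"


@dataclass(frozen=True)
class TreatmentSummary:
    """Summary statistics for one treatment arm.

    Parameters
    ----------
    mean : float
        Mean response over the arm's replicates.  Unconstrained sign for the
        additive model; must be strictly positive for the multiplicative one.
    sd : float
        Sample standard deviation of the replicates (non-negative, finite).
    n : int
        Replicate count; at least 2 so the sample SD is estimable.
    """

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean):
            raise ValueError(f"treatment mean must be finite, got {self.mean!r}")
        if not math.isfinite(self.sd) or self.sd < 0:
            raise ValueError(f"treatment sd must be finite and >= 0, got {self.sd!r}")
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"treatment n must be an integer >= 2, got {self.n!r}")
        object.__setattr__(self, "n", int(self.n))


@dataclass(frozen=True)
class FactorialExperiment:
    """The four-arm summary every interaction effect size consumes."""

    control: TreatmentSummary
    stressor_a: TreatmentSummary
    stressor_b: TreatmentSummary
    interaction: TreatmentSummary
    id: Optional[str] = None

    @property
    def arms(self) -> tuple[TreatmentSummary, TreatmentSummary, TreatmentSummary, TreatmentSummary]:
        """Arms in canonical (C, A, B, I) order."""
        return (self.control, self.stressor_a, self.stressor_b, self.interaction)

    @property
    def total_n(self) -> int:
        return sum(arm.n for arm in self.arms)

    @property
    def df(self) -> int:
        """Degrees of freedom, ΣNx − 4."""
        return self.total_n - 4

    def __post_init__(self) -> None:
        if self.df < 1:
            raise DegenerateExperimentError(
                f"experiment needs ΣNx − 4 >= 1 degrees of freedom, got {self.df}"
            )


@dataclass(frozen=True)
class EffectSizeResult:
    """An interaction (or two-group) effect size with its sampling variance
    and confidence interval.

    ``observed_effect`` and ``expected_effect`` are on the model's scale:
    X_O = X̄_I − X̄_C and X_E = X̄_A + X̄_B − 2X̄_C for the additive model,
    their log analogues for the multiplicative model.  ``pooled_sd`` is only
    defined for standardized-mean-difference models (None otherwise) and
    ``j_correction`` is 1.0 where no small-sample correction applies.
    """

    model: str
    effect_size: float
    variance: float
    se: float
    ci_low: float
    ci_high: float
    alpha: float
    df: int
    observed_effect: float
    expected_effect: float
    pooled_sd: Optional[float]
    j_correction: float

    @property
    def significant(self) -> bool:
        """True when the CI excludes zero, i.e. the null model is rejected."""
        return self.ci_low > 0.0 or self.ci_high < 0.0


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")


def pooled_sd(exp: FactorialExperiment) -> float:
    """Replicate-weighted pooled standard deviation over the four arms.

    s = sqrt( Σx (Nx − 1)·SDx² / (ΣNx − 4) ).  Zero only if every arm SD is
    zero.
    """
    df = exp.df
    if df < 1:
        raise DegenerateExperimentError("ΣNx − 4 must be >= 1 to pool SDs")
    ss = sum((arm.n - 1) * arm.sd**2 for arm in exp.arms)
    return math.sqrt(ss / df)


def j_correction(df: int) -> float:
    """Small-sample bias correction J = 1 − 3/(4·df − 1).

    Converts a biased standardized mean difference (Cohen's d) into its
    approximately unbiased form (Hedges' g).  Strictly between 0 and 1 and
    increasing toward 1 as ``df`` grows.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df!r}")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def _smd_result(
    model: str,
    contrast: float,
    s: float,
    inv_n_sum: float,
    total_n: int,
    df: int,
    alpha: float,
    observed: float,
    expected: float,
) -> EffectSizeResult:
    """Shared core for standardized-mean-difference effect sizes."""
    if s == 0.0:
        raise ZeroPooledSDError("pooled SD is zero; standardized effect size undefined")
    j = j_correction(df)
    es = j * contrast / s
    variance = j**2 * (inv_n_sum + es**2 / (2.0 * total_n))
    se = math.sqrt(variance)
    z = norm.isf(alpha / 2.0)
    return EffectSizeResult(
        model=model,
        effect_size=es,
        variance=variance,
        se=se,
        ci_low=es - z * se,
        ci_high=es + z * se,
        alpha=alpha,
        df=df,
        observed_effect=observed,
        expected_effect=expected,
        pooled_sd=s,
        j_correction=j,
    )


def additive_effect_size(exp: FactorialExperiment, alpha: float = 0.05) -> EffectSizeResult:
    """Interaction effect size under the additive null model.

    The interaction contrast X̄_I − X̄_A − X̄_B + X̄_C (observed minus
    expected combined effect) is standardized by the pooled SD and corrected
    for small-sample bias.  The variance is

        V = J²·( 1/N_I + 1/N_A + 1/N_B + 1/N_C + ES²/(2·ΣNx) )

    and the CI is ES ± z(α/2)·sqrt(V) with df = ΣNx − 4 reported for
    information.
    """
    _check_alpha(alpha)
    c, a, b, i = exp.arms
    observed = i.mean - c.mean
    expected = a.mean + b.mean - 2.0 * c.mean
    inv_n = sum(1.0 / arm.n for arm in exp.arms)
    return _smd_result(
        ADDITIVE,
        observed - expected,
        pooled_sd(exp),
        inv_n,
        exp.total_n,
        exp.df,
        alpha,
        observed,
        expected,
    )


def multiplicative_effect_size(exp: FactorialExperiment, alpha: float = 0.05) -> EffectSizeResult:
    """Interaction effect size under the multiplicative null model.

    A factorial log response ratio: ES = ln X̄_I − ln X̄_A − ln X̄_B + ln X̄_C,
    zero exactly when X̄_I·X̄_C = X̄_A·X̄_B.  The variance is the delta-method
    sum Σx SDx²/(Nx·X̄x²), independent of the effect size itself.  All four
    means must be strictly positive; otherwise the additive model should be
    used.
    """
    _check_alpha(alpha)
    c, a, b, i = exp.arms
    for name, arm in zip(("control", "stressor_a", "stressor_b", "interaction"), exp.arms):
        if arm.mean <= 0.0:
            raise NonPositiveMeanError(
                f"{name} mean {arm.mean!r} is not > 0; the log response ratio is "
                "undefined — use the additive model"
            )
    observed = math.log(i.mean) - math.log(c.mean)
    expected = math.log(a.mean) + math.log(b.mean) - 2.0 * math.log(c.mean)
    es = observed - expected
    variance = sum(arm.sd**2 / (arm.n * arm.mean**2) for arm in exp.arms)
    se = math.sqrt(variance)
    z = norm.isf(alpha / 2.0)
    return EffectSizeResult(
        model=MULTIPLICATIVE,
        effect_size=es,
        variance=variance,
        se=se,
        ci_low=es - z * se,
        ci_high=es + z * se,
        alpha=alpha,
        df=exp.df,
        observed_effect=observed,
        expected_effect=expected,
        pooled_sd=None,
        j_correction=1.0,
    )


def single_stressor_effect_size(
    control: TreatmentSummary, treated: TreatmentSummary, alpha: float = 0.05
) -> EffectSizeResult:
    """Two-group Hedges' g for a single stressor versus control.

    d = J(df)·(X̄_t − X̄_c)/s₂ with df = n_t + n_c − 2, two-group pooled SD
    s₂, and variance 1/n_t + 1/n_c + d²/(2·(n_t + n_c)).  Matches the usual
    meta-analytic standardized mean difference (e.g. metafor's SMD measure,
    up to its exact-gamma form of J).
    """
    _check_alpha(alpha)
    df = control.n + treated.n - 2
    s2 = math.sqrt(
        ((control.n - 1) * control.sd**2 + (treated.n - 1) * treated.sd**2) / df
    )
    if s2 == 0.0:
        raise ZeroPooledSDError("two-group pooled SD is zero; effect size undefined")
    total_n = control.n + treated.n
    j = j_correction(df)
    g = j * (treated.mean - control.mean) / s2
    variance = 1.0 / control.n + 1.0 / treated.n + g**2 / (2.0 * total_n)
    se = math.sqrt(variance)
    z = norm.isf(alpha / 2.0)
    return EffectSizeResult(
        model=ADDITIVE,
        effect_size=g,
        variance=variance,
        se=se,
        ci_low=g - z * se,
        ci_high=g + z * se,
        alpha=alpha,
        df=df,
        observed_effect=treated.mean - control.mean,
        expected_effect=0.0,
        pooled_sd=s2,
        j_correction=j,
    )
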