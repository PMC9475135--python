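"""Interaction classification and critical (smallest detectable) effect sizes.

A significant departure from the null model is labelled relative to the net
individual stressor effect S = E_A + E_B (with E_A = X̄_A − X̄_C etc., on
the model's scale):

* synergistic — the combined response deviates from the null expectation in
  the *same* direction as S (the stressors amplify each other);
* antagonistic — the deviation opposes S but the combined effect
  T = X̄_I − X̄_C keeps the sign of S (the stressors dampen each other);
* reversal — the deviation opposes S so strongly that T has the opposite
  sign to S (e.g. two individually growth-promoting stressors jointly
  depress growth below the control).

A non-significant result is always "null": failure to reject is not
evidence of additivity, only absence of evidence against it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import norm

from .exceptions import InfeasibleConfigurationError, ModelMismatchError
from .null_models import (
    MULTIPLICATIVE,
    EffectSizeResult,
    FactorialExperiment,
    j_correction,
)


class InteractionLabel(str, enum.Enum):
    NULL = "null"
    SYNERGISTIC = "synergistic"
    ANTAGONISTIC = "antagonistic"
    REVERSAL = "reversal"

    def __str__(self) -> str:  # so CSV cells read "synergistic", not the repr
        return self.value


@dataclass(frozen=True)
class InteractionClassification:
    """Label plus the quantities it was derived from (on the model's scale)."""

    label: InteractionLabel
    net_individual_effect: float
    interaction_deviation: float
    significant: bool


@dataclass(frozen=True)
class CriticalEffectSize:
    """Smallest |effect size| distinguishable from the null at level alpha."""

    value: float
    alpha: float
    ns: tuple[int, int, int, int]
    df: int


def classify_direction(s: float, d: float, t: float) -> InteractionLabel:
    """Directional label for a *significant* deviation.

    ``s`` is the net individual effect, ``d`` the deviation of the combined
    effect from the null expectation, ``t`` the combined effect itself.  Tie
    rules (measure-zero under continuous data) are fixed: when s == 0 the
    label is reversal if t != 0 else antagonistic.
    """
    if s < 0.0:
        if d < 0.0:
            return InteractionLabel.SYNERGISTIC
        return InteractionLabel.ANTAGONISTIC if t <= 0.0 else InteractionLabel.REVERSAL
    if s > 0.0:
        if d > 0.0:
            return InteractionLabel.SYNERGISTIC
        return InteractionLabel.ANTAGONISTIC if t >= 0.0 else InteractionLabel.REVERSAL
    return InteractionLabel.REVERSAL if t != 0.0 else InteractionLabel.ANTAGONISTIC


def classify(result: EffectSizeResult, exp: FactorialExperiment) -> InteractionClassification:
    """Classify an effect-size result computed from ``exp``.

    The comparison happens on the scale the result was computed on: raw
    response units for the additive model, log response for the
    multiplicative one.
    """
    c, a, b, i = exp.arms
    if result.model == MULTIPLICATIVE:
        if any(arm.mean <= 0.0 for arm in exp.arms):
            raise ModelMismatchError(
                "multiplicative result paired with non-positive means; it cannot "
                "have been computed from this experiment"
            )
        e_a = math.log(a.mean) - math.log(c.mean)
        e_b = math.log(b.mean) - math.log(c.mean)
        t = math.log(i.mean) - math.log(c.mean)
    else:
        e_a = a.mean - c.mean
        e_b = b.mean - c.mean
        t = i.mean - c.mean
    s = e_a + e_b
    d = result.observed_effect - result.expected_effect
    if not result.significant:
        return InteractionClassification(InteractionLabel.NULL, s, d, False)
    return InteractionClassification(classify_direction(s, d, t), s, d, True)


def critical_effect_size(
    n_c: int, n_a: int, n_b: int, n_i: int, alpha: float = 0.05
) -> CriticalEffectSize:
    """Closed-form critical effect size for the additive null model.

    Solving |ES| = z(α/2)·sqrt(V(ES)) with V(E) = J²·(Σ 1/Nx + E²/(2ΣNx))
    gives

        ES_crit = sqrt( z²·J²·Σ(1/Nx) / (1 − z²·J²/(2·ΣNx)) ).

    An experiment with these replicate counts rejects the null model exactly
    when its |effect size| exceeds this value.  For four replicates per arm
    at α = 0.05 the threshold is ≈ 1.94 — only very large deviations from
    additivity are detectable at typical sample sizes.
    """
    ns = (n_c, n_a, n_b, n_i)
    if any(int(n) != n or n < 2 for n in ns):
        raise ValueError(f"all replicate counts must be integers >= 2, got {ns!r}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha!r}")
    total_n = sum(ns)
    df = total_n - 4
    z = norm.isf(alpha / 2.0)
    j = j_correction(df)
    denom = 1.0 - z**2 * j**2 / (2.0 * total_n)
    if denom <= 0.0:
        raise InfeasibleConfigurationError(
            f"no critical effect size exists for ns={ns}, alpha={alpha}: the "
            "variance grows faster than the effect size"
        )
    value = math.sqrt(z**2 * j**2 * sum(1.0 / n for n in ns) / denom)
    return CriticalEffectSize(value=value, alpha=alpha, ns=tuple(int(n) for n in ns), df=df)


def critical_effect_size_numeric(
    n_c: int, n_a: int, n_b: int, n_i: int, alpha: float = 0.05
) -> float:
    """Bisection oracle for :func:`critical_effect_size`.

    Finds the positive root of f(E) = E − z(α/2)·sqrt(V(E)) by bracketing,
    to 1e-10.  Kept deliberately independent of the closed form so the two
    can check each other.
    """
    ns = (n_c, n_a, n_b, n_i)
    if any(int(n) != n or n < 2 for n in ns):
        raise ValueError(f"all replicate counts must be integers >= 2, got {ns!r}")
    total_n = sum(ns)
    df = total_n - 4
    z = norm.isf(alpha / 2.0)
    j = j_correction(df)
    inv_n = sum(1.0 / n for n in ns)

    def f(e: float) -> float:
        return e - z * math.sqrt(j**2 * (inv_n + e**2 / (2.0 * total_n)))

    # f(0) < 0 always; search for an upper bracket where f > 0.
    hi = 1.0
    while f(hi) <= 0.0:
        hi *= 2.0
        if hi > 1e8:
            raise InfeasibleConfigurationError(
                f"no root: configuration ns={ns}, alpha={alpha} cannot reject at any effect size"
            )
    return float(brentq(f, 0.0, hi, xtol=1e-10))
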