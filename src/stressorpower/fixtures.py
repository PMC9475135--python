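"""Synthetic factorial-experiment tables with known ground truth.

Every experiment is built in two steps: first a population (four expected
means, a common σ, a replicate count) is constructed so that its *true*
interaction type is a requested label; then replicate summaries are sampled
from that population with the same Gaussian scheme the power engine uses.
A truth sidecar records the generating parameters so recovery rates can be
checked against the power engine's own predictions.

The default replicate-count distribution is skewed low (mode 3–4, tail to
30), mimicking the sample sizes typical of published multiple-stressor
experiments, where replication rarely reaches double figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InfeasibleMixError
from .inference import InteractionLabel, classify_direction
from .null_models import FactorialExperiment
from .power import PowerConfig, simulate_experiment

_DEFAULT_MIX = {
    InteractionLabel.NULL: 0.40,
    InteractionLabel.SYNERGISTIC: 0.20,
    InteractionLabel.ANTAGONISTIC: 0.25,
    InteractionLabel.REVERSAL: 0.15,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic experiment table.

    ``stressor_effect_range`` gives the range each individual stressor
    effect (E_A, E_B = arm mean − control mean) is drawn from; both
    endpoints must share a sign so the net individual effect is never zero.
    ``deviation_scale_range`` sets the non-null deviation |D| from the
    additive expectation in units of σ (so it is also roughly the true
    effect size |D|/σ).
    """

    n_experiments: int = 100
    label_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    control_mean_range: tuple[float, float] = (0.6, 0.9)
    stressor_effect_range: tuple[float, float] = (-0.3, -0.05)
    sd_range: tuple[float, float] = (0.02, 0.08)
    deviation_scale_range: tuple[float, float] = (0.5, 3.0)
    n_range: tuple[int, int] = (3, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        mix = {InteractionLabel(k): float(v) for k, v in self.label_mix.items()}
        object.__setattr__(self, "label_mix", mix)
        if any(v < 0 for v in mix.values()) or not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError(f"label mix must be non-negative and sum to 1, got {mix!r}")
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        for name in ("control_mean_range", "stressor_effect_range", "sd_range", "deviation_scale_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is empty: {(lo, hi)!r}")
        if self.n_range[0] < 2 or self.n_range[0] > self.n_range[1]:
            raise ValueError(f"n_range must satisfy 2 <= lo <= hi, got {self.n_range!r}")
        if self.sd_range[0] <= 0:
            raise ValueError("sd_range must be strictly positive")
        lo, hi = self.stressor_effect_range
        non_null = sum(v for k, v in mix.items() if k is not InteractionLabel.NULL)
        if non_null > 0 and (lo <= 0.0 <= hi) and not (lo == hi == 0.0) and lo < 0 < hi:
            raise InfeasibleMixError(
                "stressor_effect_range straddles 0: the net individual effect's "
                "sign would be ambiguous, so directional labels cannot be guaranteed"
            )
        if non_null > 0 and lo == 0.0 and hi == 0.0:
            raise InfeasibleMixError("zero stressor effects cannot produce directional labels")
        if self.deviation_scale_range[0] <= 0 and non_null > 0:
            raise ValueError("deviation_scale_range must be strictly positive")


def _skewed_n(rng: np.random.Generator, lo: int, hi: int) -> int:
    """Replicate count with a low mode: geometric offsets from the minimum."""
    if lo == hi:
        return lo
    n = lo + rng.geometric(0.35) - 1
    return int(min(n, hi))


def _population_for_label(
    rng: np.random.Generator, spec: FixtureSpec, label: InteractionLabel
) -> tuple[float, float, float, float, float]:
    """Draw (μ_C, μ_A, μ_B, μ_I, σ) whose true classification is ``label``."""
    mu_c = rng.uniform(*spec.control_mean_range)
    e_a = rng.uniform(*spec.stressor_effect_range)
    e_b = rng.uniform(*spec.stressor_effect_range)
    sigma = rng.uniform(*spec.sd_range)
    s = e_a + e_b
    sign = 1.0 if s > 0 else -1.0
    additive_mu_i = mu_c + s
    dev = rng.uniform(*spec.deviation_scale_range) * sigma
    if label is InteractionLabel.NULL:
        mu_i = additive_mu_i
    elif label is InteractionLabel.SYNERGISTIC:
        # push the combined response further in the direction of S
        mu_i = additive_mu_i + sign * dev
    elif label is InteractionLabel.ANTAGONISTIC:
        # pull back toward control, but keep the combined effect's sign
        mu_i = additive_mu_i - sign * min(dev, 0.9 * abs(s))
    else:  # reversal: combined effect flips sign relative to S
        mu_i = mu_c - sign * dev
    return mu_c, mu_c + e_a, mu_c + e_b, mu_i, sigma


def generate_experiments(spec: FixtureSpec) -> tuple[list[FactorialExperiment], pd.DataFrame]:
    """Generate experiments plus a truth sidecar.

    Returns the experiments and a DataFrame with one row per experiment:
    id, true_label, the population means, σ, n, and the population effect
    size (additive contrast over σ).  The sidecar's labels are verified
    against the classification rules at generation time.
    """
    rng = np.random.default_rng(spec.seed)
    labels = list(spec.label_mix.keys())
    probs = np.array([spec.label_mix[lab] for lab in labels])
    assigned = rng.choice(len(labels), size=spec.n_experiments, p=probs)

    experiments: list[FactorialExperiment] = []
    truth_rows = []
    for idx, lab_i in enumerate(assigned):
        label = labels[lab_i]
        mu_c, mu_a, mu_b, mu_i, sigma = _population_for_label(rng, spec, label)
        n = _skewed_n(rng, *spec.n_range)
        d_star = mu_i - mu_a - mu_b + mu_c
        if label is not InteractionLabel.NULL:
            s_star = (mu_a - mu_c) + (mu_b - mu_c)
            implied = classify_direction(s_star, d_star, mu_i - mu_c)
            if implied is not label:  # pragma: no cover - construction guarantees this
                raise InfeasibleMixError(
                    f"could not construct a {label.value} population from the given ranges"
                )
        config = PowerConfig(
            means=(mu_c, mu_a, mu_b, mu_i),
            sds=(sigma,) * 4,
            n_per_treatment=n,
            seed=spec.seed,
        )
        exp = simulate_experiment(config, rng)
        exp = FactorialExperiment(
            control=exp.control,
            stressor_a=exp.stressor_a,
            stressor_b=exp.stressor_b,
            interaction=exp.interaction,
            id=f"exp{idx:04d}",
        )
        experiments.append(exp)
        truth_rows.append(
            {
                "id": exp.id,
                "true_label": label.value,
                "mu_c": mu_c,
                "mu_a": mu_a,
                "mu_b": mu_b,
                "mu_i": mu_i,
                "sigma": sigma,
                "n": n,
                "true_effect_size": d_star / sigma,
            }
        )
    return experiments, pd.DataFrame(truth_rows)


def write_fixture(spec: FixtureSpec, path) -> pd.DataFrame:
    """Generate a table, write it as CSV plus a ``*_truth.csv`` sidecar.

    Returns the truth DataFrame.  The experiment CSV uses the dialect
    defined in :mod:`stressorpower.io`.
    """
    from . import io as _io  # local import: io depends on null_models only

    experiments, truth = generate_experiments(spec)
    _io.write_experiments(experiments, path)
    sidecar = _io.truth_sidecar_path(path)
    truth.to_csv(sidecar, index=False)
    return truth
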