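"""CSV reading/writing and the table-level analysis pipeline.

The experiment-table dialect is one row per factorial experiment:

    id, mean_c, sd_c, n_c, mean_a, sd_a, n_a, mean_b, sd_b, n_b,
    mean_i, sd_i, n_i

UTF-8, period decimal separator, header required (column order does not
matter).  Dispersion may be supplied as SD (default), SE, or variance with
an explicit flag; SE is converted via sd = se·√n and variance via its
square root.  Missing or blank cells are errors, never imputed — a row that
fails validation is reported with its row number and, in the analysis
pipeline, carried through with an error code rather than silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from scipy.stats import norm

from .exceptions import StressorPowerError
from .inference import classify, critical_effect_size
from .null_models import (
    ADDITIVE,
    MULTIPLICATIVE,
    FactorialExperiment,
    TreatmentSummary,
    additive_effect_size,
    multiplicative_effect_size,
)

ARM_KEYS = ("c", "a", "b", "i")
NUMERIC_COLUMNS = tuple(
    f"{kind}_{arm}" for arm in ARM_KEYS for kind in ("mean", "sd", "n")
)
COLUMNS = ("id",) + NUMERIC_COLUMNS

DISPERSION_KINDS = ("sd", "se", "variance")


@dataclass(frozen=True)
class RowError:
    """A row that failed validation, with a 1-based data row number."""

    row: int
    id: Optional[str]
    message: str


def _to_sd(value: float, kind: str, n: int) -> float:
    if kind == "sd":
        return value
    if kind == "se":
        return value * math.sqrt(n)
    if kind == "variance":
        return math.sqrt(value)
    raise ValueError(f"dispersion must be one of {DISPERSION_KINDS}, got {kind!r}")


def _row_to_experiment(row: pd.Series, dispersion: str) -> FactorialExperiment:
    arms = {}
    arm_fields = {
        "c": "control",
        "a": "stressor_a",
        "b": "stressor_b",
        "i": "interaction",
    }
    for key, fieldname in arm_fields.items():
        mean = float(row[f"mean_{key}"])
        disp = float(row[f"sd_{key}"])
        n_raw = float(row[f"n_{key}"])
        if not n_raw.is_integer():
            raise ValueError(f"n_{key} must be an integer, got {row[f'n_{key}']!r}")
        n = int(n_raw)
        arms[fieldname] = TreatmentSummary(mean=mean, sd=_to_sd(disp, dispersion, n), n=n)
    ident = row.get("id")
    ident = None if pd.isna(ident) else str(ident)
    return FactorialExperiment(id=ident, **arms)


def read_experiments(
    path, dispersion: str = "sd"
) -> tuple[list[FactorialExperiment], list[RowError]]:
    """Read an experiment table.

    Returns the validated experiments and the list of row-level failures
    (bad numbers, n < 2, blank cells).  A missing column is a schema error
    and raises immediately.
    """
    if dispersion not in DISPERSION_KINDS:
        raise ValueError(f"dispersion must be one of {DISPERSION_KINDS}, got {dispersion!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in NUMERIC_COLUMNS if c not in df.columns]
    if missing:
        raise StressorPowerError(f"{path}: missing required column(s) {missing}")
    experiments: list[FactorialExperiment] = []
    errors: list[RowError] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        ident = row.get("id")
        ident = None if pd.isna(ident) else str(ident)
        if row[list(NUMERIC_COLUMNS)].isna().any():
            blank = [c for c in NUMERIC_COLUMNS if pd.isna(row[c])]
            errors.append(RowError(pos, ident, f"blank/missing cell(s): {blank}"))
            continue
        try:
            experiments.append(_row_to_experiment(row, dispersion))
        except (ValueError, StressorPowerError) as exc:
            errors.append(RowError(pos, ident, str(exc)))
    return experiments, errors


def write_experiments(experiments: Iterable[FactorialExperiment], path) -> None:
    """Write experiments in the table dialect, full float precision."""
    rows = []
    for exp in experiments:
        row = {"id": exp.id}
        for key, arm in zip(ARM_KEYS, exp.arms):
            row[f"mean_{key}"] = arm.mean
            row[f"sd_{key}"] = arm.sd
            row[f"n_{key}"] = arm.n
        rows.append(row)
    # default float formatting is the shortest round-trip repr: values
    # survive write/read without precision loss
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, index=False)


def truth_sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_truth" + p.suffix)


def analyze_experiments(
    experiments: Iterable[FactorialExperiment],
    null_model: str = ADDITIVE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Effect size, CI, classification, and critical effect size per experiment.

    One output row per input experiment; rows whose model computation fails
    (e.g. a non-positive mean under the multiplicative model) keep their
    input columns and carry the failure in the ``error`` column.
    """
    compute = (
        multiplicative_effect_size if null_model == MULTIPLICATIVE else additive_effect_size
    )
    if null_model not in (ADDITIVE, MULTIPLICATIVE):
        raise ValueError(f"null_model must be additive or multiplicative, got {null_model!r}")
    rows = []
    for exp in experiments:
        row = {"id": exp.id}
        for key, arm in zip(ARM_KEYS, exp.arms):
            row[f"mean_{key}"] = arm.mean
            row[f"sd_{key}"] = arm.sd
            row[f"n_{key}"] = arm.n
        row["model"] = null_model
        try:
            result = compute(exp, alpha=alpha)
            cls = classify(result, exp)
            if null_model == MULTIPLICATIVE:
                # on the log-ratio scale the variance does not depend on the
                # effect size, so the detectability threshold is just z·SE
                crit_value = norm.isf(alpha / 2.0) * result.se
            else:
                crit_value = critical_effect_size(
                    *(arm.n for arm in exp.arms), alpha=alpha
                ).value
            row.update(
                effect_size=result.effect_size,
                variance=result.variance,
                ci_low=result.ci_low,
                ci_high=result.ci_high,
                df=result.df,
                classification=cls.label.value,
                critical_es=crit_value,
                error="",
            )
        except StressorPowerError as exc:
            row.update(
                effect_size=float("nan"),
                variance=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                df=exp.df,
                classification="",
                critical_es=float("nan"),
                error=type(exc).__name__,
            )
        rows.append(row)
    return pd.DataFrame(rows)
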