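"""Patient-level seizure-outcome prediction statistics.

The clinical hypothesis: residual epileptiform activity (HFO or
IED-HFO at a rate ≥ 1 min⁻¹) in the *post-resection* ECoG predicts that
the patient will not be seizure-free. Each patient therefore maps to
one cell of a 2×2 contingency table:

* TP — post-resection rate ≥ threshold and not seizure-free (ILAE 2–6)
* FP — post-resection rate ≥ threshold and seizure-free (ILAE 1)
* FN — post-resection rate < threshold and not seizure-free
* TN — post-resection rate < threshold and seizure-free

with the standard diagnostic metrics (PPV, NPV, sensitivity,
specificity, accuracy), exact Clopper–Pearson binomial confidence
intervals, and two-sided Spearman rank correlation for cross-detector
rate comparisons. The rate threshold comparison is inclusive (≥).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientOutcome",
    "Contingency",
    "Metrics",
    "classify_patient",
    "contingency_from_outcomes",
    "contingency_metrics",
    "clopper_pearson",
    "spearman_rho",
    "load_cohort",
    "RATE_THRESHOLD",
]

RATE_THRESHOLD = 1.0  # events / min


@dataclass(frozen=True)
class PatientOutcome:
    patient_id: str
    ilae_class: int
    post_resection_rate: float
    pre_resection_rate: float | None = None
    kind: str = "HFO"

    def __post_init__(self) -> None:
        if self.ilae_class not in range(1, 7):
            raise ValueError("ILAE class must lie in 1..6")
        if self.post_resection_rate < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class Contingency:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def classify_patient(outcome: PatientOutcome, rate_threshold: float = RATE_THRESHOLD) -> str:
    """Map one patient to TP/FP/FN/TN (threshold comparison inclusive)."""
    positive = outcome.post_resection_rate >= rate_threshold
    seizure_free = outcome.ilae_class == 1
    if positive:
        return "FP" if seizure_free else "TP"
    return "TN" if seizure_free else "FN"


def contingency_from_outcomes(
    outcomes: list[PatientOutcome],
    rate_threshold: float = RATE_THRESHOLD,
    overrides: dict[str, str] | None = None,
) -> tuple[Contingency, dict[str, str]]:
    """Tally a cohort; ``overrides`` force specific patients' labels.

    Overrides cover judgement calls the rate alone cannot express, e.g.
    a patient whose post-resection recording contained no IED at all is
    a false negative for the IED-HFO analysis regardless of rate.
    """
    overrides = overrides or {}
    labels = {}
    for o in outcomes:
        label = overrides.get(o.patient_id, classify_patient(o, rate_threshold))
        if label not in ("TP", "FP", "FN", "TN"):
            raise ValueError(f"invalid label {label!r}")
        labels[o.patient_id] = label
    counts = {k: sum(1 for v in labels.values() if v == k) for k in ("TP", "FP", "FN", "TN")}
    return (
        Contingency(tp=counts["TP"], fp=counts["FP"], fn=counts["FN"], tn=counts["TN"]),
        labels,
    )


@dataclass(frozen=True)
class Metrics:
    """Diagnostic metrics in percent; undefined ones are NaN and listed."""

    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    accuracy: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "ppv": self.ppv, "npv": self.npv, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "accuracy": self.accuracy,
        }


def contingency_metrics(c: Contingency) -> Metrics:
    """PPV = TP/(TP+FP), NPV = TN/(TN+FN), sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), accuracy = (TP+TN)/N — in percent.

    A metric with a zero denominator is flagged as undefined (NaN), never
    silently reported as zero. An empty table is an error.
    """
    if c.n == 0:
        raise ValueError("contingency table is empty")
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return math.nan
        return 100.0 * num / den

    m = Metrics(
        ppv=ratio(c.tp, c.tp + c.fp, "ppv"),
        npv=ratio(c.tn, c.tn + c.fn, "npv"),
        sensitivity=ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=ratio(c.tn, c.tn + c.fp, "specificity"),
        accuracy=100.0 * (c.tp + c.tn) / c.n,
        undefined=(),
    )
    return Metrics(**{**m.__dict__, "undefined": tuple(undefined)})


def clopper_pearson(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact binomial CI from beta-distribution quantiles; endpoints hit 0/1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n")
    alpha = 1.0 - confidence
    low = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return low, high


def spearman_rho(x, y) -> tuple[float, float]:
    """Two-sided Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return math.nan, math.nan
    res = stats.spearmanr(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def load_cohort(path: str | Path | None = None) -> pd.DataFrame:
    """Load the shipped surgical-cohort table (22 patients).

    Columns: ``patient_id``, ``ilae``, ``hfo_post_rate`` and
    ``iedhfo_post_rate`` (events/min; sub-threshold rates reported in
    the source only as "<1" are stored as 0.5), plus ``hfo_pre_rate``.
    The IED-HFO post rates equal the HFO ones except for the one
    patient whose post-resection recording contained no IED (handled as
    an override, see :func:`iedhfo_overrides`).
    """
    if path is None:
        with resources.as_file(
            resources.files("hfosnn").joinpath("data/usz_cohort.csv")
        ) as p:
            return pd.read_csv(p, comment="#")
    return pd.read_csv(path, comment="#")


def iedhfo_overrides() -> dict[str, str]:
    """Label overrides for the IED-HFO analysis: USZ 6 had no IED in the
    post-resection recording, so it counts as a false negative."""
    return {"USZ6": "FN"}


def cohort_outcomes(df: pd.DataFrame, kind: str = "HFO") -> list[PatientOutcome]:
    col = "hfo_post_rate" if kind == "HFO" else "iedhfo_post_rate"
    pre = "hfo_pre_rate"
    return [
        PatientOutcome(
            patient_id=r.patient_id, ilae_class=int(r.ilae),
            post_resection_rate=float(getattr(r, col)),
            pre_resection_rate=float(getattr(r, pre)), kind=kind,
        )
        for r in df.itertuples()
    ]
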