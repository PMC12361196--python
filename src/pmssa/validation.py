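"""ADE incidence summaries and score-vs-error rank correlation.

Three adverse-drug-event indicators are tracked per facility over a
reporting window -- dispensing errors, prescribing errors and
medication errors -- each expressed as a percentage of the facility's
total prescription volume.  The cohort summary reports, per indicator,
the mean of the facility incidences with a 95% confidence interval
(normal approximation, mean +/- 1.96 SE, by default; Student-t by
flag).  The *overall* incidence of a facility is the sum of its three
indicator incidences, and the cohort overall is summarised from those
sums.

Instrument validity is probed by the Spearman rank correlation between
facilities' overall assessment scores and their overall ADE incidence:
a well-calibrated instrument shows a negative association (better
practice, fewer errors).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "INDICATORS",
    "ADERecord",
    "IncidenceSummary",
    "CorrelationResult",
    "facility_incidence",
    "cohort_incidence",
    "spearman",
    "ADEValidator",
]

INDICATORS = ("dispensing", "prescribing", "medication")


@dataclass(frozen=True)
class ADERecord:
    """One facility's error counts over its prescription volume."""

    facility_id: str
    dispensing_errors: int
    prescribing_errors: int
    medication_errors: int
    total_prescriptions: int

    def __post_init__(self) -> None:
        counts = (self.dispensing_errors, self.prescribing_errors, self.medication_errors)
        if self.total_prescriptions <= 0:
            raise InvalidInputError(
                f"facility {self.facility_id}: total_prescriptions must be positive")
        if any(c < 0 for c in counts):
            raise InvalidInputError(f"facility {self.facility_id}: negative error count")
        if any(c > self.total_prescriptions for c in counts):
            raise InvalidInputError(
                f"facility {self.facility_id}: error count exceeds prescription volume")

    def count(self, indicator: str) -> int:
        try:
            return {"dispensing": self.dispensing_errors,
                    "prescribing": self.prescribing_errors,
                    "medication": self.medication_errors}[indicator]
        except KeyError:
            raise InvalidInputError(f"unknown indicator {indicator!r}") from None


@dataclass(frozen=True)
class IncidenceSummary:
    indicator: str
    mean_pct: float
    ci_low_pct: float
    ci_high_pct: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def facility_incidence(record: ADERecord) -> dict[str, float]:
    """Per-indicator incidence percents plus their sum (``overall``).

    incidence = 100 x error count / total prescriptions.
    """
    out = {ind: 100.0 * record.count(ind) / record.total_prescriptions
           for ind in INDICATORS}
    out["overall"] = sum(out[ind] for ind in INDICATORS)
    return out


def cohort_incidence(
    records: Sequence[ADERecord],
    indicator: str = "overall",
    ci_method: Literal["normal", "t"] = "normal",
) -> IncidenceSummary:
    """Cohort mean incidence with a 95% CI across facilities.

    The unit of analysis is the facility: the mean is the arithmetic
    mean of facility-level incidences and the CI is
    ``mean +/- 1.96 * sd / sqrt(N)`` (or the Student-t critical value
    with ``ci_method="t"``).  The ``overall`` indicator summarises the
    facility-level *sums* of the three indicators, matching the
    construction "overall = sum of the three means".
    """
    if len(records) < 2:
        raise InvalidInputError("cohort CI needs at least 2 facilities")
    if indicator not in INDICATORS + ("overall",):
        raise InvalidInputError(f"unknown indicator {indicator!r}")
    vals = np.array([facility_incidence(r)[indicator] for r in records])
    n = len(vals)
    mean = float(vals.mean())
    se = float(vals.std(ddof=1)) / math.sqrt(n)
    if ci_method == "normal":
        crit = 1.96
    elif ci_method == "t":
        crit = float(stats.t.ppf(0.975, n - 1))
    else:
        raise InvalidInputError(f"ci_method must be 'normal' or 't', got {ci_method!r}")
    return IncidenceSummary(indicator=indicator, mean_pct=mean,
                            ci_low_pct=mean - crit * se,
                            ci_high_pct=mean + crit * se, n=n)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided exact p by full enumeration of the n! pairings of the
    observed rank vectors (feasible for n <= 10)."""
    n = len(rx)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    if denom == 0:
        raise DegenerateInputError("constant ranks")
    observed = abs(rho)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float((rx[list(perm)] * ry).sum()) / denom
        if abs(r) >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def spearman(
    scores: Sequence[float],
    incidences: Sequence[float],
    p_mode: Literal["t", "exact"] = "t",
) -> CorrelationResult:
    """Spearman rank correlation between paired facility values.

    Ties receive average ranks; rho is the Pearson correlation of the
    rank vectors.  The two-sided p-value uses the t approximation
    ``t = rho sqrt((n-2)/(1-rho^2))`` on ``n-2`` df by default;
    ``p_mode="exact"`` enumerates all n! rank pairings (n <= 10 only).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(incidences, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("scores and incidences must be equal-length 1-D")
    n = len(x)
    if n < 3:
        raise InvalidInputError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("rho undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if p_mode == "exact":
        if n > 10:
            raise InvalidInputError("exact enumeration limited to n <= 10")
        p = _exact_spearman_p(stats.rankdata(x), stats.rankdata(y), rho)
    elif p_mode != "t":
        raise InvalidInputError(f"p_mode must be 't' or 'exact', got {p_mode!r}")
    return CorrelationResult(rho=rho, p_value=float(p), n=n)


class ADEValidator:
    """Validate assessment scores against ADE incidence for a cohort.

    ``fit(scores, records)`` pairs facilities by id, computes the
    per-indicator cohort incidence summaries and the Spearman
    correlation between overall assessment score and overall incidence.

    Parameters
    ----------
    ci_method : {"normal", "t"}
        Critical value for the incidence CIs.
    score_column : str
        Which score column to correlate when ``scores`` is a DataFrame
        (default the unweighted overall).

    Attributes
    ----------
    incidence_ : dict indicator -> IncidenceSummary
    correlation_ : CorrelationResult
    scatter_ : DataFrame with facility, score, incidence and both ranks.
    """

    def __init__(self, ci_method: Literal["normal", "t"] = "normal",
                 score_column: str = "overall_pct"):
        self.ci_method = ci_method
        self.score_column = score_column

    def get_params(self, deep: bool = True) -> dict:
        return {"ci_method": self.ci_method, "score_column": self.score_column}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise InvalidInputError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, scores, records: Sequence[ADERecord]):
        if isinstance(scores, pd.DataFrame):
            score_map = scores[self.score_column].astype(float).to_dict()
            score_map = {str(k): v for k, v in score_map.items()}
        else:
            score_map = {str(k): float(v) for k, v in dict(scores).items()}
        by_id = {r.facility_id: r for r in records}
        common = sorted(set(score_map) & set(by_id))
        if len(common) < 3:
            raise InvalidInputError("need at least 3 facilities present in both tables")
        paired_records = [by_id[f] for f in common]
        xs = [score_map[f] for f in common]
        ys = [facility_incidence(by_id[f])["overall"] for f in common]

        self.incidence_ = {
            ind: cohort_incidence(paired_records, ind, ci_method=self.ci_method)
            for ind in INDICATORS + ("overall",)
        }
        self.correlation_ = spearman(xs, ys)
        self.scatter_ = pd.DataFrame({
            "facility_id": common,
            "score_pct": xs,
            "incidence_pct": ys,
            "score_rank": stats.rankdata(xs),
            "incidence_rank": stats.rankdata(ys),
        }).set_index("facility_id")
        return self
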