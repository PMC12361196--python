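"""Likert A-E scoring and mean-percent rollups for facility assessments.

Each instrument item is answered on a five-level implementation scale:

=====  =============================================  ======
level  meaning                                        points
=====  =============================================  ======
A      no activity to implement the process            0
B      process discussed but not implemented           0
C      partially implemented in part of the org        2
D      fully implemented in part of the org            3
E      fully implemented throughout the organisation   4
=====  =============================================  ======

Scores at every aggregation level are *mean percent scores*: the mean
earned points divided by the maximum (4), times 100 -- e.g. an average
item score of 3.20 out of 4 equals 80%.  Rollups are computed per
characteristic, per domain and overall; an AHP-weighted overall (using
the characteristics' combination weights) is available as a clearly
separate mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import InvalidInputError, PMSSAError
from .hierarchy import Hierarchy, load_hierarchy

__all__ = [
    "LEVEL_POINTS",
    "MAX_POINTS",
    "FacilityAssessment",
    "ScoreReport",
    "level_to_points",
    "mean_percent",
    "score_facility",
    "cohort_summary",
    "AssessmentScorer",
]

LEVEL_POINTS: dict[str, int] = {"A": 0, "B": 0, "C": 2, "D": 3, "E": 4}
MAX_POINTS = 4


class UndefinedScoreError(PMSSAError, ValueError):
    """No answered items to average over."""


@dataclass(frozen=True)
class FacilityAssessment:
    """One facility's responses: item id -> level letter.

    Unanswered items are simply absent from ``responses`` (never
    defaulted).  ``ownership`` and ``annual_patient_volume`` are
    optional descriptive metadata.
    """

    facility_id: str
    responses: dict[str, str]
    ownership: str | None = None
    annual_patient_volume: int | None = None

    def __post_init__(self) -> None:
        canon = {}
        for item, level in self.responses.items():
            lvl = str(level).strip().upper()
            if lvl not in LEVEL_POINTS:
                raise InvalidInputError(
                    f"facility {self.facility_id}: level {level!r} for item {item!r} "
                    f"is not one of A-E")
            canon[str(item)] = lvl
        object.__setattr__(self, "responses", canon)


@dataclass(frozen=True)
class ScoreReport:
    facility_id: str
    item_points: dict[str, int]
    characteristic_pct: dict[str, float]
    domain_pct: dict[str, float]
    overall_pct: float
    weighted_overall_pct: float | None = None
    completeness: float = 1.0       # answered / instrument items
    missing_items: tuple[str, ...] = field(default_factory=tuple)


def level_to_points(level: str) -> int:
    """Map an implementation level A-E to its points (A, B -> 0; C -> 2;
    D -> 3; E -> 4)."""
    lvl = str(level).strip().upper()
    try:
        return LEVEL_POINTS[lvl]
    except KeyError:
        raise InvalidInputError(f"unknown level {level!r}; expected one of A-E") from None


def mean_percent(points: Sequence[int | float]) -> float:
    """Mean percent score: (mean points / 4) x 100."""
    pts = list(points)
    if not pts:
        raise UndefinedScoreError("cannot score an empty set of items")
    return float(np.mean(pts)) / MAX_POINTS * 100.0


def score_facility(
    assessment: FacilityAssessment,
    hierarchy: Hierarchy | None = None,
    domain_aggregation: Literal["items", "characteristics"] = "items",
) -> ScoreReport:
    """Roll a facility's A-E responses up to characteristic, domain and
    overall mean-percent scores.

    Missing responses are excluded from every mean (a completeness
    fraction is reported); a response to an item outside the hierarchy
    raises.  Domain percents average over the domain's answered items by
    default; ``domain_aggregation="characteristics"`` averages the
    characteristic percents instead.  The weighted overall is the
    combination-weight-weighted mean of the characteristic percents,
    renormalised over characteristics with at least one answered item.
    """
    h = hierarchy if hierarchy is not None else load_hierarchy()
    known = set(h.item_ids())
    unknown = set(assessment.responses) - known
    if unknown:
        raise InvalidInputError(
            f"facility {assessment.facility_id}: responses to unknown items "
            f"{sorted(unknown)[:5]}")

    item_points = {item: LEVEL_POINTS[lvl] for item, lvl in assessment.responses.items()}
    if not item_points:
        raise UndefinedScoreError(f"facility {assessment.facility_id} answered no items")

    by_char: dict[str, list[int]] = {}
    for item, pts in item_points.items():
        cid = h.characteristic_of_item(item).id
        by_char.setdefault(cid, []).append(pts)
    char_pct = {cid: mean_percent(pts) for cid, pts in by_char.items()}

    domain_pct: dict[str, float] = {}
    for d in h.domains:
        kid_ids = [c.id for c in h.children(d.id)]
        if domain_aggregation == "items":
            pts = [p for cid in kid_ids for p in by_char.get(cid, [])]
            if pts:
                domain_pct[d.id] = mean_percent(pts)
        elif domain_aggregation == "characteristics":
            pcts = [char_pct[cid] for cid in kid_ids if cid in char_pct]
            if pcts:
                domain_pct[d.id] = float(np.mean(pcts))
        else:
            raise InvalidInputError(
                f"domain_aggregation must be 'items' or 'characteristics', "
                f"got {domain_aggregation!r}")

    overall = mean_percent(list(item_points.values()))

    if not h.combination_weights:
        from .hierarchy import combination_weights as _cw
        _cw(h)
    answered = [cid for cid in char_pct]
    wsum = sum(h.combination_weights[cid] for cid in answered)
    weighted = (sum(h.combination_weights[cid] * char_pct[cid] for cid in answered) / wsum
                if wsum > 0 else None)

    missing = tuple(sorted(known - set(item_points)))
    return ScoreReport(
        facility_id=assessment.facility_id,
        item_points=item_points,
        characteristic_pct=char_pct,
        domain_pct=domain_pct,
        overall_pct=overall,
        weighted_overall_pct=weighted,
        completeness=len(item_points) / len(known),
        missing_items=missing,
    )


def cohort_summary(reports: Iterable[ScoreReport]) -> pd.DataFrame:
    """Cohort mean and sample SD of the overall and per-level percents.

    Returns a frame indexed by score name (``overall``, ``weighted_overall``,
    ``domain:<id>``, ``characteristic:<id>``) with columns ``mean``, ``sd``
    and ``n``; SD is NaN for a single facility.
    """
    reports = list(reports)
    if not reports:
        raise InvalidInputError("cohort summary needs at least one report")
    rows: dict[str, list[float]] = {}
    for r in reports:
        rows.setdefault("overall", []).append(r.overall_pct)
        if r.weighted_overall_pct is not None:
            rows.setdefault("weighted_overall", []).append(r.weighted_overall_pct)
        for did, pct in r.domain_pct.items():
            rows.setdefault(f"domain:{did}", []).append(pct)
        for cid, pct in r.characteristic_pct.items():
            rows.setdefault(f"characteristic:{cid}", []).append(pct)
    out = pd.DataFrame(
        {
            name: {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                "n": len(vals),
            }
            for name, vals in rows.items()
        }
    ).T
    out["n"] = out["n"].astype(int)
    return out


class AssessmentScorer(BaseEstimator):
    """Transformer turning facility A-E responses into mean-percent scores.

    ``transform`` accepts a list of :class:`FacilityAssessment` or a
    long-format DataFrame with columns ``facility_id, item_id, level``
    and returns one row per facility with overall, weighted-overall and
    per-domain percents.  Full :class:`ScoreReport` objects are kept on
    ``reports_``.

    Parameters
    ----------
    hierarchy : Hierarchy or None
        Weighting tree; the packaged published table when None.
    domain_aggregation : {"items", "characteristics"}
    """

    def __init__(self, hierarchy: Hierarchy | None = None,
                 domain_aggregation: Literal["items", "characteristics"] = "items"):
        self.hierarchy = hierarchy
        self.domain_aggregation = domain_aggregation

    def fit(self, X=None, y=None):
        self.hierarchy_ = self.hierarchy if self.hierarchy is not None else load_hierarchy()
        return self

    def _as_assessments(self, X) -> list[FacilityAssessment]:
        if isinstance(X, pd.DataFrame):
            needed = {"facility_id", "item_id", "level"}
            if not needed <= set(X.columns):
                raise InvalidInputError(f"long-format frame needs columns {sorted(needed)}")
            dup = X.duplicated(subset=["facility_id", "item_id"])
            if dup.any():
                raise InvalidInputError("duplicate (facility_id, item_id) rows")
            return [
                FacilityAssessment(facility_id=str(fid),
                                   responses=dict(zip(g["item_id"].astype(str), g["level"])))
                for fid, g in X.groupby("facility_id", sort=True)
            ]
        return list(X)

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "hierarchy_"):
            self.fit()
        assessments = self._as_assessments(X)
        self.reports_ = [
            score_facility(a, self.hierarchy_, domain_aggregation=self.domain_aggregation)
            for a in assessments
        ]
        rows = []
        for r in self.reports_:
            row: dict[str, float | str] = {
                "facility_id": r.facility_id,
                "overall_pct": r.overall_pct,
                "weighted_overall_pct": r.weighted_overall_pct,
                "completeness": r.completeness,
            }
            for d in self.hierarchy_.domains:
                row[f"domain_{d.id}_pct"] = r.domain_pct.get(d.id, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows).set_index("facility_id")

    def fit_transform(self, X, y=None):
        return self.fit().transform(X)
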