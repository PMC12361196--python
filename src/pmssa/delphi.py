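"""Delphi-round item statistics, data-driven screening, and panel diagnostics.

A Delphi round asks ``m`` experts to rate ``n`` candidate items on a
1-5 Likert scale along one dimension (applicability, importance or
feasibility).  Item-level consensus is summarised by three statistics --
mean score, coefficient of variation (CV) and full-score frequency (the
proportion of experts awarding a 5) -- and items are screened against
thresholds derived from the distribution of those statistics over the
round itself:

* full-score frequency below ``mean - SD`` of the frequencies,
* mean score below ``mean - SD`` of the means,
* CV above ``mean + SD`` of the CVs.

An item meeting *any* of the three criteria is excluded.  Panel-level
agreement is quantified by Kendall's coefficient of concordance W with
the standard tie correction, tested via chi-square, and expert quality
by the authority coefficient Cr = (Ca + Cs) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, InvalidInputError

__all__ = [
    "RatingMatrix",
    "ItemStats",
    "ScreeningThresholds",
    "ScreeningResult",
    "ConcordanceResult",
    "ExpertProfile",
    "compute_item_stats",
    "compute_thresholds",
    "screen_items",
    "kendalls_w",
    "chi_square_from_w",
    "authority_coefficient",
    "judgment_basis_score",
    "is_high_authority",
    "DelphiScreener",
]

SdMode = Literal["sample", "population"]

#: criterion labels, in reporting order
CRITERIA = ("low_full_score", "low_mean", "high_cv")


def _ddof(sd_mode: SdMode) -> int:
    if sd_mode == "sample":
        return 1
    if sd_mode == "population":
        return 0
    raise InvalidInputError(f"sd_mode must be 'sample' or 'population', got {sd_mode!r}")


@dataclass(frozen=True)
class RatingMatrix:
    """Likert ratings from one Delphi round: ``m`` experts x ``n`` items.

    Parameters
    ----------
    ratings:
        Integer array of shape ``(m, n)`` with entries in ``{1..5}``;
        rows are experts, columns are items.
    item_ids, expert_ids:
        Unique identifiers for columns and rows respectively.
    round_id, dimension:
        Bookkeeping labels; ``dimension`` is one of ``applicability``,
        ``importance``, ``feasibility``.
    """

    ratings: np.ndarray
    item_ids: tuple[str, ...]
    expert_ids: tuple[str, ...]
    round_id: str = "round"
    dimension: str = "applicability"

    def __post_init__(self) -> None:
        arr = np.asarray(self.ratings)
        if arr.ndim != 2 or arr.size == 0:
            raise InvalidInputError("ratings must be a non-empty 2-D grid")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise InvalidInputError("ratings must be integers")
            arr = arr.astype(int)
        if arr.min() < 1 or arr.max() > 5:
            raise InvalidInputError("ratings must lie in [1, 5]")
        object.__setattr__(self, "ratings", arr)
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))
        object.__setattr__(self, "expert_ids", tuple(str(e) for e in self.expert_ids))
        m, n = arr.shape
        if len(self.item_ids) != n:
            raise InvalidInputError(f"{len(self.item_ids)} item_ids for {n} items")
        if len(self.expert_ids) != m:
            raise InvalidInputError(f"{len(self.expert_ids)} expert_ids for {m} experts")
        if len(set(self.item_ids)) != n:
            raise InvalidInputError("item_ids must be unique")
        if len(set(self.expert_ids)) != m:
            raise InvalidInputError("expert_ids must be unique")

    @property
    def m(self) -> int:
        return self.ratings.shape[0]

    @property
    def n(self) -> int:
        return self.ratings.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ratings, index=list(self.expert_ids),
                            columns=list(self.item_ids))


@dataclass(frozen=True)
class ItemStats:
    item_id: str
    mean_score: float
    sd_score: float
    cv: float                  # sd / mean, stored as a fraction
    full_score_freq: float     # proportion of experts rating 5, in [0, 1]


@dataclass(frozen=True)
class ScreeningThresholds:
    full_score_threshold: float   # mean - SD of full-score frequencies
    mean_score_threshold: float   # mean - SD of item means
    cv_threshold: float           # mean + SD of item CVs


@dataclass(frozen=True)
class ScreeningResult:
    item_id: str
    excluded: bool
    criteria_met: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.criteria_met <= set(CRITERIA):
            raise InvalidInputError(f"unknown criteria: {self.criteria_met - set(CRITERIA)}")
        if self.excluded != bool(self.criteria_met):
            raise InvalidInputError("excluded must be True iff criteria_met is non-empty")


@dataclass(frozen=True)
class ConcordanceResult:
    w: float
    chi_square: float
    df: int
    p_value: float
    m: int
    n: int


@dataclass(frozen=True)
class ExpertProfile:
    """Expert authority profile.

    ``ca`` is the judgment-basis score (sum of the four self-assessed
    components, normalised to [0, 1]); ``cs`` the self-assessed
    familiarity; ``cr`` their mean.
    """

    expert_id: str
    ca: float
    cs: float
    cr: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        computed = authority_coefficient(self.ca, self.cs)
        if self.cr is None:
            object.__setattr__(self, "cr", computed)
        elif abs(self.cr - computed) > 1e-9:
            raise InvalidInputError("cr must equal (ca + cs) / 2")

    @property
    def high_authority(self) -> bool:
        return is_high_authority(self.cr)


def compute_item_stats(ratings: RatingMatrix, sd_mode: SdMode = "sample") -> list[ItemStats]:
    """Per-item mean, SD, CV and full-score frequency for one round.

    SD uses the sample (``n-1``) convention by default; CV is stored as a
    fraction (``sd / mean``) and the full-score frequency as a proportion
    of the ``m`` experts.
    """
    arr = ratings.ratings
    if arr.shape[0] < 1:
        raise InvalidInputError("at least one expert required")
    ddof = _ddof(sd_mode)
    if arr.shape[0] <= ddof:
        raise InvalidInputError("sample SD needs at least 2 experts")
    means = arr.mean(axis=0)
    sds = arr.std(axis=0, ddof=ddof)
    cvs = sds / means  # mean >= 1 on the Likert domain, never zero
    freqs = (arr == 5).mean(axis=0)
    return [
        ItemStats(item_id=iid, mean_score=float(mu), sd_score=float(sd),
                  cv=float(cv), full_score_freq=float(fq))
        for iid, mu, sd, cv, fq in zip(ratings.item_ids, means, sds, cvs, freqs)
    ]


def compute_thresholds(stats: Sequence[ItemStats], sd_mode: SdMode = "sample") -> ScreeningThresholds:
    """Data-driven exclusion thresholds from the current round's items only.

    ``mean - SD`` for full-score frequency and mean score (low is bad),
    ``mean + SD`` for CV (high is bad).
    """
    if len(stats) < 2:
        raise InvalidInputError("thresholds need at least 2 items (SD undefined)")
    ddof = _ddof(sd_mode)
    freqs = np.array([s.full_score_freq for s in stats])
    means = np.array([s.mean_score for s in stats])
    cvs = np.array([s.cv for s in stats])
    return ScreeningThresholds(
        full_score_threshold=float(freqs.mean() - freqs.std(ddof=ddof)),
        mean_score_threshold=float(means.mean() - means.std(ddof=ddof)),
        cv_threshold=float(cvs.mean() + cvs.std(ddof=ddof)),
    )


def screen_items(stats: Sequence[ItemStats], thresholds: ScreeningThresholds) -> list[ScreeningResult]:
    """Apply the any-of-three exclusion rule.

    Comparisons are strict: an item exactly on a threshold is retained.
    """
    results = []
    for s in stats:
        met = set()
        if s.full_score_freq < thresholds.full_score_threshold:
            met.add("low_full_score")
        if s.mean_score < thresholds.mean_score_threshold:
            met.add("low_mean")
        if s.cv > thresholds.cv_threshold:
            met.add("high_cv")
        results.append(ScreeningResult(item_id=s.item_id, excluded=bool(met),
                                       criteria_met=frozenset(met)))
    return results


def kendalls_w(ratings: RatingMatrix) -> ConcordanceResult:
    """Kendall's coefficient of concordance with tie correction.

    Each expert's ratings are converted to ranks over the ``n`` items
    (average ranks for ties).  With ``S`` the sum of squared deviations
    of the item rank sums about their mean and ``T_i`` the tie
    correction ``sum(t^3 - t)`` over tie groups of expert ``i``::

        W = 12 S / (m^2 (n^3 - n) - m * sum_i T_i)

    The significance test is ``chi^2 = m (n - 1) W`` on ``n - 1``
    degrees of freedom.
    """
    arr = ratings.ratings
    m, n = arr.shape
    if m < 2 or n < 2:
        raise InvalidInputError("Kendall's W needs m >= 2 experts and n >= 2 items")
    ranks = np.apply_along_axis(stats.rankdata, 1, arr.astype(float))
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    tie_corr = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        tie_corr += float((counts.astype(float) ** 3 - counts).sum())
    denom = m * m * (n ** 3 - n) - m * tie_corr
    if denom <= 0:
        raise DegenerateInputError(
            "W undefined: every expert assigns the same rating to every item")
    w = 12.0 * s / denom
    w = float(min(max(w, 0.0), 1.0))
    chi2 = m * (n - 1) * w
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    return ConcordanceResult(w=w, chi_square=float(chi2), df=df, p_value=p, m=m, n=n)


def chi_square_from_w(w: float, m: int, n: int) -> float:
    """Chi-square statistic implied by a concordance coefficient:
    ``chi^2 = m (n - 1) W`` with ``n - 1`` degrees of freedom."""
    if not 0.0 <= w <= 1.0:
        raise InvalidInputError("W must lie in [0, 1]")
    if m < 2 or n < 2:
        raise InvalidInputError("need m >= 2 and n >= 2")
    return float(m * (n - 1) * w)


def judgment_basis_score(components: Sequence[float]) -> float:
    """Sum the four judgment-basis self-assessment components
    (theoretical analysis, practical experience, peer understanding,
    intuition) into a single normalised Ca in [0, 1]."""
    total = float(sum(components))
    if any(c < 0 for c in components) or total > 1.0 + 1e-9:
        raise InvalidInputError("judgment-basis components must be non-negative "
                                "and sum to at most 1")
    return min(total, 1.0)


def authority_coefficient(ca: float, cs: float) -> float:
    """Expert authority coefficient ``Cr = (Ca + Cs) / 2``."""
    if not (0.0 <= ca <= 1.0 and 0.0 <= cs <= 1.0):
        raise InvalidInputError("Ca and Cs must lie in [0, 1]")
    return (ca + cs) / 2.0


def is_high_authority(cr: float, cutoff: float = 0.7) -> bool:
    """An authority coefficient at or above 0.7 denotes high authority."""
    return cr >= cutoff


class DelphiScreener(BaseEstimator):
    """Item screening for a Delphi round, as a feature-selection transformer.

    ``fit`` takes the ``(m, n)`` ratings grid (array or DataFrame, rows =
    experts), computes per-item statistics, the round's data-driven
    thresholds, the screening decisions, and the panel concordance;
    ``transform`` drops the excluded item columns.

    Parameters
    ----------
    sd_mode : {"sample", "population"}
        Denominator convention for every standard deviation.

    Attributes
    ----------
    item_stats_ : pandas.DataFrame
        One row per item: mean, SD, CV, full-score frequency.
    thresholds_ : ScreeningThresholds
    results_ : list of ScreeningResult
    support_ : ndarray of bool, shape (n,)
        True for retained items.
    concordance_ : ConcordanceResult
        Kendall's W over the fitted round (None when degenerate).
    """

    def __init__(self, sd_mode: SdMode = "sample"):
        self.sd_mode = sd_mode

    def _as_matrix(self, X) -> RatingMatrix:
        if isinstance(X, RatingMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return RatingMatrix(ratings=X.to_numpy(),
                                item_ids=tuple(map(str, X.columns)),
                                expert_ids=tuple(map(str, X.index)))
        arr = np.asarray(X)
        if arr.ndim != 2:
            raise InvalidInputError("expected a 2-D experts x items grid")
        return RatingMatrix(ratings=arr,
                            item_ids=tuple(f"item{j+1}" for j in range(arr.shape[1])),
                            expert_ids=tuple(f"expert{i+1}" for i in range(arr.shape[0])))

    def fit(self, X, y=None):
        rm = self._as_matrix(X)
        stats_list = compute_item_stats(rm, sd_mode=self.sd_mode)
        self.item_ids_ = list(rm.item_ids)
        self.n_features_in_ = rm.n
        self.item_stats_ = pd.DataFrame(
            [vars(s) for s in stats_list]).set_index("item_id")
        self.thresholds_ = compute_thresholds(stats_list, sd_mode=self.sd_mode)
        self.results_ = screen_items(stats_list, self.thresholds_)
        self.support_ = np.array([not r.excluded for r in self.results_])
        try:
            self.concordance_ = kendalls_w(rm)
        except DegenerateInputError:
            self.concordance_ = None
        return self

    def get_support(self, indices: bool = False):
        if indices:
            return np.flatnonzero(self.support_)
        return self.support_

    def transform(self, X):
        rm = self._as_matrix(X)
        if rm.n != len(self.support_):
            raise InvalidInputError("column count differs from the fitted round")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return rm.ratings[:, self.support_]

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)

    @property
    def excluded_items_(self) -> list[str]:
        return [r.item_id for r in self.results_ if r.excluded]
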