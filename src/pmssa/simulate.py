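"""Synthetic expert panels, comparison matrices and facility cohorts.

No raw study data are deposited for instruments of this kind, so every
input the pipeline consumes can be generated here with controllable
ground truth:

* **Panels** -- ``m`` experts rate ``n`` items by rounding a noisy copy
  of each item's latent quality (on the 1-5 scale) to the Likert grid.
  A ``consensus`` knob scales the expert noise (1 = deterministic
  ratings, 0 = maximal noise), and a configurable number of *outlier*
  items get latent qualities low enough to trip the screening rules.
  Defaults emulate a 15-expert, 91-item first-round applicability
  survey with 7 weak items.
* **Comparison matrices** -- each expert's matrix perturbs the
  consistent matrix ``w_i / w_j`` of a true weight vector by
  multiplicative log-normal noise (optionally snapped to the Saaty
  scale); zero noise reproduces the consistent matrix exactly.
* **Cohorts** -- each facility carries a latent safety quality
  ``q ~ Beta``; A-E responses come from an ordered-threshold model on
  ``q`` plus item noise (expected score strictly increasing in ``q``)
  and error counts are binomial with per-indicator probabilities
  log-linear and *decreasing* in ``q``, times a facility-level
  log-normal frailty.  Defaults are calibrated so a 43-facility cohort
  reproduces the regime of the published application study (overall
  score around 81.5%, indicator incidences around 0.14 / 2.34 / 0.58%,
  and a moderate negative score-error rank correlation).

A single integer seed drives everything through per-module derived
streams, so each generator can be re-run independently yet
reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats as sps

from .ahp import SAATY_VALUES, PairwiseMatrix
from .delphi import RatingMatrix
from .errors import InvalidInputError
from .hierarchy import Hierarchy, load_hierarchy
from .scoring import FacilityAssessment
from .validation import INDICATORS, ADERecord

__all__ = [
    "PanelSpec",
    "CohortSpec",
    "generate_panel",
    "generate_matrices",
    "generate_cohort",
    "expected_incidence",
    "expected_score_pct",
]

# stream tags for hierarchical seed derivation
_STREAMS = {"panel": 1, "matrices": 2, "cohort": 3}

_LEVELS = np.array(["A", "B", "C", "D", "E"])
_POINTS = np.array([0, 0, 2, 3, 4], dtype=float)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class PanelSpec:
    """Configuration of a synthetic Delphi round.

    ``consensus`` in [0, 1] scales expert rating noise as
    ``sigma = noise_scale * (1 - consensus)``; ``outlier_items`` items
    receive latent qualities in ``outlier_quality`` instead of
    ``item_quality``.  Defaults emulate the 15-expert, 91-item,
    7-weak-item first round.
    """

    m_experts: int = 15
    n_items: int = 91
    consensus: float = 0.8
    outlier_items: int = 7
    seed: int = 0
    item_quality: tuple[float, float] = (4.75, 5.0)       # uniform range, 1-5 scale
    outlier_quality: tuple[float, float] = (2.0, 2.6)
    noise_scale: float = 2.0
    round_id: str = "synthetic-round"
    dimension: str = "applicability"

    def __post_init__(self) -> None:
        if not (0.0 <= self.consensus <= 1.0):
            raise InvalidInputError("consensus must lie in [0, 1]")
        if self.outlier_items < 0 or self.outlier_items > self.n_items:
            raise InvalidInputError("outlier_items must lie in [0, n_items]")
        if self.m_experts < 2 or self.n_items < 2:
            raise InvalidInputError("need at least 2 experts and 2 items")


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic facility cohort.

    ``quality_alpha/beta`` parametrise the latent safety quality
    ``q ~ Beta``; ``cutpoints`` are the ordered thresholds of the A-E
    response model on ``q + N(0, response_noise)``; the error model is
    ``p_k = base_k * exp(-error_slope * (q - E[q]) + eta)`` with
    facility frailty ``eta ~ N(0, frailty_sd)``, clipped at
    ``max_error_prob``.  Defaults target the published application
    regime at ``n_facilities = 43``.
    """

    n_facilities: int = 43
    quality_alpha: float = 36.0
    quality_beta: float = 10.0
    cutpoints: tuple[float, float, float, float] = (0.49, 0.59, 0.67, 0.80)
    response_noise: float = 0.07
    error_baseline: dict = field(default_factory=lambda: {
        "dispensing": 0.00073, "prescribing": 0.0122, "medication": 0.0030})
    error_slope: float = 9.0
    frailty_sd: float = 1.0
    max_error_prob: float = 0.2
    prescriptions_range: tuple[int, int] = (4_000, 42_000)
    public_fraction: float = 33 / 43
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_facilities < 1:
            raise InvalidInputError("need at least one facility")
        if list(self.cutpoints) != sorted(self.cutpoints):
            raise InvalidInputError("cutpoints must be non-decreasing")
        if self.prescriptions_range[0] < 1 or self.prescriptions_range[0] > self.prescriptions_range[1]:
            raise InvalidInputError("invalid prescriptions_range")
        missing = set(INDICATORS) - set(self.error_baseline)
        if missing:
            raise InvalidInputError(f"error_baseline missing indicators {missing}")

    @property
    def quality_mean(self) -> float:
        return self.quality_alpha / (self.quality_alpha + self.quality_beta)


# ---------------------------------------------------------------------
# Delphi panel
# ---------------------------------------------------------------------

def generate_panel(spec: PanelSpec) -> tuple[RatingMatrix, np.ndarray]:
    """Draw one synthetic Delphi round.

    Returns the ratings and the ground-truth latent item qualities
    (outlier items occupy the *last* ``outlier_items`` positions).
    """
    rng = _rng(spec.seed, "panel")
    n_good = spec.n_items - spec.outlier_items
    quality = np.concatenate([
        rng.uniform(*spec.item_quality, size=n_good),
        rng.uniform(*spec.outlier_quality, size=spec.outlier_items),
    ])
    sigma = spec.noise_scale * (1.0 - spec.consensus)
    noise = rng.normal(0.0, sigma, size=(spec.m_experts, spec.n_items)) if sigma > 0 \
        else np.zeros((spec.m_experts, spec.n_items))
    ratings = np.clip(np.rint(quality[None, :] + noise), 1, 5).astype(int)
    rm = RatingMatrix(
        ratings=ratings,
        item_ids=tuple(f"item{j+1:03d}" for j in range(spec.n_items)),
        expert_ids=tuple(f"expert{i+1:02d}" for i in range(spec.m_experts)),
        round_id=spec.round_id,
        dimension=spec.dimension,
    )
    return rm, quality


# ---------------------------------------------------------------------
# AHP matrices
# ---------------------------------------------------------------------

def _snap_saaty(values: np.ndarray) -> np.ndarray:
    grid = np.array(SAATY_VALUES)
    # nearest on a log scale, the natural metric for ratio judgments
    idx = np.argmin(np.abs(np.log(values[..., None]) - np.log(grid[None, :])), axis=-1)
    return grid[idx]


def generate_matrices(
    true_weights: Sequence[float],
    noise: float = 0.1,
    n_experts: int = 15,
    seed: int = 0,
    snap_to_saaty: bool = False,
    node_id: str = "node",
    labels: Sequence[str] | None = None,
) -> list[PairwiseMatrix]:
    """One comparison matrix per expert around a true weight vector.

    Above-diagonal entries are ``(w_i / w_j) * exp(eps)`` with
    ``eps ~ N(0, noise)``; the lower triangle is filled reciprocally, so
    every matrix is exactly reciprocal.  ``noise = 0`` reproduces the
    fully consistent matrix (CR = 0).
    """
    w = np.asarray(true_weights, dtype=float)
    if w.ndim != 1 or len(w) < 2 or np.any(w <= 0):
        raise InvalidInputError("true_weights must be a positive vector of length >= 2")
    w = w / w.sum()
    n = len(w)
    labels = tuple(labels) if labels is not None else tuple(f"c{i+1}" for i in range(n))
    rng = _rng(seed, "matrices")
    consistent = w[:, None] / w[None, :]
    iu = np.triu_indices(n, k=1)
    out = []
    for e in range(n_experts):
        upper = consistent[iu]
        if noise > 0:
            upper = upper * np.exp(rng.normal(0.0, noise, size=len(upper)))
        if snap_to_saaty:
            upper = _snap_saaty(upper)
        a = np.ones((n, n))
        a[iu] = upper
        a[(iu[1], iu[0])] = 1.0 / upper
        out.append(PairwiseMatrix(node_id=node_id, entries=a, labels=labels))
    return out


# ---------------------------------------------------------------------
# Facility cohort
# ---------------------------------------------------------------------

def _error_prob(spec: CohortSpec, q: np.ndarray, eta: np.ndarray,
                indicator: str) -> np.ndarray:
    base = spec.error_baseline[indicator]
    raw = base * np.exp(-spec.error_slope * (q - spec.quality_mean) + eta)
    return np.clip(raw, 0.0, spec.max_error_prob)


def generate_cohort(
    spec: CohortSpec,
    hierarchy: Hierarchy | None = None,
) -> tuple[list[FacilityAssessment], list[ADERecord], np.ndarray]:
    """Draw a facility cohort: assessments, ADE records and true qualities.

    Responses and error counts are driven by the same latent quality,
    giving the cohort a genuinely negative score-error association.
    """
    h = hierarchy if hierarchy is not None else load_hierarchy()
    items = h.item_ids()
    rng = _rng(spec.seed, "cohort")
    f = spec.n_facilities

    q = rng.beta(spec.quality_alpha, spec.quality_beta, size=f)
    u = q[:, None] + rng.normal(0.0, spec.response_noise, size=(f, len(items)))
    level_idx = np.searchsorted(np.asarray(spec.cutpoints), u)
    n_public = int(round(spec.public_fraction * f))

    assessments = []
    for i in range(f):
        responses = dict(zip(items, _LEVELS[level_idx[i]]))
        assessments.append(FacilityAssessment(
            facility_id=f"facility{i+1:02d}",
            responses=responses,
            ownership="public" if i < n_public else "private",
        ))

    volumes = rng.integers(spec.prescriptions_range[0],
                           spec.prescriptions_range[1] + 1, size=f)
    eta = rng.normal(0.0, spec.frailty_sd, size=f)
    counts = {ind: rng.binomial(volumes, _error_prob(spec, q, eta, ind))
              for ind in INDICATORS}
    records = [
        ADERecord(
            facility_id=f"facility{i+1:02d}",
            dispensing_errors=int(counts["dispensing"][i]),
            prescribing_errors=int(counts["prescribing"][i]),
            medication_errors=int(counts["medication"][i]),
            total_prescriptions=int(volumes[i]),
        )
        for i in range(f)
    ]
    return assessments, records, q


# ---------------------------------------------------------------------
# Generator expectations (closed-form up to quadrature)
# ---------------------------------------------------------------------

def expected_score_pct(spec: CohortSpec, q: float | np.ndarray) -> np.ndarray:
    """Expected mean-percent score of a facility with quality ``q``.

    Marginalises the item noise analytically: the probability of each
    level is the normal mass between consecutive cutpoints around ``q``.
    Strictly increasing in ``q``.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    edges = np.concatenate([[-np.inf], np.asarray(spec.cutpoints), [np.inf]])
    z = (edges[None, :] - q[:, None]) / spec.response_noise
    cdf = sps.norm.cdf(z)
    level_prob = np.diff(cdf, axis=1)
    return (level_prob @ _POINTS) / 4.0 * 100.0


def expected_incidence(spec: CohortSpec, indicator: str = "overall",
                       n_quad: int = 400) -> float:
    """Population mean facility incidence (percent) under the generator.

    Integrates the clipped error-probability surface over the Beta
    quality law (quantile midpoints) and the Gaussian frailty
    (Gauss-Hermite nodes); binomial sampling adds no bias.  This is the
    ground truth against which confidence-interval coverage is judged.
    """
    inds = INDICATORS if indicator == "overall" else (indicator,)
    probs = (np.arange(n_quad) + 0.5) / n_quad
    q = sps.beta.ppf(probs, spec.quality_alpha, spec.quality_beta)
    nodes, weights = hermegauss(64)           # weights for exp(-x^2/2)
    eta = nodes * spec.frailty_sd
    wts = weights / weights.sum()
    total = 0.0
    for ind in inds:
        p = _error_prob(spec, q[:, None], eta[None, :], ind)
        total += float((p @ wts).mean())
    return 100.0 * total
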