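"""CSV/JSON/YAML readers and writers for every pipeline artifact.

Conventions: UTF-8, header-rowed CSV throughout; duplicate keys are
rejected loudly; percentages are serialised as plain numbers in columns
suffixed ``_pct``; nested structures (hierarchy, summaries, manifests)
go to JSON; simulation specs are YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ahp import PairwiseMatrix
from .delphi import (
    ConcordanceResult,
    ItemStats,
    RatingMatrix,
    ScreeningResult,
    ScreeningThresholds,
)
from .errors import SchemaError
from .scoring import FacilityAssessment, ScoreReport
from .validation import ADERecord, CorrelationResult, IncidenceSummary

__all__ = [
    "load_ratings_csv", "write_ratings_csv",
    "write_round_report",
    "load_matrices_csv", "write_matrices_csv",
    "load_responses_csv", "write_responses_csv",
    "load_ade_csv", "write_ade_csv",
    "write_score_reports", "write_validation_json",
    "write_manifest",
]


def _read_csv(path: str | Path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


# -- Delphi ratings ----------------------------------------------------

def load_ratings_csv(path: str | Path, round_id: str = "round",
                     dimension: str = "applicability") -> RatingMatrix:
    """Read long-format ratings (``expert_id,item_id,rating``) into a
    complete experts x items grid; duplicates or missing cells raise."""
    df = _read_csv(path, {"expert_id", "item_id", "rating"})
    dup = df.duplicated(subset=["expert_id", "item_id"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (expert_id, item_id) rows: "
                          f"{df[dup].head().to_dict('records')}")
    wide = df.pivot(index="expert_id", columns="item_id", values="rating")
    if wide.isna().any().any():
        holes = wide.isna().stack()
        missing = list(holes[holes].index[:5])
        raise SchemaError(f"{path}: missing ratings for {missing}")
    return RatingMatrix(
        ratings=wide.to_numpy(dtype=float),
        item_ids=tuple(map(str, wide.columns)),
        expert_ids=tuple(map(str, wide.index)),
        round_id=round_id,
        dimension=dimension,
    )


def write_ratings_csv(rm: RatingMatrix, path: str | Path) -> None:
    rows = [
        {"expert_id": e, "item_id": i, "rating": int(rm.ratings[ei, ii])}
        for ei, e in enumerate(rm.expert_ids)
        for ii, i in enumerate(rm.item_ids)
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def write_round_report(
    out_dir: str | Path,
    stats: Sequence[ItemStats],
    thresholds: ScreeningThresholds,
    results: Sequence[ScreeningResult],
    concordance: ConcordanceResult | None = None,
    prefix: str = "round",
) -> dict[str, Path]:
    """Per-item screening CSV plus a JSON round summary.

    CV and full-score frequency are reported both as stored fractions
    and as display percents.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = {r.item_id: r for r in results}
    rows = []
    for s in stats:
        r = by_id[s.item_id]
        rows.append({
            "item_id": s.item_id,
            "mean_score": s.mean_score,
            "sd_score": s.sd_score,
            "cv": s.cv,
            "cv_pct": s.cv * 100.0,
            "full_score_freq": s.full_score_freq,
            "full_score_freq_pct": s.full_score_freq * 100.0,
            "low_full_score": "low_full_score" in r.criteria_met,
            "low_mean": "low_mean" in r.criteria_met,
            "high_cv": "high_cv" in r.criteria_met,
            "excluded": r.excluded,
        })
    items_path = out / f"{prefix}_items.csv"
    pd.DataFrame(rows).to_csv(items_path, index=False, encoding="utf-8")

    summary = {
        "n_items": len(stats),
        "n_excluded": sum(r.excluded for r in results),
        "mean_of_mean_scores": float(np.mean([s.mean_score for s in stats])),
        "mean_cv_pct": float(np.mean([s.cv for s in stats])) * 100.0,
        "mean_full_score_freq_pct": float(np.mean([s.full_score_freq for s in stats])) * 100.0,
        "thresholds": dataclasses.asdict(thresholds),
    }
    if concordance is not None:
        summary["kendalls_w"] = dataclasses.asdict(concordance)
    summary_path = out / f"{prefix}_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2), encoding="utf-8")
    return {"items": items_path, "summary": summary_path}


# -- AHP matrices ------------------------------------------------------

def load_matrices_csv(path: str | Path) -> dict[str, dict[str, PairwiseMatrix]]:
    """Read long-format comparisons (``node_id,expert_id,row,col,value``).

    Rows need only cover the upper triangle (and may include the rest);
    the diagonal defaults to 1 and missing lower-triangle cells are
    filled reciprocally.  Conflicting duplicates raise.  Returns
    ``{node_id: {expert_id: PairwiseMatrix}}`` with labels in first-seen
    row order.
    """
    df = _read_csv(path, {"node_id", "expert_id", "row", "col", "value"})
    df["value"] = df["value"].astype(float)
    out: dict[str, dict[str, PairwiseMatrix]] = {}
    for (node, expert), g in df.groupby(["node_id", "expert_id"], sort=False):
        labels = list(dict.fromkeys(list(g["row"]) + list(g["col"])))
        idx = {lab: k for k, lab in enumerate(labels)}
        n = len(labels)
        a = np.full((n, n), np.nan)
        np.fill_diagonal(a, 1.0)
        for _, rec in g.iterrows():
            i, j, v = idx[rec["row"]], idx[rec["col"]], float(rec["value"])
            if not np.isnan(a[i, j]) and abs(a[i, j] - v) > 1e-9 and i != j:
                raise SchemaError(
                    f"{path}: conflicting duplicate at node {node}, expert {expert}, "
                    f"({rec['row']}, {rec['col']})")
            a[i, j] = v
        # fill missing cells from their reciprocals
        nan = np.isnan(a)
        a[nan] = 1.0 / a.T[nan]
        if np.isnan(a).any():
            raise SchemaError(f"{path}: incomplete matrix at node {node}, expert {expert}")
        out.setdefault(str(node), {})[str(expert)] = PairwiseMatrix(
            node_id=str(node), entries=a, labels=tuple(labels))
    return out


def write_matrices_csv(matrices: dict[str, dict[str, PairwiseMatrix]],
                       path: str | Path) -> None:
    rows = []
    for node, by_expert in matrices.items():
        for expert, m in by_expert.items():
            for i, ri in enumerate(m.labels):
                for j, cj in enumerate(m.labels):
                    if j > i:
                        rows.append({"node_id": node, "expert_id": expert,
                                     "row": ri, "col": cj,
                                     "value": m.entries[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


# -- facility responses ------------------------------------------------

def load_responses_csv(path: str | Path) -> list[FacilityAssessment]:
    """Read ``facility_id,item_id,level`` (levels case-insensitive)."""
    df = _read_csv(path, {"facility_id", "item_id", "level"})
    dup = df.duplicated(subset=["facility_id", "item_id"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (facility_id, item_id) rows")
    return [
        FacilityAssessment(facility_id=str(fid),
                           responses=dict(zip(g["item_id"], g["level"])))
        for fid, g in df.groupby("facility_id", sort=True)
    ]


def write_responses_csv(assessments: Sequence[FacilityAssessment],
                        path: str | Path) -> None:
    rows = [
        {"facility_id": a.facility_id, "item_id": item, "level": level}
        for a in assessments
        for item, level in sorted(a.responses.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


# -- ADE records -------------------------------------------------------

_ADE_COLS = ["facility_id", "dispensing_errors", "prescribing_errors",
             "medication_errors", "total_prescriptions"]


def load_ade_csv(path: str | Path) -> list[ADERecord]:
    df = _read_csv(path, set(_ADE_COLS))
    if df["facility_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate facility_id rows")
    return [
        ADERecord(facility_id=str(r.facility_id),
                  dispensing_errors=int(r.dispensing_errors),
                  prescribing_errors=int(r.prescribing_errors),
                  medication_errors=int(r.medication_errors),
                  total_prescriptions=int(r.total_prescriptions))
        for r in df.itertuples()
    ]


def write_ade_csv(records: Sequence[ADERecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records])[_ADE_COLS].to_csv(
        path, index=False, encoding="utf-8")


# -- scoring & validation outputs --------------------------------------

def write_score_reports(reports: Sequence[ScoreReport], out_dir: str | Path,
                        cohort: pd.DataFrame | None = None) -> dict[str, Path]:
    """Per-facility JSON reports plus a one-row-per-facility cohort CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    facilities_dir = out / "facilities"
    facilities_dir.mkdir(exist_ok=True)
    rows = []
    for r in reports:
        payload = dataclasses.asdict(r)
        payload["missing_items"] = list(r.missing_items)
        (facilities_dir / f"{r.facility_id}.json").write_text(
            json.dumps(payload, indent=2), encoding="utf-8")
        row = {"facility_id": r.facility_id, "overall_pct": r.overall_pct,
               "weighted_overall_pct": r.weighted_overall_pct,
               "completeness": r.completeness}
        row.update({f"domain_{d}_pct": p for d, p in sorted(r.domain_pct.items())})
        rows.append(row)
    scores_path = out / "scores.csv"
    pd.DataFrame(rows).to_csv(scores_path, index=False, encoding="utf-8")
    paths = {"scores": scores_path, "facilities": facilities_dir}
    if cohort is not None:
        cohort_path = out / "cohort_summary.csv"
        cohort.to_csv(cohort_path, encoding="utf-8")
        paths["cohort"] = cohort_path
    return paths


def write_validation_json(
    incidence: dict[str, IncidenceSummary],
    correlation: CorrelationResult,
    scatter: pd.DataFrame,
    path: str | Path,
) -> None:
    payload = {
        "incidence": {k: dataclasses.asdict(v) for k, v in incidence.items()},
        "correlation": dataclasses.asdict(correlation),
        "scatter": scatter.reset_index().to_dict("records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


# -- reproducibility manifest ------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, inputs: dict[str, str | Path],
                   artifacts: dict[str, str | Path], seed: int | None = None,
                   extra: dict | None = None) -> Path:
    """Record inputs, produced artifacts (with SHA-256 checksums), seed
    and versions for a pipeline run."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "pmssa_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "artifacts": {
            k: {"path": str(p), "sha256": _sha256(Path(p))}
            for k, p in artifacts.items() if Path(p).is_file()
        },
    }
    if extra:
        manifest.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path
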