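"""From patch probabilities to slide risk scores and a cohort stratification.

The analysis of an OL slide proceeds in four steps:

1. argmax the four-class probabilities on the tiling grid (class heatmap);
2. collapse nondysplastic + tumor epithelium into one "epithelium" mask and
   keep only those cells;
3. score each epithelium patch by its *tumor-likeness* — the tumor
   probability renormalized over the two epithelium classes,
   p_tumor / (p_tumor + p_nondys), so residual connective/background
   probability mass does not dilute the score (the raw p_tumor variant is
   available via ``variant="raw"``);
4. the slide risk score is the median tumor-likeness over the slide's
   epithelium patches (mean-of-two-middle convention for even counts).

Patients are then ranked by slide score and split at the cohort median into
equal-sized low- and high-risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classifier import PatchPrediction
from .labels import CLASS_ORDER, EPITHELIUM_CLASSES


@dataclass
class ClassHeatmap:
    """Per-patch argmax class labels on the tiling grid."""

    slide_id: str
    grid: np.ndarray  # (rows, cols) int


@dataclass
class RiskHeatmap:
    """Per-patch tumor-likeness on epithelium cells; NaN elsewhere."""

    slide_id: str
    grid: np.ndarray  # (rows, cols) float, NaN = not epithelium


@dataclass
class SlideRiskScore:
    slide_id: str
    score: float
    n_epithelium_patches: int
    n_total_patches: int


@dataclass
class RiskStratification:
    groups: dict[str, str]  # patient_id -> "low" | "high"
    cohort_median_score: float


def build_class_heatmap(predictions: Sequence[PatchPrediction]) -> ClassHeatmap:
    """Arrange per-patch argmax classes on the grid.

    The predictions must cover a complete rows x cols grid exactly once;
    ties in the probability vector resolve to the lowest class index.
    """
    if not predictions:
        raise ValueError("no predictions supplied")
    slide_id = predictions[0].slide_id
    if any(p.slide_id != slide_id for p in predictions):
        raise ValueError("predictions mix multiple slides")
    rows = max(p.row for p in predictions) + 1
    cols = max(p.col for p in predictions) + 1
    seen = np.zeros((rows, cols), dtype=bool)
    grid = np.zeros((rows, cols), dtype=int)
    for p in predictions:
        if seen[p.row, p.col]:
            raise ValueError(f"duplicate prediction for cell ({p.row},{p.col})")
        seen[p.row, p.col] = True
        grid[p.row, p.col] = p.argmax
    if not seen.all():
        missing = np.argwhere(~seen)[0]
        raise ValueError(f"missing prediction for cell ({missing[0]},{missing[1]})")
    return ClassHeatmap(slide_id, grid)


def epithelium_mask(heatmap: ClassHeatmap) -> np.ndarray:
    """Boolean grid: True where the argmax class is either epithelium class."""
    return np.isin(heatmap.grid, EPITHELIUM_CLASSES)


def patch_tumor_likeness(pred: PatchPrediction, variant: str = "renormalized") -> float:
    """Tumor-likeness of one patch in [0, 1].

    ``renormalized`` (default): p_tumor / (p_tumor + p_nondys).
    ``raw``: p_tumor as emitted by the four-class model.
    """
    from .labels import NONDYS_EPI, TUMOR_EPI

    p_nondys, p_tumor = float(pred.probs[NONDYS_EPI]), float(pred.probs[TUMOR_EPI])
    if variant == "raw":
        return p_tumor
    if variant != "renormalized":
        raise ValueError(f"unknown tumor-likeness variant {variant!r}")
    denom = p_tumor + p_nondys
    if denom <= 0:
        raise ValueError(
            f"patch ({pred.row},{pred.col}) of slide {pred.slide_id} has zero "
            "epithelium probability mass; mask to epithelium cells first"
        )
    return p_tumor / denom


def build_risk_heatmap(
    predictions: Sequence[PatchPrediction], variant: str = "renormalized"
) -> RiskHeatmap:
    """Tumor-likeness on epithelium cells of the grid, NaN elsewhere."""
    heat = build_class_heatmap(predictions)
    mask = epithelium_mask(heat)
    grid = np.full(heat.grid.shape, np.nan)
    for p in predictions:
        if mask[p.row, p.col]:
            grid[p.row, p.col] = patch_tumor_likeness(p, variant)
    return RiskHeatmap(heat.slide_id, grid)


def slide_risk_score(
    predictions: Sequence[PatchPrediction], variant: str = "renormalized"
) -> SlideRiskScore:
    """Median tumor-likeness over the slide's epithelium patches.

    Epithelium patches are the grid cells whose argmax class is either
    epithelium class; the median uses the mean-of-two-middle convention for
    even counts.  Raises if the slide has no epithelium cells.
    """
    heat = build_class_heatmap(predictions)
    mask = epithelium_mask(heat)
    values = [
        patch_tumor_likeness(p, variant)
        for p in predictions
        if mask[p.row, p.col]
    ]
    if not values:
        raise ValueError(f"no epithelium detected on slide {heat.slide_id}")
    return SlideRiskScore(
        slide_id=heat.slide_id,
        score=float(np.median(values)),
        n_epithelium_patches=len(values),
        n_total_patches=len(predictions),
    )


def stratify_cohort(scores: Mapping[str, float]) -> RiskStratification:
    """Median split of the cohort into equal-sized low/high risk groups.

    Patients are ranked by score with ties broken by patient id (so the
    split is reproducible); the lower half is "low", the upper half "high".
    For odd cohorts the middle-ranked patient joins the low group, so
    |low| - |high| is 0 or 1.  The cohort median score is reported alongside.
    """
    if len(scores) < 2:
        raise ValueError("at least 2 patients are required for a median split")
    ranked = sorted(scores, key=lambda pid: (scores[pid], pid))
    n_low = (len(ranked) + 1) // 2
    groups = {pid: ("low" if i < n_low else "high") for i, pid in enumerate(ranked)}
    return RiskStratification(
        groups=groups,
        cohort_median_score=float(np.median(list(scores.values()))),
    )
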