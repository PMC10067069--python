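"""Readers and writers for the pipeline's on-disk formats.

Rasters are 8-bit PNGs (RGB slides, single-channel label masks), tables are
CSV with documented headers, configs and results are JSON.  Heatmaps export
one pixel per 300x300 patch using the standard palette (yellow tumor
epithelium, green nondysplastic epithelium, blue connective, purple
background).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .classifier import PatchPrediction
from .labels import PALETTE, PALETTE_ABSENT
from .slide_analysis import ClassHeatmap, SlideRiskScore
from .synthetic import AnnotatedSlide
from .tiling import DroppedPatch, LabeledPatch

PREDICTION_COLUMNS = [
    "slide_id", "row", "col",
    "p_background", "p_connective", "p_nondys", "p_tumor",
]


def save_slide(slide: AnnotatedSlide, slides_dir: Path, masks_dir: Path) -> None:
    slides_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)
    Image.fromarray(slide.image, mode="RGB").save(slides_dir / f"{slide.slide_id}.png")
    Image.fromarray(slide.mask, mode="L").save(masks_dir / f"{slide.slide_id}.png")


def load_slide(slide_id: str, slides_dir: Path, masks_dir: Path | None = None,
               true_theta: float | None = None) -> AnnotatedSlide:
    image = np.asarray(Image.open(slides_dir / f"{slide_id}.png").convert("RGB"))
    if masks_dir is not None and (masks_dir / f"{slide_id}.png").exists():
        mask = np.asarray(Image.open(masks_dir / f"{slide_id}.png"))
    else:
        mask = np.zeros(image.shape[:2], dtype=np.uint8)
    return AnnotatedSlide(slide_id, image, mask, true_theta=true_theta)


def write_patch_manifest(
    labeled: Iterable[LabeledPatch],
    dropped: Iterable[DroppedPatch],
    assignment: Mapping[str, str],
    path: Path,
) -> pd.DataFrame:
    """Manifest CSV: slide_id, row, col, y, x, label, purity, split, status."""
    rows = []
    for lp in labeled:
        rows.append(
            {
                "slide_id": lp.patch.slide_id,
                "row": lp.patch.row,
                "col": lp.patch.col,
                "y": lp.patch.pixel_origin[0],
                "x": lp.patch.pixel_origin[1],
                "label": lp.label,
                "purity": lp.purity,
                "split": assignment.get(lp.patch.slide_id, ""),
                "status": "kept",
            }
        )
    for dp in dropped:
        rows.append(
            {
                "slide_id": dp.slide_id, "row": dp.row, "col": dp.col,
                "y": None, "x": None, "label": None, "purity": None,
                "split": assignment.get(dp.slide_id, ""), "status": dp.reason,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def write_predictions(preds: Sequence[PatchPrediction], path: Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "slide_id": p.slide_id, "row": p.row, "col": p.col,
                "p_background": p.probs[0], "p_connective": p.probs[1],
                "p_nondys": p.probs[2], "p_tumor": p.probs[3],
            }
            for p in preds
        ],
        columns=PREDICTION_COLUMNS,
    )
    df.to_csv(path, index=False)
    return df


def read_predictions(path: Path) -> list[PatchPrediction]:
    df = pd.read_csv(path)
    return [
        PatchPrediction(
            r.slide_id, int(r.row), int(r.col),
            np.array([r.p_background, r.p_connective, r.p_nondys, r.p_tumor]),
        )
        for r in df.itertuples()
    ]


def write_scores(scores: Sequence[SlideRiskScore], path: Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "slide_id": s.slide_id, "score": s.score,
                "n_epithelium": s.n_epithelium_patches,
                "n_total": s.n_total_patches,
            }
            for s in scores
        ]
    )
    df.to_csv(path, index=False)
    return df


def render_class_heatmap(heatmap: ClassHeatmap, path: Path | None = None) -> np.ndarray:
    """One RGB pixel per patch using the standard palette; optionally saved."""
    rows, cols = heatmap.grid.shape
    img = np.zeros((rows, cols, 3), dtype=np.uint8)
    img[:] = PALETTE_ABSENT
    for label, color in PALETTE.items():
        img[heatmap.grid == label] = color
    if path is not None:
        Image.fromarray(img, mode="RGB").save(path)
    return img


def write_json(obj: object, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o: object):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)!r}")


def sha256_of(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
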