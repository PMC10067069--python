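"""Non-overlapping 300x300 patch extraction, mask labelling and slide-grouped splits.

The tiling grid is anchored at pixel (0, 0) with 0-based row-major indices;
right/bottom remainders smaller than the window are discarded so that every
patch is exactly window x window — the classifier's input contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .labels import ARTIFACT_EXCLUDE, CLASS_ORDER
from .synthetic import WINDOW, AnnotatedSlide


@dataclass
class Patch:
    """One window of a slide on the regular grid."""

    slide_id: str
    row: int
    col: int
    pixel_origin: tuple[int, int]  # (y, x) of the top-left pixel
    pixels: np.ndarray  # (window, window, 3) uint8


@dataclass
class LabeledPatch:
    patch: Patch
    label: int
    purity: float  # fraction of non-excluded pixels carrying the label


@dataclass
class DroppedPatch:
    slide_id: str
    row: int
    col: int
    reason: str  # "artifact" (>50% excluded) or "low_purity"


def tile_slide(slide: AnnotatedSlide, window: int = WINDOW) -> list[Patch]:
    """Extract all full non-overlapping windows on the (0,0)-anchored grid.

    Returns exactly floor(H/window) * floor(W/window) patches in row-major
    order; partial edge windows are dropped.
    """
    h, w = slide.shape
    if h < window or w < window:
        raise ValueError(
            f"slide {slide.slide_id} is {h}x{w}, smaller than the "
            f"{window}px window in at least one axis"
        )
    patches = []
    for r in range(h // window):
        for c in range(w // window):
            y, x = r * window, c * window
            patches.append(
                Patch(
                    slide.slide_id, r, c, (y, x),
                    slide.image[y : y + window, x : x + window],
                )
            )
    return patches


def label_patches(
    patches: Iterable[Patch],
    mask: np.ndarray,
    purity_threshold: float = 0.9,
    window: int = WINDOW,
) -> tuple[list[LabeledPatch], list[DroppedPatch]]:
    """Assign each patch its majority mask class, honouring artifact exclusion.

    Pixels labelled ``ARTIFACT_EXCLUDE`` are removed from consideration; a
    patch with more than 50% excluded pixels is dropped (reason
    ``"artifact"``).  Otherwise the patch's label is the majority class of
    the remaining pixels and its purity is that class's fraction; patches
    with purity below ``purity_threshold`` are dropped (``"low_purity"``).
    """
    if not 0.5 <= purity_threshold <= 1.0:
        raise ValueError("purity_threshold must lie in [0.5, 1]")
    kept: list[LabeledPatch] = []
    dropped: list[DroppedPatch] = []
    for p in patches:
        y, x = p.pixel_origin
        if y + window > mask.shape[0] or x + window > mask.shape[1]:
            raise ValueError(
                f"mask shape {mask.shape} does not cover patch "
                f"({p.row},{p.col}) of slide {p.slide_id}"
            )
        tile = mask[y : y + window, x : x + window]
        excluded = tile == ARTIFACT_EXCLUDE
        n_total = tile.size
        n_kept = n_total - int(excluded.sum())
        if n_kept < n_total / 2:
            dropped.append(DroppedPatch(p.slide_id, p.row, p.col, "artifact"))
            continue
        counts = np.bincount(tile[~excluded].ravel(), minlength=4)[: len(CLASS_ORDER)]
        label = int(np.argmax(counts))  # ties: lowest class index
        purity = counts[label] / n_kept
        if purity < purity_threshold:
            dropped.append(DroppedPatch(p.slide_id, p.row, p.col, "low_purity"))
            continue
        kept.append(LabeledPatch(p, label, float(purity)))
    return kept, dropped


SPLITS = ("train", "validation", "test")


def split_slides(
    slide_ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> dict[str, str]:
    """Partition slides into train/validation/test, grouped by slide.

    Slides are shuffled deterministically by ``seed`` and partitioned as
    close to ``fractions`` as integer counts allow (largest-remainder
    apportionment; every split with a positive fraction receives at least
    one slide).  Patches inherit their slide's split, so no slide's patches
    ever straddle two sets.
    """
    if len(set(slide_ids)) != len(slide_ids):
        raise ValueError("slide_ids contains duplicates")
    if any(f < 0 for f in fractions) or not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must be non-negative and sum to 1")
    n = len(slide_ids)
    n_nonzero = sum(f > 0 for f in fractions)
    if n < n_nonzero:
        raise ValueError(f"{n} slides cannot fill {n_nonzero} non-empty splits")
    # largest-remainder apportionment, guaranteeing >=1 per non-zero split
    exact = np.array(fractions) * n
    counts = np.floor(exact).astype(int)
    counts = np.maximum(counts, (np.array(fractions) > 0).astype(int))
    while counts.sum() > n:  # floors + minimums overshot: trim largest count
        counts[int(np.argmax(counts))] -= 1
    remainders = exact - np.floor(exact)
    while counts.sum() < n:
        order = np.argsort(-remainders)  # stable: split order breaks ties
        i = int(order[0])
        counts[i] += 1
        remainders[i] = -1
    rng = np.random.default_rng(seed)
    shuffled = [slide_ids[i] for i in rng.permutation(n)]
    assignment: dict[str, str] = {}
    start = 0
    for split, k in zip(SPLITS, counts):
        for sid in shuffled[start : start + k]:
            assignment[sid] = split
        start += k
    return assignment


def split_of_patches(
    labeled: Iterable[LabeledPatch], assignment: Mapping[str, str]
) -> dict[str, list[LabeledPatch]]:
    """Group labelled patches by their slide's split."""
    out: dict[str, list[LabeledPatch]] = {s: [] for s in SPLITS}
    for lp in labeled:
        out[assignment[lp.patch.slide_id]].append(lp)
    return out
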