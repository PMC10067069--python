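"""Synthetic slides and cohorts with known ground truth.

Real inputs to this kind of analysis are 40x H&E whole-slide scans of oral
mucosa biopsies plus clinical follow-up charts.  This module emulates the
parts of that data the downstream pipeline actually consumes:

* four texture-distinguishable tissue classes (white background, connective
  tissue, nondysplastic epithelium, tumor epithelium), rendered as Gaussian
  color noise around class-specific means plus Poisson-placed dark circular
  "nuclei".  Tumor epithelium is darker and hypercellular (higher nuclear
  density), mimicking the basophilia and crowding a pathologist keys on;
* leukoplakia-like (OL) slides whose epithelium is a per-tile Bernoulli
  mixture of tumor-like and nondysplastic-like texture with known mixing
  fraction theta;
* a cohort whose time-to-progression follows a proportional-hazards model in
  theta, with administrative censoring — so hazard-ratio and survival
  estimators can be checked against a known truth.

All three generators are bit-deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .labels import (
    ARTIFACT_EXCLUDE,
    BACKGROUND,
    CLASS_NAMES,
    CONNECTIVE,
    EPITHELIUM_CLASSES,
    NONDYS_EPI,
    TUMOR_EPI,
)

WINDOW = 300  # patch side in pixels; the unit of tiling and tile-level mixing


# --------------------------------------------------------------------------
# textures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TextureParams:
    """Rendering parameters for one tissue class.

    ``spot_density`` is the expected number of dark nuclear spots per
    300x300 tile; spots are placed by a Poisson draw per tile, so nuclear
    density varies tile to tile the way cellularity varies across a section.
    """

    class_id: int
    mean_rgb: tuple[float, float, float]
    noise_sd: float = 0.0
    spot_density: float = 0.0
    spot_radius_px: int = 3
    spot_rgb: tuple[float, float, float] = (60.0, 35.0, 95.0)
    #: SD of a per-tile constant RGB offset emulating regional stain-intensity
    #: variation across a section; gives patch-level features a realistic
    #: within-class spread.
    tile_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not all(0.0 <= v <= 255.0 for v in self.mean_rgb):
            raise ValueError("mean_rgb values must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spot_density < 0:
            raise ValueError("spot_density must be >= 0")
        if self.spot_radius_px < 1:
            raise ValueError("spot_radius_px must be >= 1")


def default_textures() -> dict[int, TextureParams]:
    """Default class textures: separable but noisy, loosely H&E-like.

    Background is near-white and acellular; connective tissue is pale
    eosinophilic with sparse fibroblast nuclei; nondysplastic epithelium is
    pink-purple with moderate nuclear density; tumor epithelium is darker
    (basophilic) and hypercellular.
    """
    return {
        BACKGROUND: TextureParams(
            BACKGROUND, (242.0, 242.0, 240.0), noise_sd=4.0, tile_jitter_sd=1.0
        ),
        CONNECTIVE: TextureParams(
            CONNECTIVE, (228.0, 165.0, 195.0), noise_sd=10.0,
            spot_density=6.0, spot_radius_px=2, tile_jitter_sd=5.0,
        ),
        NONDYS_EPI: TextureParams(
            NONDYS_EPI, (200.0, 120.0, 170.0), noise_sd=10.0,
            spot_density=35.0, spot_radius_px=3, tile_jitter_sd=7.0,
        ),
        TUMOR_EPI: TextureParams(
            TUMOR_EPI, (150.0, 90.0, 160.0), noise_sd=12.0,
            spot_density=80.0, spot_radius_px=3, tile_jitter_sd=7.0,
        ),
        ARTIFACT_EXCLUDE: TextureParams(
            ARTIFACT_EXCLUDE, (120.0, 120.0, 120.0), noise_sd=20.0,
        ),
    }


# --------------------------------------------------------------------------
# layouts and slides
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangle of one class, painted onto the mask in order."""

    label: int
    top: int
    left: int
    height: int
    width: int


@dataclass(frozen=True)
class SlideLayout:
    height: int
    width: int
    regions: tuple[Region, ...]

    def paint(self) -> np.ndarray:
        """Rasterize regions to a label mask; every pixel must be covered."""
        if self.height < WINDOW or self.width < WINDOW:
            raise ValueError(
                f"layout {self.height}x{self.width} smaller than the "
                f"{WINDOW}px window: no full patch fits"
            )
        mask = np.full((self.height, self.width), -1, dtype=np.int16)
        for r in self.regions:
            if r.label not in CLASS_NAMES:
                raise ValueError(f"unknown label {r.label}")
            mask[r.top : r.top + r.height, r.left : r.left + r.width] = r.label
        if (mask < 0).any():
            raise ValueError("layout does not cover the slide raster")
        return mask.astype(np.uint8)


def band_layout(row_labels: Sequence[int], n_cols: int, window: int = WINDOW) -> SlideLayout:
    """Layout of horizontal bands, one tile-row per label, ``n_cols`` tiles wide."""
    regions = tuple(
        Region(lab, i * window, 0, window, n_cols * window)
        for i, lab in enumerate(row_labels)
    )
    return SlideLayout(len(row_labels) * window, n_cols * window, regions)


def default_training_layout(n_cols: int = 3) -> SlideLayout:
    """One band per class: the synthetic analog of an annotated biopsy."""
    return band_layout([BACKGROUND, CONNECTIVE, NONDYS_EPI, TUMOR_EPI], n_cols)


def default_ol_layout(epi_rows: int = 2, n_cols: int = 3) -> SlideLayout:
    """OL-like slide: a background band, ``epi_rows`` epithelium tile-rows,
    and a connective band.  Epithelium rows are re-textured per tile by
    :func:`generate_ol_slide`."""
    rows = [BACKGROUND] + [NONDYS_EPI] * epi_rows + [CONNECTIVE]
    return band_layout(rows, n_cols)


@dataclass
class AnnotatedSlide:
    """An RGB raster plus its ground-truth integer class mask."""

    slide_id: str
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8
    true_theta: float | None = None  # OL slides only

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _render(mask: np.ndarray, textures: dict[int, TextureParams], rng: np.random.Generator) -> np.ndarray:
    """Render an RGB image from a label mask under the texture model."""
    h, w = mask.shape
    labels = np.unique(mask)
    missing = [int(l) for l in labels if int(l) not in textures]
    if missing:
        raise ValueError(f"no texture for labels {missing}")
    # LUT gather per pixel: class mean then scaled Gaussian color noise
    lut_mean = np.zeros((256, 3), dtype=np.float32)
    lut_sd = np.zeros(256, dtype=np.float32)
    for lab in labels:
        t = textures[int(lab)]
        lut_mean[lab] = t.mean_rgb
        lut_sd[lab] = t.noise_sd
    img = lut_mean[mask]
    if any(textures[int(l)].noise_sd > 0 for l in labels):
        noise = rng.standard_normal((h, w, 3), dtype=np.float32)
        noise *= lut_sd[mask][..., None]
        img += noise
    # per-tile work: stain jitter and Poisson-placed nuclear spots
    disk_cache: dict[int, np.ndarray] = {}
    for ty in range(0, h, WINDOW):
        for tx in range(0, w, WINDOW):
            th, tw = min(WINDOW, h - ty), min(WINDOW, w - tx)
            tile_mask = mask[ty : ty + th, tx : tx + tw]
            tile_img = img[ty : ty + th, tx : tx + tw]
            lab0 = tile_mask[0, 0]
            uniform = bool((tile_mask == lab0).all())
            tile_labels = (lab0,) if uniform else tuple(np.unique(tile_mask))
            for lab in tile_labels:
                t = textures[int(lab)]
                if t.tile_jitter_sd > 0:
                    offset = rng.normal(0.0, t.tile_jitter_sd, 3).astype(np.float32)
                    if uniform:
                        tile_img += offset
                    else:
                        tile_img[tile_mask == lab] += offset
                if t.spot_density <= 0:
                    continue
                lam = t.spot_density * (th * tw) / (WINDOW * WINDOW)
                n_spots = rng.poisson(lam)
                if n_spots == 0:
                    continue
                cy = rng.integers(0, th, n_spots) + ty
                cx = rng.integers(0, tw, n_spots) + tx
                r = t.spot_radius_px
                if r not in disk_cache:
                    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
                    disk_cache[r] = (yy * yy + xx * xx) <= r * r
                disk = disk_cache[r]
                spot = np.asarray(t.spot_rgb, dtype=np.float32)
                for y0, x0 in zip(cy, cx):
                    ys, ye = max(0, y0 - r), min(h, y0 + r + 1)
                    xs, xe = max(0, x0 - r), min(w, x0 + r + 1)
                    sub = disk[ys - (y0 - r) : ye - (y0 - r), xs - (x0 - r) : xe - (x0 - r)]
                    put = sub & (mask[ys:ye, xs:xe] == lab)
                    img[ys:ye, xs:xe][put] = spot
    np.rint(img, out=img)
    np.clip(img, 0, 255, out=img)
    return img.astype(np.uint8)


def generate_training_slide(
    layout: SlideLayout,
    textures: dict[int, TextureParams] | None = None,
    seed: int = 0,
    slide_id: str = "train_slide",
) -> AnnotatedSlide:
    """Render an annotated training slide from a region layout.

    Every pixel's color is drawn from its mask class's texture distribution;
    the painted layout is returned as the ground-truth mask.  Deterministic
    given ``seed``.
    """
    textures = textures if textures is not None else default_textures()
    mask = layout.paint()
    rng = np.random.default_rng(seed)
    return AnnotatedSlide(slide_id, _render(mask, textures, rng), mask)


def generate_ol_slide(
    theta: float,
    layout: SlideLayout | None = None,
    textures: dict[int, TextureParams] | None = None,
    seed: int = 0,
    slide_id: str = "ol_slide",
) -> AnnotatedSlide:
    """Render an OL-like slide whose epithelium tiles are a theta-mixture.

    The layout's epithelium region is partitioned into 300x300 tiles (it
    must be aligned to the tiling grid); each tile independently receives
    the tumor-epithelium texture with probability ``theta``, otherwise the
    nondysplastic texture.  The realized per-tile assignment is recorded in
    the returned mask; ``true_theta`` carries the mixing fraction.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    layout = layout if layout is not None else default_ol_layout()
    textures = textures if textures is not None else default_textures()
    mask = layout.paint()
    h, w = mask.shape
    rng = np.random.default_rng(seed)
    # epithelium tiles in row-major order get independent Bernoulli(theta) draws
    for ty in range(0, h - WINDOW + 1, WINDOW):
        for tx in range(0, w - WINDOW + 1, WINDOW):
            tile = mask[ty : ty + WINDOW, tx : tx + WINDOW]
            if np.isin(tile, EPITHELIUM_CLASSES).all():
                tile[:] = TUMOR_EPI if rng.random() < theta else NONDYS_EPI
    return AnnotatedSlide(slide_id, _render(mask, textures, rng), mask, true_theta=float(theta))


def realized_tumor_fraction(slide: AnnotatedSlide, window: int = WINDOW) -> float:
    """Fraction of full epithelium tiles carrying the tumor texture."""
    h, w = slide.shape
    n_epi = n_tum = 0
    for ty in range(0, h - window + 1, window):
        for tx in range(0, w - window + 1, window):
            tile = slide.mask[ty : ty + window, tx : tx + window]
            if np.isin(tile, EPITHELIUM_CLASSES).all():
                n_epi += 1
                n_tum += int((tile == TUMOR_EPI).all())
    if n_epi == 0:
        raise ValueError(f"slide {slide.slide_id} has no epithelium tiles")
    return n_tum / n_epi


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generating model for a synthetic OL cohort.

    Per patient i, a tumor-like epithelium fraction theta_i ~
    Beta(theta_alpha, theta_beta) drives an exponential progression hazard
    h0 * exp(beta * theta_i); follow-up is administratively censored at
    ``admin_censor_time`` years.  Defaults emulate the scale of a
    single-institution OL cohort: n = 62 patients, roughly 40% of whom
    progress within the follow-up horizon.
    """

    n_patients: int = 62
    theta_alpha: float = 0.8
    theta_beta: float = 0.8
    baseline_hazard: float = 0.03  # per year
    log_hazard_coeff: float = math.log(3.0)
    admin_censor_time: float = 10.0  # years
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2 (median split downstream)")
        if self.theta_alpha <= 0 or self.theta_beta <= 0:
            raise ValueError("Beta shape parameters must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0")


#: Marginal covariate frequencies used for the synthetic cohort, chosen to
#: match a typical leukoplakia case mix (≈48% female, ≈69% tongue lesions,
#: ≈29% prior oral cancer, ≈28% AVEH, ≈52% moderate/severe dysplasia; age
#: ≈ 56 ± 12 years).  Covariates are drawn independently of theta so that
#: multivariate hazard-model recovery has a known truth.
COVARIATE_FREQS = {
    "female": 0.48,
    "tongue": 0.69,
    "prior_oscc": 0.29,
    "aveh_present": 0.28,
    "dysplasia_high": 0.52,
}

COHORT_COLUMNS = [
    "patient_id", "slide_id", "true_theta", "ttp_years", "event",
    "age", "gender", "site", "dysplasia", "prior_oscc", "aveh",
]


def generate_cohort_records(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Draw the tabular cohort (no images): theta, survival outcome, covariates.

    Latent progression times are exponential via inverse-CDF,
    T_i = -log(U_i) / (h0 * exp(beta * theta_i)); the recorded
    time-to-progression is min(T_i, admin_censor_time) with event = 1 iff
    the latent time falls inside the horizon.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    theta = rng.beta(spec.theta_alpha, spec.theta_beta, n)
    rate = spec.baseline_hazard * np.exp(spec.log_hazard_coeff * theta)
    latent = -np.log(rng.random(n)) / rate
    event = (latent <= spec.admin_censor_time).astype(int)
    ttp = np.minimum(latent, spec.admin_censor_time)
    age = np.clip(rng.normal(55.9, 12.0, n), 25.0, 90.0)
    draws = {k: rng.random(n) < p for k, p in COVARIATE_FREQS.items()}
    width = len(str(n - 1))
    return pd.DataFrame(
        {
            "patient_id": [f"pt{i:0{width}d}" for i in range(n)],
            "slide_id": [f"ol{i:0{width}d}" for i in range(n)],
            "true_theta": theta,
            "ttp_years": ttp,
            "event": event,
            "age": np.round(age, 1),
            "gender": np.where(draws["female"], "F", "M"),
            "site": np.where(draws["tongue"], "tongue", "other"),
            "dysplasia": np.where(
                draws["dysplasia_high"], "moderate/severe", "none/mild"
            ),
            "prior_oscc": np.where(draws["prior_oscc"], "yes", "no"),
            "aveh": np.where(draws["aveh_present"], "present", "absent"),
        },
        columns=COHORT_COLUMNS,
    )


def generate_cohort(
    spec: SyntheticCohortSpec,
    layout: SlideLayout | None = None,
    textures: dict[int, TextureParams] | None = None,
) -> list[tuple[AnnotatedSlide, pd.Series]]:
    """Generate a full synthetic cohort: one OL slide per patient record.

    Each patient's slide is an OL mixture slide at their true theta; slide
    seeds derive from the cohort seed, so the whole cohort is reproducible.
    """
    records = generate_cohort_records(spec)
    slide_rng = np.random.default_rng(spec.seed + 1)
    slide_seeds = slide_rng.integers(0, 2**31 - 1, len(records))
    out = []
    for (_, rec), s in zip(records.iterrows(), slide_seeds):
        slide = generate_ol_slide(
            rec["true_theta"], layout=layout, textures=textures,
            seed=int(s), slide_id=rec["slide_id"],
        )
        out.append((slide, rec))
    return out


def noisier(textures: dict[int, TextureParams], scale: float) -> dict[int, TextureParams]:
    """Scale every class's color-noise SD: used to degrade separability."""
    return {k: replace(t, noise_sd=t.noise_sd * scale) for k, t in textures.items()}
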