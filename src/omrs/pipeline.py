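"""Stage-based pipeline: simulate -> tile -> train -> predict -> score ->
stratify -> survival.

Each stage reads and writes only documented on-disk formats under the
configured working directory, so any stage can be re-run alone once its
inputs exist.  A run manifest (config snapshot, per-stage output checksums,
timestamps) is written at the end; deterministic stages reproduce identical
checksums for the same config and seed.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classifier import PatchClassifier, TrainingConfig, predict_patches, train_classifier
from .cohort_stats import (
    DEFAULT_MULTIVARIATE,
    UNIVARIATE_CANDIDATES,
    cox_fit,
    encode_covariates,
    fisher_exact,
    km_fit,
    log_rank,
    odds_ratio,
    progression_table,
    survival_at,
)
from .io import (
    load_slide,
    render_class_heatmap,
    read_predictions,
    save_slide,
    sha256_of,
    write_json,
    write_patch_manifest,
    write_predictions,
    write_scores,
)
from .slide_analysis import build_class_heatmap, slide_risk_score, stratify_cohort
from .synthetic import (
    SyntheticCohortSpec,
    default_ol_layout,
    default_training_layout,
    generate_cohort,
    generate_training_slide,
)
from .tiling import label_patches, split_slides, tile_slide

log = logging.getLogger("omrs")

STAGES = ("simulate", "tile", "train", "predict", "score", "stratify", "survival")


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration (CLI exit code 2)."""


class DataError(RuntimeError):
    """Missing or malformed stage input (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    workdir: str = "omrs_run"
    seed: int = 0
    # simulate
    n_training_slides: int = 12
    training_cols: int = 3
    ol_epi_rows: int = 2
    ol_cols: int = 3
    cohort: dict = field(
        default_factory=lambda: dataclasses.asdict(SyntheticCohortSpec())
    )
    # tile
    purity_threshold: float = 0.9
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    # train
    training: dict = field(default_factory=lambda: dataclasses.asdict(TrainingConfig()))
    # score
    likeness_variant: str = "renormalized"
    # survival
    ties: str = "efron"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_training_slides < 3:
            raise ConfigError("n_training_slides must be >= 3 (one per split)")
        if self.likeness_variant not in ("renormalized", "raw"):
            raise ConfigError(f"unknown likeness_variant {self.likeness_variant!r}")
        if self.ties not in ("efron", "breslow"):
            raise ConfigError(f"unknown ties method {self.ties!r}")

    # -- serialization (round-trips unchanged) -----------------------------
    def to_json(self, path: Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["split_fractions"] = list(self.split_fractions)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if isinstance(source, Path) else source
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config is not valid JSON: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "split_fractions" in payload:
            payload["split_fractions"] = tuple(payload["split_fractions"])
        try:
            return cls(**payload)
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(str(exc)) from exc

    # -- paths -------------------------------------------------------------
    @property
    def root(self) -> Path:
        return Path(self.workdir)

    def path(self, name: str) -> Path:
        return {
            "slides": self.root / "slides",
            "masks": self.root / "masks",
            "heatmaps": self.root / "heatmaps",
            "cohort": self.root / "cohort.csv",
            "training_slides": self.root / "training_slides.csv",
            "patches": self.root / "patches.csv",
            "model": self.root / "model.json",
            "learning_curve": self.root / "learning_curve.csv",
            "predictions": self.root / "predictions.csv",
            "scores": self.root / "scores.csv",
            "stratification": self.root / "stratification.csv",
            "results": self.root / "results.json",
            "manifest": self.root / "manifest.json",
        }[name]


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DataError(f"stage '{stage}' requires missing input: {path}")
    return path


def _load_patches_for(cfg: PipelineConfig, slide_ids: Sequence[str]):
    slides = {
        sid: load_slide(sid, cfg.path("slides"), cfg.path("masks"))
        for sid in slide_ids
    }
    return slides


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    cfg.root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    train_layout = default_training_layout(cfg.training_cols)
    training_ids = []
    for i in range(cfg.n_training_slides):
        sid = f"tr{i:03d}"
        slide = generate_training_slide(
            train_layout, seed=int(rng.integers(2**31 - 1)), slide_id=sid
        )
        save_slide(slide, cfg.path("slides"), cfg.path("masks"))
        training_ids.append(sid)
    pd.DataFrame({"slide_id": training_ids}).to_csv(
        cfg.path("training_slides"), index=False
    )
    spec = SyntheticCohortSpec(**{**cfg.cohort, "seed": cfg.seed + 1})
    layout = default_ol_layout(cfg.ol_epi_rows, cfg.ol_cols)
    pairs = generate_cohort(spec, layout=layout)
    for slide, _rec in pairs:
        save_slide(slide, cfg.path("slides"), cfg.path("masks"))
    records = pd.DataFrame([rec for _s, rec in pairs])
    records.to_csv(cfg.path("cohort"), index=False)
    log.info("simulate: %d training slides, %d cohort slides",
             len(training_ids), len(pairs))
    return [cfg.path("training_slides"), cfg.path("cohort")]


def stage_tile(cfg: PipelineConfig) -> list[Path]:
    ids = pd.read_csv(_require(cfg.path("training_slides"), "tile"))["slide_id"].tolist()
    assignment = split_slides(ids, cfg.split_fractions, seed=cfg.seed + 2)
    all_labeled, all_dropped = [], []
    for sid in ids:
        slide = load_slide(sid, _require(cfg.path("slides"), "tile"), cfg.path("masks"))
        patches = tile_slide(slide)
        labeled, dropped = label_patches(patches, slide.mask, cfg.purity_threshold)
        all_labeled.extend(labeled)
        all_dropped.extend(dropped)
    write_patch_manifest(all_labeled, all_dropped, assignment, cfg.path("patches"))
    log.info("tile: %d patches kept, %d dropped", len(all_labeled), len(all_dropped))
    return [cfg.path("patches")]


def _labeled_from_manifest(cfg: PipelineConfig, split: str):
    from .tiling import LabeledPatch, Patch

    manifest = pd.read_csv(_require(cfg.path("patches"), "train"))
    manifest = manifest[(manifest["status"] == "kept") & (manifest["split"] == split)]
    out = []
    for sid, grp in manifest.groupby("slide_id"):
        slide = load_slide(sid, cfg.path("slides"), cfg.path("masks"))
        for r in grp.itertuples():
            y, x = int(r.y), int(r.x)
            patch = Patch(sid, int(r.row), int(r.col), (y, x),
                          slide.image[y : y + 300, x : x + 300])
            out.append(LabeledPatch(patch, int(r.label), float(r.purity)))
    return out


def stage_train(cfg: PipelineConfig) -> list[Path]:
    train = _labeled_from_manifest(cfg, "train")
    val = _labeled_from_manifest(cfg, "validation")
    if not train or not val:
        raise DataError("stage 'train' found no train/validation patches in manifest")
    config = TrainingConfig(**{**cfg.training, "seed": cfg.seed + 3})
    model, curve = train_classifier(train, val, config)
    model.save(cfg.path("model"))
    curve.to_csv(cfg.path("learning_curve"), index=False)
    log.info("train: %d train / %d val patches, final val accuracy %.3f",
             len(train), len(val), curve["val_accuracy"].iloc[-1])
    return [cfg.path("model"), cfg.path("learning_curve")]


def stage_predict(cfg: PipelineConfig) -> list[Path]:
    model = PatchClassifier.load(_require(cfg.path("model"), "predict"))
    cohort = pd.read_csv(_require(cfg.path("cohort"), "predict"))
    preds = []
    heat_dir = cfg.path("heatmaps")
    heat_dir.mkdir(parents=True, exist_ok=True)
    for sid in cohort["slide_id"]:
        slide = load_slide(sid, cfg.path("slides"))
        slide_preds = predict_patches(model, tile_slide(slide))
        render_class_heatmap(build_class_heatmap(slide_preds), heat_dir / f"{sid}.png")
        preds.extend(slide_preds)
    write_predictions(preds, cfg.path("predictions"))
    log.info("predict: %d patches over %d slides", len(preds), len(cohort))
    return [cfg.path("predictions")]


def stage_score(cfg: PipelineConfig) -> list[Path]:
    preds = read_predictions(_require(cfg.path("predictions"), "score"))
    by_slide: dict[str, list] = {}
    for p in preds:
        by_slide.setdefault(p.slide_id, []).append(p)
    scores = [
        slide_risk_score(ps, variant=cfg.likeness_variant)
        for ps in by_slide.values()
    ]
    write_scores(scores, cfg.path("scores"))
    log.info("score: %d slides scored", len(scores))
    return [cfg.path("scores")]


def stage_stratify(cfg: PipelineConfig) -> list[Path]:
    scores = pd.read_csv(_require(cfg.path("scores"), "stratify"))
    cohort = pd.read_csv(_require(cfg.path("cohort"), "stratify"))
    merged = cohort.merge(scores, on="slide_id", how="inner")
    if len(merged) < len(cohort):
        raise DataError("stage 'stratify': some cohort slides have no score")
    strat = stratify_cohort(dict(zip(merged["patient_id"], merged["score"])))
    merged["group"] = merged["patient_id"].map(strat.groups)
    out = merged[
        ["patient_id", "slide_id", "score", "n_epithelium", "group"]
    ]
    out.to_csv(cfg.path("stratification"), index=False)
    log.info("stratify: median score %.4f, %d low / %d high",
             strat.cohort_median_score,
             (out["group"] == "low").sum(), (out["group"] == "high").sum())
    return [cfg.path("stratification")]


def survival_analysis(records: pd.DataFrame, ties: str = "efron", alpha: float = 0.05) -> dict:
    """Full prognostic read-out of a stratified cohort table.

    Returns contingency statistics (odds ratio with Woolf CI, Fisher exact
    p), per-group Kaplan–Meier summaries with 5- and 10-year progression
    probabilities, the two-group log-rank test, and univariate plus
    multivariate Cox fits.
    """
    enc = encode_covariates(records)
    table = progression_table(enc)
    orr = odds_ratio(table, alpha=alpha)
    out: dict = {
        "contingency": {
            "table": dataclasses.asdict(table),
            "odds_ratio": orr.or_estimate,
            "or_ci_low": orr.ci_low,
            "or_ci_high": orr.ci_high,
            "fisher_p": fisher_exact(table),
        }
    }
    km = {}
    groups = {}
    for g, sub in enc.groupby("group"):
        curve = km_fit(sub["ttp_years"], sub["event"])
        groups[g] = (sub["ttp_years"].to_numpy(), sub["event"].to_numpy())
        entry = {"n": int(len(sub)), "events": int(sub["event"].sum())}
        for horizon in (5.0, 10.0):
            est = survival_at(curve, horizon, alpha=alpha)
            entry[f"progression_probability_{int(horizon)}y"] = 1 - est.survival
            entry[f"ci_{int(horizon)}y"] = [1 - est.ci_high, 1 - est.ci_low]
        km[g] = entry
    out["kaplan_meier"] = km
    n_events = int(enc["event"].sum())
    if set(groups) == {"low", "high"} and n_events >= 1:
        chi, p = log_rank(groups["high"], groups["low"])
        out["log_rank"] = {"chi_square": chi, "p": p}
    if n_events < 2:  # too few events for partial-likelihood fitting
        out["cox_skipped"] = f"only {n_events} events"
        return out
    uni = {}
    for cov in UNIVARIATE_CANDIDATES:
        if cov not in enc.columns or enc[cov].nunique() < 2:
            continue
        fit = cox_fit(enc, [cov], ties=ties, alpha=alpha)
        uni[cov] = {
            "HR": float(fit.hazard_ratios[0]),
            "ci": [float(fit.ci_low[0]), float(fit.ci_high[0])],
            "wald_p": float(fit.wald_p[0]),
            "converged": fit.converged,
        }
    out["cox_univariate"] = uni
    multi_covs = [
        c for c in DEFAULT_MULTIVARIATE if c in enc.columns and enc[c].nunique() > 1
    ]
    if len(multi_covs) >= 2:
        fit = cox_fit(enc, multi_covs, ties=ties, alpha=alpha)
        out["cox_multivariate"] = {
            "covariates": multi_covs,
            "HR": fit.hazard_ratios.tolist(),
            "ci_low": fit.ci_low.tolist(),
            "ci_high": fit.ci_high.tolist(),
            "wald_p": fit.wald_p.tolist(),
            "converged": fit.converged,
        }
    return out


def stage_survival(cfg: PipelineConfig) -> list[Path]:
    cohort = pd.read_csv(_require(cfg.path("cohort"), "survival"))
    strat = pd.read_csv(_require(cfg.path("stratification"), "survival"))
    records = cohort.merge(strat[["patient_id", "group", "score"]], on="patient_id")
    results = survival_analysis(records, ties=cfg.ties, alpha=cfg.alpha)
    write_json(results, cfg.path("results"))
    log.info("survival: OR %.3f, Fisher p %.4f",
             results["contingency"]["odds_ratio"],
             results["contingency"]["fisher_p"])
    return [cfg.path("results")]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "tile": stage_tile,
    "train": stage_train,
    "predict": stage_predict,
    "score": stage_score,
    "stratify": stage_stratify,
    "survival": stage_survival,
}


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict  # stage -> {"outputs": {path: sha256}, "completed_at": iso}
    log_path: str | None = None


def run_pipeline(
    config: PipelineConfig, stages: Sequence[str] | None = None
) -> RunManifest:
    """Run the requested stages in pipeline order and write a run manifest.

    Stages must be a subset of the pipeline order; each stage reads its
    inputs from disk, so earlier outputs (or pre-existing files) satisfy
    later stages.  Partial failures leave earlier stage outputs intact.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    stages = sorted(set(stages), key=STAGES.index)
    config.root.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=json.loads(config.to_json()), version=__version__, stages={}
    )
    for stage in stages:
        outputs = _STAGE_FUNCS[stage](config)
        manifest.stages[stage] = {
            "outputs": {str(p): sha256_of(p) for p in outputs},
            "completed_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
        write_json(dataclasses.asdict(manifest), config.path("manifest"))
    return manifest
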