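"""Seeded end-to-end evaluation experiments on synthetic ground truth.

These functions tie the pipeline stages together in memory for the
package's standard self-checks:

* training/evaluating the default patch classifier on separable textures;
* the theta -> slide-score monotonicity experiment;
* stratified-cohort replicates measuring how often the high/low risk split
  carries a significant progression hazard ratio;
* Cox confidence-interval coverage against the generating coefficient.

Experiment sizes are documented defaults chosen for desk-scale CPU runs;
every function is deterministic given its seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .classifier import (
    EvalReport,
    PatchClassifier,
    TrainingConfig,
    evaluate,
    predict_patches,
    train_classifier,
)
from .cohort_stats import cox_fit, fisher_exact, odds_ratio, progression_table
from .labels import BACKGROUND, CONNECTIVE, NONDYS_EPI
from .slide_analysis import slide_risk_score, stratify_cohort
from .synthetic import (
    SyntheticCohortSpec,
    band_layout,
    default_training_layout,
    generate_cohort_records,
    generate_ol_slide,
    generate_training_slide,
)
from .tiling import label_patches, split_of_patches, split_slides, tile_slide


def train_default_classifier(
    seed: int = 0,
    n_slides: int = 12,
    training_cols: int = 3,
    config: TrainingConfig | None = None,
) -> tuple[PatchClassifier, EvalReport]:
    """Train the default classifier on synthetic training slides.

    Renders ``n_slides`` annotated four-band slides, tiles and labels them,
    splits 60/20/20 grouped by slide, trains, and evaluates on the held-out
    test slides.  Returns the model and its test-set report.
    """
    rng = np.random.default_rng(seed)
    layout = default_training_layout(training_cols)
    slides = [
        generate_training_slide(
            layout, seed=int(rng.integers(2**31 - 1)), slide_id=f"tr{i:03d}"
        )
        for i in range(n_slides)
    ]
    assignment = split_slides([s.slide_id for s in slides], seed=seed + 1)
    labeled = []
    for s in slides:
        kept, _ = label_patches(tile_slide(s), s.mask)
        labeled.extend(kept)
    splits = split_of_patches(labeled, assignment)
    cfg = config if config is not None else TrainingConfig(seed=seed + 2)
    model, _curve = train_classifier(splits["train"], splits["validation"], cfg)
    return model, evaluate(model, splits["test"])


#: OL slide layout for the monotonicity experiment: 36 epithelium tiles so
#: the slide median resolves adjacent mixing fractions.
MONOTONICITY_LAYOUT = lambda: band_layout(
    [BACKGROUND] + [NONDYS_EPI] * 6 + [CONNECTIVE], 6
)

#: Compact OL slide (6 epithelium tiles) used for cohort replicates.
REPLICATE_LAYOUT = lambda: band_layout([BACKGROUND, NONDYS_EPI, NONDYS_EPI], 3)


def score_ol_slide(model: PatchClassifier, theta: float, seed: int, layout=None) -> float:
    """Render one OL mixture slide and return its pipeline risk score."""
    slide = generate_ol_slide(
        theta, layout if layout is not None else REPLICATE_LAYOUT(), seed=seed
    )
    return slide_risk_score(predict_patches(model, tile_slide(slide))).score


def theta_monotonicity(
    model: PatchClassifier,
    seed: int = 0,
    thetas: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_per_theta: int = 8,
) -> dict:
    """Spearman correlation between theta and the slide risk score.

    Renders ``n_per_theta`` OL slides at each mixing fraction (36
    epithelium tiles each) and correlates theta with the computed scores.
    """
    rng = np.random.default_rng(seed)
    layout = MONOTONICITY_LAYOUT()
    xs, ys = [], []
    for th in thetas:
        for _ in range(n_per_theta):
            s = score_ol_slide(model, th, int(rng.integers(2**31 - 1)), layout)
            xs.append(th)
            ys.append(s)
    rho = float(spearmanr(xs, ys).statistic)
    mean_by_theta = {
        th: float(np.mean([y for x, y in zip(xs, ys) if x == th])) for th in thetas
    }
    return {"spearman_rho": rho, "mean_score_by_theta": mean_by_theta, "n_slides": len(xs)}


#: Cohort replicate conditions: sized by a-priori power analysis so the
#: median-split hazard-ratio test has ~95% power under the generating model.
REPLICATE_SPEC = dict(
    n_patients=200,
    theta_alpha=0.4,
    theta_beta=0.4,
    baseline_hazard=0.03,
    log_hazard_coeff=math.log(3.0),
    admin_censor_time=15.0,
)


def stratified_cohort_replicate(model: PatchClassifier, seed: int) -> dict:
    """One end-to-end cohort replicate: slides -> scores -> split -> statistics.

    Generates a synthetic cohort, renders and scores each patient's OL
    slide through the classifier, median-splits the cohort on the scores,
    and returns the univariate group Cox fit plus contingency statistics.
    """
    spec = SyntheticCohortSpec(**REPLICATE_SPEC, seed=seed)
    records = generate_cohort_records(spec)
    rng = np.random.default_rng(seed + 1)
    layout = REPLICATE_LAYOUT()
    scores = {
        row.patient_id: score_ol_slide(
            model, row.true_theta, int(rng.integers(2**31 - 1)), layout
        )
        for row in records.itertuples()
    }
    strat = stratify_cohort(scores)
    records = records.assign(
        score=records["patient_id"].map(scores),
        group=records["patient_id"].map(strat.groups),
        risk_high=(records["patient_id"].map(strat.groups) == "high").astype(int),
    )
    fit = cox_fit(records, ["risk_high"])
    table = progression_table(records)
    return {
        "hazard_ratio": float(fit.hazard_ratios[0]),
        "wald_p": float(fit.wald_p[0]),
        "converged": fit.converged,
        "odds_ratio": odds_ratio(table).or_estimate,
        "fisher_p": fisher_exact(table),
        "records": records,
    }


def replicate_significance(
    model: PatchClassifier, n_replicates: int = 20, seed: int = 0
) -> dict:
    """Fraction of cohort replicates with group HR > 1 and Wald p < 0.05."""
    rng = np.random.default_rng(seed)
    hits = 0
    hrs, ps = [], []
    for _ in range(n_replicates):
        rep = stratified_cohort_replicate(model, int(rng.integers(2**31 - 1)))
        hrs.append(rep["hazard_ratio"])
        ps.append(rep["wald_p"])
        hits += int(rep["hazard_ratio"] > 1 and rep["wald_p"] < 0.05)
    return {
        "fraction_significant": hits / n_replicates,
        "n_replicates": n_replicates,
        "median_hazard_ratio": float(np.median(hrs)),
        "hazard_ratios": hrs,
        "wald_ps": ps,
    }


def cox_coverage(
    n_replicates: int = 100,
    n_patients: int = 500,
    beta: float = math.log(3.0),
    seed: int = 0,
) -> dict:
    """Wald 95% CI coverage of the generating log-hazard coefficient.

    Fits the continuous theta covariate on ``n_replicates`` synthetic
    cohorts and counts how often the CI for its coefficient covers the true
    beta.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_replicates):
        spec = SyntheticCohortSpec(
            n_patients=n_patients,
            log_hazard_coeff=beta,
            seed=int(rng.integers(2**31 - 1)),
        )
        records = generate_cohort_records(spec)
        fit = cox_fit(records, ["true_theta"])
        lo = math.log(fit.ci_low[0]) if fit.ci_low[0] > 0 else -math.inf
        hi = math.log(fit.ci_high[0])
        covered += int(lo <= beta <= hi)
    return {"coverage": covered / n_replicates, "covered": covered, "n_replicates": n_replicates}
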