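"""Heatmaps, tumor-likeness, slide risk scores and cohort stratification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omrs.classifier import PatchPrediction, TrainingConfig, predict_patches
from omrs.experiments import train_default_classifier
from omrs.labels import BACKGROUND, CONNECTIVE, NONDYS_EPI, TUMOR_EPI
from omrs.slide_analysis import (
    build_class_heatmap,
    build_risk_heatmap,
    epithelium_mask,
    patch_tumor_likeness,
    slide_risk_score,
    stratify_cohort,
)
from omrs.synthetic import band_layout, generate_ol_slide, realized_tumor_fraction
from omrs.tiling import tile_slide

from test_synthetic import flat_textures


def pred(row, col, probs, slide_id="s"):
    return PatchPrediction(slide_id, row, col, np.asarray(probs, float))


def grid_preds(prob_grid):
    return [
        pred(r, c, p)
        for r, row in enumerate(prob_grid)
        for c, p in enumerate(row)
    ]


class TestClassHeatmap:
    def test_argmax_cell(self):
        heat = build_class_heatmap([pred(0, 0, (0.1, 0.1, 0.1, 0.7))])
        assert heat.grid[0, 0] == TUMOR_EPI

    def test_tie_resolves_to_lowest_class_index(self):
        heat = build_class_heatmap([pred(0, 0, (0.25, 0.25, 0.25, 0.25))])
        assert heat.grid[0, 0] == BACKGROUND

    def test_grid_matches_per_cell_brute_force(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(4), size=(3, 2))
        heat = build_class_heatmap(grid_preds(probs))
        for r in range(3):
            for c in range(2):
                best, best_p = 0, -1.0
                for k in range(4):
                    if probs[r, c, k] > best_p:
                        best, best_p = k, probs[r, c, k]
                assert heat.grid[r, c] == best

    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_class_heatmap([pred(0, 0, (1, 0, 0, 0)), pred(0, 0, (1, 0, 0, 0))])

    def test_incomplete_grid_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_class_heatmap([pred(0, 0, (1, 0, 0, 0)), pred(1, 1, (1, 0, 0, 0))])


class TestEpitheliumMask:
    def test_all_background_all_false(self):
        heat = build_class_heatmap(grid_preds([[(1, 0, 0, 0)] * 3]))
        assert not epithelium_mask(heat).any()

    def test_all_tumor_all_true(self):
        heat = build_class_heatmap(grid_preds([[(0, 0, 0, 1)] * 3]))
        assert epithelium_mask(heat).all()

    def test_mixed_grid_count(self):
        probs = [[(1, 0, 0, 0), (0, 0, 1, 0), (0, 0, 0, 1), (0, 1, 0, 0)]]
        heat = build_class_heatmap(grid_preds(probs))
        assert epithelium_mask(heat).sum() == 2


class TestTumorLikeness:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ((0, 0, 0.5, 0.5), 0.5),
            ((0, 0, 0.0, 1.0), 1.0),
            ((0.2, 0.2, 0.15, 0.45), 0.75),
        ],
    )
    def test_renormalized_value(self, probs, expected):
        assert patch_tumor_likeness(pred(0, 0, probs)) == pytest.approx(expected)

    def test_raw_variant(self):
        assert patch_tumor_likeness(pred(0, 0, (0.2, 0.2, 0.15, 0.45)), "raw") == 0.45

    def test_zero_epithelium_mass_rejected(self):
        with pytest.raises(ValueError, match="epithelium"):
            patch_tumor_likeness(pred(0, 0, (0.6, 0.4, 0.0, 0.0)))

    def test_risk_heatmap_nan_outside_epithelium(self):
        probs = [[(1, 0, 0, 0), (0, 0, 0.2, 0.8)]]
        risk = build_risk_heatmap(grid_preds(probs))
        assert np.isnan(risk.grid[0, 0])
        assert risk.grid[0, 1] == pytest.approx(0.8)


def epi_preds(values):
    """One prediction per value, fully epithelial with given tumor-likeness."""
    return [pred(0, i, (0.0, 0.0, 1 - v, v)) for i, v in enumerate(values)]


class TestSlideRiskScore:
    def test_singleton(self):
        assert slide_risk_score(epi_preds([0.9])).score == pytest.approx(0.9)

    def test_even_count_mean_of_middle_two(self):
        s = slide_risk_score(epi_preds([0.1, 0.4, 0.8, 1.0]))
        assert s.score == pytest.approx(0.6)
        assert s.n_epithelium_patches == 4

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        values = rng.random(101)
        s = slide_risk_score(epi_preds(values))
        assert s.score == pytest.approx(sorted(values)[50])

    def test_non_epithelium_cells_excluded_from_median(self):
        preds = epi_preds([0.2, 0.8]) + [pred(0, 2, (1, 0, 0, 0))]
        s = slide_risk_score(preds)
        assert s.n_epithelium_patches == 2 and s.n_total_patches == 3
        assert s.score == pytest.approx(0.5)

    def test_no_epithelium_error_carries_slide_id(self):
        with pytest.raises(ValueError, match="sl9"):
            slide_risk_score([pred(0, 0, (1, 0, 0, 0), slide_id="sl9")])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.integers(0, 10**6))
    def test_permutation_invariance(self, values, seed):
        rng = np.random.default_rng(seed)
        base = epi_preds(values)
        shuffled = [base[i] for i in rng.permutation(len(base))]
        assert slide_risk_score(base).score == slide_risk_score(shuffled).score


class TestStratification:
    def test_even_cohort_splits_in_half(self):
        rng = np.random.default_rng(0)
        scores = {f"p{i:02d}": s for i, s in enumerate(rng.permutation(62) / 62)}
        strat = stratify_cohort(scores)
        groups = list(strat.groups.values())
        assert groups.count("low") == 31 and groups.count("high") == 31
        # every low-risk score is below every high-risk score
        lows = [scores[p] for p, g in strat.groups.items() if g == "low"]
        highs = [scores[p] for p, g in strat.groups.items() if g == "high"]
        assert max(lows) < min(highs)

    def test_two_patients(self):
        strat = stratify_cohort({"a": 0.2, "b": 0.8})
        assert strat.groups == {"a": "low", "b": "high"}

    def test_odd_cohort_median_patient_goes_low(self):
        strat = stratify_cohort({"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4, "e": 0.5})
        groups = list(strat.groups.values())
        assert groups.count("low") == 3 and groups.count("high") == 2
        assert strat.groups["c"] == "low"

    def test_ties_broken_by_patient_id(self):
        strat = stratify_cohort({"b": 0.5, "a": 0.5, "c": 0.5, "d": 0.5})
        assert strat.groups == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            stratify_cohort({"a": 0.5})

    @settings(deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.text("abcdefgh", min_size=1, max_size=4),
            st.floats(0, 1),
            min_size=2,
            max_size=40,
        )
    )
    def test_partition_property(self, scores):
        strat = stratify_cohort(scores)
        assert set(strat.groups) == set(scores)
        n_low = sum(g == "low" for g in strat.groups.values())
        n_high = len(scores) - n_low
        assert n_low - n_high in (0, 1)


@pytest.fixture(scope="module")
def saturated_model():
    # an unregularized long fit on separable textures saturates the
    # probabilities, so tumor-likeness is ~0/1 per tile
    model, _report = train_default_classifier(
        seed=21, n_slides=6, training_cols=1,
        config=TrainingConfig(epochs=300, learning_rate=1.0, l2=0.0, seed=1),
    )
    return model


class TestEndToEndThetaRecovery:
    @pytest.mark.parametrize("theta", [0.0, 1.0])
    def test_score_recovers_extreme_mixtures(self, saturated_model, theta):
        layout = band_layout([BACKGROUND, NONDYS_EPI, NONDYS_EPI], 3)
        slide = generate_ol_slide(theta, layout, seed=int(theta * 7 + 3))
        preds = predict_patches(saturated_model, tile_slide(slide))
        score = slide_risk_score(preds).score
        assert abs(score - realized_tumor_fraction(slide)) < 0.05
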