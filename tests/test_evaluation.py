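"""Tests of the evaluation metrics and sweep machinery."""

import numpy as np
import pandas as pd
import pytest

import ccell


class TestRmse:
    def test_zero_for_exact_estimate(self, rng):
        x = rng.normal(size=(4, 4))
        assert ccell.rmse(x, x) == 0.0

    def test_constant_offset(self, rng):
        x = rng.normal(size=(3, 5))
        assert ccell.rmse(x + 0.7, x) == pytest.approx(0.7)

    def test_masked_hand_case(self):
        est = np.array([[0.3, 9.0], [0.0, 0.4]])
        truth = np.zeros((2, 2))
        mask = np.array([[True, False], [False, True]])
        assert ccell.rmse(est, truth, mask) == pytest.approx(0.35355, abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ccell.rmse(np.zeros(3), np.zeros(4))


class TestRocPrCurves:
    def test_perfect_separation(self):
        scores = np.zeros((3, 3))
        scores[0, 1], scores[1, 2] = 0.9, 0.8
        truth = scores > 0
        out = ccell.roc_pr_curves(scores, truth)
        assert out["auroc"] == 1.0
        assert out["aupr"] == 1.0

    def test_hand_four_candidate_case(self):
        """Scores (0.9, 0.8, 0.4, 0.1) against truth (1, 0, 1, 0):
        AUROC = 0.75 by rank-pair enumeration, AP = 5/6."""
        scores = np.array([[0.9, 0.8], [0.4, 0.1]])
        truth = np.array([[True, False], [True, False]])
        mask = np.ones((2, 2), dtype=bool)
        out = ccell.roc_pr_curves(scores, truth, candidate_mask=mask)
        assert out["auroc"] == pytest.approx(0.75)
        assert out["aupr"] == pytest.approx(5.0 / 6.0)

    def test_random_scores_near_half_auroc(self):
        aurocs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            scores = r.random((100, 100))
            truth = np.zeros((100, 100), dtype=bool)
            idx = r.choice(100 * 100, size=100, replace=False)
            truth.flat[idx] = True
            out = ccell.roc_pr_curves(scores, truth, np.ones((100, 100), bool))
            aurocs.append(out["auroc"])
        assert abs(np.mean(aurocs) - 0.5) < 0.02

    def test_invariant_under_monotone_rescaling(self, rng):
        scores = rng.random((20, 20))
        truth = rng.random((20, 20)) < 0.1
        truth[np.diag_indices(20)] = False
        a = ccell.roc_pr_curves(scores, truth)
        b = ccell.roc_pr_curves(scores**3, truth)
        assert a["auroc"] == pytest.approx(b["auroc"], abs=1e-12)
        assert a["aupr"] == pytest.approx(b["aupr"], abs=1e-12)

    def test_degenerate_truth_rejected(self):
        with pytest.raises(ValueError):
            ccell.roc_pr_curves(np.zeros((3, 3)), np.zeros((3, 3), dtype=bool))


class TestSensitivitySpecificity:
    def test_perfect_structure(self):
        truth = np.array([[False, True], [False, False]])
        sens, spec = ccell.sensitivity_specificity(
            truth.astype(int), truth
        )
        assert (sens, spec) == (1.0, 1.0)

    def test_empty_structure(self):
        truth = np.array([[False, True], [False, False]])
        sens, spec = ccell.sensitivity_specificity(np.zeros((2, 2), int), truth)
        assert (sens, spec) == (0.0, 1.0)

    def test_hand_counts(self):
        """10 candidates, 3 true links, one false positive and one false
        negative: sensitivity 2/3, specificity 6/7."""
        truth = np.zeros((4, 4), dtype=bool)
        truth[0, 1] = truth[0, 2] = truth[1, 2] = True
        called = np.zeros((4, 4), dtype=int)
        called[0, 1] = called[0, 2] = 1  # two of three true links
        called[2, 3] = 1  # one false positive
        mask = np.zeros((4, 4), dtype=bool)
        mask[np.triu_indices(4, 1)] = True  # 6 pairs
        mask[1, 0] = mask[2, 0] = mask[2, 1] = mask[3, 0] = True  # 10 total
        sens, spec = ccell.sensitivity_specificity(called, truth, mask)
        assert sens == pytest.approx(2.0 / 3.0)
        assert spec == pytest.approx(6.0 / 7.0)


class TestAverageVariance:
    def test_equal_variances(self):
        from ccell.pipeline import TransitionEstimate

        est = TransitionEstimate(
            np.zeros((3, 3)),
            [0.2 * np.eye(3)] * 3,
            [np.ones(3)] * 3,
            float(np.mean([0.2] * 9)),
        )
        assert ccell.average_variance(est) == pytest.approx(0.2)

    def test_hand_two_row_case(self):
        from ccell.pipeline import TransitionEstimate

        covs = [np.diag([0.1, 0.3]), np.diag([0.2, 0.4])]
        est = TransitionEstimate(
            np.zeros((2, 2)), covs, [np.ones(2)] * 2,
            float(np.mean([0.1, 0.3, 0.2, 0.4])),
        )
        assert ccell.average_variance(est) == pytest.approx(0.25)

    def test_pruned_rows_contribute_zero(self):
        from ccell.pipeline import TransitionEstimate

        est = TransitionEstimate(
            np.zeros((2, 2)), [np.zeros((2, 2))] * 2, [np.ones(2)] * 2, 0.0
        )
        assert ccell.average_variance(est) == 0.0


class TestSweep:
    def test_single_cell_table_and_determinism(self):
        a = ccell.run_sweep(["n-4"], [2], [3])
        b = ccell.run_sweep(["n-4"], [2], [3])
        assert len(a) == 1
        assert a.iloc[0]["benchmark_id"] == "n-4"
        assert a.iloc[0]["n_perturbations"] == 2
        pd.testing.assert_frame_equal(a, b)
        assert 0.0 <= a.iloc[0]["auroc"] <= 1.0
        assert a.iloc[0]["step3_rmse"] >= 0.0

    def test_summary_spearman_on_monotone_table(self):
        table = pd.DataFrame(
            {
                "auroc": np.linspace(0.9, 1.0, 6),
                "aupr": np.linspace(0.8, 1.0, 6),
                "sensitivity": np.ones(6),
                "specificity": np.ones(6),
                "step2_rmse": np.linspace(0.2, 0.7, 6),
                "step3_rmse": np.geomspace(1e-4, 1e-1, 6),
                "rmse_ratio": np.linspace(0.1, 0.5, 6),
                "average_variance": np.geomspace(1e-8, 1e-2, 6),
                "conc_rmse_p95": np.full(6, 0.01),
            }
        )
        summary = ccell.summarize_sweep(table)
        assert summary["spearman_lnvar_rmse"] == pytest.approx(1.0)
        assert summary["n_experiments"] == 6
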