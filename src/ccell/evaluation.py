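"""Metrics and experiment sweeps.

Link recovery is scored over all ordered species pairs excluding the
diagonal (the diagonal encodes persistence, not interaction, and the
ground-truth networks carry no self-links), with |A_hat| entries as scores.
AUROC uses the trapezoidal rule over the full threshold sweep and AUPR uses
step interpolation; both therefore depend only on the ranking of scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from . import benchmark as bm
from . import pipeline as pl

__all__ = [
    "ExperimentResult",
    "rmse",
    "off_diagonal_mask",
    "roc_pr_curves",
    "sensitivity_specificity",
    "average_variance",
    "evaluate_experiment",
    "run_sweep",
    "summarize_sweep",
    "run_noise_sweep",
]


@dataclass
class ExperimentResult:
    """Metrics of one benchmark run."""

    benchmark_id: str
    n_perturbations: int
    seed: int
    concentration_rmse: np.ndarray  # (P, T)
    auroc: float
    aupr: float
    sensitivity: float
    specificity: float
    step2_rmse: float
    step3_rmse: float
    average_variance: float

    def as_row(self) -> dict:
        c = self.concentration_rmse.ravel()
        return {
            "benchmark_id": self.benchmark_id,
            "n_perturbations": self.n_perturbations,
            "seed": self.seed,
            "auroc": self.auroc,
            "aupr": self.aupr,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "step2_rmse": self.step2_rmse,
            "step3_rmse": self.step3_rmse,
            "rmse_ratio": self.step3_rmse / self.step2_rmse
            if self.step2_rmse > 0
            else np.nan,
            "average_variance": self.average_variance,
            "conc_rmse_median": float(np.median(c)),
            "conc_rmse_p95": float(np.quantile(c, 0.95)),
            "conc_rmse_max": float(c.max()),
        }


def rmse(
    estimate: np.ndarray, truth: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Root mean squared difference, optionally over a boolean mask."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("shape mismatch")
    diff = estimate - truth
    if mask is not None:
        diff = diff[mask]
    return float(np.sqrt(np.mean(diff**2)))


def off_diagonal_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def roc_pr_curves(
    score_matrix: np.ndarray,
    truth_links: np.ndarray,
    candidate_mask: Optional[np.ndarray] = None,
) -> dict:
    """Threshold-sweep ROC and precision-recall over the candidate pairs.

    Scores are |A_hat| entries; an inferred link is a true positive iff it
    exists in the ground truth.  Returns the curve points and both areas.
    """
    scores = np.abs(np.asarray(score_matrix, dtype=float))
    truth = np.asarray(truth_links, dtype=bool)
    if candidate_mask is None:
        candidate_mask = off_diagonal_mask(scores.shape[0])
    y_score = scores[candidate_mask]
    y_true = truth[candidate_mask]
    if y_true.all() or not y_true.any():
        raise ValueError("candidate set needs both link and non-link pairs")
    fpr, tpr, roc_thr = roc_curve(y_true, y_score)
    precision, recall, pr_thr = precision_recall_curve(y_true, y_score)
    return {
        "roc": np.column_stack([fpr, tpr]),
        "roc_thresholds": roc_thr,
        "auroc": float(roc_auc_score(y_true, y_score)),
        "pr": np.column_stack([recall, precision]),
        "pr_thresholds": pr_thr,
        "aupr": float(average_precision_score(y_true, y_score)),
    }


def sensitivity_specificity(
    structure: pl.NetworkStructure | np.ndarray,
    truth_links: np.ndarray,
    candidate_mask: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """(sensitivity, specificity) of binary link calls over the candidates."""
    indicator = (
        structure.indicator
        if isinstance(structure, pl.NetworkStructure)
        else np.asarray(structure)
    )
    truth = np.asarray(truth_links, dtype=bool)
    if candidate_mask is None:
        candidate_mask = off_diagonal_mask(indicator.shape[0])
    called = indicator.astype(bool)[candidate_mask]
    actual = truth[candidate_mask]
    tp = int(np.sum(called & actual))
    fn = int(np.sum(~called & actual))
    tn = int(np.sum(~called & ~actual))
    fp = int(np.sum(called & ~actual))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    return sens, spec


def average_variance(estimate: pl.TransitionEstimate) -> float:
    """Mean posterior variance over all elements of the transition matrix."""
    return float(estimate.average_variance)


def evaluate_experiment(
    bundle: bm.ExperimentBundle, result: pl.CcellResult
) -> ExperimentResult:
    """All paper-style metrics for one (bundle, pipeline result) pair.

    Step-2 and Step-3 transition RMSEs are both computed on the refined
    submatrix (rows and columns of the species the structure kept active),
    so the two steps are compared on the same elements.
    """
    truth = bundle.network.transition
    adjacency = bundle.network.adjacency()
    n = truth.shape[0]
    p, t, _ = bundle.true_concentrations.shape
    conc_rmse = np.sqrt(
        np.mean(
            (result.step1.means - bundle.true_concentrations) ** 2, axis=2
        )
    )
    curves = roc_pr_curves(result.step2.mean_matrix, adjacency)
    sens, spec = sensitivity_specificity(result.structure, adjacency)
    active = result.structure.active_species
    if active.size and result.step3_net is not None:
        sub = np.ix_(active, active)
        step2_rmse = rmse(result.step2.mean_matrix[sub], truth[sub])
        step3_rmse = rmse(result.step3_net.mean_matrix, truth[sub])
        avg_var = result.step3_net.average_variance
    else:
        step2_rmse = np.nan
        step3_rmse = np.nan
        avg_var = np.nan
    spec_ = bundle.network.spec
    return ExperimentResult(
        benchmark_id=spec_.id,
        n_perturbations=spec_.n_perturbations,
        seed=spec_.seed,
        concentration_rmse=conc_rmse,
        auroc=curves["auroc"],
        aupr=curves["aupr"],
        sensitivity=sens,
        specificity=spec,
        step2_rmse=step2_rmse,
        step3_rmse=step3_rmse,
        average_variance=avg_var,
    )


def _run_cell(
    benchmark_id: str, n_perturbations: int, seed: int, config: pl.RunConfig
) -> ExperimentResult:
    spec = bm.BenchmarkSpec.from_id(
        benchmark_id,
        n_perturbations=n_perturbations,
        seed=seed,
        system_noise_std=config.system_noise_std,
        measurement_noise_std=config.measurement_noise_std,
    )
    bundle = bm.run_experiment(spec)
    result = pl.run_ccell(
        bundle.design,
        bundle.observations,
        bundle.initial_concentrations,
        config,
    )
    return evaluate_experiment(bundle, result)


def run_sweep(
    benchmark_ids: Sequence[str],
    perturbation_range: Sequence[int],
    seeds: Sequence[int],
    config: Optional[pl.RunConfig] = None,
) -> pd.DataFrame:
    """Run the benchmark grid and return one tidy row per experiment."""
    config = config or pl.RunConfig()
    rows = []
    for benchmark_id in benchmark_ids:
        for n_pert in perturbation_range:
            for seed in seeds:
                rows.append(
                    _run_cell(benchmark_id, int(n_pert), int(seed), config).as_row()
                )
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> dict:
    """Grid summary: means, rmse-ratio quartiles, and the diagnostic
    rank correlation between ln(average variance) and Step-3 RMSE."""
    ok = table.dropna(subset=["step3_rmse", "average_variance"])
    if len(ok) >= 2 and ok["average_variance"].gt(0).all():
        rho = float(
            spearmanr(np.log(ok["average_variance"]), ok["step3_rmse"]).statistic
        )
    else:
        rho = np.nan
    ratio = table["rmse_ratio"].dropna()
    return {
        "mean_auroc": float(table["auroc"].mean()),
        "mean_aupr": float(table["aupr"].mean()),
        "mean_sensitivity": float(table["sensitivity"].mean()),
        "mean_specificity": float(table["specificity"].mean()),
        "mean_rmse_ratio": float(ratio.mean()) if len(ratio) else np.nan,
        "rmse_ratio_quartiles": [
            float(q) for q in ratio.quantile([0.25, 0.5, 0.75])
        ]
        if len(ratio)
        else [np.nan] * 3,
        "spearman_lnvar_rmse": rho,
        "conc_rmse_p95": float(table["conc_rmse_p95"].max()),
        "n_experiments": int(len(table)),
    }


def run_noise_sweep(
    benchmark_id: str = "n-39",
    n_perturbations: int = 6,
    noise_levels: Sequence[float] = (10.0, 5.0, 2.0, 1.0),
    init_mean: float = 100.0,
    init_std: float = 20.0,
    seed: int = 0,
    config: Optional[pl.RunConfig] = None,
) -> pd.DataFrame:
    """Step-2/Step-3 refined RMSE across noise levels at signal mean 100.

    Both system and measurement noise are set to each level in turn; the
    same base seed keeps the network identical across levels.
    """
    rows = []
    for level in noise_levels:
        cfg = config or pl.RunConfig()
        cfg = pl.RunConfig(
            bcs=cfg.bcs,
            theta=cfg.theta,
            measurement_noise_std=float(level),
            system_noise_std=float(level),
            seed=seed,
        )
        spec = bm.BenchmarkSpec.from_id(
            benchmark_id,
            n_perturbations=n_perturbations,
            seed=seed,
            init_mean=init_mean,
            init_std=init_std,
            system_noise_std=float(level),
            measurement_noise_std=float(level),
        )
        bundle = bm.run_experiment(spec)
        result = pl.run_ccell(
            bundle.design, bundle.observations, bundle.initial_concentrations, cfg
        )
        res = evaluate_experiment(bundle, result)
        rows.append(
            {
                "noise_std": float(level),
                "step2_rmse": res.step2_rmse,
                "step3_rmse": res.step3_rmse,
                "auroc": res.auroc,
            }
        )
    return pd.DataFrame(rows)
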