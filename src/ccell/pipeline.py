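"""The three-step network inference pipeline.

Step 1 (concentration inference) recovers per-time-point species
concentrations from pooled observations: variations between adjacent time
points are sparse, so each differenced system ``delta_g = Phi delta_x + eps``
is solved by Bayesian compressive sensing and the variations accumulated
onto the known initial state.

Step 2 (network inference) treats each row a_i of the transition matrix as
a sparse signal: stacking all (perturbation, transition) pairs gives
``x_{t+1,i} = a_i' x_t`` with the Step-1 concentration means as the design;
rows are solved independently by Bayesian compressive sensing.

Step 3 (refinement) thresholds the Step-2 estimate into a structural
indicator, removes silent species (no off-diagonal link in their row or
column), adjusts observations by the silent species' constant
contributions, re-infers the remaining concentrations by Bayesian linear
regression with the Step-1 posterior as prior (refined variations are no
longer sparse), and finally re-infers the reduced transition matrix with
extended Bayesian compressive sensing, which consumes the concentration
posteriors' covariances instead of only their means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .measurement_design import MeasurementDesign
from .sparse_bayes import (
    BCSConfig,
    DesignPosterior,
    SparseLinearProblem,
    SparsePosterior,
    bcs_estimate,
    blr_posterior,
    ext_bcs_estimate,
)

__all__ = [
    "RunConfig",
    "ConcentrationEstimate",
    "TransitionEstimate",
    "NetworkStructure",
    "RefinedProblem",
    "CcellResult",
    "infer_concentrations",
    "infer_network",
    "structural_indicator",
    "refine_problem",
    "infer_refined_concentrations",
    "infer_refined_network",
    "run_ccell",
]

#: smallest noise variance fed to the solvers, so that an advertised
#: "noiseless" run remains a valid Gaussian model
_NOISE_FLOOR = 1e-12


@dataclass
class RunConfig:
    """End-to-end settings for a pipeline run.

    ``network_noise_std`` is the working noise level of the row-wise
    transition regressions (Steps 2 and 3).  Their residuals contain not
    only system noise but also propagated concentration-estimation error,
    so the default ``None`` resolves to ``max(system_noise_std,
    10 * measurement_noise_std)`` — Step-1 errors scale with the
    measurement noise and are amplified by sparse recovery and by
    accumulation over time points.
    """

    bcs: BCSConfig = field(default_factory=BCSConfig)
    theta: float = 0.0
    measurement_noise_std: float = 0.01
    system_noise_std: float = 0.01
    network_noise_std: Optional[float] = None
    seed: int = 0

    def measurement_noise_variance(self) -> float:
        return max(self.measurement_noise_std**2, _NOISE_FLOOR)

    def system_noise_variance(self) -> float:
        return max(self.system_noise_std**2, _NOISE_FLOOR)

    def network_noise_variance(
        self, signal_scale: Optional[float] = None
    ) -> float:
        std = self.network_noise_std
        if std is None:
            std = max(self.system_noise_std, 10.0 * self.measurement_noise_std)
            if signal_scale is not None:
                # the working tolerance must stay well below the signal
                # scale (or the row regressions carry no information) but
                # above the floating-point rounding floor of the normal
                # equations, even for nominally noiseless inputs
                std = min(std, 0.1 * signal_scale)
                std = max(std, self.system_noise_std, 1e-6 * signal_scale)
        return max(std**2, _NOISE_FLOOR)


@dataclass
class ConcentrationEstimate:
    """Posterior concentrations per perturbation and time point.

    ``means`` is (P, T, N); ``covariances`` is (P, T, N, N), accumulated
    additively from the per-transition variation posteriors (cross-time
    independence assumed); t=0 equals the known initial state with zero
    covariance.  ``variation_posteriors[p][t]`` is the Step-1 sparse
    posterior of the variation between time t and t+1 (empty for the
    refined estimate, which is produced by linear regression instead).
    """

    means: np.ndarray
    covariances: np.ndarray
    variation_posteriors: list[list[SparsePosterior]] = field(default_factory=list)

    @property
    def n_perturbations(self) -> int:
        return self.means.shape[0]

    @property
    def n_time_points(self) -> int:
        return self.means.shape[1]

    @property
    def n_species(self) -> int:
        return self.means.shape[2]


@dataclass
class TransitionEstimate:
    """Row-wise posterior of the transition matrix.

    Rows are inferred independently; ``average_variance`` is the mean of the
    posterior variances over all matrix elements (pruned elements count as
    zero variance).
    """

    mean_matrix: np.ndarray
    row_covariances: list[np.ndarray]
    row_hyperparameters: list[np.ndarray]
    average_variance: float

    @property
    def variance_matrix(self) -> np.ndarray:
        return np.vstack([np.diag(c) for c in self.row_covariances])


@dataclass
class NetworkStructure:
    """Binary link calls at a threshold, with the active/silent partition."""

    indicator: np.ndarray
    threshold: float
    active_species: np.ndarray
    silent_species: np.ndarray


@dataclass
class RefinedProblem:
    """The reduced inference problem after silent-species removal."""

    active_design: np.ndarray  # (M', N')
    adjusted_observations: np.ndarray  # (P, T, M')
    active_initials: np.ndarray  # (P, N')
    prior_means: np.ndarray  # (P, T, N') from Step 1
    prior_covariances: np.ndarray  # (P, T, N', N') from Step 1
    active_species: np.ndarray
    kept_measurements: np.ndarray
    empty: bool = False


@dataclass
class CcellResult:
    """All artifacts of one end-to-end run."""

    step1: ConcentrationEstimate
    step2: TransitionEstimate
    structure: NetworkStructure
    refined: Optional[RefinedProblem]
    step3_conc: Optional[ConcentrationEstimate]
    step3_net: Optional[TransitionEstimate]
    config: RunConfig


def _design_matrix(design: MeasurementDesign | np.ndarray) -> np.ndarray:
    if isinstance(design, MeasurementDesign):
        return design.matrix
    return np.asarray(design, dtype=float)


# --------------------------------------------------------------------------
# Step 1


def infer_concentrations(
    design: MeasurementDesign | np.ndarray,
    observations: np.ndarray,
    initial_concentrations: np.ndarray,
    noise_variance: float,
    config: Optional[BCSConfig] = None,
) -> ConcentrationEstimate:
    """Recover concentrations from pooled observations, one transition at
    a time.

    For each perturbation and each adjacent pair of time points, the
    differenced system ``g_t - g_{t-1} = Phi delta_x + eps`` is solved by
    Bayesian compressive sensing (the difference of two independent
    measurement noises doubles the noise variance), and the sparse
    variation estimates are accumulated onto the known initial state.
    """
    config = config or BCSConfig()
    phi = _design_matrix(design)
    obs = np.asarray(observations, dtype=float)
    if obs.ndim == 2:
        obs = obs[None, :, :]
    x0 = np.atleast_2d(np.asarray(initial_concentrations, dtype=float))
    p, t, m = obs.shape
    if t < 2:
        raise ValueError("need at least two time points")
    if m != phi.shape[0]:
        raise ValueError("observation width does not match design rows")
    if np.any(~np.isfinite(obs)):
        bad = np.argwhere(~np.isfinite(obs).all(axis=2))
        raise ValueError(
            f"missing observation rows at (perturbation, time) = "
            f"{[tuple(map(int, b)) for b in bad[:5]]}"
        )
    n = phi.shape[1]
    diff_var = max(2.0 * float(noise_variance), _NOISE_FLOOR)
    means = np.empty((p, t, n))
    covs = np.zeros((p, t, n, n))
    posteriors: list[list[SparsePosterior]] = []
    for ip in range(p):
        means[ip, 0] = x0[ip]
        per_pert: list[SparsePosterior] = []
        for it in range(1, t):
            delta_g = obs[ip, it] - obs[ip, it - 1]
            post = bcs_estimate(
                SparseLinearProblem(phi, delta_g, diff_var), config
            )
            per_pert.append(post)
            means[ip, it] = means[ip, it - 1] + post.mean
            covs[ip, it] = covs[ip, it - 1] + post.covariance
        posteriors.append(per_pert)
    return ConcentrationEstimate(means, covs, posteriors)


# --------------------------------------------------------------------------
# Step 2


def infer_network(
    concentrations: ConcentrationEstimate,
    noise_variance: float,
    config: Optional[BCSConfig] = None,
) -> TransitionEstimate:
    """Row-wise sparse recovery of the transition matrix from concentration
    point estimates.

    All (perturbation, transition) pairs are stacked into one design whose
    rows are the concentration means at the source time points; each species'
    row of A is then an independent sparse-recovery problem.
    """
    config = config or BCSConfig()
    means = concentrations.means
    p, t, n = means.shape
    if t < 2:
        raise ValueError("need at least two time points")
    source = means[:, :-1, :].reshape(p * (t - 1), n)
    target = means[:, 1:, :].reshape(p * (t - 1), n)
    var = max(float(noise_variance), _NOISE_FLOOR)
    rows = np.empty((n, n))
    row_covs: list[np.ndarray] = []
    row_hyper: list[np.ndarray] = []
    total_var = 0.0
    for i in range(n):
        post = bcs_estimate(SparseLinearProblem(source, target[:, i], var), config)
        rows[i] = post.mean
        row_covs.append(post.covariance)
        row_hyper.append(post.hyperparameters)
        total_var += float(np.trace(post.covariance))
    return TransitionEstimate(rows, row_covs, row_hyper, total_var / (n * n))


# --------------------------------------------------------------------------
# Step 3


def structural_indicator(
    estimate: TransitionEstimate, threshold: float = 0.0
) -> NetworkStructure:
    """Binary link calls: off-diagonal ``|A_hat[i,j]| > theta``.

    Diagonal entries are compared against the identity value instead
    (``|A_hat[i,i] - 1| > theta``), so an unperturbed identity row never
    produces a self-link; diagonal deviations do not affect the
    silent/active partition, which counts off-diagonal links only.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    a = estimate.mean_matrix
    n = a.shape[0]
    indicator = (np.abs(a) > threshold).astype(np.int8)
    diag = np.abs(np.diag(a) - 1.0) > threshold
    indicator[np.diag_indices(n)] = diag.astype(np.int8)
    off = indicator.copy()
    off[np.diag_indices(n)] = 0
    linked = off.any(axis=0) | off.any(axis=1)
    return NetworkStructure(
        indicator=indicator,
        threshold=float(threshold),
        active_species=np.flatnonzero(linked),
        silent_species=np.flatnonzero(~linked),
    )


def refine_problem(
    structure: NetworkStructure,
    design: MeasurementDesign | np.ndarray,
    observations: np.ndarray,
    initial_concentrations: np.ndarray,
    step1: ConcentrationEstimate,
) -> RefinedProblem:
    """Reduce the inference problem to the active species.

    Silent species are held at their known initial concentration: their
    design-weighted contribution is subtracted from every observation, their
    columns leave the design, and measurements that pooled only silent
    species are dropped.  The Step-1 posterior restricted to the active
    species becomes the prior of the refined concentration inference.
    """
    phi = _design_matrix(design)
    obs = np.asarray(observations, dtype=float)
    if obs.ndim == 2:
        obs = obs[None, :, :]
    x0 = np.atleast_2d(np.asarray(initial_concentrations, dtype=float))
    n = phi.shape[1]
    if structure.indicator.shape[0] != n:
        raise ValueError("structure size does not match design columns")
    active = structure.active_species
    silent = structure.silent_species
    if active.size == 0:
        return RefinedProblem(
            active_design=np.zeros((0, 0)),
            adjusted_observations=np.zeros(obs.shape[:2] + (0,)),
            active_initials=np.zeros((x0.shape[0], 0)),
            prior_means=np.zeros(obs.shape[:2] + (0,)),
            prior_covariances=np.zeros(obs.shape[:2] + (0, 0)),
            active_species=active,
            kept_measurements=np.array([], dtype=int),
            empty=True,
        )
    reduced = phi[:, active]
    kept = np.flatnonzero(reduced.any(axis=1))
    reduced = reduced[kept]
    # constant contribution of silent species, per perturbation
    contrib = x0[:, silent] @ phi[np.ix_(kept, silent)].T  # (P, M')
    adjusted = obs[:, :, kept] - contrib[:, None, :]
    return RefinedProblem(
        active_design=reduced,
        adjusted_observations=adjusted,
        active_initials=x0[:, active],
        prior_means=step1.means[:, :, active],
        prior_covariances=step1.covariances[:, :, active[:, None], active[None, :]],
        active_species=active,
        kept_measurements=kept,
    )


def infer_refined_concentrations(
    problem: RefinedProblem, noise_variance: float
) -> ConcentrationEstimate:
    """Refined concentration posteriors by Bayesian linear regression.

    Refined variations are not sparse, so each (perturbation, time point)
    is a conjugate Gaussian update of the Step-1 prior under the reduced
    measurement model; singular Step-1 covariances receive a small diagonal
    jitter.  Initial time points keep the known state with zero covariance.
    """
    p, t, m = problem.adjusted_observations.shape
    n = problem.active_species.size
    means = np.empty((p, t, n))
    covs = np.zeros((p, t, n, n))
    var = max(float(noise_variance), _NOISE_FLOOR)
    for ip in range(p):
        means[ip, 0] = problem.active_initials[ip]
        for it in range(1, t):
            prior_cov = problem.prior_covariances[ip, it].copy()
            # a pruned Step-1 variation is an exact zero with zero reported
            # variance, but pruning only certifies the variation was below
            # the (differenced) noise level; without this floor the prior
            # is overconfident and blocks the refinement update
            floor = 2.0 * var * it
            prior_cov[np.diag_indices(n)] += max(
                floor, 1e-10 * np.trace(prior_cov) / max(n, 1)
            )
            if m == 0:
                means[ip, it] = problem.prior_means[ip, it]
                covs[ip, it] = prior_cov
                continue
            lin = SparseLinearProblem(
                problem.active_design, problem.adjusted_observations[ip, it], var
            )
            mean, cov = blr_posterior(
                lin, problem.prior_means[ip, it], prior_cov
            )
            means[ip, it] = mean
            covs[ip, it] = cov
    return ConcentrationEstimate(means, covs, [])


def infer_refined_network(
    refined_conc: ConcentrationEstimate,
    noise_variance: float,
    config: Optional[BCSConfig] = None,
    warm_start: Optional[list[np.ndarray]] = None,
) -> TransitionEstimate:
    """Reduced transition matrix by extended Bayesian compressive sensing.

    The design of each row problem is the Gaussian posterior of the refined
    concentrations at the source time points (means and covariances), so
    concentration uncertainty enters the expected regressor second moments
    instead of being discarded.  ``warm_start`` may carry per-row ARD
    hyperparameters (e.g. the Step-2 posteriors restricted to the active
    set): the row solvers then start from that basin directly instead of
    re-running the slow variational phase, which matters when few species
    were silenced and the reduced problem is still large.
    """
    config = config or BCSConfig()
    means = refined_conc.means
    covs = refined_conc.covariances
    p, t, n = means.shape
    if t < 2:
        raise ValueError("need at least two time points")
    design_post = DesignPosterior(
        column_means=means[:, :-1, :].reshape(p * (t - 1), n),
        column_covariances=covs[:, :-1, :, :].reshape(p * (t - 1), n, n),
    )
    target = means[:, 1:, :].reshape(p * (t - 1), n)
    var = max(float(noise_variance), _NOISE_FLOOR)
    rows = np.empty((n, n))
    row_covs: list[np.ndarray] = []
    row_hyper: list[np.ndarray] = []
    total_var = 0.0
    from dataclasses import replace as _replace

    for i in range(n):
        row_config = config
        if warm_start is not None:
            alpha0 = np.minimum(warm_start[i], config.prune_threshold * 2.0)
            alpha0 = np.maximum(alpha0, 1.0 / config.prune_threshold)
            row_config = _replace(config, update="mackay", alpha_init=alpha0)
        post = ext_bcs_estimate(design_post, target[:, i], var, row_config)
        rows[i] = post.mean
        row_covs.append(post.covariance)
        row_hyper.append(post.hyperparameters)
        total_var += float(np.trace(post.covariance))
    return TransitionEstimate(
        rows, row_covs, row_hyper, total_var / (n * n) if n else 0.0
    )


# --------------------------------------------------------------------------
# end-to-end


def run_ccell(
    design: MeasurementDesign | np.ndarray,
    observations: np.ndarray,
    initial_concentrations: np.ndarray,
    config: Optional[RunConfig] = None,
) -> CcellResult:
    """Execute Steps 1-3 and return every intermediate artifact.

    Deterministic given inputs and configuration.  If the structural
    indicator leaves no active species, the refinement stage is skipped and
    the corresponding fields are ``None``.
    """
    config = config or RunConfig()
    meas_var = config.measurement_noise_variance()
    step1 = infer_concentrations(
        design, observations, initial_concentrations, meas_var, config.bcs
    )
    signal_scale = float(np.sqrt(np.mean(step1.means**2)))
    net_var = config.network_noise_variance(signal_scale)
    step2 = infer_network(step1, net_var, config.bcs)
    structure = structural_indicator(step2, config.theta)
    if structure.active_species.size == 0:
        return CcellResult(step1, step2, structure, None, None, None, config)
    refined = refine_problem(
        structure, design, observations, initial_concentrations, step1
    )
    step3_conc = infer_refined_concentrations(refined, meas_var)
    active = structure.active_species
    warm = [
        step2.row_hyperparameters[i][active] for i in active
    ]
    step3_net = infer_refined_network(step3_conc, net_var, config.bcs, warm)
    return CcellResult(step1, step2, structure, refined, step3_conc, step3_net, config)
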