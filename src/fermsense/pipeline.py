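"""End-to-end soft-sensor orchestration and evaluation metrics.

Builds the full method from parts: per-source TCA adaptation toward the
unlabeled target condition, LSSVM sub-models with (gamma, sigma) tuned by
the goshawk optimizer against cross-validated RMSE on the embedded source
data, MIC centroids per subset, and the weighted ensemble prediction of the
target condition's cell and product concentrations.  ``run_study`` also
evaluates the ablation ladder (fixed-parameter LSSVM, NGO- and INGO-tuned
no-transfer models, single-source transfer models, equal-weight and
MIC-weighted ensembles) against the held-out target labels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Optional

import numpy as np

from .domain_adaptation import ConditionDataset, KernelSpec, fit_tca, transform
from .ensemble import EnsembleModel, SubModel, predict_ensemble_batch
from .lssvm import fit_lssvm, predict as lssvm_predict
from .mic_weighting import MICConfig, compute_centroid
from .optimizer import OptimizerConfig, SearchSpace, optimize
from .synthetic_data import SyntheticStudy

__all__ = [
    "PipelineConfig",
    "EvaluationReport",
    "rmse",
    "mae",
    "r2",
    "percentage_reduction",
    "train_submodel",
    "build_ensemble",
    "run_study",
]

TARGETS = ("cell", "product")


# --- metrics ----------------------------------------------------------------

def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean square error sqrt(mean((y_t - y_pre)^2))."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error mean(|y_t - y_pre|)."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.mean(np.abs(y_true - y_pred)))


def r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE / SST (SST about the true mean)."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    if y_true.size < 2:
        raise ValueError("r2 needs at least two observations")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise ValueError("r2 undefined for constant y_true")
    sse = float(np.sum((y_pred - y_true) ** 2))
    return 1.0 - sse / sst


def percentage_reduction(metric_a: float, metric_b: float) -> float:
    """Percent reduction 100 (a - b) / a of metric b relative to baseline a."""
    if not metric_a > 0:
        raise ValueError("baseline metric must be positive")
    return 100.0 * (metric_a - metric_b) / metric_a


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 1:
        raise ValueError("y_true and y_pred must be non-empty and equal length")
    return y_true, y_pred


# --- configuration ----------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the end-to-end study harness.

    Hyperparameter bounds are searched in log10 space.  The optimizer budget
    and the per-condition training subsample default to a modest size that
    keeps a full multi-seed ablation study at laptop scale; the adapted
    embedding and the tuned regressors are unchanged in character at larger
    budgets.
    """

    m_c: int = 2
    mu: float = 1.0
    kernel_kind: str = "rbf"
    log10_gamma_bounds: tuple[float, float] = (-2.0, 4.0)
    log10_sigma_bounds: tuple[float, float] = (-2.0, 2.0)
    pop_size: int = 10
    max_iter: int = 20
    variant: str = "ingo"
    cv_folds: int = 3
    max_train_samples: Optional[int] = 120
    mic: MICConfig = field(default_factory=MICConfig)
    theta_policy: str = "median"
    theta_value: Optional[float] = None
    seed: int = 0

    def optimizer_config(self, variant: Optional[str] = None, seed_offset: int = 0) -> OptimizerConfig:
        return OptimizerConfig(
            pop_size=self.pop_size,
            max_iter=self.max_iter,
            variant=variant or self.variant,
            seed=(self.seed + seed_offset) % (2**31 - 1),
        )

    def search_space(self) -> SearchSpace:
        return SearchSpace(
            lower=np.array([self.log10_gamma_bounds[0], self.log10_sigma_bounds[0]]),
            upper=np.array([self.log10_gamma_bounds[1], self.log10_sigma_bounds[1]]),
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _subsample(n: int, max_n: Optional[int]) -> np.ndarray:
    """Evenly strided row subset (deterministic, keeps the time coverage)."""
    if max_n is None or n <= max_n:
        return np.arange(n)
    return np.round(np.linspace(0, n - 1, max_n)).astype(int)


# --- hyperparameter fitness -------------------------------------------------

def make_cv_fitness(
    Z: np.ndarray, y: np.ndarray, folds: int
) -> Callable[[np.ndarray], float]:
    """K-fold cross-validated RMSE of an LSSVM at log10 (gamma, sigma).

    Folds are contiguous blocks of the (time-ordered) samples, so each
    validation block is a genuinely held-out stretch of the trajectory.
    Distance matrices are precomputed once per fold; each fitness call only
    re-exponentiates them, solves the dual system and scores the block.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    N = Z.shape[0]
    if folds < 2 or N // folds < 2:
        raise ValueError(f"cannot form {folds} folds of >= 2 samples from {N}")
    bounds = np.linspace(0, N, folds + 1).astype(int)
    cache = []
    from scipy.spatial.distance import cdist

    for f in range(folds):
        val = np.arange(bounds[f], bounds[f + 1])
        trn = np.setdiff1d(np.arange(N), val)
        cache.append(
            (
                cdist(Z[trn], Z[trn], "sqeuclidean"),
                cdist(Z[val], Z[trn], "sqeuclidean"),
                y[trn],
                y[val],
            )
        )

    from scipy.linalg import cho_factor, cho_solve

    def fitness(params: np.ndarray) -> float:
        gamma = 10.0 ** float(params[0])
        sigma = 10.0 ** float(params[1])
        sq_errs = 0.0
        n_val = 0
        for D_tt, D_vt, y_t, y_v in cache:
            n = y_t.size
            A = np.exp(-D_tt / (2.0 * sigma**2)) + np.eye(n) / gamma
            try:
                c = cho_factor(A)
            except np.linalg.LinAlgError:
                return 1e9  # numerically infeasible corner of the box
            ones = np.ones(n)
            u = cho_solve(c, ones)
            v = cho_solve(c, y_t)
            b = float(ones @ v) / float(ones @ u)
            alpha = v - b * u
            pred = np.exp(-D_vt / (2.0 * sigma**2)) @ alpha + b
            sq_errs += float(np.sum((pred - y_v) ** 2))
            n_val += y_v.size
        return float(np.sqrt(sq_errs / n_val))

    return fitness


def tune_lssvm(
    Z: np.ndarray,
    y: np.ndarray,
    config: PipelineConfig,
    variant: Optional[str] = None,
    seed_offset: int = 0,
):
    """INGO/NGO search over log10 (gamma, sigma); returns (model, run)."""
    fitness = make_cv_fitness(Z, y, config.cv_folds)
    run = optimize(fitness, config.search_space(), config.optimizer_config(variant, seed_offset))
    gamma = 10.0 ** float(run.best_x[0])
    sigma = 10.0 ** float(run.best_x[1])
    return fit_lssvm(Z, y, gamma, sigma), run


# --- sub-model and ensemble construction ------------------------------------

def train_submodel(
    source: ConditionDataset,
    target_features: np.ndarray,
    config: PipelineConfig,
    seed_offset: int = 0,
) -> SubModel:
    """One source condition -> (TCA map, tuned LSSVM per target, centroid)."""
    target_features = np.atleast_2d(np.asarray(target_features, dtype=float))
    if target_features.shape[0] == 0:
        raise ValueError("target features must be non-empty")
    idx_s = _subsample(source.n_samples, config.max_train_samples)
    idx_t = _subsample(target_features.shape[0], config.max_train_samples)
    Xs = source.features[idx_s]
    Xt = target_features[idx_t]

    kernel = None if config.kernel_kind == "rbf" else KernelSpec("linear")
    tca = fit_tca(Xs, Xt, kernel=kernel, m_c=min(config.m_c, Xs.shape[0] + Xt.shape[0] - 1), mu=config.mu)
    Zs = transform(tca, Xs)

    regressors = {}
    for k, target in enumerate(TARGETS):
        try:
            y = source.label(target)[idx_s]
        except ValueError:
            continue
        model, _ = tune_lssvm(Zs, y, config, seed_offset=seed_offset + 101 * (k + 1))
        regressors[target] = model
    if not regressors:
        raise ValueError(f"source {source.condition_id!r} carries no labels")

    centroid = compute_centroid(Xs, config.mic)
    return SubModel(
        condition_id=source.condition_id,
        tca=tca,
        regressors=regressors,
        centroid=centroid,
    )


def build_ensemble(study: SyntheticStudy, config: PipelineConfig) -> EnsembleModel:
    submodels = [
        train_submodel(src, study.target.features, config, seed_offset=17 * (i + 1))
        for i, src in enumerate(study.sources)
    ]
    return EnsembleModel(
        submodels=submodels,
        theta_policy=config.theta_policy,
        theta_value=config.theta_value,
        mic_config=config.mic,
    )


# --- study evaluation -------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-model, per-target metrics of one study run."""

    metrics: dict  # metrics[target][model] = {"rmse": .., "mae": .., "r2": ..}
    reductions: dict  # named percentage reductions between model pairs
    per_source_rmse: dict  # per-target list of single-source transfer RMSEs
    predictions: dict  # predictions[target][model] = list of floats
    seed: int
    config_hash: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "metrics": self.metrics,
                "reductions": self.reductions,
                "per_source_rmse": self.per_source_rmse,
                "seed": self.seed,
                "config_hash": self.config_hash,
            },
            indent=2,
        )


def _metric_block(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    return {
        "rmse": rmse(y_true, y_pred),
        "mae": mae(y_true, y_pred),
        "r2": r2(y_true, y_pred),
    }


def _pooled_no_transfer_data(study: SyntheticStudy, config: PipelineConfig):
    """Source-stratified pooled raw training data, z-scored by its own stats.

    The pooled set is capped at one condition's training size so every rung
    of the ablation ladder trains on a comparable number of samples.
    """
    cap = config.max_train_samples
    per = None if cap is None else max(2, cap // len(study.sources))
    Xs, yc, yp = [], [], []
    for src in study.sources:
        idx = _subsample(src.n_samples, per)
        Xs.append(src.features[idx])
        yc.append(src.label("cell")[idx])
        yp.append(src.label("product")[idx])
    X = np.vstack(Xs)
    mean, std = X.mean(axis=0), X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (X - mean) / std, {"cell": np.concatenate(yc), "product": np.concatenate(yp)}, mean, std


def run_study(study: SyntheticStudy, config: PipelineConfig) -> EvaluationReport:
    """Evaluate the ablation ladder on one synthetic multi-condition study.

    Models evaluated on the held-out target labels:

    - ``lssvm_fixed``: no transfer, mid-bounds (gamma, sigma);
    - ``ngo_lssvm`` / ``ingo_lssvm``: no transfer, tuned hyperparameters;
    - ``tca_single_mean`` / ``tca_single_best``: mean and best RMSE of the
      per-source TCA + INGO-LSSVM sub-models used alone;
    - ``equal_ensemble``: uniform average of all sub-models;
    - ``mic_ensemble``: MIC-score-weighted fusion of selected sub-models.
    """
    truth = study.target_truth
    Xt_full = study.target.features
    y_true = {t: truth.label(t) for t in TARGETS}

    metrics: dict = {t: {} for t in TARGETS}
    predictions: dict = {t: {} for t in TARGETS}
    reductions: dict = {}
    per_source_rmse: dict = {t: [] for t in TARGETS}

    # --- no-transfer rungs
    Xp, ys, mean, std = _pooled_no_transfer_data(study, config)
    Xt_scaled = (Xt_full - mean) / std
    mid_gamma = 10.0 ** np.mean(config.log10_gamma_bounds)
    mid_sigma = 10.0 ** np.mean(config.log10_sigma_bounds)
    for t in TARGETS:
        fixed = fit_lssvm(Xp, ys[t], mid_gamma, mid_sigma)
        pred = lssvm_predict(fixed, Xt_scaled)
        metrics[t]["lssvm_fixed"] = _metric_block(y_true[t], pred)
        predictions[t]["lssvm_fixed"] = pred.tolist()
        for variant, name in (("ngo", "ngo_lssvm"), ("ingo", "ingo_lssvm")):
            model, _ = tune_lssvm(Xp, ys[t], config, variant=variant,
                                  seed_offset=7 * (TARGETS.index(t) + 1))
            pred = lssvm_predict(model, Xt_scaled)
            metrics[t][name] = _metric_block(y_true[t], pred)
            predictions[t][name] = pred.tolist()

    # --- transfer sub-models and ensembles
    ensemble = build_ensemble(study, config)
    for t in TARGETS:
        single_preds = [sm.predict(Xt_full, t) for sm in ensemble.submodels]
        per_source_rmse[t] = [rmse(y_true[t], p) for p in single_preds]
        mean_rmse = float(np.mean(per_source_rmse[t]))
        best_i = int(np.argmin(per_source_rmse[t]))
        metrics[t]["tca_single_mean"] = {"rmse": mean_rmse}
        metrics[t]["tca_single_best"] = _metric_block(y_true[t], single_preds[best_i])
        predictions[t]["tca_single_best"] = single_preds[best_i].tolist()

        sub_preds = np.vstack(single_preds)
        eq = predict_ensemble_batch(
            Xt_full, ensemble, t, equal_weights=True, submodel_preds=sub_preds
        )
        wt = predict_ensemble_batch(Xt_full, ensemble, t, submodel_preds=sub_preds)
        metrics[t]["equal_ensemble"] = _metric_block(y_true[t], eq)
        metrics[t]["mic_ensemble"] = _metric_block(y_true[t], wt)
        predictions[t]["equal_ensemble"] = eq.tolist()
        predictions[t]["mic_ensemble"] = wt.tolist()

        m = metrics[t]
        reductions[f"{t}_ingo_vs_ngo"] = percentage_reduction(
            m["ngo_lssvm"]["rmse"], m["ingo_lssvm"]["rmse"]
        )
        reductions[f"{t}_mic_vs_single"] = percentage_reduction(
            m["tca_single_mean"]["rmse"], m["mic_ensemble"]["rmse"]
        )
        reductions[f"{t}_mic_vs_equal"] = percentage_reduction(
            m["equal_ensemble"]["rmse"], m["mic_ensemble"]["rmse"]
        )

    return EvaluationReport(
        metrics=metrics,
        reductions=reductions,
        per_source_rmse=per_source_rmse,
        predictions=predictions,
        seed=config.seed,
        config_hash=config.hash(),
    )
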