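"""Selection and weighted fusion of per-source-condition transfer sub-models.

Each sub-model couples one source condition's TCA map, its tuned LSSVM
regressors (one per target variable) and the MIC-derived weighted centroid
of the condition subset.  At prediction time a test sample is scored by MIC
against every centroid; sub-models whose score clears a threshold theta
(bounded inside [min score, max score]) are fused by score-normalized
weights:

    y* = sum_sel (w_q / sum w) f_q(x*)

The equal-weight variant (every sub-model, uniform weights) is the
benchmark the MIC weighting is compared against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .domain_adaptation import KernelSpec, TCAModel, transform
from .lssvm import LSSVMModel, predict as lssvm_predict
from .mic_weighting import CentroidResult, MICConfig, mic

__all__ = [
    "SubModel",
    "EnsembleModel",
    "score_submodels",
    "select_and_weight",
    "predict_ensemble",
    "predict_ensemble_batch",
    "save_ensemble",
    "load_ensemble",
]

BUNDLE_FORMAT_VERSION = 1


@dataclass
class SubModel:
    """One source condition's (TCA, per-target LSSVM, centroid) triple."""

    condition_id: str
    tca: TCAModel
    regressors: dict[str, LSSVMModel]
    centroid: CentroidResult

    def predict(self, X: np.ndarray, target: str) -> np.ndarray:
        if target not in self.regressors:
            raise ValueError(f"sub-model {self.condition_id!r} has no {target!r} regressor")
        Z = transform(self.tca, X)
        return lssvm_predict(self.regressors[target], Z)


@dataclass
class EnsembleModel:
    submodels: list[SubModel]
    theta_policy: str = "median"
    theta_value: Optional[float] = None
    mic_config: MICConfig = field(default_factory=MICConfig)
    scale_test_sample: bool = False

    def __post_init__(self) -> None:
        if len(self.submodels) < 1:
            raise ValueError("ensemble needs at least one sub-model")
        if self.theta_policy not in ("fixed", "median", "mean"):
            raise ValueError(f"unknown theta policy {self.theta_policy!r}")
        if self.theta_policy == "fixed" and self.theta_value is None:
            raise ValueError("fixed theta policy requires theta_value")


def score_submodels(x_star: np.ndarray, ensemble: EnsembleModel) -> np.ndarray:
    """MIC of the test sample against every sub-model's weighted centroid.

    The raw test sample's d channel values are paired with the centroid's
    (the literal reading; set ``scale_test_sample`` on the ensemble to apply
    each centroid's feature weights to the test sample symmetrically —
    MIC depends only on the orderings, so this rarely changes scores unless
    weights flip signs).
    """
    x_star = np.asarray(x_star, dtype=float).ravel()
    if x_star.size < 4:
        raise ValueError("test sample needs at least 4 channels for MIC")
    scores = np.empty(len(ensemble.submodels))
    for q, sm in enumerate(ensemble.submodels):
        x = x_star
        if ensemble.scale_test_sample:
            x = sm.centroid.feature_weights * x_star
        scores[q] = mic(x, sm.centroid.weighted_centroid, ensemble.mic_config)
    return scores


def select_and_weight(
    O: np.ndarray, theta_policy: str = "median", theta_value: Optional[float] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold the correlation set and normalize the surviving scores.

    theta is clamped into [min(O), max(O)], so at least the argmax set
    always survives.  Returns (selected indices, weights summing to 1).
    """
    O = np.asarray(O, dtype=float).ravel()
    if O.size == 0:
        raise ValueError("empty correlation set")
    if theta_policy == "median":
        theta = float(np.median(O))
    elif theta_policy == "mean":
        theta = float(np.mean(O))
    elif theta_policy == "fixed":
        if theta_value is None:
            raise ValueError("fixed theta policy requires theta_value")
        theta = float(theta_value)
    else:
        raise ValueError(f"unknown theta policy {theta_policy!r}")
    theta = min(max(theta, float(O.min())), float(O.max()))
    selected = np.flatnonzero(O >= theta)
    w = O[selected]
    total = w.sum()
    weights = np.full(selected.size, 1.0 / selected.size) if total == 0 else w / total
    return selected, weights


def predict_ensemble(
    x_star: np.ndarray,
    ensemble: EnsembleModel,
    target: str,
    equal_weights: bool = False,
) -> float:
    """Weighted fusion of the selected sub-models' predictions for one sample.

    ``equal_weights=True`` bypasses selection and averages every sub-model
    uniformly (the benchmark ensemble).
    """
    x_star = np.asarray(x_star, dtype=float).ravel()
    preds = np.array(
        [float(sm.predict(x_star[None, :], target)[0]) for sm in ensemble.submodels]
    )
    if equal_weights:
        return float(np.mean(preds))
    O = score_submodels(x_star, ensemble)
    selected, weights = select_and_weight(
        O, ensemble.theta_policy, ensemble.theta_value
    )
    return float(np.sum(weights * preds[selected]))


def predict_ensemble_batch(
    X: np.ndarray,
    ensemble: EnsembleModel,
    target: str,
    equal_weights: bool = False,
    submodel_preds: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Row-wise ensemble predictions; equals :func:`predict_ensemble` per row.

    Sub-model predictions (q x n) can be passed in when already computed —
    each sub-model's TCA transform and kernel evaluation then run once for
    the whole batch instead of once per sample.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if submodel_preds is None:
        submodel_preds = np.vstack(
            [sm.predict(X, target) for sm in ensemble.submodels]
        )
    if equal_weights:
        return submodel_preds.mean(axis=0)
    out = np.empty(X.shape[0])
    for i, x in enumerate(X):
        O = score_submodels(x, ensemble)
        selected, weights = select_and_weight(
            O, ensemble.theta_policy, ensemble.theta_value
        )
        out[i] = float(np.sum(weights * submodel_preds[selected, i]))
    return out


# --- serialization ----------------------------------------------------------

def save_ensemble(ensemble: EnsembleModel, path: str | Path) -> None:
    """Write a versioned bundle: JSON metadata + one npz of arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "theta_policy": ensemble.theta_policy,
        "theta_value": ensemble.theta_value,
        "scale_test_sample": ensemble.scale_test_sample,
        "mic_config": {
            "b_exponent": ensemble.mic_config.b_exponent,
            "min_bins": ensemble.mic_config.min_bins,
            "max_bins": ensemble.mic_config.max_bins,
            "exact_threshold": ensemble.mic_config.exact_threshold,
        },
        "submodels": [],
    }
    arrays: dict[str, np.ndarray] = {}
    for q, sm in enumerate(ensemble.submodels):
        sm_meta = {
            "condition_id": sm.condition_id,
            "kernel_kind": sm.tca.kernel.kind,
            "kernel_sigma": sm.tca.kernel.sigma,
            "m_c": sm.tca.m_c,
            "mu": sm.tca.mu,
            "n_source": sm.tca.n_source,
            "n_target": sm.tca.n_target,
            "centroid_index": sm.centroid.index_k,
            "targets": {},
        }
        arrays[f"sm{q}_pool"] = sm.tca.fit_pool
        arrays[f"sm{q}_W"] = sm.tca.W
        arrays[f"sm{q}_scaler_mean"] = sm.tca.scaler_mean
        arrays[f"sm{q}_scaler_std"] = sm.tca.scaler_std
        arrays[f"sm{q}_raw_centroid"] = sm.centroid.raw_centroid
        arrays[f"sm{q}_feature_weights"] = sm.centroid.feature_weights
        arrays[f"sm{q}_weighted_centroid"] = sm.centroid.weighted_centroid
        for t, reg in sm.regressors.items():
            sm_meta["targets"][t] = {
                "gamma": reg.gamma,
                "sigma": reg.sigma,
                "b": reg.b,
            }
            arrays[f"sm{q}_{t}_X"] = reg.X_train
            arrays[f"sm{q}_{t}_alpha"] = reg.alpha
        meta["submodels"].append(sm_meta)
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "arrays.npz", **arrays)


def load_ensemble(path: str | Path) -> EnsembleModel:
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    if meta["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(f"unsupported bundle version {meta['format_version']}")
    data = np.load(path / "arrays.npz")
    submodels = []
    for q, sm_meta in enumerate(meta["submodels"]):
        tca = TCAModel(
            fit_pool=data[f"sm{q}_pool"],
            kernel=KernelSpec(sm_meta["kernel_kind"], sm_meta["kernel_sigma"]),
            W=data[f"sm{q}_W"],
            m_c=sm_meta["m_c"],
            mu=sm_meta["mu"],
            scaler_mean=data[f"sm{q}_scaler_mean"],
            scaler_std=data[f"sm{q}_scaler_std"],
            n_source=sm_meta["n_source"],
            n_target=sm_meta["n_target"],
        )
        regressors = {
            t: LSSVMModel(
                X_train=data[f"sm{q}_{t}_X"],
                alpha=data[f"sm{q}_{t}_alpha"],
                b=tm["b"],
                gamma=tm["gamma"],
                sigma=tm["sigma"],
            )
            for t, tm in sm_meta["targets"].items()
        }
        centroid = CentroidResult(
            index_k=sm_meta["centroid_index"],
            raw_centroid=data[f"sm{q}_raw_centroid"],
            feature_weights=data[f"sm{q}_feature_weights"],
            weighted_centroid=data[f"sm{q}_weighted_centroid"],
        )
        submodels.append(
            SubModel(
                condition_id=sm_meta["condition_id"],
                tca=tca,
                regressors=regressors,
                centroid=centroid,
            )
        )
    mic_cfg = MICConfig(**meta["mic_config"])
    return EnsembleModel(
        submodels=submodels,
        theta_policy=meta["theta_policy"],
        theta_value=meta["theta_value"],
        mic_config=mic_cfg,
        scale_test_sample=meta["scale_test_sample"],
    )
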