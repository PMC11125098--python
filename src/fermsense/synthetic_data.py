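"""Synthetic multi-condition fed-batch fermentation data.

Emulates the data shapes of a *Pichia pastoris* fed-batch campaign: per
batch, 180 samples at a 0.5 h cadence over a 90 h cycle; six auxiliary
sensor channels (stirring speed v, temperature T, airflow q, pH, dissolved
oxygen Do, head pressure P) inside standard operating ranges, and two label
channels (cell concentration X and product concentration P, g/L).

Latent kinetics are the minimal standard abstraction that reproduces
sigmoidal fermentation trajectories: logistic growth

    dX/dt = mu_max X (1 - X / X_max)

with Luedeking-Piret product formation dP/dt = alpha dX/dt + beta X,
integrated by fixed-step Euler on the sampling grid.  Auxiliary channels
are driven by the latent biomass (airflow and stirring ramp up with demand,
dissolved oxygen declines as a saturating function of biomass, pH drifts
slightly acidic) plus measurement noise.

A "working condition" is a perturbation of this base process: multiplicative
tweaks of the kinetic parameters plus per-channel affine sensor calibration
shifts — the covariate-shift structure that motivates transfer learning
between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .domain_adaptation import ConditionDataset

__all__ = [
    "KineticParams",
    "ConditionShift",
    "SyntheticStudy",
    "simulate_batch",
    "make_multicondition_study",
    "write_study",
    "read_condition_csv",
    "load_study",
]

logger = logging.getLogger(__name__)

N_SAMPLES = 180  # 90 h cycle sampled every 0.5 h, t = 0.5 .. 90.0
DT_H = 0.5
CSV_COLUMNS = ["time_h", "v_rpm", "T_C", "q_Lmin", "pH", "DO_pct", "P_MPa", "X_gL", "P_gL"]

# physically plausible clip bounds per observed channel (order v,T,q,Ph,Do,P)
_CLIP_LO = np.array([250.0, 20.0, 100.0, 3.5, 0.0, 0.005])
_CLIP_HI = np.array([450.0, 35.0, 350.0, 7.0, 120.0, 0.08])

# per-channel scales used when drawing condition shifts: a unit-scale shift
# moves offsets by a few percent of each channel's working range.  Conditions
# differ mainly through sensor calibration (covariate shift of the feature
# marginals); kinetic perturbations are kept mild so the feature-label
# relation remains shared across conditions — the premise of transfer.
_OFFSET_SCALE = np.array([8.0, 0.4, 12.0, 0.08, 3.0, 0.0025])
_NOISE_SD = np.array([1.5, 0.05, 2.5, 0.015, 0.8, 0.0006])


@dataclass(frozen=True)
class KineticParams:
    """Base kinetic parameters of the latent batch trajectories."""

    mu_max: float = 0.12  # 1/h
    X_max: float = 110.0  # g/L carrying capacity
    alpha_lp: float = 0.05  # growth-associated product yield
    beta_lp: float = 0.002  # non-growth-associated rate, 1/h
    X0: float = 1.0  # g/L inoculum
    P0: float = 0.0  # g/L

    def __post_init__(self) -> None:
        for name in ("mu_max", "X_max", "alpha_lp", "beta_lp", "X0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.P0 < 0:
            raise ValueError("P0 must be nonnegative")
        if not self.X0 < self.X_max:
            raise ValueError("X0 must be below the carrying capacity")


@dataclass(frozen=True)
class ConditionShift:
    """One working condition's deviation from the base process."""

    kinetic_factors: dict = field(default_factory=dict)
    sensor_offsets: np.ndarray = field(default_factory=lambda: np.zeros(6))
    sensor_gains: np.ndarray = field(default_factory=lambda: np.ones(6))
    noise_sd: np.ndarray = field(default_factory=lambda: _NOISE_SD.copy())

    def __post_init__(self) -> None:
        for name in ("sensor_offsets", "sensor_gains", "noise_sd"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.sensor_gains <= 0):
            raise ValueError("sensor gains must be positive")
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be nonnegative")

    def apply_kinetics(self, params: KineticParams) -> KineticParams:
        changes = {
            name: getattr(params, name) * factor
            for name, factor in self.kinetic_factors.items()
        }
        return replace(params, **changes)


def _latent_trajectories(params: KineticParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euler-integrated latent (t, X, P) on the 0.5 h sampling grid."""
    t = DT_H * np.arange(1, N_SAMPLES + 1)
    X = np.empty(N_SAMPLES)
    P = np.empty(N_SAMPLES)
    x, p = params.X0, params.P0
    for k in range(N_SAMPLES):
        dx = DT_H * params.mu_max * x * (1.0 - x / params.X_max)
        p = p + params.alpha_lp * dx + DT_H * params.beta_lp * x
        x = x + dx
        X[k] = x
        P[k] = p
    return t, X, P


def simulate_batch(
    params: KineticParams = KineticParams(),
    shift: ConditionShift = ConditionShift(),
    seed: int = 0,
    condition_id: str = "batch",
) -> ConditionDataset:
    """Simulate one 90 h batch (180 rows) under a working-condition shift.

    Labels are the noiseless latent concentrations; the observed auxiliary
    channels get the shift's gains, offsets and Gaussian measurement noise,
    then are clipped to plausible physical bounds (clip events are logged).
    """
    rng = np.random.default_rng(seed)
    p_eff = shift.apply_kinetics(params)
    t, X, P = _latent_trajectories(p_eff)
    frac = X / p_eff.X_max  # biomass fraction drives the auxiliary channels

    v = 300.0 + 100.0 * frac**0.8 + 3.0 * np.sin(2.0 * np.pi * t / 24.0)
    T = 28.0 + 0.4 * np.sin(2.0 * np.pi * t / 30.0) + 0.3 * frac
    q = 150.0 + 150.0 * frac
    ph = 5.0 - 0.25 * frac + 0.05 * np.sin(2.0 * np.pi * t / 40.0)
    do = 100.0 * (1.0 - 0.7 * frac)  # saturating decline with biomass
    pr = 0.02 + 0.025 * frac + 0.003 * np.sin(2.0 * np.pi * t / 36.0)

    clean = np.column_stack([v, T, q, ph, do, pr])
    noise = rng.standard_normal(clean.shape) * shift.noise_sd
    observed = clean * shift.sensor_gains + shift.sensor_offsets + noise
    clipped = np.clip(observed, _CLIP_LO, _CLIP_HI)
    n_clipped = int(np.sum(clipped != observed))
    if n_clipped:
        logger.info("condition %s: clipped %d sensor readings", condition_id, n_clipped)

    return ConditionDataset(
        features=clipped,
        labels_cell=X,
        labels_product=P,
        condition_id=condition_id,
        time_h=t,
    )


def _draw_shift(rng: np.random.Generator, scale: float) -> ConditionShift:
    """A random working-condition shift; ``scale`` multiplies every deviation."""
    if scale == 0:
        return ConditionShift()
    kin = {
        name: float(np.exp(scale * sd * rng.standard_normal()))
        for name, sd in (
            ("mu_max", 0.03),
            ("X_max", 0.02),
            ("alpha_lp", 0.03),
            ("beta_lp", 0.03),
        )
    }
    gains = np.exp(scale * 0.08 * rng.standard_normal(6))
    offsets = scale * _OFFSET_SCALE * rng.standard_normal(6)
    return ConditionShift(kinetic_factors=kin, sensor_offsets=offsets, sensor_gains=gains)


@dataclass
class SyntheticStudy:
    """A generated multi-condition study: labeled sources, unlabeled target,
    and the target's held-out labels for evaluation only."""

    sources: list[ConditionDataset]
    target: ConditionDataset
    target_truth: ConditionDataset
    seed: int = 0


def make_multicondition_study(
    q_sources: int = 3,
    target_shift_scale: float = 1.5,
    seed: int = 0,
    params: KineticParams = KineticParams(),
) -> SyntheticStudy:
    """Generate ``q_sources`` labeled conditions plus one unlabeled target.

    Source 0 is the unshifted reference condition; the remaining sources get
    distinct moderate shifts (unit scale).  The target condition's shift is
    drawn at ``target_shift_scale``; at 0 the target distribution coincides
    with source 0 (only the noise realization differs).  The returned target
    dataset carries no labels; the truth is returned separately.
    """
    if q_sources < 1:
        raise ValueError("q_sources must be >= 1")
    rng = np.random.default_rng(seed)
    sources = []
    for i in range(q_sources):
        shift = ConditionShift() if i == 0 else _draw_shift(rng, 1.0)
        sources.append(
            simulate_batch(
                params,
                shift,
                seed=int(rng.integers(0, 2**31 - 1)),
                condition_id=f"source_{i}",
            )
        )
    target_shift = _draw_shift(rng, target_shift_scale)
    truth = simulate_batch(
        params, target_shift, seed=int(rng.integers(0, 2**31 - 1)), condition_id="target"
    )
    target = ConditionDataset(
        features=truth.features.copy(),
        condition_id="target",
        time_h=truth.time_h.copy(),
    )
    return SyntheticStudy(sources=sources, target=target, target_truth=truth, seed=seed)


# --- on-disk study format ---------------------------------------------------

def _to_frame(ds: ConditionDataset, with_labels: bool) -> pd.DataFrame:
    df = pd.DataFrame(ds.features, columns=CSV_COLUMNS[1:7])
    df.insert(0, "time_h", ds.time_h if ds.time_h is not None else np.arange(ds.n_samples))
    if with_labels and ds.labels_cell is not None:
        df["X_gL"] = ds.labels_cell
        df["P_gL"] = ds.labels_product
    return df


def write_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write per-condition CSVs and a YAML manifest; returns the manifest path.

    The target's CSV holds features only; its held-out labels go to a
    separate truth CSV referenced by the manifest for evaluation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": study.seed, "sources": [], "target": {}, "held_out": {}}
    for src in study.sources:
        fname = f"{src.condition_id}.csv"
        _to_frame(src, with_labels=True).to_csv(out / fname, index=False)
        manifest["sources"].append({"condition_id": src.condition_id, "file": fname})
    _to_frame(study.target, with_labels=False).to_csv(out / "target.csv", index=False)
    manifest["target"] = {"condition_id": "target", "file": "target.csv"}
    _to_frame(study.target_truth, with_labels=True).to_csv(out / "target_truth.csv", index=False)
    manifest["held_out"] = {"file": "target_truth.csv", "labels": ["X_gL", "P_gL"]}
    manifest_path = out / "study.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_condition_csv(path: str | Path, condition_id: Optional[str] = None) -> ConditionDataset:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return ConditionDataset(
        features=df[CSV_COLUMNS[1:7]].to_numpy(),
        labels_cell=df["X_gL"].to_numpy() if "X_gL" in df else None,
        labels_product=df["P_gL"].to_numpy() if "P_gL" in df else None,
        condition_id=condition_id or Path(path).stem,
        time_h=df["time_h"].to_numpy(),
    )


def load_study(manifest_path: str | Path) -> SyntheticStudy:
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    sources = [
        read_condition_csv(base / s["file"], s["condition_id"])
        for s in manifest["sources"]
    ]
    target = read_condition_csv(base / manifest["target"]["file"], "target")
    truth = read_condition_csv(base / manifest["held_out"]["file"], "target")
    return SyntheticStudy(
        sources=sources, target=target, target_truth=truth, seed=manifest.get("seed", 0)
    )
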