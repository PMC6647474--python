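"""Pony-level cross-validated ensemble regression of cartilage properties.

For each reference property an independent model family is trained under
fivefold animal-level cross-validation: ponies are ranked by their mean
target value and fold k holds out the ponies of rank k and k + n/2 for
validation, so calibration and validation never share an animal and both
span the value range.  Targets are range-scaled to [0, 1] and spectra
standardized per feature on calibration data only.  Per fold the ensemble
has six members -- a 1-D convolutional and a dense architecture, each
initialized from the three fixed seeds 7, 14, 21 -- trained with Adam on
mean squared error, early stopping on validation RMSE and plateau learning
rate reduction; the ensemble prediction is the arithmetic mean of the six
members, mapped back to physical units.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .core import AlignmentError, ConfigurationError, NirscartError
from . import nnet


class ShapeError(NirscartError, ValueError):
    pass


class DegenerateScalingError(NirscartError, ValueError):
    pass


N_FOLDS = 5
MEMBER_SEEDS = (7, 14, 21)


# ---------------------------------------------------------------------------
# fold plan

@dataclass(frozen=True)
class FoldPlan:
    """Animal-level validation pairs per fold for one target."""

    target: str
    validation: tuple[tuple[str, ...], ...]  # per fold
    calibration: tuple[tuple[str, ...], ...]

    @property
    def n_folds(self) -> int:
        return len(self.validation)


def make_folds(pony_mean_targets: Mapping[str, float], target: str = "") -> FoldPlan:
    """Rank-paired fold plan: fold k validates ponies of rank k and k + 5.

    Ponies are sorted ascending by their mean target value (ties broken by
    pony identifier), so each validation pair spans the value range.  With
    the 10-pony cohort this is the 1-6, 2-7, ... pairing; other cohort
    sizes generalize by round-robin over the ranking (fold k holds out
    ranks k, k+5, k+10, ...), which keeps the validation sets disjoint and
    covering for any n >= 5 and reduces to the paired scheme at n = 10.
    """
    ids = list(pony_mean_targets)
    if len(set(ids)) != len(ids):
        raise KeyError("duplicate pony ids")
    if len(ids) < N_FOLDS:
        raise ConfigurationError(f"need at least {N_FOLDS} ponies, got {len(ids)}")
    ranked = sorted(ids, key=lambda p: (float(pony_mean_targets[p]), p))
    n = len(ranked)
    validation, calibration = [], []
    for k in range(N_FOLDS):
        val = tuple(ranked[r] for r in range(k, n, N_FOLDS))
        validation.append(val)
        calibration.append(tuple(p for p in ranked if p not in val))
    return FoldPlan(target, tuple(validation), tuple(calibration))


# ---------------------------------------------------------------------------
# scaling

@dataclass
class ScalerParams:
    """Calibration-set scaling: targets to [0, 1], spectra standardized."""

    target_min: float
    target_max: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def apply_target(self, y) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.target_min) / (
            self.target_max - self.target_min
        )

    def invert_target(self, y) -> np.ndarray:
        return np.asarray(y, dtype=float) * (
            self.target_max - self.target_min
        ) + self.target_min

    def apply_spectra(self, x) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.feature_mean) / self.feature_sd

    @property
    def target_range(self) -> float:
        return self.target_max - self.target_min


def fit_scalers(targets: np.ndarray, spectra: np.ndarray) -> ScalerParams:
    """Fit target range scaling and per-feature spectral standardization.

    Statistics come from calibration data only.  Constant spectral features
    get unit spread (they carry no information and map to zero); a constant
    target cannot be range-scaled and raises.
    """
    y = np.asarray(targets, dtype=float).reshape(-1, 1)
    X = np.asarray(spectra, dtype=float)
    if y.size == 0 or X.shape[0] == 0:
        raise ConfigurationError("empty calibration set")
    mm = MinMaxScaler().fit(y)
    t_min, t_max = float(mm.data_min_[0]), float(mm.data_max_[0])
    if t_max <= t_min:
        raise DegenerateScalingError("constant target cannot be range-scaled")
    ss = StandardScaler().fit(X)
    sd = np.sqrt(ss.var_)
    sd[sd == 0.0] = 1.0
    return ScalerParams(t_min, t_max, ss.mean_.copy(), sd)


# ---------------------------------------------------------------------------
# architectures and training configuration

CONV = "conv"
DENSE = "dense"


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer constants of the two ensemble architectures."""

    variant: str
    conv_kernels: tuple[int, int] = (8, 64)
    conv_filters: tuple[int, int] = (64, 16)
    conv_dropout: float = 0.75
    conv_dense: int = 128
    dense_units: tuple[int, int, int] = (120, 60, 15)
    dense_dropout: float = 0.20

    def __post_init__(self) -> None:
        if self.variant not in (CONV, DENSE):
            raise ConfigurationError(f"unknown architecture variant {self.variant!r}")

    @property
    def min_input_length(self) -> int:
        if self.variant == CONV:
            # two valid convolutions must leave at least one position
            return sum(self.conv_kernels) - len(self.conv_kernels)
        return 1


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol shared by all ensemble members.

    Patience values, seeds, loss and the monitored quantity follow the
    measurement protocol; learning-rate constants, batch size and the epoch
    cap are conventional defaults and freely configurable.
    """

    seeds: tuple[int, ...] = MEMBER_SEEDS
    early_stop_patience: int = 25
    lr_patience: int = 20
    lr_factor: float = 0.5
    learning_rate: float = 1e-3
    min_lr: float = 1e-5
    max_epochs: int = 500
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.lr_patience >= self.early_stop_patience:
            raise ConfigurationError(
                "learning-rate patience must be smaller than early-stop patience"
            )
        if not self.seeds:
            raise ConfigurationError("need at least one member seed")


#: epoch-reduced profile used by the end-to-end pipeline default
REDUCED_TRAIN_CONFIG = TrainConfig(
    early_stop_patience=5, lr_patience=3, max_epochs=10
)


def build_model(
    spec: ArchitectureSpec, input_length: int, seed: int
) -> nnet.Sequential:
    """Untrained single-output network with deterministic seeded weights."""
    if input_length < max(spec.min_input_length + 1, 2):
        raise ShapeError(
            f"input length {input_length} too short for the {spec.variant} variant"
        )
    rng = np.random.default_rng(seed)
    if spec.variant == CONV:
        k1, k2 = spec.conv_kernels
        f1, f2 = spec.conv_filters
        l1 = input_length - k1 + 1
        l2 = l1 - k2 + 1
        return nnet.Sequential([
            nnet.Reshape3D(),
            nnet.Conv1D(1, f1, k1, rng, needs_input_grad=False),
            nnet.ReLU(),
            nnet.Conv1D(f1, f2, k2, rng),
            nnet.ReLU(),
            nnet.Flatten(),
            nnet.Dropout(spec.conv_dropout),
            nnet.Dense(l2 * f2, spec.conv_dense, rng),
            nnet.ReLU(),
            nnet.Dense(spec.conv_dense, 1, rng),
        ])
    u1, u2, u3 = spec.dense_units
    return nnet.Sequential([
        nnet.Dense(input_length, u1, rng),
        nnet.Sigmoid(),
        nnet.Dense(u1, u2, rng),
        nnet.ReLU(),
        nnet.Dropout(spec.dense_dropout),
        nnet.Dense(u2, u3, rng),
        nnet.ReLU(),
        nnet.Dense(u3, 1, rng),
    ])


@dataclass
class EnsembleMember:
    architecture: str
    seed: int
    model: nnet.Sequential
    history: nnet.TrainingHistory


@dataclass
class EnsembleModel:
    """Six trained members plus the fold's scalers and provenance."""

    target: str
    fold_id: int
    scalers: ScalerParams
    members: list[EnsembleMember]

    def member_predictions(self, spectra: np.ndarray) -> np.ndarray:
        """(n_members, n_spectra) member outputs in scaled units."""
        X = self.scalers.apply_spectra(spectra).astype(np.float32)
        return np.stack([m.model.predict(X) for m in self.members])

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        """Ensemble prediction in physical units: member mean, inverse-scaled."""
        X = np.asarray(spectra, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.scalers.feature_mean.size:
            raise AlignmentError(
                "spectra do not match the feature grid this ensemble was trained on"
            )
        return self.scalers.invert_target(
            self.member_predictions(X).mean(axis=0)
        )


def train_member(
    spec: ArchitectureSpec,
    x_cal: np.ndarray,
    y_cal: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    seed: int,
    name: str = "",
) -> EnsembleMember:
    model = build_model(spec, x_cal.shape[1], seed)
    history = nnet.train(
        model, x_cal, y_cal, x_val, y_val,
        max_epochs=config.max_epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        early_stop_patience=config.early_stop_patience,
        lr_patience=config.lr_patience,
        lr_factor=config.lr_factor,
        min_lr=config.min_lr,
        seed=seed,
        member_name=name or f"{spec.variant}/seed{seed}",
    )
    return EnsembleMember(spec.variant, seed, model, history)


def train_ensemble(
    x_cal: np.ndarray,
    y_cal: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    target: str,
    fold_id: int,
    config: TrainConfig = TrainConfig(),
) -> EnsembleModel:
    """Train the six-member ensemble of one fold for one target.

    Inputs are unscaled: scalers are fitted here on the calibration rows
    (which already include every in-vitro repeat as its own row -- the
    repeat-level augmentation) and stored with the ensemble.
    """
    scalers = fit_scalers(y_cal, x_cal)
    xc = scalers.apply_spectra(x_cal).astype(np.float32)
    yc = scalers.apply_target(y_cal)
    xv = scalers.apply_spectra(x_val).astype(np.float32)
    yv = scalers.apply_target(y_val)
    members = [
        train_member(
            ArchitectureSpec(variant), xc, yc, xv, yv, config, seed,
            name=f"{target}/fold{fold_id}/{variant}/seed{seed}",
        )
        for variant in (CONV, DENSE)
        for seed in config.seeds
    ]
    return EnsembleModel(target, fold_id, scalers, members)


# ---------------------------------------------------------------------------
# persistence: weights as .npz, scalers and provenance as JSON

def save_ensemble(model: EnsembleModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "target": model.target,
        "fold_id": model.fold_id,
        "scalers": {
            "target_min": model.scalers.target_min,
            "target_max": model.scalers.target_max,
        },
        "members": [
            {"architecture": m.architecture, "seed": m.seed,
             "best_epoch": m.history.best_epoch}
            for m in model.members
        ],
        "input_length": int(model.scalers.feature_mean.size),
    }
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))
    np.savez_compressed(
        directory / "scalers.npz",
        feature_mean=model.scalers.feature_mean,
        feature_sd=model.scalers.feature_sd,
    )
    for i, m in enumerate(model.members):
        np.savez_compressed(
            directory / f"member_{i}.npz",
            **{f"w{j:03d}": w for j, w in enumerate(m.model.get_weights())},
        )
    return directory


def load_ensemble(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    sc = np.load(directory / "scalers.npz")
    scalers = ScalerParams(
        meta["scalers"]["target_min"], meta["scalers"]["target_max"],
        sc["feature_mean"], sc["feature_sd"],
    )
    members = []
    for i, m in enumerate(meta["members"]):
        model = build_model(
            ArchitectureSpec(m["architecture"]), meta["input_length"], m["seed"]
        )
        data = np.load(directory / f"member_{i}.npz")
        model.set_weights([data[k] for k in sorted(data.files)])
        hist = nnet.TrainingHistory(best_epoch=m["best_epoch"])
        members.append(EnsembleMember(m["architecture"], m["seed"], model, hist))
    return EnsembleModel(meta["target"], meta["fold_id"], scalers, members)
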