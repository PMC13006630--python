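"""Traditional (centralized) machine-learning baseline.

Participant-wise k-fold cross-validation with an 80/10/10
train/validation/test participant split per fold: preprocessing is fitted
on the training participants only, early stopping monitors the validation
participants' MAE, and the test participants' predictions — inverse-scaled
back to the 0-132 clinical scale — are pooled over folds for the headline
metrics (per-fold metrics are reported alongside).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MODEL_FEATURES
from .metrics import AgreementReport, agreement_report, mae
from .nn import (
    ModelWeights,
    NetworkSpec,
    TrainingConfig,
    default_network_spec,
    init_weights,
    predict,
    train,
)
from .preprocess import (
    FoldAssignment,
    PreprocessState,
    carry_forward_bmi,
    fit_preprocess,
    inverse_scale_target,
    participant_kfold,
    scale_target,
    transform,
)

__all__ = ["FoldResult", "CentralizedResult", "run_traditional", "mean_baseline_mae"]


@dataclass
class FoldResult:
    """One fold's test predictions (0-132 scale) and fitted artifacts."""

    fold_index: int
    predictions: pd.DataFrame  # participant_id, visit_month, day_index, y_true, y_pred
    preprocess_state: PreprocessState
    weights: ModelWeights
    history: pd.DataFrame | None = None


@dataclass
class CentralizedResult:
    fold_results: list[FoldResult]
    pooled: AgreementReport
    per_fold_mae: dict[int, float]

    @property
    def predictions(self) -> pd.DataFrame:
        frames = []
        for fr in self.fold_results:
            df = fr.predictions.copy()
            df["fold"] = fr.fold_index
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _subset(df: pd.DataFrame, participants) -> pd.DataFrame:
    return df[df["participant_id"].isin(set(participants))]


def run_traditional(
    dataset: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    spec: NetworkSpec | None = None,
    training: TrainingConfig | None = None,
    folds: list[FoldAssignment] | None = None,
    folds_to_run: int | None = None,
) -> CentralizedResult:
    """Run the centralized baseline; returns pooled and per-fold results.

    ``folds_to_run`` limits execution to the first m folds (reduced-scale
    runs); pooling then covers those folds' test participants only.
    """
    spec = spec or default_network_spec()
    training = training or TrainingConfig(seed=seed)
    df = carry_forward_bmi(dataset)
    if folds is None:
        folds = participant_kfold(df["participant_id"].unique(), k, seed)
    if folds_to_run is not None:
        folds = folds[:folds_to_run]

    fold_results = []
    per_fold_mae = {}
    for fold in folds:
        train_df = _subset(df, fold.train_participants)
        val_df = _subset(df, fold.validation_participants)
        test_df = _subset(df, fold.test_participants)
        state = fit_preprocess(
            train_df, MODEL_FEATURES, fit_population=f"fold{fold.fold_index}/train"
        )
        X_tr = transform(state, train_df)
        y_tr = scale_target(train_df["updrs3"])
        X_val = transform(state, val_df)
        y_val = scale_target(val_df["updrs3"])
        X_te = transform(state, test_df)

        w0 = init_weights(spec, seed=training.seed + fold.fold_index)
        cfg = TrainingConfig(
            learning_rate=training.learning_rate,
            max_epochs=training.max_epochs,
            patience=training.patience,
            batch_size=training.batch_size,
            seed=training.seed + fold.fold_index,
        )
        w, hist = train(w0, X_tr, y_tr, cfg, spec=spec, monitor=(X_val, y_val))
        y_pred = inverse_scale_target(predict(w, X_te, spec=spec))

        preds = test_df[["participant_id", "visit_month", "day_index"]].copy()
        preds["y_true"] = test_df["updrs3"].to_numpy(dtype=float)
        preds["y_pred"] = y_pred
        fold_results.append(FoldResult(fold.fold_index, preds, state, w, hist))
        per_fold_mae[fold.fold_index] = mae(preds["y_true"], preds["y_pred"])

    pooled = pd.concat([fr.predictions for fr in fold_results], ignore_index=True)
    targets = (
        pooled["participant_id"].astype(str)
        + "/"
        + pooled["visit_month"].astype(str)
    )
    report = agreement_report(pooled["y_true"], pooled["y_pred"], targets)
    return CentralizedResult(fold_results, report, per_fold_mae)


def mean_baseline_mae(
    dataset: pd.DataFrame, folds: list[FoldAssignment]
) -> float:
    """Pooled test MAE of predicting each fold's training-label mean."""
    errs = []
    for fold in folds:
        mu = _subset(dataset, fold.train_participants)["updrs3"].mean()
        y = _subset(dataset, fold.test_participants)["updrs3"].to_numpy(float)
        errs.append(np.abs(y - mu))
    pooled = np.concatenate(errs)
    return float(pooled.mean())
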