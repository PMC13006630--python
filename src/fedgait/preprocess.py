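"""Participant-wise splitting, imputation, standardization, target scaling.

All data splits are by *participant*, never by sample: all days of a
participant land in exactly one of train/validation/test, so no
within-person leakage is possible. Missing feature values are imputed with
the median of the fit population and features standardized to zero mean /
unit variance of that population; which population the statistics come
from is tracked explicitly because the federated privacy model forbids
mixing them (clients fit on their own local training days, the global
model's test transform is fitted on the withheld test participants only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.preprocessing import StandardScaler

from .cohort import MODEL_FEATURES, UPDRS3_MAX

__all__ = [
    "FoldAssignment",
    "PreprocessState",
    "PreprocessError",
    "participant_kfold",
    "fit_preprocess",
    "transform",
    "carry_forward_bmi",
    "scale_target",
    "inverse_scale_target",
    "folds_to_frame",
]


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class FoldAssignment:
    """One cross-validation fold's participant-level role assignment."""

    fold_index: int
    test_participants: tuple[str, ...]
    validation_participants: tuple[str, ...]
    train_participants: tuple[str, ...]

    def __post_init__(self):
        roles = (
            set(self.test_participants),
            set(self.validation_participants),
            set(self.train_participants),
        )
        for i in range(3):
            for j in range(i + 1, 3):
                if roles[i] & roles[j]:
                    raise PreprocessError(
                        f"fold {self.fold_index}: overlapping role sets"
                    )


def participant_kfold(
    participant_ids,
    k: int,
    seed: int,
    validation: bool = True,
) -> list[FoldAssignment]:
    """Participant-wise k-fold assignment.

    Participants are shuffled (seeded) and partitioned into ``k`` groups.
    Fold ``i`` uses group ``i`` as test; with ``validation=True`` the next
    group cyclically serves as validation (a further ~1/k of participants,
    the early-stopping monitor for centralized training) and the rest
    train — the 80/10/10 split. With ``validation=False`` (federated
    folds) all non-test participants are clients.
    """
    ids = sorted(set(map(str, participant_ids)))
    if k < 2:
        raise PreprocessError("k must be >= 2")
    if k > len(ids):
        raise PreprocessError(f"k={k} exceeds number of participants ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    groups = np.array_split(np.asarray(ids, dtype=object)[order], k)
    folds = []
    for i in range(k):
        test = tuple(groups[i])
        if validation and k >= 2:
            val = tuple(groups[(i + 1) % k])
        else:
            val = ()
        train = tuple(
            pid for g in range(k) if g != i and not (validation and g == (i + 1) % k)
            for pid in groups[g]
        )
        folds.append(FoldAssignment(i + 1, test, val, train))
    return folds


def folds_to_frame(folds: list[FoldAssignment]) -> pd.DataFrame:
    """Export fold assignments as (participant_id, fold, role) rows."""
    rows = []
    for f in folds:
        for pid in f.test_participants:
            rows.append((pid, f.fold_index, "test"))
        for pid in f.validation_participants:
            rows.append((pid, f.fold_index, "validation"))
        for pid in f.train_participants:
            rows.append((pid, f.fold_index, "train"))
    return pd.DataFrame(rows, columns=["participant_id", "fold", "role"])


@dataclass
class PreprocessState:
    """Fitted imputation medians and standardization statistics.

    ``fit_population`` records which samples the statistics came from
    (e.g. ``"fold3/train"``, ``"client/P017"``, ``"fold3/test"``) so the
    no-mixing invariant is auditable.
    """

    feature_names: list[str]
    medians: np.ndarray
    means: np.ndarray
    scales: np.ndarray
    fit_population: str


def fit_preprocess(
    samples: pd.DataFrame,
    feature_names: list[str] | None = None,
    fit_population: str = "unspecified",
    allow_all_missing: bool = False,
) -> PreprocessState:
    """Fit median imputation + standardization on a sample population.

    Medians are taken over observed values only; standardization statistics
    over the imputed matrix. A zero-variance feature keeps scale 1 (it is
    centered only) — this is how a client-locally-constant input such as
    sex survives preprocessing as a constant instead of dividing by zero.

    A feature with no observed value anywhere in the population raises by
    default (the caller must widen the fit population). Federated clients
    cannot widen theirs — no external statistics may cross the client
    boundary — so with ``allow_all_missing=True`` such a feature instead
    gets median 0 and scale 1, entering the model as a constant exactly
    like a locally-constant input.
    """
    feature_names = list(feature_names or MODEL_FEATURES)
    if samples.empty:
        raise PreprocessError("cannot fit preprocessing on an empty sample set")
    X = samples.loc[:, feature_names].to_numpy(dtype=float)
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        if not allow_all_missing:
            bad = [f for f, m in zip(feature_names, all_missing) if m]
            raise PreprocessError(
                f"feature(s) entirely missing in fit population: {bad}; "
                "widen the fit population"
            )
        X = X.copy()
        X[:, all_missing] = 0.0
    imputer = SimpleImputer(strategy="median").fit(X)
    scaler = StandardScaler().fit(imputer.transform(X))
    return PreprocessState(
        feature_names=feature_names,
        medians=np.asarray(imputer.statistics_, dtype=float),
        means=np.asarray(scaler.mean_, dtype=float),
        scales=np.asarray(scaler.scale_, dtype=float),  # 1.0 where var == 0
        fit_population=fit_population,
    )


def transform(state: PreprocessState, samples: pd.DataFrame) -> np.ndarray:
    """Impute + standardize a sample set with previously fitted statistics."""
    X = samples.loc[:, state.feature_names].to_numpy(dtype=float)
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.broadcast_to(state.medians, X.shape)[nan]
    return (X - state.means) / state.scales


def carry_forward_bmi(dataset: pd.DataFrame) -> pd.DataFrame:
    """Forward-fill each participant's missing visit BMI from earlier visits.

    A visit with no recorded BMI takes the participant's most recent
    earlier value; a first-visit gap stays missing (later handled by
    median imputation). Never fills backward.
    """
    df = dataset.sort_values(
        ["participant_id", "visit_month", "day_index"], kind="stable"
    ).reset_index(drop=True)
    df["bmi"] = df.groupby("participant_id", sort=False)["bmi"].ffill()
    return df


def scale_target(y):
    """Scale MDS-UPDRS III scores to [0, 1] by the instrument range (/132)."""
    y = np.asarray(y, dtype=float)
    if ((y < 0) | (y > UPDRS3_MAX)).any():
        raise ValueError(f"target outside [0, {UPDRS3_MAX}]")
    return y / UPDRS3_MAX


def inverse_scale_target(y_scaled):
    """Map model outputs in [0, 1] back to the 0-132 clinical scale."""
    y_scaled = np.asarray(y_scaled, dtype=float)
    if ((y_scaled < 0) | (y_scaled > 1)).any():
        raise ValueError("scaled target outside [0, 1]")
    return y_scaled * UPDRS3_MAX
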