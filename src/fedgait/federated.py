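"""Edge-device federated learning simulation.

Each client holds exactly one participant's data — the extreme non-IID
case — keeps 20% of its days as a local holdout, and fits its own
preprocessing statistics on its local training days. Every round, each
client trains the received global weights on its local training data
(early stopping monitored on the local *training* MAE, since a
single-participant client has no validation cohort), the server
aggregates the returned weights with FedAvg (per-parameter mean weighted
by client sample counts), redistributes the aggregate, and each client
then *personalises* a copy of it by fine-tuning at a 10x lower learning
rate for local-holdout evaluation; the personalised weights are discarded
before the next round. The global model is evaluated each round on the
fold's withheld test participants, whose imputation and standardization
statistics come from the test cohort itself (nothing about the clients
crosses to the test side). After the last round the global weights roll
back to the round with the lowest global test MAE.

Three modes:

* ``conventional`` — the cycle above, nothing else;
* ``server_side`` — 8% of the training participants are withheld from
  the client pool as a server-held tuning cohort; after every FedAvg the
  server fine-tunes the aggregate on the pooled tuning data at the low
  learning rate;
* ``client_side`` — the same withheld cohort's raw samples are instead
  copied into every client's local training pool once, before round 1,
  and never transmitted again; during personalisation each client's own
  samples are up-weighted 4:1 against the shared samples.

Every artifact crossing the client boundary is recorded in a
transmission audit log; after initialisation only weight vectors and
scalar metrics appear in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MODEL_FEATURES
from .metrics import mae
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
    fit_preprocess,
    inverse_scale_target,
    scale_target,
    transform,
)

__all__ = [
    "FLConfig",
    "ClientState",
    "RoundLog",
    "FederatedResult",
    "fedavg",
    "local_round",
    "personalize",
    "server_side_tune",
    "build_clients",
    "run_federated",
    "audit_is_private",
]

_MODES = ("conventional", "server_side", "client_side")


@dataclass(frozen=True)
class FLConfig:
    """Federated simulation configuration.

    Defaults are the full-scale protocol: 100 rounds, base learning rate
    1e-3 for local training, 1e-4 for fine-tuning (personalisation and
    server-side tuning), 8% tuning participants in the data-sharing
    modes, 4:1 own-vs-shared sample weighting during client-side
    personalisation, and the full early-stopping budget (150 epochs,
    patience 20) for every local fit.
    """

    rounds: int = 100
    mode: str = "conventional"
    tuning_fraction: float = 0.08
    base_lr: float = 1e-3
    fine_tune_lr: float = 1e-4
    own_weight_ratio: float = 4.0
    holdout_fraction: float = 0.2
    local_max_epochs: int = 150
    local_patience: int = 20
    batch_size: int = 32
    rollback_on: str = "test"  # "test" (as published) or "tuning"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if not 0.0 <= self.tuning_fraction < 1.0:
            raise ValueError("tuning_fraction must be in [0, 1)")
        if self.own_weight_ratio < 1.0:
            raise ValueError("own_weight_ratio must be >= 1")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.rollback_on not in ("test", "tuning"):
            raise ValueError("rollback_on must be 'test' or 'tuning'")


@dataclass
class ClientState:
    """One participant's client: local split, preprocessing, data matrices."""

    participant_id: str
    train_rows: pd.DataFrame  # own training days (+ shared rows in client_side)
    holdout_rows: pd.DataFrame
    preprocess_state: PreprocessState
    X_train: np.ndarray
    y_train: np.ndarray
    X_holdout: np.ndarray
    y_holdout: np.ndarray
    own_mask: np.ndarray  # True for the client's own training rows

    @property
    def n_train(self) -> int:
        return len(self.X_train)


@dataclass
class RoundLog:
    round_index: int
    global_mae: float
    local_mae: float  # sample-count-weighted mean of client holdout MAEs
    per_client_mae: dict[str, float]
    tuning_mae: float | None = None


@dataclass
class FederatedResult:
    fold_index: int
    best_round: int
    global_predictions: pd.DataFrame  # fold test participants, 0-132 scale
    local_predictions: pd.DataFrame  # per-client holdout, 0-132 scale
    round_logs: list[RoundLog]
    audit_log: list[dict]
    global_weights: ModelWeights

    @property
    def global_mae(self) -> float:
        return mae(
            self.global_predictions["y_true"], self.global_predictions["y_pred"]
        )

    @property
    def local_mae(self) -> float:
        return mae(
            self.local_predictions["y_true"], self.local_predictions["y_pred"]
        )


def fedavg(models: list[tuple[ModelWeights, int]]) -> ModelWeights:
    """Sample-count-weighted mean of model weights, parameter by parameter."""
    if not models:
        raise ValueError("fedavg needs at least one model")
    shapes = models[0][0].shapes
    for w, n in models:
        if w.shapes != shapes:
            raise ValueError("shape manifest mismatch between client models")
        if n <= 0:
            raise ValueError("client sample count must be positive")
    total = float(sum(n for _, n in models))
    arrays = []
    for i in range(len(shapes)):
        acc = np.zeros(shapes[i])
        for w, n in models:
            acc += (n / total) * w.arrays[i]
        arrays.append(acc)
    return ModelWeights(arrays)


def _fit_config(config: FLConfig, lr: float, seed: int) -> TrainingConfig:
    return TrainingConfig(
        learning_rate=lr,
        max_epochs=config.local_max_epochs,
        patience=config.local_patience,
        batch_size=config.batch_size,
        seed=seed,
    )


def local_round(
    client: ClientState,
    global_weights: ModelWeights,
    config: FLConfig,
    spec: NetworkSpec,
    seed: int,
) -> tuple[ModelWeights, int]:
    """One client's local training pass, starting from the global weights.

    Trains at the base learning rate on the client's training pool
    (including shared rows in client-side mode, unweighted), early
    stopping monitored on the local training MAE with the incoming
    weights as rollback candidate. Returns the trained weights and the
    local sample count used for FedAvg weighting.
    """
    if client.n_train == 0:
        raise ValueError(f"client {client.participant_id} has no training data")
    w, _ = train(
        global_weights,
        client.X_train,
        client.y_train,
        _fit_config(config, config.base_lr, seed),
        spec=spec,
    )
    return w, client.n_train


def personalize(
    client: ClientState,
    global_weights: ModelWeights,
    config: FLConfig,
    spec: NetworkSpec,
    seed: int,
) -> ModelWeights:
    """Fine-tune a copy of the global model to the client's participant.

    Uses the reduced learning rate; in client-side mode the client's own
    samples are weighted ``own_weight_ratio`` against the shared samples
    (with no shared samples a uniform weight rescales the loss only, so
    any ratio is equivalent to 1). The result is used for local-holdout
    evaluation and then discarded — personalised weights never feed the
    next aggregation.
    """
    sample_weight = None
    if not client.own_mask.all():
        sample_weight = np.where(client.own_mask, config.own_weight_ratio, 1.0)
    w, _ = train(
        global_weights,
        client.X_train,
        client.y_train,
        _fit_config(config, config.fine_tune_lr, seed),
        spec=spec,
        sample_weight=sample_weight,
    )
    return w


def server_side_tune(
    global_weights: ModelWeights,
    X_tuning: np.ndarray,
    y_tuning: np.ndarray,
    config: FLConfig,
    spec: NetworkSpec,
    seed: int,
) -> ModelWeights:
    """Fine-tune the aggregated global model on the server's tuning cohort."""
    if len(X_tuning) == 0:
        raise ValueError("server-side mode requires a non-empty tuning set")
    w, _ = train(
        global_weights,
        X_tuning,
        y_tuning,
        _fit_config(config, config.fine_tune_lr, seed),
        spec=spec,
    )
    return w


def _split_holdout(rows: pd.DataFrame, fraction: float, rng) -> tuple:
    n = len(rows)
    n_hold = max(1, int(round(fraction * n))) if n >= 2 else 0
    idx = rng.permutation(n)
    hold = rows.iloc[idx[:n_hold]]
    tr = rows.iloc[idx[n_hold:]]
    return tr, hold


def build_clients(
    dataset: pd.DataFrame,
    client_participants,
    config: FLConfig,
    shared_rows: pd.DataFrame | None = None,
    audit_log: list | None = None,
) -> list[ClientState]:
    """Create per-participant clients with local splits and preprocessing.

    ``shared_rows`` (client-side mode) are appended to every client's
    training pool before any training; this one-time provisioning is the
    only raw-data movement and is recorded in the audit log.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 97]))
    clients = []
    for pid in sorted(map(str, client_participants)):
        own = dataset[dataset["participant_id"] == pid]
        tr, hold = _split_holdout(own, config.holdout_fraction, rng)
        if shared_rows is not None and len(shared_rows):
            pool = pd.concat([tr, shared_rows], ignore_index=True)
            own_mask = np.zeros(len(pool), dtype=bool)
            own_mask[: len(tr)] = True
            if audit_log is not None:
                audit_log.append(
                    {
                        "round": 0,
                        "kind": "raw_samples",
                        "from": "server",
                        "to": pid,
                        "count": int(len(shared_rows)),
                    }
                )
        else:
            pool = tr.reset_index(drop=True)
            own_mask = np.ones(len(pool), dtype=bool)
        state = fit_preprocess(
            pool, MODEL_FEATURES, fit_population=f"client/{pid}",
            allow_all_missing=True,
        )
        clients.append(
            ClientState(
                participant_id=pid,
                train_rows=pool,
                holdout_rows=hold,
                preprocess_state=state,
                X_train=transform(state, pool),
                y_train=scale_target(pool["updrs3"]),
                X_holdout=transform(state, hold) if len(hold) else np.empty((0, len(MODEL_FEATURES))),
                y_holdout=scale_target(hold["updrs3"]) if len(hold) else np.empty(0),
                own_mask=own_mask,
            )
        )
    return clients


def _n_tuning(n_train_participants: int, fraction: float) -> int:
    """Round-half-to-even, minimum 1 (e.g. 0.08 x 80 = 6.4 -> 6)."""
    return max(1, round(fraction * n_train_participants))


def run_federated(
    dataset: pd.DataFrame,
    fold: FoldAssignment,
    config: FLConfig,
    spec: NetworkSpec | None = None,
) -> FederatedResult:
    """Simulate the federated system for one cross-validation fold."""
    spec = spec or default_network_spec()
    train_pids = sorted(fold.train_participants + fold.validation_participants)
    test_pids = set(fold.test_participants)
    if not train_pids:
        raise ValueError("no training participants in fold")
    if test_pids & set(train_pids):
        raise ValueError("test participants overlap clients")

    ss = np.random.SeedSequence([config.seed, fold.fold_index])
    seeds = ss.generate_state(4)
    rng = np.random.default_rng(seeds[0])
    audit_log: list[dict] = []

    # reserve tuning participants in the data-sharing modes
    tuning_pids: list[str] = []
    if config.mode in ("server_side", "client_side"):
        n_tune = _n_tuning(len(train_pids), config.tuning_fraction)
        tuning_pids = list(
            rng.choice(np.asarray(train_pids, object), size=n_tune, replace=False)
        )
    client_pids = [p for p in train_pids if p not in set(tuning_pids)]
    tuning_rows = dataset[dataset["participant_id"].isin(set(tuning_pids))]

    shared = tuning_rows if config.mode == "client_side" else None
    clients = build_clients(
        dataset, client_pids, config, shared_rows=shared, audit_log=audit_log
    )

    X_tuning = y_tuning = None
    if config.mode == "server_side":
        tune_state = fit_preprocess(
            tuning_rows, MODEL_FEATURES,
            fit_population=f"fold{fold.fold_index}/tuning",
            allow_all_missing=True,
        )
        X_tuning = transform(tune_state, tuning_rows)
        y_tuning = scale_target(tuning_rows["updrs3"])

    # privacy-preserving test transform: statistics from the withheld cohort
    test_rows = dataset[dataset["participant_id"].isin(test_pids)]
    # the withheld cohort cannot be widened either (privacy), so a feature
    # with no observed value there also enters as a constant
    test_state = fit_preprocess(
        test_rows, MODEL_FEATURES, fit_population=f"fold{fold.fold_index}/test",
        allow_all_missing=True,
    )
    X_test = transform(test_state, test_rows)
    y_test = test_rows["updrs3"].to_numpy(dtype=float)

    global_w = init_weights(spec, seed=int(seeds[1]))
    round_logs: list[RoundLog] = []
    best = None  # (criterion_mae, round, weights, local_pred_frame, global_pred)

    for r in range(1, config.rounds + 1):
        updates = []
        for ci, client in enumerate(clients):
            w_c, n_c = local_round(
                client, global_w, config, spec, seed=int(seeds[2]) + 1000 * r + ci
            )
            updates.append((w_c, n_c))
            audit_log.append(
                {"round": r, "kind": "weights", "from": client.participant_id,
                 "to": "server", "count": 1}
            )
        global_w = fedavg(updates)
        if config.mode == "server_side":
            global_w = server_side_tune(
                global_w, X_tuning, y_tuning, config, spec,
                seed=int(seeds[3]) + r,
            )
        for client in clients:
            audit_log.append(
                {"round": r, "kind": "weights", "from": "server",
                 "to": client.participant_id, "count": 1}
            )

        # personalised local evaluation (evaluation-side branch only)
        local_frames = []
        per_client_mae = {}
        for ci, client in enumerate(clients):
            w_p = personalize(
                client, global_w, config, spec,
                seed=int(seeds[2]) + 1000 * r + 500 + ci,
            )
            if len(client.X_holdout):
                pred = inverse_scale_target(predict(w_p, client.X_holdout, spec=spec))
                frame = client.holdout_rows[
                    ["participant_id", "visit_month", "day_index"]
                ].copy()
                frame["y_true"] = client.holdout_rows["updrs3"].to_numpy(float)
                frame["y_pred"] = pred
                local_frames.append(frame)
                per_client_mae[client.participant_id] = mae(
                    frame["y_true"], frame["y_pred"]
                )
                audit_log.append(
                    {"round": r, "kind": "scalar", "from": client.participant_id,
                     "to": "server", "count": 1}
                )
        local_pred = pd.concat(local_frames, ignore_index=True)
        counts = np.array(
            [len(c.X_holdout) for c in clients if c.participant_id in per_client_mae],
            dtype=float,
        )
        maes = np.array(
            [per_client_mae[c.participant_id] for c in clients
             if c.participant_id in per_client_mae]
        )
        local_mae = float(np.sum(counts * maes) / np.sum(counts))

        g_pred = inverse_scale_target(predict(global_w, X_test, spec=spec))
        g_mae = mae(y_test, g_pred)
        tuning_mae = None
        if config.rollback_on == "tuning":
            if X_tuning is None:
                raise ValueError("rollback_on='tuning' requires server_side mode")
            t_pred = inverse_scale_target(predict(global_w, X_tuning, spec=spec))
            tuning_mae = mae(inverse_scale_target(y_tuning), t_pred)
        round_logs.append(RoundLog(r, g_mae, local_mae, per_client_mae, tuning_mae))

        criterion = g_mae if config.rollback_on == "test" else tuning_mae
        if best is None or criterion < best[0]:
            best = (criterion, r, global_w.copy(), local_pred, g_pred)

    _, best_round, best_w, best_local, best_g_pred = best
    g_frame = test_rows[["participant_id", "visit_month", "day_index"]].copy()
    g_frame["y_true"] = y_test
    g_frame["y_pred"] = best_g_pred
    return FederatedResult(
        fold_index=fold.fold_index,
        best_round=best_round,
        global_predictions=g_frame.reset_index(drop=True),
        local_predictions=best_local.reset_index(drop=True),
        round_logs=round_logs,
        audit_log=audit_log,
        global_weights=best_w,
    )


def audit_is_private(audit_log: list[dict]) -> bool:
    """True iff nothing but weights and scalar metrics moved after round 0."""
    return all(
        entry["kind"] in ("weights", "scalar")
        for entry in audit_log
        if entry["round"] > 0
    )
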