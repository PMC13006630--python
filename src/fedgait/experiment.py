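"""End-to-end experiment contrasting the four training approaches.

Generates one synthetic cohort, runs the traditional centralized
baseline and the three federated modes (conventional, server-side
training, client-side data) on it, computes pooled agreement metrics for
each, and attributes the centralized, global and one personalised local
model with Shapley values so the constant-feature collapse can be
compared across approaches. Everything derives deterministically from a
single master seed via stage-name hashing, so adding a stage never
perturbs another stage's stream.

The default profile is reduced-scale (40 participants, k=5 with one fold
executed, 30 rounds); the full-scale study protocol (89 participants,
k=10 with all folds, 100 rounds) is available via
:func:`full_scale_config`. Both profiles use the full early-stopping
budget (150 epochs, patience 20) for every fit — the budget is part of
the training protocol, not of the problem size.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import (
    AttributionResult,
    compare_importance,
    shapley_attribute,
    top_n_overlap,
)
from .centralized import run_traditional
from .cohort import CohortConfig, MODEL_FEATURES, generate_dataset
from .federated import (
    FLConfig,
    FederatedResult,
    build_clients,
    personalize,
    run_federated,
)
from .metrics import agreement_report
from .nn import TrainingConfig, default_network_spec, predict
from .preprocess import (
    carry_forward_bmi,
    fit_preprocess,
    participant_kfold,
    transform,
)

__all__ = [
    "ExperimentConfig",
    "full_scale_config",
    "derive_seed",
    "run_experiment",
]

FL_MODES = ("conventional", "server_side", "client_side")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: sha256(master:stage) reduced below 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """Reduced-scale defaults; see :func:`full_scale_config` for the study scale."""

    n_participants: int = 40
    k: int = 5
    folds_to_run: int = 1
    rounds: int = 30
    local_max_epochs: int = 150
    local_patience: int = 20
    central_max_epochs: int = 150
    central_patience: int = 20
    master_seed: int = 0
    modes: tuple[str, ...] = FL_MODES
    attribution_permutations: int = 12
    attribution_samples: int = 24
    out_dir: str | None = None

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_participants=self.n_participants,
            seed=derive_seed(self.master_seed, "cohort"),
        )

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            max_epochs=self.central_max_epochs,
            patience=self.central_patience,
            seed=derive_seed(self.master_seed, "central"),
        )

    def fl_config(self, mode: str) -> FLConfig:
        return FLConfig(
            rounds=self.rounds,
            mode=mode,
            local_max_epochs=self.local_max_epochs,
            local_patience=self.local_patience,
            seed=derive_seed(self.master_seed, f"fl/{mode}"),
        )


def full_scale_config(master_seed: int = 0, **overrides) -> ExperimentConfig:
    """The study-scale protocol: 89 participants, k=10, 100 rounds."""
    cfg = ExperimentConfig(
        n_participants=89,
        k=10,
        folds_to_run=10,
        rounds=100,
        local_max_epochs=150,
        local_patience=20,
        central_max_epochs=150,
        central_patience=20,
        master_seed=master_seed,
    )
    return replace(cfg, **overrides)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, float):
        return round(obj, ndigits)
    return obj


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full contrast; returns the report dict (and writes files).

    The report contains, per approach, the pooled agreement metrics and —
    for the federated modes — the best round, plus MAS-based feature
    rankings for the centralized, global and a representative local
    model, and a provenance manifest.
    """
    spec = default_network_spec()
    cohort_cfg = config.cohort_config()
    dataset = carry_forward_bmi(generate_dataset(cohort_cfg))
    folds = participant_kfold(
        dataset["participant_id"].unique(), config.k,
        derive_seed(config.master_seed, "folds"),
    )
    run_folds = folds[: config.folds_to_run]

    config_hash = hashlib.sha256(
        repr(replace(config, out_dir=None)).encode()
    ).hexdigest()[:16]
    report: dict = {
        "manifest": {
            "config_sha256": config_hash,
            "package_version": __version__,
            "master_seed": config.master_seed,
            "n_participants": config.n_participants,
            "k": config.k,
            "folds_run": [f.fold_index for f in run_folds],
            "rounds": config.rounds,
            "modes": list(config.modes),
            "trainable_parameters": int(
                sum((fi + 1) * fo for fi, fo in spec.dense_shapes())
            ),
        },
        "approaches": {},
    }
    outputs: dict[str, pd.DataFrame] = {}

    central = run_traditional(
        dataset,
        k=config.k,
        seed=derive_seed(config.master_seed, "central"),
        spec=spec,
        training=config.training_config(),
        folds=folds,
        folds_to_run=config.folds_to_run,
    )
    report["approaches"]["traditional"] = {
        "pooled": central.pooled.to_dict(),
        "per_fold_mae": central.per_fold_mae,
    }
    outputs["predictions_traditional"] = central.predictions

    fl_results: dict[str, list[FederatedResult]] = {}
    for mode in config.modes:
        fl_cfg = config.fl_config(mode)
        results = [run_federated(dataset, fold, fl_cfg, spec=spec) for fold in run_folds]
        fl_results[mode] = results
        g_pool = pd.concat([r.global_predictions for r in results], ignore_index=True)
        l_pool = pd.concat([r.local_predictions for r in results], ignore_index=True)
        g_targets = g_pool["participant_id"].astype(str) + "/" + g_pool[
            "visit_month"
        ].astype(str)
        report["approaches"][f"fl_{mode}"] = {
            "global_pooled": agreement_report(
                g_pool["y_true"], g_pool["y_pred"], g_targets
            ).to_dict(),
            "local_mae": float(np.mean(np.abs(l_pool["y_true"] - l_pool["y_pred"]))),
            "best_round": [r.best_round for r in results],
            "audit_private": all(
                all(e["kind"] in ("weights", "scalar") for e in r.audit_log if e["round"] > 0)
                for r in results
            ),
        }
        outputs[f"predictions_global_{mode}"] = g_pool
        outputs[f"predictions_local_{mode}"] = l_pool
        outputs[f"rounds_{mode}"] = pd.DataFrame(
            [
                {"fold": r.fold_index, "round": log.round_index,
                 "global_mae": log.global_mae, "local_mae": log.local_mae}
                for r in results
                for log in r.round_logs
            ]
        )

    report["attribution"] = _attribution_contrast(
        dataset, folds[0], central, fl_results, config, spec
    )

    report = _round_floats(report)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        for name, frame in outputs.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        report["manifest"]["files"] = sorted(
            ["metrics.json"] + [f"{n}.csv" for n in outputs]
        )
        (out / "metrics.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return report


def _attribution_contrast(dataset, fold, central, fl_results, config, spec):
    """MAS rankings for centralized / global / one local model on fold 1.

    The fold's test cohort (which the server holds for evaluation) serves
    as both explanation samples and background for every model, keeping
    the rankings comparable across approaches.
    """
    seed = derive_seed(config.master_seed, "attribution")
    test_rows = dataset[
        dataset["participant_id"].isin(set(fold.test_participants))
    ]
    results: dict[str, AttributionResult] = {}

    fr = central.fold_results[0]
    X = transform(fr.preprocess_state, test_rows)
    samples = X[: config.attribution_samples]
    results["traditional"] = shapley_attribute(
        lambda M: predict(fr.weights, M, spec=spec),
        samples, X, feature_names=MODEL_FEATURES,
        n_permutations=config.attribution_permutations, seed=seed,
        metadata={"background": fr.preprocess_state.fit_population},
    )

    # the global models are attributed in test-cohort coordinates
    test_state = fit_preprocess(test_rows, MODEL_FEATURES,
                                fit_population="test", allow_all_missing=True)
    Xg = transform(test_state, test_rows)
    for mode, runs in fl_results.items():
        run = runs[0]
        results[f"global_{mode}"] = shapley_attribute(
            lambda M: predict(run.global_weights, M, spec=spec),
            Xg[: config.attribution_samples], Xg, feature_names=MODEL_FEATURES,
            n_permutations=config.attribution_permutations, seed=seed,
            metadata={"background": "fold test cohort"},
        )

    # one personalised local model (the conventional run's largest client),
    # attributed against its own sex-constant local data
    first_mode = next(iter(fl_results))
    run = fl_results[first_mode][0]
    fl_cfg = config.fl_config(first_mode)
    clients = build_clients(
        dataset,
        fold.train_participants + fold.validation_participants,
        fl_cfg,
    )
    client = max(clients, key=lambda c: c.n_train)
    w_local = personalize(client, run.global_weights, fl_cfg, spec,
                          seed=seed + 1)
    X_local = client.X_holdout if len(client.X_holdout) else client.X_train
    results[f"local_{first_mode}"] = shapley_attribute(
        lambda M: predict(w_local, M, spec=spec),
        X_local[: config.attribution_samples], client.X_train,
        feature_names=MODEL_FEATURES,
        n_permutations=config.attribution_permutations, seed=seed,
        metadata={"background": client.preprocess_state.fit_population},
    )

    table = compare_importance(results)
    sex_ranks = {model: int(table.loc["sex", f"rank_{model}"])
                 for model in results}
    sex_mas = {model: float(res.mas[MODEL_FEATURES.index("sex")])
               for model, res in results.items()}
    return {
        "sex_rank": sex_ranks,
        "sex_mas": sex_mas,
        "top10": {m: res.ranking[:10] for m, res in results.items()},
        "top10_overlap_with_traditional": {
            m: top_n_overlap(results["traditional"], res)
            for m, res in results.items() if m != "traditional"
        },
    }
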