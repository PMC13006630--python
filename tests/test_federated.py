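"""FedAvg aggregation, client mechanics, modes and the privacy audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fedgait.cohort import CohortConfig, generate_dataset
from fedgait.federated import (
    FLConfig,
    _n_tuning,
    audit_is_private,
    build_clients,
    fedavg,
    local_round,
    personalize,
    run_federated,
    server_side_tune,
)
from fedgait.nn import (
    Dense,
    Dropout,
    ModelWeights,
    NetworkSpec,
    init_weights,
    predict,
)
from fedgait.preprocess import carry_forward_bmi, participant_kfold

SMALL_SPEC = NetworkSpec(
    input_width=91, layers=(Dense(8), Dropout(0.5), Dense(1, "sigmoid"))
)


@pytest.fixture(scope="module")
def fl_dataset():
    return carry_forward_bmi(generate_dataset(CohortConfig(n_participants=12, seed=7)))


@pytest.fixture(scope="module")
def fl_fold(fl_dataset):
    return participant_kfold(
        fl_dataset["participant_id"].unique(), k=3, seed=0, validation=False
    )[0]


def _quick_config(**kw):
    defaults = dict(rounds=2, local_max_epochs=3, local_patience=3, seed=0)
    defaults.update(kw)
    return FLConfig(**defaults)


class TestFedavg:
    def test_identical_weights_fixed_point(self):
        w = init_weights(SMALL_SPEC, 0)
        out = fedavg([(w, 5), (w, 2), (w, 9)])
        np.testing.assert_allclose(out.to_flat(), w.to_flat(), atol=1e-12)

    def test_scalar_weighted_mean(self):
        a = ModelWeights([np.array([0.0])])
        b = ModelWeights([np.array([3.0])])
        out = fedavg([(a, 1), (b, 3)])
        assert out.arrays[0][0] == pytest.approx(2.25, abs=1e-15)

    def test_single_client_identity(self):
        w = init_weights(SMALL_SPEC, 1)
        np.testing.assert_array_equal(fedavg([(w, 4)]).to_flat(), w.to_flat())

    def test_shape_mismatch_rejected(self):
        a = ModelWeights([np.zeros(3)])
        b = ModelWeights([np.zeros(4)])
        with pytest.raises(ValueError):
            fedavg([(a, 1), (b, 1)])

    @given(
        n_models=st.integers(1, 5),
        seed=st.integers(0, 50),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_independent_weighted_mean_oracle(self, n_models, seed):
        """fedavg equals a per-parameter loop-coded weighted mean to 1e-12."""
        rng = np.random.default_rng(seed)
        shapes = [(3, 2), (2,), (2, 1), (1,)]
        models = [
            (
                ModelWeights([rng.normal(size=s) for s in shapes]),
                int(rng.integers(1, 20)),
            )
            for _ in range(n_models)
        ]
        out = fedavg(models)
        total = sum(n for _, n in models)
        for ai, shape in enumerate(shapes):
            expected = np.zeros(shape)
            for w, n in models:
                expected = expected + w.arrays[ai] * (n / total)
            np.testing.assert_allclose(out.arrays[ai], expected, atol=1e-12)


class TestClientMechanics:
    def test_holdout_fraction_and_disjointness(self, fl_dataset, fl_fold):
        cfg = _quick_config()
        clients = build_clients(fl_dataset, fl_fold.train_participants, cfg)
        for c in clients:
            n_own = int(c.own_mask.sum()) + len(c.holdout_rows)
            assert len(c.holdout_rows) == max(1, round(cfg.holdout_fraction * n_own))
            merged = pd.merge(
                c.train_rows[["participant_id", "visit_month", "day_index"]],
                c.holdout_rows[["participant_id", "visit_month", "day_index"]],
            )
            assert merged.empty  # holdout and training never share a day

    def test_zero_epochs_returns_global_weights(self, fl_dataset, fl_fold):
        cfg = _quick_config(local_max_epochs=0)
        clients = build_clients(fl_dataset, fl_fold.train_participants, cfg)
        gw = init_weights(SMALL_SPEC, 0)
        w, n = local_round(clients[0], gw, cfg, SMALL_SPEC, seed=0)
        np.testing.assert_allclose(w.to_flat(), gw.to_flat(), atol=1e-7)
        assert n == clients[0].n_train

    def test_local_round_never_worsens_training_mae(self, fl_dataset, fl_fold):
        cfg = _quick_config(local_max_epochs=5)
        clients = build_clients(fl_dataset, fl_fold.train_participants, cfg)
        c = clients[0]
        gw = init_weights(SMALL_SPEC, 2)
        before = np.mean(np.abs(predict(gw, c.X_train, spec=SMALL_SPEC) - c.y_train))
        w, _ = local_round(c, gw, cfg, SMALL_SPEC, seed=3)
        after = np.mean(np.abs(predict(w, c.X_train, spec=SMALL_SPEC) - c.y_train))
        assert after <= before + 1e-6

    def test_personalize_zero_lr_is_identity(self, fl_dataset, fl_fold):
        cfg = _quick_config(fine_tune_lr=0.0)
        clients = build_clients(fl_dataset, fl_fold.train_participants, cfg)
        gw = init_weights(SMALL_SPEC, 0)
        w = personalize(clients[0], gw, cfg, SMALL_SPEC, seed=0)
        np.testing.assert_allclose(w.to_flat(), gw.to_flat(), atol=1e-7)

    def test_ratio_irrelevant_without_shared_data(self, fl_dataset, fl_fold):
        """With no shared samples the 4:1 weighting rescales the loss
        uniformly, so any ratio gives the ratio-1 result."""
        clients = build_clients(
            fl_dataset, fl_fold.train_participants, _quick_config()
        )
        gw = init_weights(SMALL_SPEC, 1)
        w4 = personalize(
            clients[1], gw, _quick_config(own_weight_ratio=4.0), SMALL_SPEC, seed=5
        )
        w1 = personalize(
            clients[1], gw, _quick_config(own_weight_ratio=1.0), SMALL_SPEC, seed=5
        )
        np.testing.assert_allclose(w4.to_flat(), w1.to_flat(), atol=1e-5)

    def test_tuning_cohort_size_rule(self):
        assert _n_tuning(80, 0.08) == 6  # 6.4 rounds to 6
        assert _n_tuning(5, 0.08) == 1  # minimum of one participant
        assert _n_tuning(32, 0.08) == 3

    def test_server_side_tune_zero_lr_identity(self, rng):
        gw = init_weights(SMALL_SPEC, 0)
        X = rng.normal(size=(10, 91))
        y = rng.random(10)
        w = server_side_tune(
            gw, X, y, _quick_config(fine_tune_lr=0.0), SMALL_SPEC, seed=0
        )
        np.testing.assert_allclose(w.to_flat(), gw.to_flat(), atol=1e-7)
        with pytest.raises(ValueError):
            server_side_tune(gw, np.empty((0, 91)), np.empty(0),
                             _quick_config(), SMALL_SPEC, seed=0)


class TestRunFederated:
    def test_single_client_single_round_is_local_model(self, fl_dataset):
        pids = sorted(fl_dataset["participant_id"].unique())
        from fedgait.preprocess import FoldAssignment

        fold = FoldAssignment(1, tuple(pids[:2]), (), tuple(pids[2:3]))
        cfg = _quick_config(rounds=1)
        result = run_federated(fl_dataset, fold, cfg, spec=SMALL_SPEC)
        clients = build_clients(fl_dataset, fold.train_participants, cfg)
        from fedgait.nn import init_weights as iw

        ss = np.random.SeedSequence([cfg.seed, fold.fold_index])
        seeds = ss.generate_state(4)
        gw = iw(SMALL_SPEC, seed=int(seeds[1]))
        w_local, _ = local_round(clients[0], gw, cfg, SMALL_SPEC,
                                 seed=int(seeds[2]) + 1000)
        np.testing.assert_allclose(
            result.global_weights.to_flat(), w_local.to_flat(), atol=1e-7
        )

    def test_rollback_is_min_round_mae(self, fl_dataset, fl_fold):
        cfg = _quick_config(rounds=3)
        result = run_federated(fl_dataset, fl_fold, cfg, spec=SMALL_SPEC)
        maes = [log.global_mae for log in result.round_logs]
        assert result.best_round == int(np.argmin(maes)) + 1
        assert result.global_mae == pytest.approx(min(maes))

    def test_local_aggregate_is_weighted_mean(self, fl_dataset, fl_fold):
        cfg = _quick_config(rounds=1)
        result = run_federated(fl_dataset, fl_fold, cfg, spec=SMALL_SPEC)
        log = result.round_logs[0]
        grouped = result.local_predictions.groupby("participant_id")
        counts = grouped.size()
        per_client = grouped.apply(
            lambda g: np.mean(np.abs(g["y_true"] - g["y_pred"])),
            include_groups=False,
        )
        expected = float((per_client * counts).sum() / counts.sum())
        assert log.local_mae == pytest.approx(expected)
        for pid, m in log.per_client_mae.items():
            assert m == pytest.approx(per_client[pid])

    def test_test_participants_never_clients(self, fl_dataset, fl_fold):
        cfg = _quick_config(rounds=1)
        result = run_federated(fl_dataset, fl_fold, cfg, spec=SMALL_SPEC)
        test_set = set(fl_fold.test_participants)
        local_pids = set(result.local_predictions["participant_id"])
        assert not (test_set & local_pids)
        assert set(result.global_predictions["participant_id"]) <= test_set

    @pytest.mark.parametrize("mode", ["conventional", "server_side", "client_side"])
    def test_audit_log_private_in_all_modes(self, fl_dataset, fl_fold, mode):
        """After initialisation only weights and scalar metrics cross the
        client boundary; raw samples appear only at client-side provisioning."""
        cfg = _quick_config(rounds=2, mode=mode)
        result = run_federated(fl_dataset, fl_fold, cfg, spec=SMALL_SPEC)
        assert audit_is_private(result.audit_log)
        raw = [e for e in result.audit_log if e["kind"] == "raw_samples"]
        if mode == "client_side":
            assert raw and all(e["round"] == 0 for e in raw)
        else:
            assert not raw

    def test_deterministic_given_config(self, fl_dataset, fl_fold):
        cfg = _quick_config(rounds=2)
        a = run_federated(fl_dataset, fl_fold, cfg, spec=SMALL_SPEC)
        b = run_federated(fl_dataset, fl_fold, cfg, spec=SMALL_SPEC)
        np.testing.assert_array_equal(
            a.global_weights.to_flat(), b.global_weights.to_flat()
        )
        pd.testing.assert_frame_equal(a.global_predictions, b.global_predictions)
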