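"""Dataset assembly, network training, ensembling, cross-validation."""

import numpy as np
import pytest

from hrvsdi import (AnnConfig, AnnModel, InvalidArgumentError, SDISeries,
                    assemble_dataset, blind_cross_validation, ensemble_predict,
                    load_ensemble, predict, save_ensemble, train_ann,
                    train_ensemble)
from hrvsdi.doa_model import CaseDataset, model_from_dict, model_to_dict
from hrvsdi.eacl import EACLCurve

FAST = AnnConfig(max_epochs=200, patience=50)


def _toy_dataset(n_cases=6, n_points=120, noise=0.0, seed=0, fn=None):
    """Cases with a shared monotone SDI -> score mapping plus noise."""
    rng = np.random.default_rng(seed)
    fn = fn or (lambda x: 0.8 * x + 10)
    cases = {}
    for k in range(n_cases):
        x = rng.uniform(0, 100, n_points)
        y = np.clip(fn(x) + rng.normal(0, noise, n_points), 0, 100)
        cases[f"c{k}"] = (x, y)
    ids = list(cases)
    return CaseDataset(cases=cases, correlations={c: 1.0 for c in ids},
                       model_building=ids[:-2], pure_test=ids[-2:])


def _series(x, t=None):
    t = np.arange(len(x)) * 5.0 if t is None else t
    return SDISeries(times=t, values=np.asarray(x, dtype=float),
                     valid=np.ones(len(x), dtype=bool))


def _curve(y, t=None):
    t = np.arange(len(y)) * 5.0 if t is None else t
    return EACLCurve(times=t, mean=np.asarray(y, dtype=float), sd=np.zeros(len(y)))


class TestAssembleDataset:
    def test_perfectly_correlated_case_retained(self):
        v = np.linspace(20, 90, 50)
        ds = assemble_dataset({"a": _series(v)}, {"a": _curve(v)}, n_pure_test=0)
        assert "a" in ds.cases
        assert ds.correlations["a"] == pytest.approx(1.0)

    def test_constant_sdi_excluded_with_warning(self):
        v = np.full(50, 42.0)
        y = np.linspace(20, 90, 50)
        with pytest.warns(UserWarning, match="constant"):
            ds = assemble_dataset({"a": _series(v)}, {"a": _curve(y)}, n_pure_test=0)
        assert "a" not in ds.cases
        assert "a" in ds.excluded

    def test_retained_set_matches_brute_force_filter(self):
        """20-case batch at threshold 0.3 against a per-case loop oracle."""
        rng = np.random.default_rng(5)
        sdi_by, eacl_by, oracle_keep = {}, {}, set()
        for k in range(20):
            x = rng.uniform(40, 100, 80)
            mix = rng.uniform(-0.5, 1.0)
            y = np.clip(mix * (x - 70) + 55 + rng.normal(0, 10, 80), 0, 100)
            sdi_by[f"c{k:02d}"] = _series(x)
            eacl_by[f"c{k:02d}"] = _curve(y)
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            if num / den >= 0.3:
                oracle_keep.add(f"c{k:02d}")
        ds = assemble_dataset(sdi_by, eacl_by, min_case_correlation=0.3, n_pure_test=0)
        assert set(ds.cases) == oracle_keep

    def test_no_overlap_skipped(self):
        with pytest.warns(UserWarning, match="overlap"):
            ds = assemble_dataset({"a": _series(np.linspace(1, 2, 10))},
                                  {"a": _curve([50.0, 60.0], t=np.array([500.0, 505.0]))},
                                  n_pure_test=0)
        assert "a" not in ds.cases

    def test_configured_pure_test_ids(self):
        v = np.linspace(20, 90, 50)
        ds = assemble_dataset({c: _series(v) for c in "abc"},
                              {c: _curve(v) for c in "abc"},
                              pure_test_ids=["b"])
        assert ds.pure_test == ["b"]
        assert set(ds.model_building) == {"a", "c"}


class TestTrainAnn:
    def test_seeded_determinism(self):
        ds = _toy_dataset()
        m1 = train_ann(ds, FAST)
        m2 = train_ann(ds, FAST)
        for (W1, b1), (W2, b2) in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(W1, W2)
            np.testing.assert_array_equal(b1, b2)

    def test_affine_map_learned(self):
        """A two-hidden-layer network must represent an affine target:
        noiseless y = 0.8 x + 10 reaches test MSE < 1 score^2."""
        ds = _toy_dataset(n_cases=6, n_points=200)
        model = train_ann(ds, AnnConfig(seed=3))
        x, y = ds.cases[ds.pure_test[0]]
        assert np.mean((predict(model, x) - y) ** 2) < 1.0

    def test_noisy_monotone_recovery(self):
        """Monotone mapping + noise SD 5: pure-test MAE within twice the
        noise floor (Gaussian MAE = sd * sqrt(2/pi))."""
        fn = lambda x: 100 / (1 + np.exp(-(x - 50) / 15))
        ds = _toy_dataset(n_cases=8, n_points=200, noise=5.0, seed=1, fn=fn)
        model = train_ann(ds, AnnConfig(seed=0))
        maes = []
        for cid in ds.pure_test:
            x, y = ds.cases[cid]
            maes.append(np.mean(np.abs(predict(model, x) - y)))
        assert np.mean(maes) <= 2 * 5.0 * np.sqrt(2 / np.pi)

    def test_empty_pool_rejected(self):
        ds = _toy_dataset()
        ds.model_building = []
        with pytest.raises(InvalidArgumentError):
            train_ann(ds, FAST)

    def test_history_within_epoch_budget(self):
        ds = _toy_dataset()
        model = train_ann(ds, FAST)
        assert 0 < len(model.history) <= FAST.max_epochs


class TestPredict:
    def test_hand_computed_forward_pass(self):
        """1-2-1 network with hand-set weights against manual arithmetic."""
        cfg = AnnConfig(hidden_layers=(2,), output_clip=False)
        W1 = np.array([[0.5, -1.0]])
        b1 = np.array([0.1, 0.2])
        W2 = np.array([[2.0], [0.3]])
        b2 = np.array([-0.05])
        model = AnnModel(config=cfg, weights=[(W1, b1), (W2, b2)],
                         x_scale=(0.0, 1.0), y_scale=(0.0, 1.0), trained=True)
        x = 0.4
        h = np.tanh(np.array([0.5 * x + 0.1, -1.0 * x + 0.2]))
        expected = 2.0 * h[0] + 0.3 * h[1] - 0.05
        assert predict(model, [x])[0] == pytest.approx(expected, abs=1e-12)

    def test_output_clipped_to_score_range(self):
        ds = _toy_dataset()
        model = train_ann(ds, FAST)
        out = predict(model, np.linspace(-500, 500, 101))
        assert out.min() >= 0.0 and out.max() <= 100.0

    def test_deterministic(self):
        ds = _toy_dataset()
        model = train_ann(ds, FAST)
        x = np.linspace(0, 100, 50)
        np.testing.assert_array_equal(predict(model, x), predict(model, x))

    def test_untrained_model_rejected(self):
        model = AnnModel(config=FAST, weights=[], x_scale=(0, 1), y_scale=(0, 1))
        with pytest.raises(InvalidArgumentError):
            predict(model, [1.0])


class TestEnsemble:
    def test_single_member_equals_member(self):
        ds = _toy_dataset()
        ens = train_ensemble(ds, FAST, n_members=1, base_seed=4)
        x = np.linspace(0, 100, 40)
        np.testing.assert_allclose(ensemble_predict(ens, x),
                                   predict(ens.members[0], x), atol=1e-12)

    def test_identical_seeds_identical_members(self):
        ds = _toy_dataset()
        a = train_ensemble(ds, FAST, n_members=1, base_seed=2)
        b = train_ensemble(ds, FAST, n_members=1, base_seed=2)
        x = np.linspace(0, 100, 40)
        np.testing.assert_array_equal(ensemble_predict(a, x), ensemble_predict(b, x))

    def test_mean_contract_pre_clip(self):
        ds = _toy_dataset()
        ens = train_ensemble(ds, FAST, n_members=3, base_seed=0)
        x = np.linspace(0, 100, 40)
        manual = np.mean([predict(m, x, clip=False) for m in ens.members], axis=0)
        np.testing.assert_allclose(ensemble_predict(ens, x, clip=False), manual, atol=1e-9)

    def test_member_average_at_a_point(self):
        # members predicting 40 and 60 average to 50
        cfg = AnnConfig(hidden_layers=(1,), output_clip=False)

        def const_model(value):
            return AnnModel(config=cfg, weights=[(np.zeros((1, 1)), np.zeros(1)),
                                                 (np.zeros((1, 1)), np.array([value]))],
                            x_scale=(0.0, 1.0), y_scale=(0.0, 1.0), trained=True)

        from hrvsdi.doa_model import Ensemble
        ens = Ensemble(members=[const_model(40.0), const_model(60.0)])
        assert ensemble_predict(ens, [5.0])[0] == pytest.approx(50.0)

    def test_serialisation_round_trip(self, tmp_path):
        ds = _toy_dataset()
        ens = train_ensemble(ds, FAST, n_members=2, base_seed=1)
        path = tmp_path / "ens.json"
        save_ensemble(ens, path)
        back = load_ensemble(path)
        x = np.linspace(0, 100, 30)
        np.testing.assert_allclose(ensemble_predict(back, x),
                                   ensemble_predict(ens, x), atol=1e-12)

    def test_model_dict_round_trip(self):
        ds = _toy_dataset()
        model = train_ann(ds, FAST)
        back = model_from_dict(model_to_dict(model))
        x = np.linspace(0, 100, 30)
        np.testing.assert_allclose(predict(back, x), predict(model, x), atol=1e-12)


class TestBlindCrossValidation:
    def test_identical_seeds_identical_rows(self):
        ds = _toy_dataset()
        a = blind_cross_validation(ds, FAST, n_repeats=2, base_seed=3)
        b = blind_cross_validation(ds, FAST, n_repeats=2, base_seed=3)
        assert a.equals(b)

    def test_table_shape(self):
        ds = _toy_dataset()
        table = blind_cross_validation(ds, FAST, n_repeats=3, base_seed=0)
        assert len(table) == 3
        assert {"corr_mean", "corr_sd", "mae_mean", "mae_sd"} <= set(table.columns)

    def test_empty_pure_test_rejected(self):
        ds = _toy_dataset()
        ds.pure_test = []
        with pytest.raises(InvalidArgumentError):
            blind_cross_validation(ds, FAST)
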