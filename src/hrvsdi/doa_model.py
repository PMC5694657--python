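"""Regression of the SDI onto the expert consciousness level (EACL).

A small feed-forward network (two hidden layers, 17 and 10 tanh nodes)
maps the scalar SDI at time t to the EACL score at t.  Samples are
pooled across the model-building cases and split 70/15/15 into
train/validation/test by a seeded shuffle; training minimises mean
squared error with a gradient method (Adam, full batch) and keeps the
weights of the best validation epoch within the 1000-epoch budget.

Because a single training run depends on its random initial weights, an
ensemble of independently seeded networks is trained and their outputs
averaged (EANN); blind cross-validation repeats the whole procedure to
check that the fit does not depend on the particular realisation.

The network is implemented directly on numpy: the model is tiny
(1-17-10-1) and bit-reproducibility under a seed is part of the
contract, so every arithmetic step is owned by this module.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

DEFAULT_HIDDEN = (17, 10)
DEFAULT_MAX_EPOCHS = 1000
DEFAULT_SPLIT = (0.70, 0.15, 0.15)
DEFAULT_N_MEMBERS = 10
DEFAULT_MIN_CASE_CORRELATION = 0.3


@dataclass(frozen=True)
class AnnConfig:
    """Architecture and training parameters of one network."""

    hidden_layers: tuple = DEFAULT_HIDDEN
    max_epochs: int = DEFAULT_MAX_EPOCHS
    split_fractions: tuple = DEFAULT_SPLIT
    seed: int = 0
    input_scaling: str = "minmax"   # none | minmax | zscore
    output_clip: bool = True
    learning_rate: float = 0.02
    patience: int = 150             # epochs without validation improvement before stopping
    split_level: str = "sample"     # sample | case

    def __post_init__(self):
        if not self.hidden_layers:
            raise InvalidArgumentError("hidden_layers must be nonempty")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise InvalidArgumentError("split fractions must sum to 1")
        if self.input_scaling not in ("none", "minmax", "zscore"):
            raise InvalidArgumentError("input_scaling must be none|minmax|zscore")
        if self.split_level not in ("sample", "case"):
            raise InvalidArgumentError("split_level must be sample|case")


@dataclass
class AnnModel:
    """A trained network: weights, fitted scalers, training history."""

    config: AnnConfig
    weights: list          # per layer: (W, b) ndarrays
    x_scale: tuple         # (offset, divisor) applied as (x - offset) / divisor
    y_scale: tuple
    history: list = field(default_factory=list)  # (train_loss, val_loss) per epoch
    seed: int = 0
    trained: bool = False


@dataclass
class CaseDataset:
    """Per-case aligned (SDI, EACL) pairs plus the role partition."""

    cases: dict            # case_id -> (x: sdi values, y: eacl scores)
    correlations: dict     # case_id -> per-case Pearson r (retained cases)
    model_building: list
    pure_test: list
    excluded: dict = field(default_factory=dict)  # case_id -> reason


# --- dataset assembly --------------------------------------------------

def align_case(sdi_series, eacl_curve):
    """Pair valid SDI samples with the EACL interpolated at their times."""
    t = sdi_series.times[sdi_series.valid]
    x = sdi_series.values[sdi_series.valid]
    et, em = eacl_curve.times[eacl_curve.valid], eacl_curve.mean[eacl_curve.valid]
    if et.size < 2 or t.size == 0:
        return np.array([]), np.array([])
    inside = (t >= et[0]) & (t <= et[-1])
    return x[inside], np.interp(t[inside], et, em)


def assemble_dataset(sdi_by_case: dict, eacl_by_case: dict,
                     min_case_correlation: float = DEFAULT_MIN_CASE_CORRELATION,
                     pure_test_ids=None, n_pure_test: int | None = None,
                     seed: int = 0) -> CaseDataset:
    """Align, filter and partition the per-case data.

    Cases whose SDI-EACL Pearson correlation is undefined (constant
    series) or below ``min_case_correlation`` are excluded — panel
    disagreement produces occasional low-correlation cases that would
    only inject label noise into the regression.  The retained cases are
    split into a model-building pool and a pure-test group, either by
    explicit ids or by a seeded draw (default about 19% held out,
    mirroring an 85/20 split at 105 cases).
    """
    cases, correlations, excluded = {}, {}, {}
    for cid in sorted(sdi_by_case, key=str):
        if cid not in eacl_by_case:
            excluded[cid] = "no EACL"
            warnings.warn(f"case {cid}: no EACL curve; skipped", stacklevel=2)
            continue
        x, y = align_case(sdi_by_case[cid], eacl_by_case[cid])
        if x.size < 3:
            excluded[cid] = "no overlapping timestamps"
            warnings.warn(f"case {cid}: no usable SDI/EACL overlap; skipped", stacklevel=2)
            continue
        if np.std(x) == 0 or np.std(y) == 0:
            excluded[cid] = "undefined correlation (constant series)"
            warnings.warn(f"case {cid}: constant series, correlation undefined; excluded",
                          stacklevel=2)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r < min_case_correlation:
            excluded[cid] = f"correlation {r:.3f} < {min_case_correlation}"
            continue
        cases[cid] = (x, y)
        correlations[cid] = r

    ids = list(cases)
    if pure_test_ids is not None:
        pure = [c for c in pure_test_ids if c in cases]
        building = [c for c in ids if c not in set(pure)]
    else:
        if n_pure_test is None:
            n_pure_test = max(1, round(0.19 * len(ids))) if len(ids) > 1 else 0
        rng = np.random.default_rng(seed)
        pure = sorted(rng.choice(ids, size=min(n_pure_test, len(ids) - 1),
                                 replace=False).tolist()) if n_pure_test else []
        building = [c for c in ids if c not in set(pure)]
    return CaseDataset(cases=cases, correlations=correlations,
                       model_building=building, pure_test=pure, excluded=excluded)


# --- network internals -------------------------------------------------

def _init_weights(sizes, rng):
    weights = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (n_in + n_out))
        weights.append((rng.uniform(-limit, limit, size=(n_in, n_out)),
                        np.zeros(n_out)))
    return weights


def _forward(weights, x):
    """Returns per-layer activations; hidden layers tanh, output linear."""
    a = [x]
    for i, (W, b) in enumerate(weights):
        z = a[-1] @ W + b
        a.append(z if i == len(weights) - 1 else np.tanh(z))
    return a


def _backward(weights, activations, y):
    n = y.shape[0]
    grads = [None] * len(weights)
    delta = 2.0 * (activations[-1] - y) / n
    for i in range(len(weights) - 1, -1, -1):
        grads[i] = (activations[i].T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ weights[i][0].T) * (1.0 - activations[i] ** 2)
    return grads


def _fit_scaler(kind, arr):
    if kind == "none":
        return (0.0, 1.0)
    if kind == "zscore":
        s = float(arr.std())
        return (float(arr.mean()), s if s > 0 else 1.0)
    lo, hi = float(arr.min()), float(arr.max())
    return (lo, (hi - lo) if hi > lo else 1.0)


def _scale(arr, scale):
    return (arr - scale[0]) / scale[1]


def _unscale(arr, scale):
    return arr * scale[1] + scale[0]


def _pool(dataset: CaseDataset, ids):
    xs = np.concatenate([dataset.cases[c][0] for c in ids])
    ys = np.concatenate([dataset.cases[c][1] for c in ids])
    return xs, ys


def _split_indices(n, fractions, rng):
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return order[:n_train], order[n_train:n_train + n_val], order[n_train + n_val:]


def train_ann(dataset: CaseDataset, config: AnnConfig = AnnConfig()) -> AnnModel:
    """Train one network on the pooled model-building samples.

    Deterministic given ``config.seed`` (initial weights and the
    70/15/15 shuffle both derive from it).  The returned model carries
    the weights of the epoch with the lowest validation loss.
    """
    if not dataset.model_building:
        raise InvalidArgumentError("model-building pool is empty")
    rng = np.random.default_rng(config.seed)

    if config.split_level == "case":
        ids = list(dataset.model_building)
        tr_i, va_i, _ = _split_indices(len(ids), config.split_fractions, rng)
        tr_ids = [ids[i] for i in tr_i] or ids
        va_ids = [ids[i] for i in va_i]
        x_tr, y_tr = _pool(dataset, tr_ids)
        x_va, y_va = _pool(dataset, va_ids) if va_ids else (np.array([]), np.array([]))
    else:
        x_all, y_all = _pool(dataset, dataset.model_building)
        tr, va, _ = _split_indices(x_all.size, config.split_fractions, rng)
        x_tr, y_tr = x_all[tr], y_all[tr]
        x_va, y_va = x_all[va], y_all[va]

    sizes = [1, *config.hidden_layers, 1]
    n_params = sum(W.size + b.size for W, b in _init_weights(sizes, np.random.default_rng(0)))
    if x_tr.size < n_params:
        warnings.warn(f"{x_tr.size} training samples for {n_params} parameters; "
                      "fit proceeds but may be under-determined", stacklevel=2)

    x_scale = _fit_scaler(config.input_scaling, x_tr)
    y_scale = _fit_scaler("minmax", y_tr)
    Xt = _scale(x_tr, x_scale).reshape(-1, 1)
    Yt = _scale(y_tr, y_scale).reshape(-1, 1)
    has_val = x_va.size > 0
    if has_val:
        Xv = _scale(x_va, x_scale).reshape(-1, 1)
        Yv = _scale(y_va, y_scale).reshape(-1, 1)

    weights = _init_weights(sizes, rng)
    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate

    best_loss, best_weights, best_epoch = np.inf, [(W.copy(), b.copy()) for W, b in weights], 0
    history = []
    for epoch in range(1, config.max_epochs + 1):
        acts = _forward(weights, Xt)
        train_loss = float(np.mean((acts[-1] - Yt) ** 2))
        grads = _backward(weights, acts, Yt)
        new_w = []
        for i, ((W, b), (gW, gb)) in enumerate(zip(weights, grads)):
            mW = b1 * m[i][0] + (1 - b1) * gW
            mb = b1 * m[i][1] + (1 - b1) * gb
            vW = b2 * v[i][0] + (1 - b2) * gW ** 2
            vb = b2 * v[i][1] + (1 - b2) * gb ** 2
            m[i], v[i] = (mW, mb), (vW, vb)
            c1, c2 = 1 - b1 ** epoch, 1 - b2 ** epoch
            new_w.append((W - lr * (mW / c1) / (np.sqrt(vW / c2) + eps),
                          b - lr * (mb / c1) / (np.sqrt(vb / c2) + eps)))
        weights = new_w

        if has_val:
            val_loss = float(np.mean((_forward(weights, Xv)[-1] - Yv) ** 2))
        else:
            val_loss = train_loss
        history.append((train_loss, val_loss))
        if val_loss < best_loss:
            best_loss, best_epoch = val_loss, epoch
            best_weights = [(W.copy(), b.copy()) for W, b in weights]
        elif epoch - best_epoch >= config.patience:
            break

    return AnnModel(config=config, weights=best_weights, x_scale=x_scale,
                    y_scale=y_scale, history=history, seed=config.seed, trained=True)


def predict(model: AnnModel, sdi_values, clip: bool | None = None) -> np.ndarray:
    """Forward pass on SDI values, in DoA score units.

    ``clip=None`` follows ``model.config.output_clip``; pass ``False``
    for the raw (pre-clip) output used inside the ensemble average.
    """
    if not model.trained:
        raise InvalidArgumentError("model is not trained")
    x = _scale(np.asarray(sdi_values, dtype=float), model.x_scale).reshape(-1, 1)
    y = _unscale(_forward(model.weights, x)[-1].ravel(), model.y_scale)
    if clip or (clip is None and model.config.output_clip):
        y = np.clip(y, 0.0, 100.0)
    return y


@dataclass
class Ensemble:
    """Independently trained members whose raw outputs are averaged."""

    members: list
    aggregation: str = "mean"

    def __post_init__(self):
        if not self.members:
            raise InvalidArgumentError("ensemble needs >= 1 member")


def train_ensemble(dataset: CaseDataset, config: AnnConfig = AnnConfig(),
                   n_members: int = DEFAULT_N_MEMBERS, base_seed: int = 0) -> Ensemble:
    """Train ``n_members`` networks differing only in seed."""
    members = []
    for k in range(n_members):
        cfg = AnnConfig(**{**config.__dict__, "seed": base_seed + k})
        members.append(train_ann(dataset, cfg))
    return Ensemble(members=members)


def ensemble_predict(ensemble: Ensemble, sdi_values, clip: bool = True) -> np.ndarray:
    """Pointwise mean of the members' pre-clip outputs, then clip."""
    preds = np.vstack([predict(mdl, sdi_values, clip=False) for mdl in ensemble.members])
    out = preds.mean(axis=0)
    return np.clip(out, 0.0, 100.0) if clip else out


def blind_cross_validation(dataset: CaseDataset, config: AnnConfig = AnnConfig(),
                           n_repeats: int = 10, base_seed: int = 0) -> pd.DataFrame:
    """Repeat the whole training with fresh seeds; per repeat, report
    mean +/- SD of per-case correlation and MAE over the pure-test group.
    """
    if not dataset.pure_test:
        raise InvalidArgumentError("pure-test group is empty")
    rows = []
    for rep in range(n_repeats):
        cfg = AnnConfig(**{**config.__dict__, "seed": base_seed + rep})
        model = train_ann(dataset, cfg)
        corrs, maes = [], []
        for cid in dataset.pure_test:
            x, y = dataset.cases[cid]
            yhat = predict(model, x)
            if np.std(yhat) == 0 or np.std(y) == 0:
                continue
            corrs.append(float(np.corrcoef(yhat, y)[0, 1]))
            maes.append(float(np.mean(np.abs(yhat - y))))
        rows.append({"repeat": rep, "seed": cfg.seed,
                     "corr_mean": np.mean(corrs), "corr_sd": np.std(corrs, ddof=1),
                     "mae_mean": np.mean(maes), "mae_sd": np.std(maes, ddof=1)})
    return pd.DataFrame(rows)


# --- serialisation -----------------------------------------------------

def model_to_dict(model: AnnModel) -> dict:
    return {
        "config": {**model.config.__dict__,
                   "hidden_layers": list(model.config.hidden_layers),
                   "split_fractions": list(model.config.split_fractions)},
        "weights": [[W.tolist(), b.tolist()] for W, b in model.weights],
        "x_scale": list(model.x_scale),
        "y_scale": list(model.y_scale),
        "seed": model.seed,
    }


def model_from_dict(d: dict) -> AnnModel:
    cfg_d = dict(d["config"])
    cfg_d["hidden_layers"] = tuple(cfg_d["hidden_layers"])
    cfg_d["split_fractions"] = tuple(cfg_d["split_fractions"])
    cfg = AnnConfig(**cfg_d)
    weights = [(np.asarray(W), np.asarray(b)) for W, b in d["weights"]]
    return AnnModel(config=cfg, weights=weights, x_scale=tuple(d["x_scale"]),
                    y_scale=tuple(d["y_scale"]), seed=d["seed"], trained=True)


def save_ensemble(ensemble: Ensemble, path) -> None:
    with open(path, "w") as fh:
        json.dump({"aggregation": ensemble.aggregation,
                   "members": [model_to_dict(m) for m in ensemble.members]}, fh)


def load_ensemble(path) -> Ensemble:
    with open(path) as fh:
        d = json.load(fh)
    return Ensemble(members=[model_from_dict(m) for m in d["members"]],
                    aggregation=d.get("aggregation", "mean"))
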