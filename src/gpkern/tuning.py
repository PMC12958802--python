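"""Hyperparameter tuning and epoch-selection protocol for the networks.

The protocol: sample a budget of configurations (random search over the
declared space); train each on one randomly chosen training/validation pair
with early stopping (patience 7, up to 500 epochs); retrain the 4 best
configurations on all validation splits for the full epoch budget; pick the
winner by binned validation loss (10 bins of 50 epochs, bin loss = average
over the bin of the across-split mean + sd, winner takes the most bins); and
choose the epoch count as the earliest minimizer of the 20-epoch rolling
mean of the validation loss summed across splits.

Ties in bins won are broken by fewest parameters, then lowest overall mean
validation loss.  The final configuration is trained in 10 independently
seeded replicates, whose penultimate-layer outputs can be recombined into
fusion training sets to propagate single-model sampling variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidConfigError
from .ffn import FFNConfig, Network, SearchSpace, build_network

__all__ = [
    "TuningResult",
    "tune_hyperparameters",
    "select_best_config",
    "select_epochs",
    "train_final",
    "assemble_fusion_inputs",
]


@dataclass
class EvaluatedConfig:
    config: FFNConfig
    split_id: int
    trajectory: list  # validation loss per trained epoch (early-stopped)
    failed: bool = False

    @property
    def best_loss(self) -> float:
        return float(np.min(self.trajectory)) if self.trajectory else np.inf


@dataclass
class TuningResult:
    """Everything the tuning protocol produced."""

    evaluated: list  # EvaluatedConfig per sampled configuration
    top_configs: list  # FFNConfig, ranked
    top_trajectories: list  # (n_splits, n_epochs) arrays, aligned with top_configs
    selected_config: FFNConfig = None
    selected_epochs: int = None
    param_counts: list = field(default_factory=list)


def _train_once(config, X, y, tr_idx, va_idx, seed, max_epochs, patience):
    net = build_network(config.arch, _input_shape(X), seed=seed)
    history = net.fit(
        _rows(X, tr_idx),
        y[tr_idx],
        epochs=max_epochs,
        X_val=_rows(X, va_idx),
        y_val=y[va_idx],
        patience=patience,
        spec=config.training,
    )
    return net, history


def _input_shape(X):
    X = np.asarray(X)
    return X.shape[1] if X.ndim == 2 else tuple(X.shape[1:])


def _rows(X, idx):
    return np.asarray(X)[np.asarray(idx)]


def tune_hyperparameters(
    space: SearchSpace,
    X,
    y,
    splits,
    budget: int = 40,
    seed: int = 0,
    max_epochs: int = 500,
    patience: int = 7,
    top_k: int = 4,
) -> TuningResult:
    """Run the full tuning protocol and return the selected configuration.

    ``splits`` is a list of dicts with boolean/integer ``train_index`` and
    ``val_index`` arrays (as produced by ``make_validation_splits``); each
    sampled configuration is trained on one randomly chosen pair to avoid
    overfitting a single validation set.
    """
    if len(splits) < 2:
        raise InvalidConfigError("at least 2 train/validation splits required")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    idx_pairs = [
        (np.where(np.asarray(s["train_index"]))[0], np.where(np.asarray(s["val_index"]))[0])
        if np.asarray(s["train_index"]).dtype == bool
        else (np.asarray(s["train_index"]), np.asarray(s["val_index"]))
        for s in splits
    ]

    evaluated = []
    for i in range(budget):
        config = space.sample(rng)
        split_id = int(rng.integers(len(idx_pairs)))
        tr, va = idx_pairs[split_id]
        try:
            _, history = _train_once(
                config, X, y, tr, va, seed=seed + 1000 + i,
                max_epochs=max_epochs, patience=patience,
            )
            failed = not np.all(np.isfinite(history))
        except FloatingPointError:  # pragma: no cover - divergence guard
            history, failed = [], True
        evaluated.append(
            EvaluatedConfig(config=config, split_id=split_id, trajectory=list(history),
                            failed=failed)
        )

    ranked = sorted(
        [e for e in evaluated if not e.failed], key=lambda e: e.best_loss
    )[:top_k]
    top_configs, top_trajs, param_counts = [], [], []
    for j, e in enumerate(ranked):
        rows = []
        for tr, va in idx_pairs:
            net, history = _train_once(
                e.config, X, y, tr, va, seed=seed + 5000 + j,
                max_epochs=max_epochs, patience=None,
            )
            rows.append(history)
        top_configs.append(e.config)
        top_trajs.append(np.array(rows))
        param_counts.append(net.n_params())

    result = TuningResult(
        evaluated=evaluated,
        top_configs=top_configs,
        top_trajectories=top_trajs,
        param_counts=param_counts,
    )
    if top_configs:
        winner = select_best_config(top_trajs, param_counts)
        result.selected_config = top_configs[winner]
        result.selected_epochs = select_epochs(top_trajs[winner])
    return result


def select_best_config(
    trajectories, param_counts=None, bin_width: int = 50, n_bins: int = 10
) -> int:
    """Index of the configuration winning the most validation-loss bins.

    For each configuration, per-epoch mean and sd of the validation loss are
    taken across splits; epochs are grouped into ``n_bins`` bins of
    ``bin_width`` epochs; the bin loss is the average over the bin of
    (mean + sd).  The configuration with the lowest bin loss in the most
    bins wins; ties break on fewest parameters, then lowest overall mean
    loss.
    """
    trajectories = [np.asarray(t, dtype=float) for t in trajectories]
    n_epochs = min(t.shape[1] for t in trajectories)
    n_bins_eff = min(n_bins, int(np.ceil(n_epochs / bin_width)))
    scores = []
    for t in trajectories:
        per_epoch = t[:, :n_epochs].mean(axis=0) + t[:, :n_epochs].std(axis=0, ddof=0)
        bins = [
            per_epoch[b * bin_width : (b + 1) * bin_width].mean()
            for b in range(n_bins_eff)
        ]
        scores.append(bins)
    scores = np.array(scores)  # configs x bins
    wins = (scores == scores.min(axis=0, keepdims=True)).sum(axis=1)
    best = np.where(wins == wins.max())[0]
    if best.size > 1 and param_counts is not None:
        pc = np.asarray(param_counts, dtype=float)[best]
        best = best[pc == pc.min()]
    if best.size > 1:
        overall = np.array([trajectories[i][:, :n_epochs].mean() for i in best])
        best = best[[int(np.argmin(overall))]]
    return int(best[0])


def select_epochs(trajectories, window: int = 20) -> int:
    """Earliest epoch minimizing the rolling mean of the summed validation loss.

    The loss is summed across splits per epoch; a trailing rolling mean of
    ``window`` epochs is evaluated at every epoch where the window is full,
    and the earliest minimizer (1-based epoch count) is returned.
    """
    t = np.asarray(trajectories, dtype=float)
    summed = t.sum(axis=0)
    n = summed.size
    if n < window:
        raise InvalidConfigError(f"need at least {window} epochs, got {n}")
    csum = np.concatenate([[0.0], np.cumsum(summed)])
    rolling = (csum[window:] - csum[:-window]) / window  # ends at epochs window..n
    best = int(np.argmin(rolling))  # earliest due to argmin tie rule
    return best + window  # 1-based epoch count at the window end


def train_final(
    config: FFNConfig,
    X_train,
    y_train,
    epochs: int,
    X_test=None,
    n_replicates: int = 10,
    seed: int = 0,
):
    """Train ``n_replicates`` independently initialized copies of a config.

    Returns (models, predictions) where predictions is a list of test-set
    prediction arrays (or None entries when no test inputs were given).
    Replicates that diverge (non-finite loss) are dropped with a warning.
    """
    import warnings

    models, preds = [], []
    for r in range(n_replicates):
        net = build_network(config.arch, _input_shape(X_train), seed=seed + r)
        history = net.fit(
            np.asarray(X_train), np.asarray(y_train, dtype=float),
            epochs=epochs, spec=config.training,
        )
        if not np.all(np.isfinite(history)):
            warnings.warn(f"replicate {r} diverged; excluded")
            continue
        models.append(net)
        preds.append(net.predict(np.asarray(X_test)) if X_test is not None else None)
    return models, preds


def assemble_fusion_inputs(replicates_by_modality: dict, X_by_modality: dict,
                           n_sets: int = 10, seed: int = 0):
    """Concatenate penultimate outputs of randomly chosen replicates.

    For each of ``n_sets`` fusion training sets, one trained replicate per
    modality is sampled and its final-hidden-layer outputs on that modality's
    inputs are concatenated column-wise.  Returns (list of arrays, list of
    chosen replicate index dicts).
    """
    if not replicates_by_modality:
        raise InvalidConfigError("no modalities supplied")
    for name, reps in replicates_by_modality.items():
        if not reps:
            raise InvalidConfigError(f"modality {name!r} has no trained replicates")
        if name not in X_by_modality:
            raise InvalidConfigError(f"missing inputs for modality {name!r}")
    rng = np.random.default_rng(seed)
    sets, choices = [], []
    names = list(replicates_by_modality)
    for _ in range(n_sets):
        chosen = {n: int(rng.integers(len(replicates_by_modality[n]))) for n in names}
        blocks = [
            replicates_by_modality[n][chosen[n]].penultimate(X_by_modality[n])
            for n in names
        ]
        sets.append(np.column_stack(blocks))
        choices.append(chosen)
    return sets, choices
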