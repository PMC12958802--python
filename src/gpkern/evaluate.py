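"""Scoring of predictions under a five-problem taxonomy.

The taxonomy separates prediction problems by the data modalities a model may
use and by what it therefore predicts: (1) additive genomic only — breeding
values; (2) plus dominance — hybrid values; (3) plus non-linear genomic
kernels or genomic networks — total genetic values; (4) plus soil, weather
and their interactions — phenotypes; (5) soil and/or weather only — site
means.  Models are scored by Pearson's r and RMSE, across and within
environments, with replicate-aware many-to-one significance testing
(Dunnett's test) against a designated control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidConfigError, ProblemMismatchError, ShapeError

__all__ = [
    "ProblemSpec",
    "ModelResult",
    "EvalReport",
    "problem",
    "score",
    "rmse_decomposition",
    "intercept_baseline",
    "dunnett_test",
    "run_taxonomy",
]

_PROBLEMS = {
    1: ("breeding value", {"genomic_additive"}),
    2: ("hybrid value", {"genomic_additive", "genomic_dominance"}),
    3: (
        "total genetic value",
        {"genomic_additive", "genomic_dominance", "genomic_nonlinear"},
    ),
    4: (
        "phenotype",
        {
            "genomic_additive",
            "genomic_dominance",
            "genomic_nonlinear",
            "soil",
            "weather",
            "interaction",
        },
    ),
    5: ("site mean", {"soil", "weather"}),
}


@dataclass(frozen=True)
class ProblemSpec:
    """One of the five prediction problems: id, predictand, allowed modalities."""

    problem_id: int
    predictand: str
    allowed_modalities: frozenset


def problem(problem_id: int) -> ProblemSpec:
    if problem_id not in _PROBLEMS:
        raise InvalidConfigError(f"unknown problem id {problem_id}")
    predictand, allowed = _PROBLEMS[problem_id]
    return ProblemSpec(problem_id, predictand, frozenset(allowed))


@dataclass
class ModelResult:
    """Replicate predictions of one fitted model on the test set."""

    name: str
    modalities: set
    predictions: np.ndarray  # (n_replicates, n_test)

    def __post_init__(self):
        self.predictions = np.atleast_2d(np.asarray(self.predictions, dtype=float))


@dataclass
class EvalReport:
    """Tidy metric table plus significance tests and the intercept baseline."""

    problem: ProblemSpec
    metrics: pd.DataFrame  # model, replicate, scope, env, metric, value
    dunnett: pd.DataFrame
    baseline_rmse: float
    control: str = None


# ---------------------------------------------------------------------------
# metrics


def _pearson(obs, pred):
    if np.std(obs) == 0 or np.std(pred) == 0:
        return np.nan
    return float(np.corrcoef(obs, pred)[0, 1])


def score(observed, predicted, env_labels=None, min_group: int = 3) -> pd.DataFrame:
    """Pearson r and RMSE, across environments and per environment.

    Environments with fewer than ``min_group`` records are skipped; groups
    with zero observed variance get r recorded as missing with a warning.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ShapeError("observed and predicted must align")
    if obs.size < min_group:
        raise InvalidConfigError(f"need at least {min_group} records")
    rows = [
        {"scope": "across", "env": None, "metric": "r", "value": _pearson(obs, pred)},
        {
            "scope": "across",
            "env": None,
            "metric": "rmse",
            "value": float(np.sqrt(np.mean((obs - pred) ** 2))),
        },
    ]
    if env_labels is not None:
        env_labels = np.asarray(env_labels)
        for env in pd.unique(env_labels):
            m = env_labels == env
            if m.sum() < min_group:
                continue
            r = _pearson(obs[m], pred[m])
            if np.isnan(r):
                warnings.warn(f"zero-variance group {env!r}: r undefined")
            rows.append({"scope": "within", "env": env, "metric": "r", "value": r})
            rows.append(
                {
                    "scope": "within",
                    "env": env,
                    "metric": "rmse",
                    "value": float(np.sqrt(np.mean((obs[m] - pred[m]) ** 2))),
                }
            )
    return pd.DataFrame(rows)


def rmse_decomposition(observed, predicted) -> tuple:
    """Orthogonal MSE decomposition: (bias^2, sd-mismatch^2, correlation-lack).

    MSE = (mean_p - mean_o)^2 + (sd_p - sd_o)^2 + 2 sd_p sd_o (1 - r); the
    correlation term is set to 0 when either sd vanishes.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3:
        raise InvalidConfigError("need at least 3 records")
    so, sp = obs.std(), pred.std()
    bias2 = (pred.mean() - obs.mean()) ** 2
    sd2 = (sp - so) ** 2
    if so == 0 or sp == 0:
        lack = 0.0
    else:
        lack = 2.0 * sp * so * (1.0 - _pearson(obs, pred))
    return float(bias2), float(sd2), float(lack)


def intercept_baseline(train_y, test_y) -> float:
    """RMSE of predicting every test record with the training mean."""
    train_y = np.asarray(train_y, dtype=float)
    test_y = np.asarray(test_y, dtype=float)
    if train_y.size == 0 or test_y.size == 0:
        raise InvalidConfigError("empty partition")
    return float(np.sqrt(np.mean((test_y - train_y.mean()) ** 2)))


# ---------------------------------------------------------------------------
# Dunnett's test


def dunnett_test(
    samples: dict,
    control: str,
    direction: str = "greater",
    n_mc: int = 400_000,
    seed: int = 0,
) -> pd.DataFrame:
    """One-sided many-to-one comparisons against a control group.

    ``samples`` maps group name -> replicate metric values.  The max-T
    adjusted p-values are computed by Monte-Carlo integration of the
    multivariate-t reference distribution under the classical equal-variance
    assumption (a Welch-style caveat is warned when group variances differ
    by more than 4x).  ``direction='greater'`` tests treatment > control
    (use for r); ``'less'`` tests treatment < control (use for RMSE).
    """
    if direction not in ("greater", "less"):
        raise InvalidConfigError("direction must be 'greater' or 'less'")
    if control not in samples:
        raise InvalidConfigError(f"control group {control!r} not among samples")
    names = [k for k in samples if k != control]
    if not names:
        raise InvalidConfigError("no treatment groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InvalidConfigError(f"group {k!r} needs >= 2 replicates")

    variances = np.array([v.var(ddof=1) for v in arrays.values()])
    pos = variances[variances > 0]
    if pos.size and pos.max() / max(pos.min(), 1e-300) > 4:
        warnings.warn("group variances differ by more than 4x; "
                      "equal-variance Dunnett may be anti-conservative")

    nc = arrays[control].size
    mc_mean = arrays[control].mean()
    df = sum(v.size - 1 for v in arrays.values())
    s2 = sum((v.size - 1) * v.var(ddof=1) for v in arrays.values()) / df

    tstats, lams, ns = [], [], []
    for k in names:
        v = arrays[k]
        diff = v.mean() - mc_mean if direction == "greater" else mc_mean - v.mean()
        se = np.sqrt(s2 * (1.0 / v.size + 1.0 / nc))
        tstats.append(diff / se if se > 0 else 0.0)
        lams.append(np.sqrt(v.size / (v.size + nc)))
        ns.append(v.size)
    tstats = np.array(tstats)
    lams = np.array(lams)

    if s2 == 0:
        # all groups constant: equal means -> p = 1, any difference separates
        p_adj = np.where(tstats > 0, 0.0, 1.0)
    else:
        rng = np.random.default_rng(seed)
        z0 = rng.standard_normal(n_mc)
        zi = rng.standard_normal((n_mc, len(names)))
        Z = lams[None, :] * z0[:, None] + np.sqrt(1.0 - lams**2)[None, :] * zi
        denom = np.sqrt(rng.chisquare(df, size=n_mc) / df)
        T_max = (Z / denom[:, None]).max(axis=1)
        p_adj = np.array([np.mean(T_max >= t) for t in tstats])

    return pd.DataFrame(
        {
            "group": names,
            "n": ns,
            "mean_diff": [
                arrays[k].mean() - mc_mean for k in names
            ],
            "t": tstats,
            "p_adj": p_adj,
        }
    ).set_index("group")


# ---------------------------------------------------------------------------
# taxonomy


def run_taxonomy(
    prob: ProblemSpec,
    models: list,
    observed,
    env_labels,
    train_y,
    control: str = None,
    metric_for_test: str = "r",
    seed: int = 0,
) -> EvalReport:
    """Score a set of models under one prediction problem.

    Every model's modality set must be a subset of the problem's allowed
    modalities — a violation raises naming the offending modality, so a
    model built for a richer problem can never silently enter a simpler
    comparison.
    """
    observed = np.asarray(observed, dtype=float)
    for m in models:
        extra = set(m.modalities) - set(prob.allowed_modalities)
        if extra:
            raise ProblemMismatchError(
                f"model {m.name!r} uses modalities {sorted(extra)} not allowed "
                f"in problem {prob.problem_id} ({prob.predictand})"
            )
    frames = []
    for m in models:
        for rep in range(m.predictions.shape[0]):
            sc = score(observed, m.predictions[rep], env_labels)
            sc.insert(0, "replicate", rep)
            sc.insert(0, "model", m.name)
            frames.append(sc)
    metrics = pd.concat(frames, ignore_index=True)

    dunnett = pd.DataFrame()
    if control is not None and len(models) > 1:
        across = metrics[(metrics["scope"] == "across") & (metrics["metric"] == metric_for_test)]
        groups = {
            name: grp["value"].to_numpy() for name, grp in across.groupby("model")
        }
        direction = "greater" if metric_for_test == "r" else "less"
        dunnett = dunnett_test(groups, control=control, direction=direction, seed=seed)

    baseline = intercept_baseline(train_y, observed)
    return EvalReport(
        problem=prob, metrics=metrics, dunnett=dunnett,
        baseline_rmse=baseline, control=control,
    )
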