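"""Bayesian multi-kernel RKHS regression via Gibbs sampling in the eigenbasis.

Model: y = 1*mu + sum_k u_k + eps, with u_k ~ N(0, K_k sig2_k) for each
kernel in the set and eps ~ N(0, I sig2_e).  Writing u_k = U_k b_k in the
(truncated) eigenbasis K_k = U_k diag(lambda_k) U_k' turns every full
conditional into an independent-component Gaussian, which is what makes the
sampler efficient: each sweep costs O(N r_k) per kernel.

Kernels are built over all records (training and test); the likelihood
conditions on training responses only.  This is implemented by data
augmentation — test responses are imputed from their posterior predictive
each sweep — which is marginally equivalent to dropping them from the
likelihood while keeping all conditionals diagonal.

Variances carry scaled-inverse-chi-square priors; the population mean has a
flat prior.  The usual interface is the Model/Results pair::

    model = MultiKernelRKHS(y, {"A": K_add, "E": K_env}, train_mask=mask)
    res = model.fit(n_iter=15000, burnin=5000, thin=5, seed=1)
    res.variance_components()
    res.predict(test_ids)
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    DivergenceError,
    EstimationError,
    InvalidConfigError,
    RecordLookupError,
)
from .kernels import EigenBasis, KernelMatrix, eigendecompose

__all__ = ["ChainConfig", "MultiKernelRKHS", "RKHSResults", "fit_multikernel"]

DEFAULT_PRIOR_DF = 5.0


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain settings (defaults: 15,000 sweeps, 5,000 burn-in, thin 5)."""

    n_iter: int = 15000
    burnin: int = 5000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_iter <= self.burnin:
            raise InvalidConfigError("n_iter must exceed burnin")
        if self.thin < 1:
            raise InvalidConfigError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burnin) // self.thin


def _kernel_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, order-insensitive stream per kernel name."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


class MultiKernelRKHS:
    """Multi-kernel RKHS model over a fixed set of labeled records.

    Parameters
    ----------
    y : array over all records; entries outside the training mask may be NaN.
    kernels : mapping name -> KernelMatrix or EigenBasis, all sharing the
        full record labeling.
    train_mask : boolean array marking training records (default: all).
    prior_df : degrees of freedom of the scaled-inv-chi-square variance priors.
    prior_scales : optional mapping name/'residual' -> prior scale; by default
        scales are set so each prior mode equals var(y_train)/(n_kernels+1).
    """

    def __init__(self, y, kernels, train_mask=None, labels=None,
                 prior_df: float = DEFAULT_PRIOR_DF, prior_scales=None):
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        if train_mask is None:
            train_mask = np.ones(n, dtype=bool)
        self.train_mask = np.asarray(train_mask, dtype=bool)
        if self.train_mask.size != n:
            raise InvalidConfigError("train_mask length must match y")
        if not np.any(self.train_mask):
            raise InvalidConfigError("no training records")
        if not np.all(np.isfinite(self.y[self.train_mask])):
            raise InvalidConfigError("training responses must be finite")

        self.bases = {}
        self.labels = list(labels) if labels is not None else None
        for name, K in kernels.items():
            if isinstance(K, KernelMatrix):
                basis = eigendecompose(K, tol=1e-10, max_rank=K.n)
            elif isinstance(K, EigenBasis):
                basis = K
            else:
                raise InvalidConfigError(f"kernel {name!r} must be KernelMatrix or EigenBasis")
            if basis.vectors.shape[0] != n:
                raise InvalidConfigError(f"kernel {name!r} does not span all records")
            if self.labels is None:
                self.labels = list(basis.labels)
            elif list(basis.labels) != self.labels:
                raise InvalidConfigError(f"kernel {name!r} labels differ from the model's")
            self.bases[name] = basis
        if not self.bases:
            raise InvalidConfigError("at least one kernel is required")
        if self.labels is None:
            self.labels = list(range(n))

        self.prior_df = float(prior_df)
        vy = float(np.var(self.y[self.train_mask]))
        default_scale = vy * (self.prior_df + 2.0) / (
            self.prior_df * (len(self.bases) + 1.0)
        )
        self.prior_scales = {name: default_scale for name in self.bases}
        self.prior_scales["residual"] = default_scale
        if prior_scales:
            self.prior_scales.update(prior_scales)

    # -- sampling ---------------------------------------------------------

    def fit(self, n_iter: int = 15000, burnin: int = 5000, thin: int = 5,
            seed: int = 0, fixed_variances=None, fixed_mu=None) -> "RKHSResults":
        """Run the Gibbs sampler and return retained posterior draws.

        ``fixed_variances`` may pin any of the kernel variances and/or
        'residual' at known values (degenerate priors); ``fixed_mu`` pins the
        population mean.
        """
        chain = ChainConfig(n_iter=n_iter, burnin=burnin, thin=thin, seed=seed)
        names = list(self.bases)
        n = self.y.size
        test = ~self.train_mask
        fixed_variances = dict(fixed_variances or {})

        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
        rngs = {name: _kernel_rng(seed, name) for name in names}

        vy = float(np.var(self.y[self.train_mask]))
        mu = float(fixed_mu) if fixed_mu is not None else float(
            np.mean(self.y[self.train_mask])
        )
        sig2 = {
            name: float(fixed_variances.get(name, vy / (len(names) + 1.0)))
            for name in names
        }
        sig2_e = float(fixed_variances.get("residual", vy / (len(names) + 1.0)))

        b = {name: np.zeros(self.bases[name].rank) for name in names}
        u = {name: np.zeros(n) for name in names}
        g = np.zeros(n)
        y_full = self.y.copy()
        y_full[test] = mu

        df0 = self.prior_df
        n_keep = chain.n_retained
        mu_draws = np.empty(n_keep)
        sig2_draws = {name: np.empty(n_keep) for name in names}
        sig2_e_draws = np.empty(n_keep)
        g_draws = np.empty((n_keep, n))
        keep = 0

        for it in range(chain.n_iter):
            # data augmentation: impute unobserved responses
            if np.any(test):
                y_full[test] = mu + g[test] + rng.normal(
                    scale=np.sqrt(sig2_e), size=int(test.sum())
                )

            e = y_full - mu - g
            for name in names:
                basis = self.bases[name]
                lam = basis.values
                r_k = e + u[name]
                yt = basis.vectors.T @ r_k
                var_j = lam * sig2[name] * sig2_e / (lam * sig2[name] + sig2_e)
                mean_j = var_j * yt / sig2_e
                b[name] = mean_j + np.sqrt(var_j) * rngs[name].standard_normal(lam.size)
                u_new = basis.vectors @ b[name]
                e = r_k - u_new
                u[name] = u_new
                if name not in fixed_variances:
                    ssq = float(np.sum(b[name] ** 2 / lam))
                    df_n = df0 + lam.size
                    sig2[name] = (df0 * self.prior_scales[name] + ssq) / rngs[
                        name
                    ].chisquare(df_n)
            g = sum(u.values())

            if not np.all(np.isfinite(e)):
                raise DivergenceError(f"non-finite residuals at iteration {it}")

            if fixed_mu is None:
                resid0 = y_full - g
                mu = float(rng.normal(resid0.mean(), np.sqrt(sig2_e / n)))
            if "residual" not in fixed_variances:
                resid = y_full - mu - g
                sig2_e = float(
                    (df0 * self.prior_scales["residual"] + resid @ resid)
                    / rng.chisquare(df0 + n)
                )

            if it >= chain.burnin and (it - chain.burnin) % chain.thin == 0 and keep < n_keep:
                mu_draws[keep] = mu
                for name in names:
                    sig2_draws[name][keep] = sig2[name]
                sig2_e_draws[keep] = sig2_e
                g_draws[keep] = g
                keep += 1

        return RKHSResults(
            model=self,
            chain=chain,
            mu_draws=mu_draws[:keep],
            sig2_draws={k: v[:keep] for k, v in sig2_draws.items()},
            sig2_e_draws=sig2_e_draws[:keep],
            g_draws=g_draws[:keep],
        )


def _batch_mc_se(draws: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Batch-means Monte-Carlo standard error along axis 0."""
    m = draws.shape[0]
    nb = min(n_batches, max(m // 2, 1))
    size = m // nb
    trimmed = draws[: nb * size]
    means = trimmed.reshape(nb, size, *draws.shape[1:]).mean(axis=1)
    return means.std(axis=0, ddof=1) / np.sqrt(nb)


@dataclass
class RKHSResults:
    """Retained posterior draws of a fitted multi-kernel RKHS model."""

    model: MultiKernelRKHS
    chain: ChainConfig
    mu_draws: np.ndarray
    sig2_draws: dict
    sig2_e_draws: np.ndarray
    g_draws: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.mu_draws.size

    def _indices(self, record_ids):
        if record_ids is None:
            return np.arange(len(self.model.labels))
        lookup = {lab: i for i, lab in enumerate(self.model.labels)}
        try:
            return np.array([lookup[r] for r in record_ids])
        except KeyError as exc:
            raise RecordLookupError(f"unknown record {exc.args[0]!r}") from exc

    def predict(self, record_ids=None, destandardize=None, with_se: bool = False):
        """Posterior mean of mu + g at the requested records.

        ``destandardize`` may be a (mean, sd) pair or an object with
        train_mean/train_sd attributes to map back to the original scale.
        """
        if self.n_retained == 0:
            raise EstimationError("no retained draws")
        idx = self._indices(record_ids)
        draws = self.mu_draws[:, None] + self.g_draws[:, idx]
        pred = draws.mean(axis=0)
        se = _batch_mc_se(draws)
        if destandardize is not None:
            if hasattr(destandardize, "train_mean"):
                mean, sd = destandardize.train_mean, destandardize.train_sd
            else:
                mean, sd = destandardize
            pred = pred * sd + mean
            se = se * sd
        return (pred, se) if with_se else pred

    def variance_components(self) -> pd.DataFrame:
        """Posterior summary of every variance and its share of the total."""
        if self.n_retained == 0:
            raise EstimationError("no retained draws to summarize")
        comp = dict(self.sig2_draws)
        comp["residual"] = self.sig2_e_draws
        total = sum(comp.values())
        rows = []
        for name, draws in comp.items():
            prop = draws / total
            rows.append(
                {
                    "component": name,
                    "mean": draws.mean(),
                    "sd": draws.std(ddof=1),
                    "ci2.5": np.quantile(draws, 0.025),
                    "ci97.5": np.quantile(draws, 0.975),
                    "proportion": prop.mean(),
                    "prop_ci2.5": np.quantile(prop, 0.025),
                    "prop_ci97.5": np.quantile(prop, 0.975),
                }
            )
        return pd.DataFrame(rows).set_index("component")

    def summary(self) -> str:
        vc = self.variance_components()
        lines = [
            "Multi-kernel RKHS regression (Gibbs)",
            f"records: {len(self.model.labels)}  "
            f"(train {int(self.model.train_mask.sum())})",
            f"chain: {self.chain.n_iter} iter, burn-in {self.chain.burnin}, "
            f"thin {self.chain.thin} -> {self.n_retained} draws",
            f"posterior mean mu: {self.mu_draws.mean():.4f}",
            "",
            vc.round(4).to_string(),
        ]
        return "\n".join(lines)


def fit_multikernel(y, kernels, train_mask=None, **fit_kwargs) -> RKHSResults:
    """Convenience wrapper: build the model and run the sampler in one call."""
    return MultiKernelRKHS(y, kernels, train_mask=train_mask).fit(**fit_kwargs)
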