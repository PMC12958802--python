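"""Genomic predictor sets: allele codings, principal components, GWAS subsets.

Additive effects are modeled by centered reference-allele counts and
dominance deviations by the Hardy-Weinberg coding, so that under HWE both
codings have zero expectation.  Principal components of parental genotypes
can be carried to hybrids either by averaging parental scores or by
projecting averaged genotypes; the two paths are algebraically identical and
both are exposed for verification.  A per-environment mixed-model GWAS with
Fisher combination of p-values produces reduced SNP subsets of a requested
size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    EstimationError,
    MonomorphicLocusError,
    ShapeError,
)

__all__ = [
    "CodedGenotypes",
    "PCBasis",
    "GwasSelection",
    "additive_code",
    "dominance_code",
    "compute_pcs",
    "hybrid_gpcs",
    "hybrid_covariance_identity",
    "fisher_combine",
    "gwas_select_snps",
]

P_VALUE_FLOOR = 1e-300


@dataclass
class CodedGenotypes:
    """Real-valued genotype coding with its source allele frequencies."""

    values: np.ndarray
    coding: str  # 'additive' | 'dominance'
    freqs: np.ndarray
    individual_ids: list = None
    locus_ids: list = None


@dataclass
class PCBasis:
    """Truncated centered PCA of a genotype (or coded) matrix.

    ``loadings`` are loci x retained components, ``scores`` individuals x
    retained components; ``explained`` holds the explained-variance fraction
    of every component (not just the retained ones).
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained: np.ndarray
    threshold: float
    mean_: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[1]


@dataclass
class GwasSelection:
    """Per-environment and combined GWAS p-values with the selected loci."""

    pvalues: pd.DataFrame  # loci x environments
    combined: pd.Series  # loci
    selected: list


def _check_freqs(freqs, allow_monomorphic):
    freqs = np.asarray(freqs, dtype=float)
    if not allow_monomorphic and (np.any(freqs <= 0.0) or np.any(freqs >= 1.0)):
        bad = np.where((freqs <= 0.0) | (freqs >= 1.0))[0]
        raise MonomorphicLocusError(
            f"{bad.size} monomorphic loci (freq 0 or 1) must be dropped before coding"
        )
    return freqs


def additive_code(G, freqs=None, allow_monomorphic=False) -> CodedGenotypes:
    """Additive coding: call c at locus l maps to c - 2 p_l."""
    calls = np.asarray(G.calls, dtype=float)
    if freqs is None:
        freqs = G.ref_allele_freqs
    freqs = _check_freqs(freqs, allow_monomorphic)
    values = calls - 2.0 * freqs[None, :]
    return CodedGenotypes(
        values=values,
        coding="additive",
        freqs=freqs,
        individual_ids=list(G.individual_ids),
        locus_ids=list(G.locus_ids),
    )


def dominance_code(G, freqs=None, allow_monomorphic=False) -> CodedGenotypes:
    """Dominance coding under HWE: calls (0,1,2) -> (-2p^2, 2pq, -2q^2)."""
    calls = np.asarray(G.calls, dtype=float)
    if freqs is None:
        freqs = G.ref_allele_freqs
    p = _check_freqs(freqs, allow_monomorphic)
    q = 1.0 - p
    # quadratic in the call that interpolates the three genotype values,
    # exact for calls in {0, 1, 2}; hybrid parental averages stay in {0,1,2}
    v0, v1, v2 = -2 * p**2, 2 * p * q, -2 * q**2
    c = calls
    values = v0[None, :] * (c - 1) * (c - 2) / 2 - v1[None, :] * c * (c - 2) + v2[
        None, :
    ] * c * (c - 1) / 2
    return CodedGenotypes(
        values=values,
        coding="dominance",
        freqs=p,
        individual_ids=list(G.individual_ids),
        locus_ids=list(G.locus_ids),
    )


def compute_pcs(X, var_threshold: float = 0.99) -> PCBasis:
    """Centered PCA retaining the minimal components reaching ``var_threshold``.

    Accepts a raw array, a GenotypeMatrix, or CodedGenotypes.
    """
    values = np.asarray(getattr(X, "calls", getattr(X, "values", X)), dtype=float)
    if values.shape[0] < 2:
        raise DegenerateInputError("PCA requires at least 2 individuals")
    mean = values.mean(axis=0)
    centered = values - mean
    if np.allclose(centered, 0.0):
        raise DegenerateInputError("constant matrix has no principal components")
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    explained = var / var.sum()
    cum = np.cumsum(explained)
    k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    k = min(k, len(s))
    return PCBasis(
        loadings=Vt[:k].T,
        scores=U[:, :k] * s[:k],
        explained=explained,
        threshold=var_threshold,
        mean_=mean,
    )


def hybrid_gpcs(parent_basis: PCBasis, design, X=None) -> np.ndarray:
    """Hybrid PC scores as the average of the two parents' scores.

    When the parental genotype matrix ``X`` is supplied, the result is
    verified (to 1e-10) against the equivalent path of averaging parental
    genotypes first and then projecting onto the parental loadings.
    """
    M = np.asarray(design.M, dtype=float)
    if M.shape[1] != parent_basis.scores.shape[0]:
        raise AlignmentError("parent scores do not cover all parents in the design")
    averaged = 0.5 * (M @ parent_basis.scores)
    if X is not None:
        calls = np.asarray(getattr(X, "calls", X), dtype=float)
        projected = (0.5 * (M @ calls) - parent_basis.mean_) @ parent_basis.loadings
        err = np.max(np.abs(averaged - projected))
        if err > 1e-10:
            raise EstimationError(f"average/project paths disagree by {err:.2e}")
    return averaged


def hybrid_covariance_identity(X, design) -> dict:
    """Both routes to the hybrid SNP covariance S = (1/4m)(MX)'(MX).

    Returns the direct product form, the parental form (1/4m) X'(M'M)X, their
    maximum absolute discrepancy, and the M'M progeny-count diagonal.
    """
    calls = np.asarray(getattr(X, "calls", X), dtype=float)
    M = np.asarray(design.M, dtype=float)
    if M.shape[1] != calls.shape[0]:
        raise ShapeError("design columns must match panel individuals")
    m = M.shape[0]
    MX = M @ calls
    direct = (MX.T @ MX) / (4.0 * m)
    MtM = M.T @ M
    via_contrib = calls.T @ MtM @ calls / (4.0 * m)
    return {
        "S_direct": direct,
        "S_via_MtM": via_contrib,
        "max_discrepancy": float(np.max(np.abs(direct - via_contrib))),
        "MtM_diagonal": np.diag(MtM).copy(),
    }


def fisher_combine(pvals, floor: float = P_VALUE_FLOOR) -> float:
    """Fisher's method: -2 sum(ln p) referred to chi-square with 2k df."""
    p = np.asarray(pvals, dtype=float)
    if np.any(p > 1.0) or np.any(p < 0.0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p < floor):
        warnings.warn(f"p-values below {floor} clipped for Fisher's method")
        p = np.clip(p, floor, 1.0)
    stat = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(stat, df=2 * p.size))


def _null_variance_ratio(K_e, y):
    """Profile-ML estimate of sig2_g/sig2_e on the intercept-only model.

    Returns the ratio and the full (untruncated) spectral factors of K_e.
    """
    from scipy.linalg import eigh

    from .hyperopt import profile_ratio

    lam, U = eigh(np.asarray(K_e, dtype=float))
    lam = np.clip(lam[::-1], 0.0, None)
    U = U[:, ::-1]
    yc = y - y.mean()
    fit = profile_ratio(lam, U, yc)
    return fit["ratio"], lam, U


def gwas_select_snps(
    H: CodedGenotypes,
    pheno: pd.DataFrame,
    K,
    n_select: int,
    n_kinship_pcs: int = 0,
    response: str = "y_std",
) -> GwasSelection:
    """Per-environment single-marker mixed-model scan, Fisher-combined.

    ``pheno`` must contain hybrid_id, site_year and the response column for
    training records only.  For each environment the null model (intercept
    plus an optional fixed number of kinship PCs) is fitted once by spectral
    profile ML; each marker is then tested by generalized least squares under
    the estimated covariance.  Per-locus p-values are combined across
    environments with Fisher's method and the ``n_select`` smallest are
    selected.
    """
    values = H.values
    hybrid_index = {h: i for i, h in enumerate(H.individual_ids)}
    envs = sorted(pheno["site_year"].unique())
    if len(envs) < 2:
        raise EstimationError("GWAS requires at least 2 environments")
    Kv = np.asarray(getattr(K, "values", K), dtype=float)

    pv = {}
    for env in envs:
        sub = pheno[pheno["site_year"] == env]
        idx = np.array([hybrid_index[h] for h in sub["hybrid_id"]])
        y = sub[response].to_numpy(dtype=float)
        if len(y) < 5:
            continue
        K_e = Kv[np.ix_(idx, idx)]
        ratio, lam, U = _null_variance_ratio(K_e, y)
        w = 1.0 / (ratio * lam + 1.0)  # precision up to sig2_e
        yt = U.T @ y
        ones_t = U.T @ np.ones(len(y))
        cols = [ones_t]
        if n_kinship_pcs > 0:
            pcs = U[:, :n_kinship_pcs] * np.sqrt(lam[:n_kinship_pcs])
            cols.extend((U.T @ pcs).T)
        X0 = np.column_stack(cols)
        Xm_all = U.T @ values[idx]  # rotated marker columns
        n, k0 = len(y), X0.shape[1]
        p_env = np.ones(values.shape[1])
        for j in range(values.shape[1]):
            Xj = np.column_stack([X0, Xm_all[:, j]])
            sw = np.sqrt(w)
            A = Xj * sw[:, None]
            b = yt * sw
            beta, res, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            if rank < Xj.shape[1]:
                p_env[j] = 1.0  # marker collinear with fixed effects
                continue
            dof = n - Xj.shape[1]
            resid = b - A @ beta
            sigma2 = resid @ resid / dof
            XtX_inv = np.linalg.inv(A.T @ A)
            se = np.sqrt(sigma2 * XtX_inv[-1, -1])
            tstat = beta[-1] / se if se > 0 else 0.0
            p_env[j] = 2.0 * stats.t.sf(abs(tstat), dof)
        pv[env] = p_env

    pvalues = pd.DataFrame(pv, index=H.locus_ids)
    combined = pvalues.apply(lambda row: fisher_combine(row.dropna().to_numpy()), axis=1)
    n_select = min(n_select, len(combined))
    selected = list(combined.nsmallest(n_select).index)
    return GwasSelection(pvalues=pvalues, combined=combined, selected=selected)
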