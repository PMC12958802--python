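"""Similarity kernels for RKHS genomic prediction.

Implements the linear (gBLUP), Gaussian, and arc-cosine kernels, composite
weather kernels built per variable and combined by inverse-hyperparameter
weights, interaction kernels via Hadamard products of expanded constituents,
and truncated spectral decomposition used both for hyperparameter search and
for the Gibbs sampler's orthogonal reparameterization.

The arc-cosine kernel of one layer equals the covariance function of an
infinite-width single-hidden-layer ReLU network; deeper analogues follow the
standard recursion on the normalized angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    InvalidKernelError,
    ShapeError,
)

__all__ = [
    "KernelMatrix",
    "EigenBasis",
    "linear_kernel",
    "gaussian_kernel",
    "arc_cosine_kernel",
    "identity_kernel",
    "composite_weather_kernel",
    "expand_kernel",
    "eigendecompose",
    "validate_kernel",
]


@dataclass
class KernelMatrix:
    """Labeled symmetric PSD similarity matrix with construction metadata."""

    values: np.ndarray
    labels: list
    kind: str  # linear | gaussian | arccosine | composite | interaction | identity
    hyperparams: dict = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ShapeError("kernel must be square")
        if len(self.labels) != self.values.shape[0]:
            raise ShapeError("label count must match kernel dimension")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class EigenBasis:
    """Truncated spectral decomposition of a kernel.

    ``vectors`` (n x r) are orthonormal, ``values`` (r,) descending and all
    at or above the truncation threshold; ``variance_captured`` is the
    retained share of the total (positive) eigenvalue mass.
    """

    vectors: np.ndarray
    values: np.ndarray
    labels: list
    tol: float
    max_rank: int
    variance_captured: float

    @property
    def rank(self) -> int:
        return self.values.size


def validate_kernel(K: KernelMatrix, sym_tol: float = 1e-10, psd_tol: float = 1e-8):
    """Raise unless K is finite, symmetric and PSD up to tolerance."""
    v = K.values
    if not np.all(np.isfinite(v)):
        raise InvalidKernelError("kernel has non-finite entries")
    asym = np.max(np.abs(v - v.T)) if v.size else 0.0
    if asym > sym_tol:
        raise InvalidKernelError(f"kernel asymmetric by {asym:.2e}")
    w = np.linalg.eigvalsh((v + v.T) / 2.0)
    if w[0] < -psd_tol * max(w[-1], 1e-30):
        raise InvalidKernelError(f"kernel has negative eigenvalue {w[0]:.2e}")
    return True


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ShapeError("kernels require at least 2 records")
    return X


def linear_kernel(X, labels=None) -> KernelMatrix:
    """Linear kernel K = XX' / (tr(XX')/n); trace equals n exactly."""
    Xv = _as_matrix(X)
    G = Xv @ Xv.T
    tr = np.trace(G)
    if tr <= 0:
        raise DegenerateInputError("all-zero feature matrix has no linear kernel")
    K = G / (tr / Xv.shape[0])
    labels = list(labels) if labels is not None else list(range(Xv.shape[0]))
    return KernelMatrix(values=K, labels=labels, kind="linear", normalized=True)


def gaussian_kernel(X, h: float, labels=None) -> KernelMatrix:
    """Gaussian kernel exp(-h d^2/q), q the median off-diagonal squared distance."""
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    Xv = _as_matrix(X)
    d2 = squareform(pdist(Xv, metric="sqeuclidean"))
    q = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    if q <= 0:
        raise DegenerateInputError("all records identical: median distance is zero")
    K = np.exp(-h * d2 / q)
    np.fill_diagonal(K, 1.0)
    labels = list(labels) if labels is not None else list(range(Xv.shape[0]))
    return KernelMatrix(
        values=K, labels=labels, kind="gaussian", hyperparams={"h": float(h), "q": q}
    )


def _arc_layer_first(Xv: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Xv, axis=1)
    if np.any(norms == 0):
        raise DegenerateInputError("zero-norm rows are not allowed for the arc-cosine kernel")
    G = Xv @ Xv.T
    outer = np.outer(norms, norms)
    cosang = G / outer
    overshoot = np.max(np.abs(cosang)) - 1.0
    if overshoot > 1e-12:
        raise InvalidKernelError(f"cosine overshoot {overshoot:.2e} beyond tolerance")
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))
    J = np.sin(theta) + (np.pi - theta) * np.cos(theta)
    return (outer / np.pi) * J


def _arc_recurse(K: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(K))
    outer = np.outer(d, d)
    cosang = K / outer
    overshoot = np.max(np.abs(cosang)) - 1.0
    if overshoot > 1e-12:
        raise InvalidKernelError(f"cosine overshoot {overshoot:.2e} beyond tolerance")
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))
    J = np.sin(theta) + (np.pi - theta) * np.cos(theta)
    return (outer / np.pi) * J


def arc_cosine_kernel(X, layers: int = 1, labels=None) -> KernelMatrix:
    """Arc-cosine (deep) kernel with the given number of layers (>= 1)."""
    if layers < 1:
        raise ValueError("layers must be >= 1")
    Xv = _as_matrix(X)
    K = _arc_layer_first(Xv)
    for _ in range(layers - 1):
        K = _arc_recurse(K)
    K = (K + K.T) / 2.0
    labels = list(labels) if labels is not None else list(range(Xv.shape[0]))
    return KernelMatrix(
        values=K, labels=labels, kind="arccosine", hyperparams={"layers": int(layers)}
    )


def arc_cosine_layers(X, l_max: int, labels=None):
    """Yield (l, KernelMatrix) for l = 1..l_max, reusing the recursion."""
    Xv = _as_matrix(X)
    labels = list(labels) if labels is not None else list(range(Xv.shape[0]))
    K = _arc_layer_first(Xv)
    for l in range(1, l_max + 1):
        yield l, KernelMatrix(
            values=(K + K.T) / 2.0,
            labels=labels,
            kind="arccosine",
            hyperparams={"layers": l},
        )
        if l < l_max:
            K = _arc_recurse(K)


def identity_kernel(n: int, labels=None) -> KernelMatrix:
    labels = list(labels) if labels is not None else list(range(n))
    return KernelMatrix(values=np.eye(n), labels=labels, kind="identity", normalized=True)


def composite_weather_kernel(kernels, kind: str) -> KernelMatrix:
    """Combine per-variable kernels into one composite environmental kernel.

    ``linear``: plain sum, then trace-normalized to trace = n.  ``gaussian``
    and ``arccosine``: weighted average with weights proportional to the
    inverse of each constituent's hyperparameter (1/h or 1/layers),
    normalized to sum to 1, so strongly-smoothing variables contribute more.
    """
    kernels = list(kernels)
    if not kernels:
        raise ValueError("no constituent kernels")
    labels = kernels[0].labels
    for k in kernels[1:]:
        if list(k.labels) != list(labels):
            raise AlignmentError("constituent kernels have mismatched record labels")
    n = kernels[0].n
    if kind == "linear":
        total = sum(k.values for k in kernels)
        tr = np.trace(total)
        if tr <= 0:
            raise DegenerateInputError("composite kernel has non-positive trace")
        values = total / (tr / n)
        hyper = {"n_constituents": len(kernels)}
        return KernelMatrix(
            values=values, labels=list(labels), kind="composite",
            hyperparams=hyper, normalized=True,
        )
    if kind in ("gaussian", "arccosine"):
        key = "h" if kind == "gaussian" else "layers"
        raw = np.array([1.0 / float(k.hyperparams[key]) for k in kernels])
        weights = raw / raw.sum()
        values = sum(w * k.values for w, k in zip(weights, kernels))
        return KernelMatrix(
            values=values,
            labels=list(labels),
            kind="composite",
            hyperparams={"weights": weights, "constituent_kind": kind},
        )
    raise ValueError(f"unknown composite kind: {kind}")


def expand_kernel(K_a: KernelMatrix, Z_a, K_b: KernelMatrix = None, Z_b=None, labels=None):
    """Expand kernels to the record level and take their Hadamard product.

    ``Z`` matrices map records to kernel levels (one 1 per row).  With a
    single data type, the partner kernel is an identity over its levels:
    pass ``K_b=None`` together with ``Z_b`` (or omit both for a pure
    single-kernel expansion Z_a K_a Z_a').
    """
    Z_a = np.asarray(Z_a, dtype=float)
    if Z_a.shape[1] != K_a.n:
        raise ShapeError("Z_a columns must match K_a dimension")
    left = Z_a @ K_a.values @ Z_a.T
    if Z_b is None and K_b is None:
        values = left
    else:
        Z_b = np.asarray(Z_b, dtype=float)
        if K_b is None:
            right = Z_b @ Z_b.T  # identity kernel over the partner's levels
        else:
            if Z_b.shape[1] != K_b.n:
                raise ShapeError("Z_b columns must match K_b dimension")
            right = Z_b @ K_b.values @ Z_b.T
        if right.shape != left.shape:
            raise ShapeError("expanded kernels do not conform")
        values = left * right
    labels = list(labels) if labels is not None else list(range(values.shape[0]))
    return KernelMatrix(values=values, labels=labels, kind="interaction")


def eigendecompose(K: KernelMatrix, tol: float = 1e-10, max_rank: int = 7500) -> EigenBasis:
    """Descending spectral decomposition truncated at ``tol`` or ``max_rank``.

    Whichever rule binds first applies; the retained variance fraction is
    reported relative to the total positive eigenvalue mass.
    """
    v = K.values
    asym = np.max(np.abs(v - v.T)) if v.size else 0.0
    if asym > 1e-8:
        raise InvalidKernelError(f"kernel asymmetric by {asym:.2e}")
    w, U = eigh((v + v.T) / 2.0)
    w, U = w[::-1], U[:, ::-1]
    pos_mass = float(np.sum(np.clip(w, 0.0, None)))
    keep = min(int(np.sum(w >= tol)), max_rank)
    captured = float(np.sum(w[:keep]) / pos_mass) if pos_mass > 0 else 0.0
    return EigenBasis(
        vectors=U[:, :keep].copy(),
        values=w[:keep].copy(),
        labels=list(K.labels),
        tol=tol,
        max_rank=max_rank,
        variance_captured=captured,
    )


def design_matrix(record_levels, levels) -> np.ndarray:
    """0/1 incidence of records onto kernel levels, one 1 per row."""
    index = {lv: j for j, lv in enumerate(levels)}
    Z = np.zeros((len(record_levels), len(levels)))
    for i, lv in enumerate(record_levels):
        try:
            Z[i, index[lv]] = 1.0
        except KeyError:
            raise AlignmentError(f"record level {lv!r} missing from kernel labels")
    return Z
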