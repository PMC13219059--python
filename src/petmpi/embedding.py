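"""Diffusion-map embedding of a standardized PET feature matrix.

The construction follows the standard density-normalized diffusion-map
recipe with a locally adaptive Gaussian kernel:

1. z-score each feature column (constant columns are dropped);
2. build a k-nearest-neighbour graph (Euclidean distance, union
   symmetrization) and set the local scale ``sigma_i`` to half the
   distance to the k-th neighbour;
3. affinities ``W_ij = exp(-d_ij^2 / (sigma_i^2 + sigma_j^2))`` on graph
   edges, zero diagonal;
4. anisotropic normalization with alpha = 1 (divide by the product of row
   sums) to remove sampling-density effects, then row-normalize to a
   Markov operator P;
5. eigendecompose P through its symmetric conjugate
   ``S = D^{1/2} P D^{-1/2}``; the trivial eigenpair (eigenvalue 1,
   constant right eigenvector) is discarded and the remaining right
   eigenvectors, ordered by descending eigenvalue, are the diffusion
   components DC1, DC2, ...

Components are defined only up to a global sign; a deterministic sign
convention is applied here, and every downstream consumer must stay
invariant under sign flips (the trajectory module re-orients DC1 against
tumor burden explicitly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors


#: local scale = (distance to k-th neighbour) / SIGMA_DIVISOR
SIGMA_DIVISOR = 2.0


class DisconnectedGraphError(RuntimeError):
    """kNN graph split into several components; a single ordering is
    ill-defined across disconnected components."""


@dataclass
class StandardizedMatrix:
    """z-scored feature matrix with the scaling retained for provenance."""

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    dropped_columns: list[str]


@dataclass
class DiffusionOperator:
    """Row-stochastic Markov operator P plus its construction metadata."""

    P: np.ndarray
    stationary: np.ndarray  # row sums of the alpha-normalized kernel
    sigma: np.ndarray
    k: int
    index: pd.Index
    n_graph_components: int
    component_labels: np.ndarray


@dataclass
class DiffusionEmbedding:
    k: int
    sigma: np.ndarray
    eigenvalues: np.ndarray  # non-trivial, descending
    components: pd.DataFrame  # columns DC1..DCm
    connected: bool


def standardize(fm: pd.DataFrame) -> StandardizedMatrix:
    """Feature-wise z-score normalization (population sd).

    Constant columns carry no ordering information and are dropped with a
    warning; an all-constant matrix is an error.
    """
    if fm.shape[0] < 3:
        raise ValueError("standardize requires n >= 3 rows")
    means = fm.mean(axis=0)
    sds = fm.std(axis=0, ddof=0)
    constant = sds <= 0
    if constant.all():
        raise ValueError("all feature columns are constant; nothing to embed")
    if constant.any():
        warnings.warn(
            f"dropping constant feature columns: {list(fm.columns[constant])}",
            stacklevel=2,
        )
    keep = fm.columns[~constant]
    z = (fm[keep] - means[keep]) / sds[keep]
    return StandardizedMatrix(
        values=z, means=means[keep], sds=sds[keep],
        dropped_columns=list(fm.columns[constant]),
    )


def build_diffusion_operator(
    X: StandardizedMatrix | pd.DataFrame,
    k: int = 20,
    on_disconnected: str = "error",
    use_prefactor: bool = False,
) -> DiffusionOperator:
    """Locally scaled kNN kernel -> alpha=1 normalization -> Markov operator.

    Parameters
    ----------
    X : StandardizedMatrix or DataFrame
        n x p standardized features.
    k : int
        Neighbourhood size; 1 <= k < n.
    on_disconnected : {"error", "largest"}
        Policy when the union-kNN graph is not connected: raise (default)
        or restrict to the largest component.
    use_prefactor : bool
        Kernel-variant toggle: multiply the affinity by the local-scaling
        prefactor ``sqrt(2 sigma_i sigma_j / (sigma_i^2 + sigma_j^2))``.
        Orderings must be insensitive to this choice; the robustness suite
        checks that.
    """
    values = X.values if isinstance(X, StandardizedMatrix) else X
    index = values.index
    arr = np.asarray(values, dtype=float)
    n = arr.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (k={k}, n={n})")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(arr)
    dist, idx = nn.kneighbors(arr)  # includes self at position 0
    sigma = dist[:, k] / SIGMA_DIVISOR
    sigma = np.maximum(sigma, 1e-12)  # duplicated points give sigma 0

    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    mask[rows, cols] = True
    mask |= mask.T  # union symmetrization
    np.fill_diagonal(mask, False)

    d2 = _sq_distances(arr)
    denom = sigma[:, None] ** 2 + sigma[None, :] ** 2
    W = np.where(mask, np.exp(-d2 / denom), 0.0)
    if use_prefactor:
        pref = np.sqrt(2.0 * np.outer(sigma, sigma) / denom)
        W = W * np.where(mask, pref, 0.0)

    n_comp, labels = connected_components(W > 0, directed=False)
    if n_comp > 1:
        if on_disconnected == "largest":
            largest = np.bincount(labels).argmax()
            keep = labels == largest
            warnings.warn(
                f"kNN graph has {n_comp} components; restricting to the "
                f"largest ({keep.sum()} of {n} points)",
                stacklevel=2,
            )
            sub = values.loc[index[keep]]
            op = build_diffusion_operator(
                sub, k=min(k, keep.sum() - 1), on_disconnected="error",
                use_prefactor=use_prefactor,
            )
            return DiffusionOperator(
                P=op.P, stationary=op.stationary, sigma=op.sigma, k=op.k,
                index=op.index, n_graph_components=n_comp, component_labels=labels,
            )
        raise DisconnectedGraphError(
            f"kNN graph has {n_comp} components; increase k or pass "
            "on_disconnected='largest'"
        )

    # alpha = 1 anisotropic normalization, then row-normalize
    q = W.sum(axis=1)
    W1 = W / np.outer(q, q)
    d1 = W1.sum(axis=1)
    P = W1 / d1[:, None]
    return DiffusionOperator(
        P=P, stationary=d1, sigma=sigma, k=k, index=index,
        n_graph_components=1, component_labels=labels,
    )


def _sq_distances(arr: np.ndarray) -> np.ndarray:
    sq = np.sum(arr**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * arr @ arr.T
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return d2


def diffusion_components(op: DiffusionOperator, n_components: int = 5) -> DiffusionEmbedding:
    """Eigendecompose P via its symmetric conjugate.

    With ``P = D^{-1} W1`` (D = diag of W1 row sums), the operator
    ``S = D^{-1/2} W1 D^{-1/2}`` is symmetric and shares eigenvalues with
    P; right eigenvectors of P are ``D^{-1/2} v``.  The leading eigenpair
    (eigenvalue 1, constant eigenvector) is trivial and excluded from the
    components.
    """
    n = op.P.shape[0]
    n_components = min(n_components, n - 1)
    d = op.stationary
    sqrt_d = np.sqrt(d)
    S = op.P * (sqrt_d[:, None] / sqrt_d[None, :])
    S = 0.5 * (S + S.T)  # symmetrize against round-off
    eigvals, eigvecs = eigh(S)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if abs(eigvals[0] - 1.0) > 1e-8:
        raise RuntimeError(
            f"defective decomposition: leading eigenvalue {eigvals[0]!r} != 1"
        )
    psi = eigvecs / sqrt_d[:, None]  # right eigenvectors of P
    trivial = psi[:, 0]
    if np.std(trivial) > 1e-6 * np.abs(np.mean(trivial)):
        raise RuntimeError("defective decomposition: trivial eigenvector not constant")

    comps = psi[:, 1 : n_components + 1]
    # deterministic sign: largest-magnitude entry positive
    for j in range(comps.shape[1]):
        pivot = np.argmax(np.abs(comps[:, j]))
        if comps[pivot, j] < 0:
            comps[:, j] = -comps[:, j]
    # unit-norm scaling keeps coordinates comparable across n
    norms = np.linalg.norm(comps, axis=0)
    norms[norms == 0] = 1.0
    comps = comps / norms

    components = pd.DataFrame(
        comps,
        index=op.index,
        columns=[f"DC{j + 1}" for j in range(comps.shape[1])],
    )
    return DiffusionEmbedding(
        k=op.k,
        sigma=op.sigma,
        eigenvalues=eigvals[1 : n_components + 1],
        components=components,
        connected=op.n_graph_components == 1,
    )


def embed(
    fm: pd.DataFrame,
    k: int = 20,
    n_components: int = 5,
    on_disconnected: str = "error",
    use_prefactor: bool = False,
    pre_standardized: bool = False,
) -> DiffusionEmbedding:
    """standardize -> operator -> components in one call.

    ``pre_standardized=True`` skips the z-scoring step and uses ``fm`` as
    is (frozen-scaling variants of the robustness suite).
    """
    Z = fm if pre_standardized else standardize(fm)
    op = build_diffusion_operator(
        Z, k=k, on_disconnected=on_disconnected, use_prefactor=use_prefactor
    )
    return diffusion_components(op, n_components=n_components)
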