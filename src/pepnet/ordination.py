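"""PCA and two-group PLS-DA of complete-case log2 ratio profiles.

Samples are the observations, peptides the variables.  Variables are
mean-centered only by default — the data are already on a common log2-ratio
scale — with optional unit-variance autoscaling.  PCA component signs are
fixed by forcing the largest-magnitude loading positive; PLS-DA uses a
NIPALS-style latent-variable extraction against a ±1 class indicator with
deflation between components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_model import RatioMatrix


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # samples × components
    explained_variance: np.ndarray  # fraction per component
    loadings: pd.DataFrame  # peptides × components
    method: str
    eigenvalues: np.ndarray | None = None


def _prepare(matrix: RatioMatrix, autoscale: bool) -> tuple[np.ndarray, list[str], list[str]]:
    x = matrix.values.to_numpy(dtype=float).T  # samples × peptides
    if np.isnan(x).any():
        raise ValidationError("ordination requires a complete-case matrix "
                              "(run filter_complete_cases first)")
    x = x - x.mean(axis=0, keepdims=True)
    if autoscale:
        sd = x.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
    return x, matrix.samples, matrix.peptides


def pca(matrix: RatioMatrix, n_components: int | None = None,
        autoscale: bool = False) -> OrdinationResult:
    """Principal component analysis via SVD of the centered sample matrix."""
    x, samples, peptides = _prepare(matrix, autoscale)
    n, p = x.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    max_comp = min(n, p)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        warnings.warn(f"requested {n_components} components; only {max_comp} "
                      "available", stacklevel=2)
        n_components = max_comp
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float((s ** 2).sum())
    explained = (s ** 2) / total if total > 0 else np.zeros_like(s)
    scores = u * s
    loadings = vt.T
    for c in range(loadings.shape[1]):
        jmax = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[jmax, c] < 0:
            loadings[:, c] = -loadings[:, c]
            scores[:, c] = -scores[:, c]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(scores[:, :n_components], index=samples, columns=cols),
        explained_variance=explained[:n_components],
        loadings=pd.DataFrame(loadings[:, :n_components], index=peptides, columns=cols),
        method="PCA",
        eigenvalues=(s ** 2) / (n - 1),
    )


def plsda(matrix: RatioMatrix, groups: pd.Series, n_components: int = 2,
          autoscale: bool = False, tol: float = 1e-10,
          max_iter: int = 500) -> OrdinationResult:
    """Two-class partial least squares discriminant analysis.

    ``groups`` maps each sample to one of exactly two class labels; the
    response is coded +1 for the lexicographically first class and −1 for
    the second.  Components maximize covariance between projected profiles
    and the class indicator; X is deflated between components and the weight
    vector iteration stops when its change drops below ``tol``.
    """
    x, samples, peptides = _prepare(matrix, autoscale)
    groups = groups.loc[samples]
    classes = sorted(groups.unique())
    if len(classes) != 2:
        raise ValidationError(f"PLS-DA needs exactly 2 classes, got {classes}")
    counts = groups.value_counts()
    if (counts < 2).any():
        warnings.warn("a class has a single sample; PLS-DA is degenerate",
                      stacklevel=2)
    y = np.where(groups.to_numpy() == classes[0], 1.0, -1.0)
    y = y - y.mean()

    n, p = x.shape
    n_components = min(n_components, min(n - 1, p))
    xk = x.copy()
    t_scores, w_weights, p_loads = [], [], []
    ss_total = float((x ** 2).sum())
    explained = []
    for _ in range(n_components):
        w = xk.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            break
        w = w / norm
        for _ in range(max_iter):
            t = xk @ w
            denom = float(t @ t)
            if denom < 1e-14:
                break
            c = float(y @ t) / denom
            u_vec = y * c
            w_new = xk.T @ u_vec
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = xk @ w
        denom = float(t @ t)
        if denom < 1e-14:
            break
        pl = xk.T @ t / denom
        xk = xk - np.outer(t, pl)
        t_scores.append(t)
        w_weights.append(w)
        p_loads.append(pl)
        explained.append(denom * float(pl @ pl) / ss_total if ss_total > 0 else 0.0)

    cols = [f"LV{i + 1}" for i in range(len(t_scores))]
    return OrdinationResult(
        scores=pd.DataFrame(np.column_stack(t_scores) if t_scores else
                            np.empty((n, 0)), index=samples, columns=cols),
        explained_variance=np.asarray(explained),
        loadings=pd.DataFrame(np.column_stack(w_weights) if w_weights else
                              np.empty((p, 0)), index=peptides, columns=cols),
        method="PLS-DA",
    )
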