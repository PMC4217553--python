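"""Hypergeometric functional enrichment of protein sets.

For a query of n annotated proteins drawn from a background of N annotated
proteins, of which M belong to a category and m of the query do, the
enrichment p-value is the upper-tail probability

    p = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n),

i.e. the chance of at least m category members under sampling without
replacement.  Binomial coefficients are evaluated in log space (lgamma) so
backgrounds in the hundreds do not overflow.  The fold ratio (m/n)/(M/N)
compares the query's category share with the background's.

Only annotated proteins enter the counts: both query and background are
intersected with the proteins carrying at least one annotation in the
namespace before N and n are formed.  No multiple-testing correction is
applied by default; Benjamini–Hochberg q-values are available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ValidationError
from .io_model import AnnotationMap

logger = logging.getLogger(__name__)


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper_p(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n), evaluated in log space."""
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValidationError(f"invalid hypergeometric parameters N={N}, M={M}, n={n}")
    if m <= max(0, n - (N - M)):
        return 1.0
    hi = min(M, n)
    if m > hi:
        return 0.0
    i = np.arange(m, hi + 1)
    lp = _log_binom(M, i) + _log_binom(N - M, n - i) - _log_binom(N, n)
    return float(min(1.0, np.exp(logsumexp(lp))))


def enrich(query: Iterable[str], background: Iterable[str], ann: AnnotationMap,
           namespace: str, fdr: bool = False) -> pd.DataFrame:
    """Per-category enrichment of ``query`` against ``background``.

    Records are sorted by ascending p, ties by descending fold ratio then
    category id.  Categories absent from the background (M = 0) are skipped;
    a query with no annotated member yields an empty table with a warning.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        raise ValidationError("query must be a subset of the background")
    annotated = ann.annotated_proteins(namespace)
    bg = background & annotated
    q = query & annotated
    N, n = len(bg), len(q)
    columns = ["namespace", "category_id", "category_name",
               "N", "M", "n", "m", "p", "fold_ratio"]
    if n == 0:
        warnings.warn(f"no query protein carries a {namespace} annotation",
                      stacklevel=2)
        return pd.DataFrame(columns=columns)
    rows = []
    for cid, members in sorted(ann.categories(namespace).items()):
        M = len(members & bg)
        if M == 0:
            continue
        m = len(members & q)
        p = hypergeom_upper_p(N, M, n, m)
        fold = (m / n) / (M / N)
        rows.append({"namespace": namespace, "category_id": cid,
                     "category_name": ann.category_name(namespace, cid),
                     "N": N, "M": M, "n": n, "m": m, "p": p, "fold_ratio": fold})
    df = pd.DataFrame(rows, columns=columns)
    df = df.sort_values(["p", "fold_ratio", "category_id"],
                        ascending=[True, False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    if fdr and len(df):
        from statsmodels.stats.multitest import multipletests
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def enrich_modules(partition_labels: pd.Series, selected: Iterable[str],
                   protein_of: pd.Series, ann: AnnotationMap,
                   background: Iterable[str], namespace: str,
                   fdr: bool = False, pooled: bool = True
                   ) -> Mapping[str, pd.DataFrame]:
    """Enrichment table per selected module (peptides rolled up to proteins).

    ``partition_labels`` maps peptide → module label; a module's query is the
    set of parent proteins of its member peptides intersected with the
    background (any-peptide rule).  When ``pooled`` is true an additional
    table for the union of all selected modules is returned under the key
    ``"pooled"``.
    """
    background = set(background)
    out: dict[str, pd.DataFrame] = {}
    union: set[str] = set()
    for module in selected:
        peptides = partition_labels.index[partition_labels == module]
        proteins = set(protein_of.loc[peptides]) & background
        union |= proteins
        out[module] = enrich(proteins, background, ann, namespace, fdr=fdr)
    if pooled and union:
        out["pooled"] = enrich(union, background, ann, namespace, fdr=fdr)
    return out
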