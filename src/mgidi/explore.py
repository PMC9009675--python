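"""Correlation and principal-component exploration of predicted means.

Operates on the BLUP-based mean matrices from the mixed-model stage
(typically the (genotype, environment) x trait matrix, so control and
drought responses appear as separate observations).  Pearson correlations
carry two-sided p-values from the t reference with n-2 df; PCA is an
eigen-decomposition of the correlation (standardized) or covariance matrix
with per-variable contributions to the leading components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "PCAResult",
    "pearson_matrix",
    "pca",
    "percent_change",
]


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p_values: pd.DataFrame
    n: int

    def flagged(self, alpha: tuple[float, float] = (0.05, 0.01)) -> pd.DataFrame:
        """Correlations annotated '*' (p < alpha[0]) or '**' (p < alpha[1])."""
        out = self.r.round(2).astype(str)
        out = out.where(~(self.p_values < alpha[0]), out + "*")
        out = out.where(~(self.p_values < alpha[1]), out + "*")
        return out


def pearson_matrix(means: pd.DataFrame) -> CorrelationMatrix:
    """Product-moment correlations between trait columns.

    p-values use t = r * sqrt((n-2) / (1-r^2)) with n-2 df, the classical
    test of zero correlation; no multiple-testing correction is applied.
    """
    X = means.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("correlation needs at least three observations")
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = means.columns[np.flatnonzero(sds == 0)[0]]
        raise ValueError(f"trait {bad!r} is constant; correlation undefined")
    r = np.corrcoef(X, rowvar=False)
    rc = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rc * np.sqrt((n - 2) / np.maximum(1.0 - rc**2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(pvals, 0.0)
    cols = means.columns
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p_values=pd.DataFrame(pvals, index=cols, columns=cols),
        n=n,
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # observation x component
    loadings: pd.DataFrame  # variable x component (eigenvectors)
    explained_pct: pd.Series  # percent variance per component, sums to 100
    contributions: pd.DataFrame  # variable x component, each column sums to 100
    leading_contribution: pd.Series  # per-variable share over the first 2 PCs

    @property
    def pc12_pct(self) -> float:
        """Percent of total variation carried by the first two components."""
        return float(self.explained_pct.iloc[:2].sum())


def pca(means: pd.DataFrame, *, standardize: bool = True) -> PCAResult:
    """Principal components of an observation x trait matrix.

    Standardized PCA (the default) diagonalizes the correlation matrix, so
    every trait enters with unit variance regardless of units.  Scores are
    the centered (and scaled) data projected on the eigenvectors.  The
    contribution of variable j to component c is 100 * loading_jc^2 (columns
    sum to 100); ``leading_contribution`` weights the first two components
    by their eigenvalues, the usual "contribution to total variation"
    summary of a biplot.
    """
    X = means.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least two observations and two variables")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = means.columns[np.flatnonzero(sd == 0)[0]]
            raise ValueError(f"trait {bad!r} is constant; cannot standardize")
        Xc = Xc / sd
    C = (Xc.T @ Xc) / (n - 1)
    w, vec = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, vec = np.clip(w[order], 0.0, None), vec[:, order]
    # deterministic sign: largest-magnitude coefficient positive
    for j in range(vec.shape[1]):
        k = np.argmax(np.abs(vec[:, j]))
        if vec[k, j] < 0:
            vec[:, j] = -vec[:, j]
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate matrix: total variance is zero")
    labels = [f"PC{j + 1}" for j in range(p)]
    scores = Xc @ vec
    explained = pd.Series(100.0 * w / total, index=labels, name="explained_pct")
    contrib = pd.DataFrame(100.0 * vec**2, index=means.columns, columns=labels)
    k = min(2, p)
    lead = (vec[:, :k] ** 2 * w[:k]).sum(axis=1)
    lead = pd.Series(100.0 * lead / lead.sum(), index=means.columns, name="contribution")
    return PCAResult(
        scores=pd.DataFrame(scores, index=means.index, columns=labels),
        loadings=pd.DataFrame(vec, index=means.columns, columns=labels),
        explained_pct=explained,
        contributions=contrib,
        leading_contribution=lead,
    )


def percent_change(reference: float, observed: float) -> float:
    """Relative change 100 * (observed - reference) / reference."""
    if reference == 0:
        raise ValueError("percent change undefined for zero reference")
    return 100.0 * (observed - reference) / reference
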