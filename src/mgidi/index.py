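"""Multi-trait genotype-ideotype distance index (MGIDI).

Ranks genotypes by their distance, in factor-score space, from an ideotype
that holds the best value of every trait.  Steps:

1. **Rescale** the genotype x trait matrix of predicted means so every
   column spans 0-100 with 100 at the desirable extreme (largest value for
   "increase" traits, smallest for "decrease" traits).  The map is affine,
   so the correlation structure is preserved up to sign.
2. **Factor analysis** of the rescaled matrix: eigen-decomposition of its
   correlation matrix R, retention of factors with eigenvalue > 1 (Kaiser
   criterion, minimum one factor), varimax rotation of the loadings A, and
   factorial scores F = Z (A' R^-1)' on the column-standardized matrix Z.
3. **Ideotype**: the vector [100, ..., 100], standardized with the genotype
   columns' means and standard deviations, scored with the same A and R.
4. **Index**: MGIDI_i = sqrt( sum_j (F_ij - F_ideotype_j)^2 ); lower is
   closer to the ideotype.  The per-factor share omega_ij = D_ij^2 / sum_j
   D_ij^2 decomposes each genotype's distance: a small share means the
   genotype is strong (near-ideal) for the traits in that factor.

Selection takes the floor(proportion * g) lowest-MGIDI genotypes (at least
one); selection differentials compare the selected genotypes' mean with the
overall mean on the original trait scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trial import TraitSpec, TrialDataError

__all__ = [
    "RescaledMatrix",
    "FactorModel",
    "MGIDIResult",
    "rescale",
    "varimax",
    "fit_factor_model",
    "compute_index",
    "select_genotypes",
    "selection_differentials",
    "strengths_weaknesses",
    "run_mgidi",
]


@dataclass
class RescaledMatrix:
    """Direction-aware 0-100 rescaling of a genotype x trait mean matrix."""

    values: pd.DataFrame  # g x p, in [0, 100]
    specs: list[TraitSpec]
    original: pd.DataFrame
    bounds: pd.DataFrame  # per trait: original min/max, new min/max

    @property
    def genotypes(self) -> list:
        return self.values.index.tolist()


def rescale(means: pd.DataFrame, specs: Sequence[TraitSpec]) -> RescaledMatrix:
    """Map each trait column affinely onto [0, 100].

    For ``increase`` traits the original (min, max) maps to (0, 100); for
    ``decrease`` traits to (100, 0), so 100 is always the desirable extreme.

    Raises
    ------
    TrialDataError
        If a column is constant (the map is undefined) or a declared trait
        is missing from ``means``.
    """
    if len(means) < 2:
        raise TrialDataError("rescaling needs at least two genotypes")
    out = {}
    bounds = []
    for spec in specs:
        if spec.name not in means.columns:
            raise TrialDataError(f"trait {spec.name!r} not in mean matrix")
        col = means[spec.name].astype(float)
        lo, hi = float(col.min()), float(col.max())
        if hi <= lo:
            raise TrialDataError(
                f"trait {spec.name!r} is constant across genotypes; rescaling undefined"
            )
        new_min, new_max = (0.0, 100.0) if spec.direction == "increase" else (100.0, 0.0)
        out[spec.name] = ((new_max - new_min) / (hi - lo) * (col - lo) + new_min).clip(0.0, 100.0)
        bounds.append(
            {
                "trait": spec.name,
                "original_min": lo,
                "original_max": hi,
                "new_min": new_min,
                "new_max": new_max,
            }
        )
    values = pd.DataFrame(out, index=means.index)[[s.name for s in specs]]
    return RescaledMatrix(
        values=values,
        specs=list(specs),
        original=means[[s.name for s in specs]].copy(),
        bounds=pd.DataFrame(bounds),
    )


def varimax(loadings: np.ndarray, *, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal varimax rotation of a p x f loading matrix (raw criterion)."""
    p, f = loadings.shape
    if f < 2:
        return loadings.copy()
    R = np.eye(f)
    d = 0.0
    for _ in range(max_iter):
        Lr = loadings @ R
        grad = loadings.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return loadings @ R


def _fix_signs(A: np.ndarray) -> np.ndarray:
    """Flip each factor so its largest-magnitude loading is positive."""
    A = A.copy()
    for j in range(A.shape[1]):
        k = np.argmax(np.abs(A[:, j]))
        if A[k, j] < 0:
            A[:, j] = -A[:, j]
    return A


@dataclass
class FactorModel:
    """Exploratory factor model of the rescaled trait matrix."""

    correlation: pd.DataFrame  # R, p x p
    eigenvalues: np.ndarray
    n_factors: int
    loadings: pd.DataFrame  # A, p x f (rotated unless rotate=False)
    communalities: pd.Series
    scores: pd.DataFrame  # F, g x f
    trait_factor: pd.Series  # trait -> factor label (largest |loading|)
    column_means: pd.Series
    column_sds: pd.Series
    r_inv: np.ndarray = field(repr=False, default=None)

    @property
    def factor_labels(self) -> list[str]:
        return list(self.loadings.columns)


def fit_factor_model(rx: RescaledMatrix, *, rotate: bool = True) -> FactorModel:
    """Eigen-based factor analysis with Kaiser retention and varimax rotation.

    Initial loadings are eigenvectors of the correlation matrix scaled by
    the square root of their eigenvalues; factors with eigenvalue > 1 are
    retained (at least one).  Scores follow F = Z (A' R^-1)' with Z the
    column-standardized rescaled matrix.  A singular correlation matrix is
    pseudo-inverted with a warning.
    """
    V = rx.values
    g, p = V.shape
    R = np.corrcoef(V.to_numpy(), rowvar=False)
    w, vec = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, vec = w[order], vec[:, order]
    w = np.clip(w, 0.0, None)
    f = int(max(1, (w > 1.0).sum()))
    A = vec[:, :f] * np.sqrt(w[:f])
    if rotate and f > 1:
        A = varimax(A)
    A = _fix_signs(A)

    cond = np.linalg.cond(R)
    if cond > 1e12:
        warnings.warn(
            "correlation matrix is singular; using pseudo-inverse for factor scores",
            RuntimeWarning,
        )
        Rinv = np.linalg.pinv(R)
    else:
        Rinv = np.linalg.inv(R)

    mu = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    Z = (V - mu) / sd
    F = Z.to_numpy() @ (A.T @ Rinv).T

    labels = [f"FA{j + 1}" for j in range(f)]
    loadings = pd.DataFrame(A, index=V.columns, columns=labels)
    communalities = (loadings**2).sum(axis=1).clip(upper=1.0)
    trait_factor = loadings.abs().idxmax(axis=1)
    return FactorModel(
        correlation=pd.DataFrame(R, index=V.columns, columns=V.columns),
        eigenvalues=w,
        n_factors=f,
        loadings=loadings,
        communalities=communalities,
        scores=pd.DataFrame(F, index=V.index, columns=labels),
        trait_factor=trait_factor,
        column_means=mu,
        column_sds=sd,
        r_inv=Rinv,
    )


@dataclass
class MGIDIResult:
    """Per-genotype index, factor decomposition, ranking."""

    mgidi: pd.Series  # indexed by genotype
    ideotype_scores: pd.Series  # per factor
    distances: pd.DataFrame  # |F_ij - ideotype_j|, g x f
    contributions: pd.DataFrame  # omega_ij, rows sum to 1
    ranking: list  # genotype ids, ascending MGIDI
    model: FactorModel

    def rank_table(self) -> pd.DataFrame:
        out = self.mgidi.loc[self.ranking].rename("mgidi").reset_index()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        return out


def compute_index(model: FactorModel) -> MGIDIResult:
    """Distance of every genotype from the all-100 ideotype in score space.

    The ideotype vector is standardized with the genotype columns' means and
    standard deviations and scored with the same loadings and correlation
    matrix, so distances live in the genotypes' factor-score space.
    """
    A = model.loadings.to_numpy()
    ideo_z = ((100.0 - model.column_means) / model.column_sds).to_numpy()
    ideo_scores = ideo_z @ (A.T @ model.r_inv).T
    diff = model.scores.to_numpy() - ideo_scores
    D = np.abs(diff)
    mgidi = np.sqrt((diff**2).sum(axis=1))
    d2 = D**2
    denom = d2.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0  # a genotype exactly at the ideotype: share undefined -> 0
    omega = d2 / denom
    idx = model.scores.index
    mgidi_s = pd.Series(mgidi, index=idx, name="mgidi")
    order = sorted(idx, key=lambda gid: (mgidi_s.loc[gid], str(gid)))
    return MGIDIResult(
        mgidi=mgidi_s,
        ideotype_scores=pd.Series(ideo_scores, index=model.factor_labels),
        distances=pd.DataFrame(D, index=idx, columns=model.factor_labels),
        contributions=pd.DataFrame(omega, index=idx, columns=model.factor_labels),
        ranking=list(order),
        model=model,
    )


def select_genotypes(result: MGIDIResult, proportion: float = 0.25) -> list:
    """The floor(proportion * g) lowest-MGIDI genotypes (at least one).

    Ties are broken by genotype id, so selection is deterministic.
    """
    if not 0.0 < proportion <= 1.0:
        raise ValueError(f"selection proportion must be in (0, 1], got {proportion}")
    g = len(result.mgidi)
    k = max(1, int(np.floor(proportion * g)))
    return result.ranking[:k]


def selection_differentials(
    means: pd.DataFrame,
    selected: Sequence,
    specs: Sequence[TraitSpec],
    trait_factor: pd.Series | None = None,
) -> pd.DataFrame:
    """Selection-gain table on the original trait scale.

    Per trait: Xo = mean over all genotypes, Xs = mean over the selected
    ones, SD = Xs - Xo, SD% = 100 * SD / Xo, plus the desired sense and
    whether the differential moved in that sense.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("selected set is empty")
    missing = [s for s in selected if s not in means.index]
    if missing:
        raise ValueError(f"selected ids not in mean matrix: {missing}")
    rows = []
    for spec in specs:
        col = means[spec.name].astype(float)
        xo = float(col.mean())
        xs = float(col.loc[selected].mean())
        if xo == 0:
            raise ValueError(f"trait {spec.name!r}: SD%% undefined at zero mean")
        sd = xs - xo
        sd_pct = 100.0 * sd / xo
        goal_met = sd >= 0 if spec.direction == "increase" else sd <= 0
        rows.append(
            {
                "trait": spec.name,
                "factor": None if trait_factor is None else trait_factor.get(spec.name),
                "Xo": xo,
                "Xs": xs,
                "SD": sd,
                "SD_pct": sd_pct,
                "sense": spec.direction,
                "goal_met": bool(goal_met),
            }
        )
    return pd.DataFrame(rows)


def strengths_weaknesses(result: MGIDIResult) -> pd.DataFrame:
    """Per-genotype factor shares of the index, with factor trait membership.

    Rows sum to one.  The *smallest* share marks the genotype's strongest
    factor: little of its distance comes from those traits, i.e. it is close
    to the ideotype there.
    """
    omega = result.contributions.copy()
    members = result.model.trait_factor
    out = omega.reset_index().rename(columns={omega.index.name or "index": "genotype"})
    out["strongest_factor"] = omega.idxmin(axis=1).to_numpy()
    for fa in result.model.factor_labels:
        out.attrs[fa] = tuple(members.index[members == fa])
    return out


def run_mgidi(
    means: pd.DataFrame,
    specs: Sequence[TraitSpec],
    *,
    proportion: float = 0.25,
    rotate: bool = True,
) -> tuple[MGIDIResult, list, pd.DataFrame]:
    """Convenience wrapper: rescale -> factor model -> index -> selection.

    Returns the index result, the selected genotype ids and the
    selection-differential table.
    """
    rx = rescale(means, specs)
    model = fit_factor_model(rx, rotate=rotate)
    result = compute_index(model)
    selected = select_genotypes(result, proportion)
    gains = selection_differentials(means, selected, specs, model.trait_factor)
    return result, selected, gains
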