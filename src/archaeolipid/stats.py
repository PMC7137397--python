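"""Statistical layer: Ring Index, class totals, PCA, imputation, CCA, trees.

The Ring Index (RI) is the abundance-weighted mean number of cyclopentane
rings per tetraether structure:

    RI = (GDGT-1 + GMGT-1 + GTGT-1 + 2 GDGT-2 + 3 GDGT-3 + 4 GDGT-4)
         / (GDGT-0 + GMGT-0 + GTGT-0 + GDGT-1 + GMGT-1 + GTGT-1
            + GDGT-2 + GDGT-3 + GDGT-4)

Canonical correlation analysis (CCA) and the iterative-PCA imputation it
requires are implemented directly on the linear-algebra primitives so the
whole chain (impute -> CCA -> correlation table with significance stars)
is reproducible without external statistics packages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist

from .quantify import CompositionProfile

__all__ = [
    "ring_index", "class_totals", "ClassTotals", "class_totals_table",
    "pca", "PcaResult",
    "impute_iterative_pca", "ImputationResult", "ImputationConvergenceError",
    "multiple_impute",
    "cca", "CcaResult", "significance_stars",
    "composition_tree", "tree_congruence",
]

_RI_NUMERATOR = {"GDGT-1": 1, "GMGT-1": 1, "GTGT-1": 1, "GDGT-2": 2, "GDGT-3": 3, "GDGT-4": 4}
_RI_DENOMINATOR = ["GDGT-0", "GMGT-0", "GTGT-0", "GDGT-1", "GMGT-1", "GTGT-1",
                   "GDGT-2", "GDGT-3", "GDGT-4"]


def _as_values(profile: CompositionProfile | Mapping[str, float]) -> Mapping[str, float]:
    if isinstance(profile, CompositionProfile):
        return profile.values
    return profile


def ring_index(profile: CompositionProfile | Mapping[str, float]) -> float:
    """Average cyclopentane rings per tetraether structure.

    ND and TRACE species count as 0.  Raises ``ValueError`` for a profile
    with no quantified tetraethers (RI undefined).
    """
    v = _as_values(profile)
    denom = sum(v.get(k, 0.0) for k in _RI_DENOMINATOR)
    if denom <= 0:
        raise ValueError("ring index undefined: no quantified tetraethers")
    num = sum(w * v.get(k, 0.0) for k, w in _RI_NUMERATOR.items())
    return num / denom


@dataclass(frozen=True)
class ClassTotals:
    """Skeleton-class totals (%) for one strain, cyclic + acyclic pooled."""

    strain: str
    dgd: float
    gdgt: float
    gmgt: float
    gtgt: float
    ri: float | None  # None when the profile has no quantified tetraethers


def _skeleton_class(lipid_id: str) -> str:
    for cls in ("GDGT", "GMGT", "GTGT"):
        if lipid_id.startswith(cls):
            return cls.lower()
    return "dgd"  # all diether skeletons pool into the bilayer-forming class


def class_totals(profile: CompositionProfile | Mapping[str, float],
                 strain: str | None = None) -> ClassTotals:
    """Pool ring variants into the four skeleton totals and attach RI."""
    v = _as_values(profile)
    if strain is None:
        strain = profile.strain if isinstance(profile, CompositionProfile) else "sample"
    tot = {"dgd": 0.0, "gdgt": 0.0, "gmgt": 0.0, "gtgt": 0.0}
    for lid, val in v.items():
        tot[_skeleton_class(lid)] += val
    try:
        ri: float | None = ring_index(v)
    except ValueError:
        ri = None
    return ClassTotals(strain=strain, ri=ri, **tot)


def class_totals_table(profiles: Sequence[CompositionProfile]) -> pd.DataFrame:
    """Class totals for many strains, indexed by strain."""
    rows = [class_totals(p) for p in profiles]
    return pd.DataFrame(
        {"dgd": [r.dgd for r in rows], "gdgt": [r.gdgt for r in rows],
         "gmgt": [r.gmgt for r in rows], "gtgt": [r.gtgt for r in rows],
         "ri": [np.nan if r.ri is None else r.ri for r in rows]},
        index=[r.strain for r in rows],
    )


@dataclass
class PcaResult:
    scores: np.ndarray              # n x k
    loadings: np.ndarray            # p x k, orthonormal columns
    explained_variance: np.ndarray  # k, sums to total variance when k = rank
    explained_variance_ratio: np.ndarray


def pca(matrix: np.ndarray | pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """Principal component analysis by SVD of the column-centered matrix."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    Xc = X - X.mean(axis=0)
    total_var = float((Xc ** 2).sum()) / (X.shape[0] - 1)
    if total_var <= 0:
        raise ValueError("constant matrix: no variance to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components if n_components is not None else len(s)
    var = s**2 / (X.shape[0] - 1)
    return PcaResult(
        scores=(U * s)[:, :k],
        loadings=Vt.T[:, :k],
        explained_variance=var[:k],
        explained_variance_ratio=var[:k] / total_var,
    )


class ImputationConvergenceError(RuntimeError):
    """Raised when iterative PCA hits max_iter; carries the last iterate."""

    def __init__(self, message: str, result: "ImputationResult"):
        super().__init__(message)
        self.result = result


@dataclass
class ImputationResult:
    completed: pd.DataFrame | np.ndarray
    n_iter: int
    converged: bool
    objective: list[float]  # observed-cell SSE per iteration, non-increasing


def impute_iterative_pca(
    matrix: np.ndarray | pd.DataFrame,
    n_components: int = 5,
    tol: float = 1e-4,
    max_iter: int = 500,
    regularized: bool = True,
) -> ImputationResult:
    """Complete missing cells with mean-initialized iterative PCA.

    Missing cells start at their column mean and are then repeatedly
    replaced by a rank-``n_components`` SVD reconstruction (about the
    running column means) until the relative change of the imputed cells
    drops below ``tol``.  Observed cells are never altered, and (in the
    unregularized variant) the observed-cell squared reconstruction error
    is non-increasing across iterations.  A matrix without missing cells is
    returned unchanged after a single pass.

    With ``regularized=True`` (default) the retained singular values are
    shrunk by the residual variance of the discarded ones
    (``s_k -> (s_k^2 - sigma^2) / s_k``), which keeps the imputation from
    chasing noise directions and speeds convergence on noisy data; on
    exactly low-rank data the shrinkage vanishes and both variants agree.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = np.array(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("need a 2-D matrix")
    mask = np.isnan(X)
    if mask.all(axis=0).any():
        raise ValueError("matrix has an entirely-missing column")
    if n_components >= min(X.shape):
        raise ValueError("n_components must be smaller than both matrix dimensions")

    def _wrap(arr: np.ndarray) -> pd.DataFrame | np.ndarray:
        if is_df:
            return pd.DataFrame(arr, index=matrix.index, columns=matrix.columns)
        return arr

    if not mask.any():
        return ImputationResult(_wrap(X), n_iter=1, converged=True, objective=[0.0])

    completed = X.copy()
    col_means = np.nanmean(X, axis=0)
    completed[mask] = np.take(col_means, np.nonzero(mask)[1])
    objective: list[float] = []
    for it in range(1, max_iter + 1):
        mu = completed.mean(axis=0)
        U, s, Vt = np.linalg.svd(completed - mu, full_matrices=False)
        kept = s[:n_components]
        if regularized and len(s) > n_components:
            sigma2 = float(np.mean(s[n_components:] ** 2))
            kept = np.clip((kept**2 - sigma2) / np.maximum(kept, 1e-12), 0.0, None)
        approx = (U[:, :n_components] * kept) @ Vt[:n_components] + mu
        objective.append(float(((X[~mask] - approx[~mask]) ** 2).sum()))
        old = completed[mask]
        new = approx[mask]
        completed = completed.copy()
        completed[mask] = new
        denom = max(float(np.linalg.norm(old)), 1e-12)
        if float(np.linalg.norm(new - old)) / denom < tol:
            return ImputationResult(_wrap(completed), n_iter=it, converged=True,
                                    objective=objective)
    result = ImputationResult(_wrap(completed), n_iter=max_iter, converged=False,
                              objective=objective)
    raise ImputationConvergenceError(
        f"iterative PCA did not converge in {max_iter} iterations", result
    )


def multiple_impute(
    matrix: np.ndarray | pd.DataFrame,
    n_draws: int = 20,
    noise_scale: float = 0.1,
    seed: int | None = None,
    n_components: int = 5,
    tol: float = 1e-4,
    max_iter: int = 500,
    regularized: bool = True,
) -> np.ndarray | pd.DataFrame:
    """Per-missing-cell imputation standard deviation via multiple imputation.

    Each draw perturbs the *observed* cells with Gaussian noise of standard
    deviation ``noise_scale`` and re-runs :func:`impute_iterative_pca`; the
    spread of the imputed values across draws measures how much the
    prediction depends on the observed data.  Returns an array/frame shaped
    like the input with the sd at originally-missing cells and NaN
    elsewhere; ``noise_scale = 0`` gives all-zero sds.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    is_df = isinstance(matrix, pd.DataFrame)
    X = np.array(matrix, dtype=float)
    mask = np.isnan(X)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        Xp = X.copy()
        Xp[~mask] += rng.normal(0.0, noise_scale, int((~mask).sum())) if noise_scale > 0 else 0.0
        res = impute_iterative_pca(Xp, n_components=n_components, tol=tol,
                                   max_iter=max_iter, regularized=regularized)
        comp = np.asarray(res.completed, dtype=float)
        draws.append(comp[mask])
    sd = np.full(X.shape, np.nan)
    sd[mask] = np.std(np.stack(draws, axis=0), axis=0, ddof=1)
    if is_df:
        return pd.DataFrame(sd, index=matrix.index, columns=matrix.columns)
    return sd


def significance_stars(p: float) -> str:
    """Star labels for correlation tests: *** <0.001, ** <0.01, * <0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CcaResult:
    canonical_correlations: np.ndarray     # non-increasing, in [0, 1]
    x_weights: np.ndarray                  # p_x x k canonical coefficient vectors
    y_weights: np.ndarray                  # p_y x k
    structure_correlations: pd.DataFrame   # lipid (Y) vars x env (X) vars, Pearson r
    p_values: pd.DataFrame
    stars: pd.DataFrame


def _inv_sqrt(S: np.ndarray, label: str, ridge: float) -> np.ndarray:
    S = S + ridge * np.eye(S.shape[0])
    w, V = np.linalg.eigh(S)
    if w.min() <= 1e-12:
        raise np.linalg.LinAlgError(
            f"singular within-block covariance ({label}); pass a small ridge (e.g. 1e-8)"
        )
    return V @ np.diag(w ** -0.5) @ V.T

def cca(
    X: pd.DataFrame | np.ndarray,
    Y: pd.DataFrame | np.ndarray,
    ridge: float = 0.0,
) -> CcaResult:
    """Classical canonical correlation analysis of two complete blocks.

    Columns are standardized internally; the canonical correlations and
    weights come from the SVD of ``Sxx^{-1/2} Sxy Syy^{-1/2}`` (equivalent
    to the generalized eigenproblem of the between-block covariance).  The
    correlation table reported alongside is the plain Pearson
    cross-correlation of each Y (lipid) variable with each X (env)
    variable, with two-sided t-test significance stars.

    ``ridge`` adds ``ridge * I`` to both within-block covariances for
    near-singular data.
    """
    Xd = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    Yd = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, float))
    if Xd.isna().any().any() or Yd.isna().any().any():
        raise ValueError("CCA requires complete matrices; impute first")
    n = Xd.shape[0]
    if Yd.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if n < 3:
        raise ValueError("need at least 3 observations")
    Xs = (Xd - Xd.mean()) / Xd.std(ddof=1)
    Ys = (Yd - Yd.mean()) / Yd.std(ddof=1)
    Xa, Ya = Xs.to_numpy(), Ys.to_numpy()
    Sxx = Xa.T @ Xa / (n - 1)
    Syy = Ya.T @ Ya / (n - 1)
    Sxy = Xa.T @ Ya / (n - 1)
    Wx = _inv_sqrt(Sxx, "X", ridge)
    Wy = _inv_sqrt(Syy, "Y", ridge)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    k = min(Xa.shape[1], Ya.shape[1])
    corr = np.clip(s[:k], 0.0, 1.0)

    r = pd.DataFrame(
        (Ya.T @ Xa / (n - 1)), index=Yd.columns, columns=Xd.columns
    ).clip(-1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * math.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = pd.DataFrame(2.0 * sstats.t.sf(np.abs(t), df=n - 2),
                     index=r.index, columns=r.columns)
    stars = p.map(significance_stars)
    return CcaResult(
        canonical_correlations=corr,
        x_weights=Wx @ U[:, :k],
        y_weights=Wy @ Vt.T[:, :k],
        structure_correlations=r,
        p_values=p,
        stars=stars,
    )


def composition_tree(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "average",
) -> str:
    """Hierarchical clustering of strains by lipid composition, as newick.

    Rows are sorted lexicographically by label before clustering so ties
    break deterministically.  Branch lengths are half the merge-height
    difference (ultrametric under average linkage on Euclidean input).
    """
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 strains to build a tree")
    if matrix.index.duplicated().any():
        dupes = sorted(matrix.index[matrix.index.duplicated()].unique())
        raise ValueError(f"duplicate strain labels: {dupes}")
    m = matrix.sort_index()
    Z = sch.linkage(pdist(m.to_numpy(dtype=float), metric=distance), method=linkage)
    labels = [str(x) for x in m.index]

    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node_newick(i: int) -> str:
        if i < n:
            return labels[i].replace(" ", "_")
        a, b, h, _ = Z[i - n]
        a, b = int(a), int(b)
        la = (h - heights[a]) / 2.0
        lb = (h - heights[b]) / 2.0
        return f"({node_newick(a)}:{la:.6g},{node_newick(b)}:{lb:.6g})"

    for i, (_, _, h, _) in enumerate(Z):
        heights[n + i] = h
    return node_newick(n + len(Z) - 1) + ";"


def tree_congruence(tree_a: str, tree_b: str) -> float:
    """Normalized Robinson-Foulds distance between two newick trees.

    Counts the bipartitions present in exactly one of the two (unrooted)
    trees and divides by the total number of non-trivial bipartitions, so
    0 means topologically identical and 1 means no shared internal split.
    Trees must share their leaf set.
    """
    import dendropy
    from dendropy.calculate import treecompare

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=tree_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=tree_b, schema="newick", taxon_namespace=tns)
    leaves_a = {lf.taxon.label for lf in ta.leaf_node_iter()}
    leaves_b = {lf.taxon.label for lf in tb.leaf_node_iter()}
    if leaves_a != leaves_b:
        raise ValueError(
            "leaf sets differ: only in first tree "
            f"{sorted(leaves_a - leaves_b)}, only in second {sorted(leaves_b - leaves_a)}"
        )
    for t in (ta, tb):
        t.encode_bipartitions()
    sd = treecompare.symmetric_difference(ta, tb)

    def n_internal(t: "dendropy.Tree") -> int:
        n_leaves = len(leaves_a)
        return sum(
            1 for bp in t.bipartition_encoding
            if 1 < bin(bp.leafset_bitmask).count("1") < n_leaves - 1
        )

    max_sd = n_internal(ta) + n_internal(tb)
    if max_sd == 0:
        return 0.0
    return min(1.0, sd / max_sd)
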