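"""Distance-based permutation tests, PCA coordinates, and two-group PLS-DA with
VIP scoring.

``permanova`` partitions the total sum of squares of a (Gower-centered)
Euclidean distance matrix sequentially by model term — the convention of
vegan's ``adonis2`` with default sequential sums of squares and free
permutation of whole samples — and reports a permutation p-value with the +1
correction so p is never exactly 0.

``plsda_fit`` is a from-scratch NIPALS PLS2 against one-hot-coded class
membership; ``vip_scores`` implements the standard variable-importance-in-
projection statistic whose squared values average to 1 across variables, with
the selection rule VIP >= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateDataError
from .pools import LOG1P, PoolMatrix

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "PlsdaModel",
    "euclidean_distances",
    "permanova",
    "pca",
    "plsda_fit",
    "vip_scores",
]


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix has nonzero diagonal")
        if (d < -1e-10).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "d", d)


def euclidean_distances(data: PoolMatrix | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between samples over metabolite columns.

    Accepts a log1p-state :class:`PoolMatrix` (the state the treatment analysis
    uses) or any samples x variables DataFrame (e.g. an enrichment matrix).
    """
    if isinstance(data, PoolMatrix):
        if data.state != LOG1P:
            raise ValueError(
                f"euclidean_distances expects a log1p-state PoolMatrix, got {data.state!r}"
            )
        frame = data.values
    else:
        frame = data
    X = frame.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in data matrix")
    return DistanceMatrix(tuple(map(str, frame.index)), squareform(pdist(X)))


@dataclass(frozen=True)
class PermanovaTerm:
    name: str
    df: int
    ss: float
    pseudo_f: float
    r2: float
    p: float


@dataclass(frozen=True)
class PermanovaResult:
    terms: tuple[PermanovaTerm, ...]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t.name, "df": t.df, "ss": t.ss, "pseudo_f": t.pseudo_f,
             "r2": t.r2, "p": t.p}
            for t in self.terms
        ]
        rows.append({"term": "residual", "df": self.residual_df, "ss": self.residual_ss,
                     "pseudo_f": np.nan, "r2": self.residual_ss / self.total_ss,
                     "p": np.nan})
        rows.append({"term": "total", "df": self.residual_df + sum(t.df for t in self.terms),
                     "ss": self.total_ss, "pseudo_f": np.nan, "r2": 1.0, "p": np.nan})
        return pd.DataFrame(rows)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummy(levels: pd.Series) -> np.ndarray:
    cats = pd.Categorical(levels)
    if len(cats.categories) < 2:
        raise ValueError(f"factor has a single level: {cats.categories.tolist()}")
    return pd.get_dummies(cats, drop_first=True).to_numpy(dtype=float)


def _hat(X: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    rank = (np.abs(np.diag(r)) > 1e-10).sum()
    q = q[:, :rank]
    return q @ q.T


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    factors: list[str] | None = None,
    interaction: bool = False,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Sequential (Type I) sum-of-squares decomposition for up to two factors plus
    an optional interaction; sample labels are permuted as whole rows.  The
    permutation p-value is ``(count of permuted F >= observed F + 1) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    design = design.loc[list(dm.sample_ids)]
    factors = factors or list(design.columns)
    if not 1 <= len(factors) <= 2:
        raise ValueError("permanova supports one or two factors")
    if interaction and len(factors) != 2:
        raise ValueError("interaction requires two factors")
    for f in factors:
        counts = design[f].value_counts()
        if (counts < 2).any():
            raise ValueError(f"factor {f!r} has a level with fewer than 2 samples")

    n = len(dm.sample_ids)
    blocks: list[tuple[str, np.ndarray]] = []
    mats = {}
    for f in factors:
        mats[f] = _dummy(design[f])
        blocks.append((f, mats[f]))
    if interaction:
        a, b = mats[factors[0]], mats[factors[1]]
        inter = np.einsum("ij,ik->ijk", a, b).reshape(n, -1)
        blocks.append((f"{factors[0]}:{factors[1]}", inter))

    # nested hat matrices: intercept, then each term added sequentially
    X = np.ones((n, 1))
    hats = [_hat(X)]
    dfs = []
    for _, block in blocks:
        prev_rank = int(round(np.trace(hats[-1])))
        X = np.hstack([X, block])
        hats.append(_hat(X))
        dfs.append(int(round(np.trace(hats[-1]))) - prev_rank)
    h_full = hats[-1]
    residual_df = n - int(round(np.trace(h_full)))
    if residual_df < 1:
        raise ValueError("fewer samples than model degrees of freedom")

    G = _gower_center(dm.d)
    diffs = [hats[i + 1] - hats[i] for i in range(len(blocks))]
    resid_proj = np.eye(n) - h_full

    def stats_for(Gp: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float(np.sum(dh * Gp)) for dh in diffs])
        ss_res = float(np.sum(resid_proj * Gp))
        return ss_terms, ss_res

    ss_terms, ss_res = stats_for(G)
    total_ss = float(np.trace(G))
    ms_res = ss_res / residual_df
    f_obs = (ss_terms / np.array(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    ge = np.zeros(len(blocks))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_t, ss_r = stats_for(Gp)
        f_perm = (ss_t / np.array(dfs)) / (ss_r / residual_df)
        ge += f_perm >= f_obs
    pvals = (ge + 1) / (n_perm + 1)

    terms = tuple(
        PermanovaTerm(name, df, float(ss), float(f), float(ss / total_ss), float(p))
        for (name, _), df, ss, f, p in zip(blocks, dfs, ss_terms, f_obs, pvals)
    )
    return PermanovaResult(terms, residual_df, ss_res, total_ss, n_perm, seed)


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame


def pca(data: PoolMatrix | pd.DataFrame, center: bool = True, scale: bool = False) -> PcaResult:
    """Principal components of a samples x variables matrix via SVD."""
    frame = data.values if isinstance(data, PoolMatrix) else data
    X = frame.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            cols = [c for c, s in zip(frame.columns, sd) if s == 0]
            raise DegenerateDataError(f"constant columns cannot be scaled: {cols}")
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    k = len(s)
    comp = [f"PC{i+1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(u * s, index=frame.index, columns=comp),
        explained_variance_ratio=ratio,
        loadings=pd.DataFrame(vt.T, index=frame.columns, columns=comp),
    )


@dataclass(frozen=True)
class PlsdaModel:
    """Two-group PLS-DA fitted by NIPALS PLS2 on autoscaled X.

    ``x_weights`` columns are unit-norm; ``ssy`` is the Y sum of squares
    captured by each component (the weighting used for VIP).
    """

    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    x_weights: np.ndarray      # p x A
    x_loadings: np.ndarray     # p x A
    x_scores: np.ndarray       # n x A
    y_loadings: np.ndarray     # q x A
    explained_x_variance: np.ndarray  # A
    ssy: np.ndarray            # A
    x_mean: np.ndarray = field(repr=False, default=None)
    x_scale: np.ndarray = field(repr=False, default=None)

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Project new samples onto the fitted components.

        Applies the training centering/scaling, then the rotation
        ``W (P'W)^{-1}`` that accounts for deflation.
        """
        Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        Xs = (Xm - self.x_mean) / self.x_scale
        rotation = self.x_weights @ np.linalg.inv(self.x_loadings.T @ self.x_weights)
        return Xs @ rotation


def plsda_fit(
    X: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    n_components: int = 2,
    autoscale: bool = True,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> PlsdaModel:
    """Fit a two-group PLS-DA model.

    X is column-centered (and unit-variance scaled when ``autoscale``); Y is the
    centered one-hot coding of the two class labels. NIPALS extracts components
    with X deflated by its loadings per component, giving mutually orthogonal
    scores. The fit is deterministic: the starting u-vector is the first column
    of the Y residual.
    """
    labels = pd.Series(np.asarray(labels), index=X.index) if not isinstance(labels, pd.Series) else labels.reindex(X.index)
    classes = sorted(pd.unique(labels.astype(str)))
    if len(classes) != 2:
        raise ValueError(f"plsda_fit requires exactly two classes; got {classes}")
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds rank bound {min(n - 1, p)}")
    y_dummy = np.column_stack([(labels.astype(str) == c).to_numpy(float) for c in classes])

    x_mean = Xm.mean(axis=0)
    Xc = Xm - x_mean
    if autoscale:
        x_scale = Xc.std(axis=0, ddof=1)
        if (x_scale == 0).any():
            cols = [c for c, s in zip(X.columns, x_scale) if s == 0]
            raise DegenerateDataError(f"constant columns cannot be autoscaled: {cols}")
    else:
        x_scale = np.ones(p)
    Xc = Xc / x_scale
    Yc = y_dummy - y_dummy.mean(axis=0)

    ss_x_total = float(np.sum(Xc**2))
    ss_y_total = float(np.sum(Yc**2))
    if ss_y_total == 0:
        raise DegenerateDataError("class coding has zero variance")

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    Q = np.zeros((Yc.shape[1], n_components))
    expl_x = np.zeros(n_components)
    ssy = np.zeros(n_components)

    Xr, Yr = Xc.copy(), Yc.copy()
    for a in range(n_components):
        u = Yr[:, 0].copy()
        if np.allclose(u, 0):
            u = Yr[:, 1].copy()
        t_old = None
        for _ in range(max_iter):
            w = Xr.T @ u
            norm = np.linalg.norm(w)
            if norm == 0:
                raise DegenerateDataError("X residual collapsed to zero during NIPALS")
            w = w / norm
            t = Xr @ w
            q = Yr.T @ t / (t @ t)
            u = Yr @ q / (q @ q)
            if t_old is not None and np.linalg.norm(t - t_old) < tol * np.linalg.norm(t):
                break
            t_old = t
        p_load = Xr.T @ t / (t @ t)
        W[:, a], P[:, a], T[:, a], Q[:, a] = w, p_load, t, q
        tt = float(t @ t)
        expl_x[a] = tt * float(p_load @ p_load) / ss_x_total
        ssy[a] = tt * float(q @ q)
        Xr = Xr - np.outer(t, p_load)
        Yr = Yr - np.outer(t, q)

    return PlsdaModel(
        feature_names=tuple(map(str, X.columns)),
        classes=tuple(classes),
        x_weights=W,
        x_loadings=P,
        x_scores=T,
        y_loadings=Q,
        explained_x_variance=expl_x,
        ssy=ssy,
        x_mean=x_mean,
        x_scale=x_scale,
    )


def vip_scores(model: PlsdaModel, threshold: float = 1.0) -> pd.DataFrame:
    """Variable importance in projection with the VIP >= threshold selection rule.

    VIP_j = sqrt( p * sum_a(SSY_a * w_aj^2) / sum_a(SSY_a) ) with unit-norm
    weight vectors, so mean(VIP^2) = 1 over variables.
    """
    total_ssy = model.ssy.sum()
    if total_ssy <= 0:
        raise DegenerateDataError("model explains zero Y variance; VIP undefined")
    p = len(model.feature_names)
    contrib = (model.x_weights**2) @ model.ssy
    vip = np.sqrt(p * contrib / total_ssy)
    return pd.DataFrame(
        {"metabolite": model.feature_names, "vip": vip, "selected": vip >= threshold}
    )
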