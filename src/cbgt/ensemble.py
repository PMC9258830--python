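"""Low-dimensional control-ensemble analysis of (W, R, P) feature matrices.

Given row-aligned matrices of synaptic weights W (n x 14), firing-rate
features R (n x 16) and diffusion-model parameters P (n x 4), this module
provides: per-pair regression influence of weights on postsynaptic rates;
cross-validated canonical correlation analysis (CCA) with the prediction
R-squared score used for component-count selection; canonical loadings;
sensitivity-based normalization of the DDM parameters by their effect on
mean reaction time; and K-means clustering with silhouette-based model
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import CCA as _SkCCA
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .ddm import DDMParams, mean_rt_ddm

P_COLUMNS = ("a", "nu", "t", "z")


@dataclass
class FeatureMatrices:
    """Row-aligned weight / rate / parameter matrices for n networks."""

    W: np.ndarray          # n x 14
    R: np.ndarray          # n x 16
    P: np.ndarray          # n x 4  (a, nu, t, z)
    network_ids: np.ndarray | None = None
    excluded: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        n = self.W.shape[0]
        if self.R.shape[0] != n or self.P.shape[0] != n:
            raise ValueError("W, R, P must have the same number of rows")
        if self.network_ids is None:
            self.network_ids = np.arange(n)

    @property
    def n(self) -> int:
        return self.W.shape[0]


def _zscore(x: np.ndarray, axis=0):
    sd = x.std(axis=axis, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance column; slope undefined")
    return (x - x.mean(axis=axis)) / sd


def regression_influence(
    W: np.ndarray,
    R: np.ndarray,
    weight_names=None,
    rate_names=None,
    pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """OLS slope (with 95% CI) of each postsynaptic rate on each weight.

    Both weights and rates are z-scored before the regression, so the
    slope equals the Pearson correlation and is comparable across pairs.
    ``pairs`` restricts the output to selected (weight, rate) column
    index pairs; by default all pairs are computed.
    """
    W = np.atleast_2d(np.asarray(W, float))
    R = np.atleast_2d(np.asarray(R, float))
    n = W.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows for a regression interval")
    Wz, Rz = _zscore(W), _zscore(R)
    if pairs is None:
        pairs = [(i, j) for i in range(W.shape[1]) for j in range(R.shape[1])]
    weight_names = weight_names or [f"w{i}" for i in range(W.shape[1])]
    rate_names = rate_names or [f"r{j}" for j in range(R.shape[1])]
    rows = []
    for i, j in pairs:
        x, y = Wz[:, i], Rz[:, j]
        sxx = float(x @ x)
        slope = float(x @ y) / sxx
        resid = y - slope * x
        dof = n - 2
        se = float(np.sqrt((resid @ resid) / dof / sxx))
        half = 1.959963984540054 * se
        rows.append({
            "weight": weight_names[i], "rate": rate_names[j],
            "slope": slope, "se": se,
            "ci_low": slope - half, "ci_high": slope + half,
            "covers_zero": (slope - half) <= 0.0 <= (slope + half),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# canonical correlation analysis

@dataclass
class CCAModel:
    """Fitted two-block CCA with a prediction map from X to Y."""

    n_components: int
    estimator: _SkCCA
    canonical_correlations: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray

    def transform(self, X, Y):
        return self.estimator.transform(X, Y)

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(X)


@dataclass
class LoadingsMatrix:
    """Correlations between original variables and canonical variates."""

    values: np.ndarray           # (n_variables, n_components)
    variable_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"component_{k + 1}" for k in range(self.values.shape[1])]
        return pd.DataFrame(self.values, index=self.variable_names, columns=cols)


def cca_fit(X: np.ndarray, Y: np.ndarray, n_components: int) -> CCAModel:
    """Iterative two-block CCA (columns centered and unit-scaled).

    Retains the regression map needed to predict Y from X for the
    R-squared score.  Rank deficiency reduces the effective number of
    components with a warning.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    max_comp = min(X.shape[1], Y.shape[1], X.shape[0] - 1)
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds max {max_comp}")
    eff = min(n_components, int(np.linalg.matrix_rank(X - X.mean(0))),
              int(np.linalg.matrix_rank(Y - Y.mean(0))))
    if eff < n_components:
        warnings.warn(f"rank deficiency: reducing components {n_components} -> {eff}")
    est = _SkCCA(n_components=eff, scale=True, max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, Y)
    xs, ys = est.transform(X, Y)
    cors = np.array([np.corrcoef(xs[:, k], ys[:, k])[0, 1] for k in range(eff)])
    return CCAModel(n_components=eff, estimator=est,
                    canonical_correlations=cors, x_scores=xs, y_scores=ys)


def cca_score(model: CCAModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Prediction R-squared: 1 - sum((y - y_pred)^2) / sum((y - ybar)^2).

    The sums run over every entry of Y, with ``ybar`` the grand mean of
    Y's entries; the score can be negative (worse than predicting the
    mean everywhere).
    """
    Y = np.asarray(Y, float)
    if np.allclose(Y, Y.flat[0]):
        raise ValueError("constant Y: score denominator undefined")
    Y_pred = model.predict(np.asarray(X, float))
    a = float(np.sum((Y - Y_pred) ** 2))
    b = float(np.sum((Y - Y.mean()) ** 2))
    return 1.0 - a / b


def cross_validate_cca(
    X: np.ndarray,
    Y: np.ndarray,
    n_folds: int = 4,
    component_grid=None,
) -> pd.DataFrame:
    """Held-out prediction score per component count over contiguous folds.

    Rows are split into ``n_folds`` contiguous blocks in their stored
    order; fold i tests the i-th block and trains on the rest.  Returns a
    table of mean and SD of the held-out score per component count; the
    selected count maximizes the mean score.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    if n < n_folds:
        raise ValueError("fewer rows than folds")
    if n % n_folds != 0:
        raise ValueError("rows must divide evenly into contiguous folds")
    block = n // n_folds
    max_k = min(X.shape[1], Y.shape[1], n - block - 1)
    if component_grid is None:
        component_grid = range(1, max_k + 1)
    else:
        component_grid = [k for k in component_grid if k <= max_k]
    rows = []
    for k in component_grid:
        scores = []
        for i in range(n_folds):
            test = slice(i * block, (i + 1) * block)
            train_idx = np.r_[0:i * block, (i + 1) * block:n]
            model = cca_fit(X[train_idx], Y[train_idx], k)
            scores.append(cca_score(model, X[test], Y[test]))
        rows.append({"n_components": int(k),
                     "mean_score": float(np.mean(scores)),
                     "sd_score": float(np.std(scores, ddof=1)),
                     "scores": scores})
    df = pd.DataFrame(rows)
    df.attrs["selected"] = int(df.loc[df["mean_score"].idxmax(), "n_components"])
    return df


def canonical_loadings(model: CCAModel, X: np.ndarray, Y: np.ndarray,
                       x_names=None, y_names=None) -> tuple[LoadingsMatrix, LoadingsMatrix]:
    """Pearson correlation of each original column with the canonical
    variates of its own block."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    xs, ys = model.transform(X, Y)
    x_names = list(x_names) if x_names is not None else [f"x{i}" for i in range(X.shape[1])]
    y_names = list(y_names) if y_names is not None else [f"y{i}" for i in range(Y.shape[1])]

    def block(data, scores, names):
        k = scores.shape[1]
        vals = np.full((data.shape[1], k), np.nan)
        for j in range(data.shape[1]):
            col = data[:, j]
            if col.std() == 0:
                continue  # zero-variance column reported as missing
            for c in range(k):
                vals[j, c] = np.corrcoef(col, scores[:, c])[0, 1]
        return LoadingsMatrix(vals, names)

    return block(X, xs, x_names), block(Y, ys, y_names)


# ---------------------------------------------------------------------------
# sensitivity normalization and clustering

@dataclass
class SensitivityScale:
    """Per-parameter mean and reaction-time sensitivity (centered difference)."""

    means: np.ndarray          # x-bar per parameter (a, nu, t, z)
    deltas: np.ndarray         # Delta_x per parameter, s per unit
    h: float
    n_runs: int


def _clip_param(name: str, value: float, reference: dict[str, float]) -> DDMParams:
    p = dict(reference)
    p[name] = value
    p["a"] = max(p["a"], 1e-3)
    p["z"] = min(max(p["z"], 1e-3), 1.0 - 1e-3)
    p["t"] = max(p["t"], 0.0)
    return DDMParams(**p)


def sensitivity_normalize(
    P: np.ndarray,
    h: float = 0.1,
    n_runs: int = 100_000,
    seed: int = 0,
    reference: np.ndarray | None = None,
    rt_engine=mean_rt_ddm,
    dt: float = 1e-3,
) -> tuple[np.ndarray, SensitivityScale]:
    """Transform each parameter column to (x - x_bar) * Delta_x.

    ``Delta_x`` is the centered difference of Monte-Carlo mean RT with
    step ``h`` around the reference point (the column means by default),
    holding the other three parameters at their reference values.  Steps
    are clipped to the parameter's valid domain (relevant for t near 0 and
    z near the unit interval's edges), with the difference quotient taken
    over the actual step used.  The Monte-Carlo engine uses a 1 ms path
    step by default; with bridge-corrected absorption its bias is O(dt),
    far below the h = 0.1 difference scale.
    """
    P = np.asarray(P, float)
    ref = P.mean(axis=0) if reference is None else np.asarray(reference, float)
    ref_dict = dict(zip(P_COLUMNS, ref))
    deltas = np.empty(4)
    rng = np.random.default_rng(seed)
    for i, name in enumerate(P_COLUMNS):
        lo_val, hi_val = ref[i] - h, ref[i] + h
        if name == "t":
            lo_val = max(lo_val, 0.0)
        elif name == "z":
            lo_val, hi_val = max(lo_val, 1e-3), min(hi_val, 1.0 - 1e-3)
        elif name == "a":
            lo_val = max(lo_val, 1e-3)
        s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, 2))
        rt_hi = rt_engine(_clip_param(name, hi_val, ref_dict), n_runs=n_runs,
                          seed=s1, dt=dt)
        rt_lo = rt_engine(_clip_param(name, lo_val, ref_dict), n_runs=n_runs,
                          seed=s2, dt=dt)
        deltas[i] = (rt_hi - rt_lo) / (hi_val - lo_val)
    normalized = (P - ref) * deltas
    return normalized, SensitivityScale(means=ref, deltas=deltas, h=h, n_runs=n_runs)


@dataclass
class ClusteringResult:
    """K-means solution and silhouette quality for one K."""

    K: int
    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    silhouette: float


def kmeans_with_silhouette(
    Pn: np.ndarray,
    k_grid=tuple(range(2, 11)),
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> tuple[dict[int, ClusteringResult], int]:
    """Best-inertia K-means per K plus silhouette-based K selection.

    Ten restarts per K with distinct centroid seeds, convergence when the
    Frobenius movement of centers falls below ``tol`` (relative); the
    selected K maximizes the mean silhouette coefficient
    (b - a) / max(a, b).  K=1 (silhouette undefined) is skipped.
    """
    Pn = np.asarray(Pn, float)
    results: dict[int, ClusteringResult] = {}
    skipped = [k for k in k_grid if k < 2]
    if skipped:
        warnings.warn(f"silhouette undefined for K={skipped}; skipping")
    for K in k_grid:
        if K < 2 or K >= Pn.shape[0]:
            continue
        km = KMeans(n_clusters=K, n_init=n_init, max_iter=max_iter, tol=tol,
                    random_state=seed)
        labels = km.fit_predict(Pn)
        sil = float(silhouette_score(Pn, labels))
        results[K] = ClusteringResult(K=K, labels=labels,
                                      centers=km.cluster_centers_,
                                      inertia=float(km.inertia_), silhouette=sil)
    if not results:
        raise ValueError("no valid K in grid")
    selected = max(results, key=lambda k: results[k].silhouette)
    return results, selected


def silhouette_brute_force(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette by exhaustive pairwise distances (reference oracle)."""
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    n = points.shape[0]
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        a = dist[i, same].mean() if same.any() else 0.0
        bs = [dist[i, labels == other].mean()
              for other in np.unique(labels) if other != labels[i]]
        b = min(bs)
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# model-style front end

@dataclass
class ControlEnsembleResults:
    """Fitted control-ensemble analysis: CV curves, loadings, clusters."""

    cv_wr: pd.DataFrame
    cv_rp: pd.DataFrame
    selected_wr: int
    selected_rp: int
    model_wr: CCAModel
    model_rp: CCAModel
    loadings_wr: tuple[LoadingsMatrix, LoadingsMatrix]
    loadings_rp: tuple[LoadingsMatrix, LoadingsMatrix]
    P_normalized: np.ndarray
    sensitivity: SensitivityScale
    clustering: dict[int, ClusteringResult]
    selected_K: int

    def summary(self) -> str:
        best_wr = self.cv_wr.loc[self.cv_wr["n_components"] == self.selected_wr].iloc[0]
        best_rp = self.cv_rp.loc[self.cv_rp["n_components"] == self.selected_rp].iloc[0]
        sil = self.clustering[self.selected_K].silhouette
        lines = [
            "Control-ensemble analysis",
            "=" * 58,
            f"W->R: {self.selected_wr} components, held-out score "
            f"{best_wr['mean_score']:.3f} +/- {best_wr['sd_score']:.3f}",
            f"R->P: {self.selected_rp} components, held-out score "
            f"{best_rp['mean_score']:.3f} +/- {best_rp['sd_score']:.3f}",
            f"K-means on sensitivity-normalized P: K = {self.selected_K} "
            f"(mean silhouette {sil:.2f})",
        ]
        return "\n".join(lines)


class ControlEnsembleAnalysis:
    """End-to-end statistical analysis bound to one (W, R, P) data set.

    ``fit()`` runs the cross-validated CCA for W->R and R->P, computes
    canonical loadings at the selected component counts, sensitivity-
    normalizes P and clusters it with silhouette-based K selection.
    """

    def __init__(self, data: FeatureMatrices, w_names=None, r_names=None,
                 p_names=P_COLUMNS):
        self.data = data
        self.w_names = list(w_names) if w_names is not None else \
            [f"w{i}" for i in range(data.W.shape[1])]
        self.r_names = list(r_names) if r_names is not None else \
            [f"r{i}" for i in range(data.R.shape[1])]
        self.p_names = list(p_names)

    def fit(self, n_folds: int = 4, seed: int = 0,
            sensitivity_runs: int = 100_000, sensitivity_step: float = 0.1,
            k_grid=tuple(range(2, 11)), sensitivity_dt: float = 1e-3,
            ) -> ControlEnsembleResults:
        W, R, P = self.data.W, self.data.R, self.data.P
        cv_wr = cross_validate_cca(W, R, n_folds=n_folds)
        cv_rp = cross_validate_cca(R, P, n_folds=n_folds)
        k_wr, k_rp = cv_wr.attrs["selected"], cv_rp.attrs["selected"]
        model_wr = cca_fit(W, R, k_wr)
        model_rp = cca_fit(R, P, k_rp)
        Pn, scale = sensitivity_normalize(
            P, h=sensitivity_step, n_runs=sensitivity_runs, seed=seed,
            dt=sensitivity_dt)
        clustering, selected_K = kmeans_with_silhouette(Pn, k_grid, seed=seed)
        return ControlEnsembleResults(
            cv_wr=cv_wr, cv_rp=cv_rp, selected_wr=k_wr, selected_rp=k_rp,
            model_wr=model_wr, model_rp=model_rp,
            loadings_wr=canonical_loadings(model_wr, W, R, self.w_names, self.r_names),
            loadings_rp=canonical_loadings(model_rp, R, P, self.r_names, self.p_names),
            P_normalized=Pn, sensitivity=scale,
            clustering=clustering, selected_K=selected_K,
        )
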