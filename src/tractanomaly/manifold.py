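"""Normative manifold model of healthy-control tract microstructure.

The model is Y = f(x) + eps: Y is a subject's voxel-value vector for one
bundle, x its coordinate in a low-dimensional embedding learned on healthy
controls (UMAP by default, PCA as a linear reducer), f the latent-to-tract
Nadaraya-Watson kernel regression, and eps the subject's residual. Patients
are projected out-of-sample into the HC latent space, back-projected, and
their residuals standardized by leave-one-out HC residual SDs to give
per-voxel z-scores. Group divergence in latent space is tested with a
k-nearest-neighbour Kullback-Leibler estimator under label permutation.

Organised statsmodels-style: build a :class:`NormativeTractModel` from the HC
matrix, ``fit()`` returns a :class:`NormativeTractResults` carrying the
embedding, bandwidth and residual scale, with projection / anomaly methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .cohort import TractVoxelMatrix

__all__ = [
    "NormativeTractModel",
    "NormativeTractResults",
    "AnomalyResult",
    "KLResult",
    "fit_embedding",
    "choose_latent_dim",
    "kl_divergence",
    "bootstrap_kl_test",
    "agreement_analysis",
]


# ---------------------------------------------------------------------------
# reducers

class _PCAReducer:
    def __init__(self, d: int, seed: int | None):
        from sklearn.decomposition import PCA

        self._pca = PCA(n_components=d, random_state=seed)

    def fit_transform(self, y: np.ndarray) -> np.ndarray:
        return self._pca.fit_transform(y)

    def transform(self, y: np.ndarray) -> np.ndarray:
        return self._pca.transform(y)


class _UMAPReducer:
    def __init__(self, d: int, seed: int | None, n_neighbors: int, min_dist: float,
                 metric: str):
        import umap

        self._umap = umap.UMAP(
            n_components=d,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            metric=metric,
            random_state=seed,
            transform_seed=42 if seed is None else seed,
        )

    def fit_transform(self, y: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(self._umap.fit_transform(y), dtype=float)

    def transform(self, y: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(self._umap.transform(y), dtype=float)


def _make_reducer(name: str, d: int, seed: int | None, n_neighbors: int,
                  min_dist: float, metric: str, n_samples: int):
    if name == "pca":
        return _PCAReducer(d, seed)
    if name == "umap":
        return _UMAPReducer(d, seed, min(n_neighbors, n_samples - 2), min_dist, metric)
    raise ValueError(f"unknown reducer {name!r} (use 'umap' or 'pca')")


# ---------------------------------------------------------------------------
# results containers

@dataclass
class AnomalyResult:
    """Per-voxel residuals and standardized z-scores for one subject/tract."""

    residuals: np.ndarray        # eps, metric units
    z_scores: np.ndarray         # eps / hc_residual_sd, SD units
    voxel_index: np.ndarray
    hc_residual_sd: np.ndarray
    tract_label: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        n = self.residuals.shape[0]
        if not (self.z_scores.shape[0] == n == self.hc_residual_sd.shape[0]
                == self.voxel_index.shape[0]):
            raise ValueError("residuals, z-scores, scale and voxel index must align")


@dataclass
class KLResult:
    """Latent-space divergence estimate with permutation inference."""

    dkl: float
    p_value: float
    n_boot: int
    corrected_alpha: float

    def __post_init__(self) -> None:
        if self.dkl < 0:
            raise ValueError("divergence must be >= 0")
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha


# ---------------------------------------------------------------------------
# model

class NormativeTractModel:
    """Normative model of one bundle's voxel profile, fit on healthy controls.

    Parameters
    ----------
    hc_matrix : TractVoxelMatrix or (n_HC, V) array
        Control voxel-value vectors (rows are subjects).
    latent_dim : int
        Embedding dimension d (must satisfy d < n_HC). Use
        :func:`choose_latent_dim` to optimize it.
    reducer : {'umap', 'pca'}
        Dimension-reduction algorithm. UMAP is the default; PCA gives an exact
        linear reducer useful for verification.
    projection : {'kernel', 'transform'}
        Out-of-sample rule: 'kernel' uses a Gaussian-weighted barycentre of
        the nearest HC embedding coordinates (reducer-agnostic,
        deterministic); 'transform' delegates to the reducer's native
        transform.
    kernel_bandwidth : float, optional
        Bandwidth h of the latent-space Gaussian used by the back-projection
        f(x); defaults to the median pairwise latent distance among controls.
    """

    MIN_HC = 10

    def __init__(
        self,
        hc_matrix,
        latent_dim: int = 2,
        reducer: str = "umap",
        projection: str = "kernel",
        n_projection_neighbors: int = 5,
        kernel_bandwidth: float | None = None,
        n_neighbors: int = 15,
        min_dist: float = 0.1,
        metric: str = "euclidean",
        seed: int | None = None,
    ):
        if isinstance(hc_matrix, TractVoxelMatrix):
            self.endog = hc_matrix.values.copy()
            self.voxel_index = hc_matrix.voxel_index.copy()
            self.subject_ids = list(hc_matrix.subject_ids)
            self.tract_label = hc_matrix.tract_label
        else:
            self.endog = np.array(hc_matrix, dtype=float)
            self.voxel_index = np.column_stack(
                [np.arange(self.endog.shape[1])] + [np.zeros(self.endog.shape[1], int)] * 2
            )
            self.subject_ids = [f"hc{i:03d}" for i in range(self.endog.shape[0])]
            self.tract_label = ""
        n, v = self.endog.shape
        if n < self.MIN_HC:
            raise ValueError(f"need at least {self.MIN_HC} controls, got {n}")
        if not (1 <= latent_dim < n):
            raise ValueError(f"latent_dim must satisfy 1 <= d < n_HC={n}")
        if np.allclose(self.endog, self.endog[0]):
            raise ValueError("constant control matrix: degenerate geometry")
        if projection not in ("kernel", "transform"):
            raise ValueError("projection must be 'kernel' or 'transform'")
        self.latent_dim = latent_dim
        self.reducer_name = reducer
        self.projection = projection
        self.n_projection_neighbors = n_projection_neighbors
        self.kernel_bandwidth = kernel_bandwidth
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.metric = metric
        self.seed = seed

    @classmethod
    def from_cohort(cls, cohort, tract_label: str, **kwargs) -> "NormativeTractModel":
        m = cohort.matrices[tract_label]
        hc = m.rows(cohort.manifest.hc_ids)
        model = cls(hc, **kwargs)
        model.voxel_index = m.voxel_index.copy()
        model.subject_ids = list(cohort.manifest.hc_ids)
        model.tract_label = tract_label
        return model

    def fit(self) -> "NormativeTractResults":
        reducer = _make_reducer(
            self.reducer_name, self.latent_dim, self.seed, self.n_neighbors,
            self.min_dist, self.metric, self.endog.shape[0],
        )
        embedding = np.asarray(reducer.fit_transform(self.endog), dtype=float)
        if self.kernel_bandwidth is not None:
            h = float(self.kernel_bandwidth)
        else:
            h = float(np.median(pdist(embedding)))
            if h <= 0:
                h = 1.0
        if h <= 0:
            raise ValueError("kernel bandwidth must be positive")
        return NormativeTractResults(self, embedding, h, reducer)


@dataclass
class NormativeTractResults:
    """Fitted normative manifold: frozen HC embedding plus kernel regression.

    The model is frozen after fit: projecting patients never mutates the
    stored embedding or reference vectors.
    """

    model: NormativeTractModel
    hc_embedding: np.ndarray
    kernel_bandwidth: float
    _reducer: object = field(repr=False, default=None)
    _loo_scale: np.ndarray | None = field(default=None, repr=False)

    @property
    def hc_tract_vectors(self) -> np.ndarray:
        return self.model.endog

    @property
    def latent_dim(self) -> int:
        return self.model.latent_dim

    # -- projection ---------------------------------------------------------

    def project(self, vector: np.ndarray, *, exclude: int | None = None) -> np.ndarray:
        """Out-of-sample latent coordinate x for one tract-space vector.

        In 'kernel' mode x is the Gaussian-weighted barycentre of the k
        nearest controls' embedding coordinates, with weights Gaussian in
        tract-space distance (bandwidth = median of the k distances). An
        exact copy of a training control maps onto that control's own
        embedding point.
        """
        y = np.asarray(vector, dtype=float).ravel()
        if y.shape[0] != self.model.endog.shape[1]:
            raise ValueError(
                f"vector length {y.shape[0]} != tract space {self.model.endog.shape[1]}"
            )
        if self.model.projection == "transform" and exclude is None:
            return self._reducer.transform(y[None, :])[0]
        ref_y = self.model.endog
        ref_x = self.hc_embedding
        if exclude is not None:
            keep = np.arange(ref_y.shape[0]) != exclude
            ref_y, ref_x = ref_y[keep], ref_x[keep]
        d = np.linalg.norm(ref_y - y[None, :], axis=1)
        zero = d <= 1e-12 * max(1.0, float(np.max(d)))
        if np.any(zero):
            return ref_x[zero].mean(axis=0)
        k = min(self.model.n_projection_neighbors, ref_y.shape[0])
        nn = np.argpartition(d, k - 1)[:k]
        dk = d[nn]
        h = float(np.median(dk))
        w = np.exp(-0.5 * (dk / h) ** 2)
        w /= w.sum()
        return (w[:, None] * ref_x[nn]).sum(axis=0)

    def back_project(self, x: np.ndarray, *, exclude: int | None = None) -> np.ndarray:
        """Nadaraya-Watson estimate f(x): local mean of control vectors.

        f(x) = sum_i K(||x - x_i|| / h) Y_i / sum_i K(.), Gaussian K with
        h = ``kernel_bandwidth``. At a control's own embedding coordinate the
        regression is taken as interpolating (the h -> 0 limit at coincident
        nodes), so back-projecting a training point returns that control's
        vector. If every kernel weight underflows, falls back to the nearest
        control's vector with a warning.
        """
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != self.latent_dim:
            raise ValueError(f"latent point has dim {x.shape[0]}, model is {self.latent_dim}")
        ref_x = self.hc_embedding
        ref_y = self.model.endog
        if exclude is not None:
            keep = np.arange(ref_x.shape[0]) != exclude
            ref_x, ref_y = ref_x[keep], ref_y[keep]
        d2 = ((ref_x - x[None, :]) ** 2).sum(axis=1)
        scale2 = float(d2.max())
        if scale2 == 0.0:
            return ref_y.mean(axis=0)
        node = d2 <= 1e-18 * scale2
        if np.any(node):
            return ref_y[node].mean(axis=0)
        logw = -0.5 * d2 / self.kernel_bandwidth**2
        raw_total = np.exp(logw).sum()
        if raw_total == 0.0 or not np.isfinite(raw_total):
            warnings.warn("all kernel weights underflowed; using nearest control")
            return ref_y[int(np.argmin(d2))].copy()
        w = np.exp(logw - logw.max())
        w /= w.sum()
        return w @ ref_y

    def predict(self, vector: np.ndarray) -> np.ndarray:
        """f(project(Y)): the normative expectation for a subject's vector."""
        return self.back_project(self.project(vector))

    # -- anomaly ------------------------------------------------------------

    def loo_residual_scale(self, refit_embedding: bool = False) -> np.ndarray:
        """Per-voxel SD of leave-one-out control residuals.

        Each control is held out, projected and back-projected through the
        model restricted to the remaining controls (by default only the
        regression is refit; ``refit_embedding=True`` re-runs the reducer per
        fold — the slow, fully faithful mode). SDs are floored at 1e-12 and
        flagged in the returned array's ``flagged`` companion attribute via
        :attr:`loo_floor_flags`.
        """
        n = self.model.endog.shape[0]
        if n < NormativeTractModel.MIN_HC:
            raise ValueError(f"need at least {NormativeTractModel.MIN_HC} controls")
        resid = np.empty_like(self.model.endog)
        if refit_embedding:
            for i in range(n):
                keep = np.arange(n) != i
                sub = NormativeTractModel(
                    self.model.endog[keep],
                    latent_dim=min(self.latent_dim, keep.sum() - 1),
                    reducer=self.model.reducer_name,
                    projection="kernel",
                    n_projection_neighbors=self.model.n_projection_neighbors,
                    kernel_bandwidth=self.model.kernel_bandwidth,
                    n_neighbors=self.model.n_neighbors,
                    min_dist=self.model.min_dist,
                    metric=self.model.metric,
                    seed=self.model.seed,
                ).fit()
                y = self.model.endog[i]
                resid[i] = y - sub.back_project(sub.project(y))
        else:
            for i in range(n):
                y = self.model.endog[i]
                x = self.project(y, exclude=i)
                resid[i] = y - self.back_project(x, exclude=i)
        sd = resid.std(axis=0, ddof=1)
        self.loo_floor_flags = sd < 1e-12
        sd = np.maximum(sd, 1e-12)
        self._loo_scale = sd
        return sd

    def anomaly(self, vector: np.ndarray, scale: np.ndarray | None = None,
                subject_id: str = "") -> AnomalyResult:
        """Residual and z-score map for one subject.

        eps = Y - f(project(Y)); z = eps / scale, with scale the leave-one-out
        control residual SD (computed and cached on first use if not given).
        """
        y = np.asarray(vector, dtype=float).ravel()
        if scale is None:
            scale = self._loo_scale if self._loo_scale is not None else self.loo_residual_scale()
        resid = y - self.predict(y)
        return AnomalyResult(
            residuals=resid,
            z_scores=resid / scale,
            voxel_index=self.model.voxel_index,
            hc_residual_sd=np.asarray(scale, dtype=float),
            tract_label=self.model.tract_label,
            subject_id=subject_id,
        )

    def project_many(self, vectors: np.ndarray) -> np.ndarray:
        return np.stack([self.project(v) for v in np.atleast_2d(vectors)])

    def summary(self) -> str:
        m = self.model
        lines = [
            "Normative tract manifold",
            "=" * 40,
            f"tract:            {m.tract_label or '<array>'}",
            f"controls:         {m.endog.shape[0]}",
            f"voxels:           {m.endog.shape[1]}",
            f"latent dim:       {self.latent_dim}",
            f"reducer:          {m.reducer_name}",
            f"projection:       {m.projection}",
            f"kernel bandwidth: {self.kernel_bandwidth:.4g}",
        ]
        if self._loo_scale is not None:
            lines.append(f"LOO residual SD:  median {np.median(self._loo_scale):.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface

def fit_embedding(hc_matrix, d: int = 2, seed: int | None = None,
                  **params) -> NormativeTractResults:
    """Fit the normative embedding on controls (functional wrapper)."""
    return NormativeTractModel(hc_matrix, latent_dim=d, seed=seed, **params).fit()


def choose_latent_dim(hc_matrix, d_max: int, seed: int | None = None,
                      **params) -> int:
    """Latent dimension minimizing leave-one-out back-projection error.

    For each d in 1..d_max and each control, the reducer is refit without
    that control, the held-out subject is transformed into the fold's latent
    space, and a linear readout from latent coordinates to tract space
    (fitted on the remaining controls) predicts the held-out vector. A linear
    readout is the standard probe for how many latent coordinates the tract
    space needs: unlike the smoothing kernel regression, its held-out error
    is not floored by local averaging bias. Because any whole-vector
    out-of-sample transform sees the held-out data itself, the held-out
    subject is scored by voxel-block cross-validation (Eastment-Krzanowski
    style): the latent coordinate is estimated from the subject's observed
    voxels only and the withheld voxel block is predicted from it, so
    superfluous dimensions add prediction variance instead of absorbing the
    target. Ties break toward the smaller dimension.
    """
    y = hc_matrix.values if isinstance(hc_matrix, TractVoxelMatrix) else np.asarray(hc_matrix, float)
    n = y.shape[0]
    if d_max >= n:
        raise ValueError("d_max must be < n_HC")
    reducer_name = params.pop("reducer", "pca")
    n_neighbors = params.pop("n_neighbors", 15)
    min_dist = params.pop("min_dist", 0.1)
    metric = params.pop("metric", "euclidean")
    v = y.shape[1]
    n_folds = min(5, v)
    fold_of = np.arange(v) % n_folds
    errs = np.empty(d_max)
    for d in range(1, d_max + 1):
        sse, cnt = 0.0, 0
        for i in range(n):
            keep = np.arange(n) != i
            red = _make_reducer(reducer_name, d, seed, n_neighbors, min_dist,
                                metric, n - 1)
            x_train = np.asarray(red.fit_transform(y[keep]), dtype=float)
            xt = np.column_stack([np.ones(n - 1), x_train])
            beta, *_ = np.linalg.lstsq(xt, y[keep], rcond=None)  # (d+1, V)
            for b in range(n_folds):
                test = fold_of == b
                # latent coordinate from observed voxels only
                a = beta[1:, ~test].T                      # (V_obs, d)
                rhs = y[i, ~test] - beta[0, ~test]
                x_hat, *_ = np.linalg.lstsq(a, rhs, rcond=None)
                pred = beta[0, test] + x_hat @ beta[1:, test]
                sse += float(((y[i, test] - pred) ** 2).sum())
                cnt += int(test.sum())
        errs[d - 1] = sse / cnt
    tol = errs.min() * 1e-9 + 1e-18
    return int(np.flatnonzero(errs <= errs.min() + tol)[0] + 1)


def kl_divergence(points_a: np.ndarray, points_b: np.ndarray, k: int = 3) -> float:
    """k-NN Kullback-Leibler divergence estimate D(A || B) in nats.

    Wang-Kulkarni-Verdu estimator: D = (d/n) sum_i log(s_k(i) / r_k(i))
    + log(m / (n - 1)), where r_k is the k-th neighbour distance within A
    (self excluded) and s_k within B. Negative estimates are clipped at 0.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    n, d = a.shape
    m, d2 = b.shape
    if d != d2:
        raise ValueError("point clouds must share the latent dimension")
    if n < 5 or m < 5:
        raise ValueError("need at least 5 points per group")
    tree_a = cKDTree(a)
    tree_b = cKDTree(b)
    r, _ = tree_a.query(a, k=k + 1)   # first column is the zero self-distance
    r_k = r[:, k]
    s, _ = tree_b.query(a, k=k)
    s_k = s[:, k - 1]
    if np.any(r_k <= 0):
        raise ValueError("degenerate cloud: >= k duplicated points")
    s_k = np.maximum(s_k, 1e-300)
    dkl = d / n * float(np.sum(np.log(s_k / r_k))) + float(np.log(m / (n - 1)))
    return max(dkl, 0.0)


def bootstrap_kl_test(
    points_a: np.ndarray,
    points_b: np.ndarray,
    n_boot: int = 2000,
    seed: int | None = None,
    m_tests: int = 1,
    alpha: float = 0.05,
    significance_threshold: float | None = None,
    k: int = 3,
) -> KLResult:
    """Permutation test of latent-space group divergence.

    The null distribution is built by permuting group labels ``n_boot`` times;
    p = (r + 1)/(n_boot + 1). The Bonferroni-like corrected threshold is
    alpha / m_tests, tightened further if a stricter explicit
    ``significance_threshold`` is configured.
    """
    a = np.asarray(points_a, float)
    b = np.asarray(points_b, float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if n_boot < 1000:
        warnings.warn(f"n_boot={n_boot} < 1000: permutation p-values will be coarse")
    obs = kl_divergence(a, b, k=k)
    pool = np.vstack([a, b])
    n = a.shape[0]
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_boot):
        perm = rng.permutation(pool.shape[0])
        if kl_divergence(pool[perm[:n]], pool[perm[n:]], k=k) >= obs:
            r += 1
    corrected = alpha / m_tests
    if significance_threshold is not None:
        corrected = min(corrected, significance_threshold)
    return KLResult(dkl=obs, p_value=(r + 1) / (n_boot + 1), n_boot=n_boot,
                    corrected_alpha=corrected)


@dataclass
class AgreementResult:
    """Bland-Altman style agreement between |t| and DKL across tracts."""

    mean_difference: float
    differences: pd.Series
    spread_sd: float


def agreement_analysis(t_values: pd.Series, dkl_values: pd.Series) -> AgreementResult:
    """Agreement between tract-level |t| statistics and latent divergences.

    Both measures are standardized to zero mean / unit SD across tracts; the
    mean standardized difference (the Bland-Altman bias, 0 by construction up
    to rounding) and the per-tract differences with their SD (the spread that
    carries the disagreement) are returned.
    """
    t_values = pd.Series(t_values)
    dkl_values = pd.Series(dkl_values)
    if len(t_values) < 3 or len(dkl_values) < 3:
        raise ValueError("need at least 3 tracts")
    if not t_values.index.equals(dkl_values.index):
        dkl_values = dkl_values.reindex(t_values.index)
        if dkl_values.isna().any():
            raise ValueError("tract sets of the two measures differ")
    zt = _standardize(t_values.abs())
    zd = _standardize(dkl_values)
    diff = zt - zd
    return AgreementResult(
        mean_difference=float(diff.mean()),
        differences=diff,
        spread_sd=float(diff.std(ddof=1)),
    )


def _standardize(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if sd == 0:
        return s - s.mean()
    return (s - s.mean()) / sd
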