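"""Brain-behavior linking: Spearman tables, latent probability maps, VLBM.

Stage 4 of the funnel relates structural alteration to clinical and cognitive
variables at three scales: tract/cluster mean values (Spearman correlations
with pairwise deletion of missing covariates), the latent space (logistic
class-probability surfaces over the 2-D embedding), and single voxels
(voxel-based lesion-behavior mapping with max-statistic permutation FWE
correction, restricted to voxels lesioned in a minimum number of patients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def spearman_matrix(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman correlations of tract/cluster features with covariates.

    Missing covariate values are pairwise-deleted; cells with fewer than
    ``min_n`` complete pairs are flagged (``computed=False``) rather than
    silently dropped. Ties take average ranks; p-values use the
    t-approximation. Both raw and Bonferroni-adjusted p columns are emitted.
    """
    rows = []
    for var in covariates.columns:
        for feat in features.columns:
            x = covariates[var].reindex(features.index)
            y = features[feat]
            ok = x.notna() & y.notna()
            n_used = int(ok.sum())
            rec = {"variable": var, "feature": feat, "n_used": n_used,
                   "rho": np.nan, "p_value": np.nan, "computed": False}
            if n_used >= min_n:
                xv, yv = x[ok].to_numpy(float), y[ok].to_numpy(float)
                if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                    warnings.warn(f"constant input for ({var}, {feat}); rho undefined")
                else:
                    rho, p = stats.spearmanr(xv, yv)
                    rec.update(rho=float(rho), p_value=float(p), computed=True)
            rows.append(rec)
    out = pd.DataFrame(rows)
    m = int(out["computed"].sum())
    out["p_bonferroni"] = np.minimum(out["p_value"] * max(m, 1), 1.0)
    out["selected"] = out["p_value"] < alpha
    out.attrs["alpha"] = alpha
    return out


@dataclass
class LatentProbabilityMap:
    """Logistic class-probability surface over the 2-D latent bounding box."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    probabilities: np.ndarray     # (res, res) in [0, 1]
    coef: np.ndarray              # latent-units^-1
    intercept: float
    binarization_cut: float | None = None

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


def latent_probability_map(
    latent_points: np.ndarray,
    labels: np.ndarray,
    grid_res: int = 50,
    margin: float = 0.1,
    binarize_cut: float | None = None,
) -> LatentProbabilityMap:
    """Fit logistic regression on 2-D latent coordinates, evaluate on a grid.

    Continuous ``labels`` are binarized at ``binarize_cut`` (e.g. 0.4 for an
    absolute fMRI lateralization index, the bound for "highly lateralized");
    if no cut is given, the median is used and recorded. The grid covers the
    embedded points with a relative margin.
    """
    from sklearn.linear_model import LogisticRegression

    x = np.asarray(latent_points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("latent points must be n x 2")
    y = np.asarray(labels, dtype=float)
    cut_used: float | None = None
    if set(np.unique(y)) - {0.0, 1.0}:
        cut_used = float(np.median(y)) if binarize_cut is None else float(binarize_cut)
        y = (y > cut_used).astype(int)
    y = y.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    clf = LogisticRegression().fit(x, y)
    lo, hi = x.min(axis=0), x.max(axis=0)
    pad = margin * (hi - lo + 1e-12)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_res)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_res)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    probs = clf.predict_proba(np.column_stack([xx.ravel(), yy.ravel()]))[:, 1]
    return LatentProbabilityMap(
        grid_x=gx, grid_y=gy,
        probabilities=probs.reshape(grid_res, grid_res),
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        binarization_cut=cut_used,
    )


@dataclass
class VLBMResult:
    """Voxelwise lesion-behavior statistics on the analyzed voxel subset."""

    voxel_columns: np.ndarray      # indices of analyzed voxels (overlap >= min)
    statistic: np.ndarray          # per-voxel correlation r
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray        # max-statistic FWE permutation p
    overlap: np.ndarray            # lesion counts of analyzed voxels
    min_overlap: int
    n_perm: int

    @property
    def significant(self) -> np.ndarray:
        return self.p_corrected < 0.05

    def significant_at(self, alpha: float) -> np.ndarray:
        return self.voxel_columns[self.p_corrected < alpha]


def vlbm(
    values: np.ndarray,
    score: np.ndarray,
    lesion_mask: np.ndarray | None = None,
    min_overlap: int = 6,
    n_perm: int = 5000,
    seed: int | None = None,
) -> VLBMResult:
    """Voxel-based lesion-behavior mapping with permutation FWE correction.

    ``values`` is patients x voxels (continuous z by default; pass binary
    lesion status for the binary mode). Analysis is restricted to voxels
    lesioned in at least ``min_overlap`` patients (about one-third of the
    cohort by default), avoiding low-power voxels. Per-voxel Pearson r of
    values against the behavioral score; family-wise correction permutes the
    score vector ``n_perm`` times and compares each |r| to the permutation
    distribution of the maximum |r|; p = (r_exceed + 1)/(n_perm + 1).
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(score, dtype=float)
    if v.shape[0] != s.shape[0]:
        raise ValueError("values and score must share the patient dimension")
    if v.shape[0] < min_overlap:
        raise ValueError("fewer patients than the minimum overlap")
    binary = lesion_mask if lesion_mask is not None else (v != 0)
    overlap = np.asarray(binary, bool).sum(axis=0)
    cols = np.flatnonzero(overlap >= min_overlap)
    if cols.size == 0:
        warnings.warn("no voxel reaches the minimum lesion overlap; empty result")
        empty = np.empty(0)
        return VLBMResult(cols, empty, empty, empty, overlap[cols], min_overlap, n_perm)
    va = v[:, cols]
    r_obs = _pearson_columns(va, s)
    rng = np.random.default_rng(seed)
    n = s.shape[0]
    exceed = np.zeros(cols.size, dtype=int)
    exceed_max = np.zeros(cols.size, dtype=int)
    for _ in range(n_perm):
        sp = s[rng.permutation(n)]
        r_perm = np.abs(_pearson_columns(va, sp))
        exceed += r_perm >= np.abs(r_obs)
        exceed_max += r_perm.max() >= np.abs(r_obs)
    p_unc = (exceed + 1) / (n_perm + 1)
    p_fwe = (exceed_max + 1) / (n_perm + 1)
    return VLBMResult(cols, r_obs, p_unc, p_fwe, overlap[cols], min_overlap, n_perm)


def _pearson_columns(a: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Pearson r of each column of ``a`` against ``s`` (vectorized)."""
    ac = a - a.mean(axis=0)
    sc = s - s.mean()
    denom = np.sqrt((ac**2).sum(axis=0) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (ac * sc[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    return r


@dataclass
class ClusterAttribution:
    cluster: str
    n_significant: int
    n_impaired: int

    @property
    def percent(self) -> float:
        from .lesions import relative_lesion_percent

        if self.n_impaired == 0:
            return 0.0
        return relative_lesion_percent(self.n_significant, self.n_impaired)


def cluster_attribution(
    significant_voxels: set,
    tract_voxels: dict[str, set],
    tract_cluster: dict[str, str],
    impaired_voxels: dict[str, set],
) -> tuple[dict[str, ClusterAttribution], int]:
    """Distribute behavior-correlated voxels across alteration clusters.

    Each significant voxel is attributed to the cluster(s) of the tract(s)
    containing it; the per-cluster proportion is significant-in-cluster over
    impaired-in-cluster. Voxels inside no tract are counted as unattributed.

    Returns (per-cluster attributions, n_unattributed).
    """
    clusters = sorted(set(tract_cluster.values()))
    sig_by_cluster = {c: set() for c in clusters}
    imp_by_cluster = {c: set() for c in clusters}
    for tract, voxels in tract_voxels.items():
        c = tract_cluster.get(tract)
        if c is None:
            continue
        sig_by_cluster[c] |= significant_voxels & voxels
        imp_by_cluster[c] |= impaired_voxels.get(tract, set())
    all_tract_voxels = set().union(*tract_voxels.values()) if tract_voxels else set()
    unattributed = len(significant_voxels - all_tract_voxels)
    out = {
        c: ClusterAttribution(c, len(sig_by_cluster[c]), len(imp_by_cluster[c]))
        for c in clusters
    }
    return out, unattributed
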