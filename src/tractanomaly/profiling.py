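"""Global tract profiling: group statistics, FOI selection and clustering.

First stage of the global-to-specific funnel. Tract-mean values per subject
are compared between patients and controls with a bootstrapped two-sample
Welch test; bundles surviving Bonferroni correction become fascicles of
interest (FOIs), whose centered alteration profiles are clustered
hierarchically (Ward / Euclidean by default) with elbow, silhouette and
inter-cluster-distance validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

from .cohort import Cohort, TractVoxelMatrix
from .registry import TractRegistry, anatomical_for_role, role_registry_labels


def tract_means(matrix: TractVoxelMatrix) -> pd.Series:
    """Per-subject mean of the metric over the bundle's (retained) voxels."""
    if matrix.n_voxels == 0:
        raise ValueError(f"{matrix.tract_label}: empty matrix")
    return pd.Series(matrix.values.mean(axis=1), index=matrix.subject_ids,
                     name=matrix.tract_label)


def role_tract_means(
    cohort: Cohort, registry: TractRegistry, hc_side: str = "average"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tract-mean tables in epileptogenic-role space.

    Patients contribute the anatomical tract matching each role for their own
    focus side. Controls have no focus; for lateralized roles each HC
    contributes (by default) the mean of its left and right values, keeping
    one value per control and a side-symmetric reference. ``hc_side`` may pin
    the reference to "left" or "right" instead.

    Returns (hc_table, patient_table), subjects x role-tracts.
    """
    if hc_side not in ("average", "left", "right"):
        raise ValueError(f"hc_side must be average/left/right, got {hc_side!r}")
    man = cohort.manifest
    roles = [r for r in role_registry_labels(registry)
             if _role_available(r, cohort.tract_labels)]
    anat_means = {lab: tract_means(m) for lab, m in cohort.matrices.items()}

    hc_cols, pat_cols = {}, {}
    for role in roles:
        if role.endswith(("_ipsi", "_contra")):
            left = anatomical_for_role(role, "left")
            right = anatomical_for_role(role, "right")
            if hc_side == "average":
                hc_vals = (anat_means[left][man.hc_ids] + anat_means[right][man.hc_ids]) / 2.0
            else:
                lab = left if (role.endswith("_ipsi")) == (hc_side == "left") else right
                hc_vals = anat_means[lab][man.hc_ids]
            pat_vals = pd.Series(
                {
                    sid: anat_means[anatomical_for_role(role, man.side_of(sid))][sid]
                    for sid in man.patient_ids
                }
            )
        else:  # commissural
            hc_vals = anat_means[role][man.hc_ids]
            pat_vals = anat_means[role][man.patient_ids]
        hc_cols[role] = hc_vals
        pat_cols[role] = pat_vals
    return pd.DataFrame(hc_cols), pd.DataFrame(pat_cols)


def _role_available(role: str, labels) -> bool:
    if role.endswith(("_ipsi", "_contra")):
        return (anatomical_for_role(role, "left") in labels
                and anatomical_for_role(role, "right") in labels)
    return role in labels


def _welch_t(a: np.ndarray, b: np.ndarray, axis: int = -1) -> np.ndarray:
    ma, mb = a.mean(axis=axis), b.mean(axis=axis)
    va = a.var(axis=axis, ddof=1) / a.shape[axis]
    vb = b.var(axis=axis, ddof=1) / b.shape[axis]
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def bootstrap_two_sample_test(
    a, b, n_boot: int = 2000, seed: int | None = None
) -> tuple[float, float]:
    """Bootstrapped two-sample Welch t-test.

    The statistic is the Welch t on the observed samples. The null is built by
    shifting both samples to the pooled mean, resampling each group with
    replacement ``n_boot`` times, and counting replicates with |t*| >= |t|.
    The two-sided p carries the add-one correction (r+1)/(n_boot+1), so it is
    never exactly zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if n_boot < 1000:
        warnings.warn(f"n_boot={n_boot} < 1000: bootstrap p-values will be coarse")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t_obs = float(_welch_t(a[None, :], b[None, :])[0])
    rng = np.random.default_rng(seed)
    pooled_mean = np.concatenate([a, b]).mean()
    a0 = a - a.mean() + pooled_mean
    b0 = b - b.mean() + pooled_mean
    a_star = rng.choice(a0, size=(n_boot, a.size), replace=True)
    b_star = rng.choice(b0, size=(n_boot, b.size), replace=True)
    t_star = _welch_t(a_star, b_star)
    r = int(np.sum(np.abs(t_star) >= abs(t_obs)))
    return t_obs, (r + 1) / (n_boot + 1)


def group_tract_tests(
    hc_table: pd.DataFrame,
    patient_table: pd.DataFrame,
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Bootstrap Welch tests for every role tract (patients vs HC).

    Returns a frame indexed by tract with ``mean_diff`` (patient - HC, metric
    units), ``t_value`` and bootstrap ``p_value``.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for tract in hc_table.columns:
        a = patient_table[tract].to_numpy()
        b = hc_table[tract].to_numpy()
        t, p = bootstrap_two_sample_test(
            a, b, n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
        )
        rows[tract] = {"mean_diff": a.mean() - b.mean(), "t_value": t, "p_value": p}
    return pd.DataFrame.from_dict(rows, orient="index")


def select_fois(results: pd.DataFrame, alpha: float = 0.05, m: int | None = None) -> pd.DataFrame:
    """Bonferroni FOI selection: selected iff p < alpha / m (strict).

    ``m`` defaults to the number of tested tracts. The per-test threshold is
    recorded in ``results.attrs['per_test_threshold']``.
    """
    if m is None:
        m = len(results)
    if m < 1:
        raise ValueError("m must be >= 1")
    out = results.copy()
    thr = alpha / m
    out["selected"] = out["p_value"] < thr
    out.attrs["per_test_threshold"] = thr
    return out


def centered_profiles(
    hc_table: pd.DataFrame, patient_table: pd.DataFrame, fois: list[str] | None = None
) -> pd.DataFrame:
    """FOI alteration profiles: patient tract mean minus HC group mean.

    Rows are tracts, columns patients — the objects clustered downstream.
    """
    cols = list(patient_table.columns if fois is None else fois)
    missing = [c for c in cols if c not in hc_table.columns]
    if missing:
        raise KeyError(f"no HC pairing for tracts: {missing}")
    centered = patient_table[cols] - hc_table[cols].mean(axis=0)
    return centered.T  # tracts x patients


@dataclass
class ClusterSolution:
    k: int
    assignment: pd.Series            # tract -> cluster id (1..k)
    linkage_tree: np.ndarray         # scipy linkage matrix, (n-1) merges
    silhouette: pd.Series | None     # per tract
    mean_silhouette: float | None
    intercluster_distances: np.ndarray | None


def hierarchical_cluster(
    profiles: pd.DataFrame,
    method: str = "ward",
    k: int | None = None,
    metric: str = "euclidean",
) -> ClusterSolution:
    """Agglomerative clustering of tract alteration profiles.

    ``metric='euclidean'`` clusters raw profile vectors; ``metric='correlation'``
    uses 1 - Pearson r, the alternative distance for correlation-matrix
    clustering. Deterministic given the input.
    """
    n = len(profiles)
    if n < 3:
        raise ValueError("need at least 3 tracts to cluster")
    if k is not None and not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} tracts")
    dvec = pdist(profiles.to_numpy(), metric=metric)
    tree = linkage(dvec, method=method)
    if k is None:
        return ClusterSolution(0, pd.Series(dtype=int), tree, None, None, None)
    labels = fcluster(tree, t=k, criterion="maxclust")
    assignment = pd.Series(labels, index=profiles.index, name="cluster")
    sil, mean_sil, inter = None, None, None
    if k >= 2:
        sil_vals = silhouette_samples(squareform(dvec), labels, metric="precomputed")
        # singleton clusters: silhouette of the lone member is defined as 0
        sil = pd.Series(sil_vals, index=profiles.index, name="silhouette")
        mean_sil = float(sil_vals.mean())
        inter = _centroid_distances(profiles.to_numpy(), labels, k)
    return ClusterSolution(k, assignment, tree, sil, mean_sil, inter)


def _centroid_distances(x: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    cents = np.stack([x[labels == c].mean(axis=0) for c in range(1, k + 1)])
    return squareform(pdist(cents))


def within_cluster_dispersion(profiles: pd.DataFrame, tree: np.ndarray, k: int) -> float:
    """Total within-cluster sum of squared distances to centroids at a k-cut."""
    x = profiles.to_numpy()
    labels = fcluster(tree, t=k, criterion="maxclust")
    w = 0.0
    for c in np.unique(labels):
        xc = x[labels == c]
        w += float(((xc - xc.mean(axis=0)) ** 2).sum())
    return w


def knee_point(ks: np.ndarray, values: np.ndarray) -> tuple[int, bool]:
    """Elbow of a decreasing curve by the max-distance-to-chord rule.

    The chord joins the first and last (k, value) points (both axes scaled to
    [0, 1]); the knee is the k whose point lies farthest below the chord.
    Ties break toward smaller k. Returns (k, flat) where ``flat`` marks a
    curve with no point below the chord (no usable knee).
    """
    ks = np.asarray(ks, dtype=float)
    v = np.asarray(values, dtype=float)
    if ks.size != v.size or ks.size < 3:
        raise ValueError("need >= 3 (k, dispersion) points")
    kx = (ks - ks[0]) / (ks[-1] - ks[0])
    span = v[0] - v[-1]
    if span == 0:
        return int(ks[0]), True
    vy = (v - v[-1]) / span
    chord = 1.0 - kx  # normalized line from (0,1) to (1,0)
    below = chord - vy
    if np.all(below[1:-1] <= 1e-12):
        return int(ks[0]), True
    tie = np.flatnonzero(below >= below.max() - 1e-12)  # smallest k among ties
    return int(ks[tie[0]]), False


def select_k_elbow(profiles: pd.DataFrame, k_range=range(2, 9), method: str = "ward") -> int:
    """Choose the cluster count at the elbow of within-cluster dispersion.

    Dispersion is evaluated at every k in ``k_range`` on the same linkage
    tree, with the scree anchored at k = 1 (total sum of squares) so the first
    real partition can itself be the knee. A monotone-flat curve (no knee)
    returns min(k_range) with a warning.
    """
    ks = np.array(sorted(k_range))
    n = len(profiles)
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    dvec = pdist(profiles.to_numpy())
    tree = linkage(dvec, method=method)
    ks_full = np.concatenate([[1], ks])
    disp = np.array([within_cluster_dispersion(profiles, tree, int(k)) for k in ks_full])
    k, flat = knee_point(ks_full, disp)
    if flat or k < ks[0]:
        warnings.warn("dispersion curve has no knee; returning smallest k")
        return int(ks[0])
    return k


def cluster_validation(
    solution: ClusterSolution, profiles: pd.DataFrame
) -> tuple[float, np.ndarray]:
    """Mean silhouette and centroid inter-cluster distance matrix.

    Singleton clusters are flagged with a warning (their members' silhouette
    is 0 by definition).
    """
    if solution.k < 2:
        raise ValueError("validation requires k >= 2")
    labels = solution.assignment.to_numpy()
    counts = np.bincount(labels)[1:]
    if np.any(counts == 1):
        warnings.warn("singleton cluster present; its silhouette is defined as 0")
    x = profiles.loc[solution.assignment.index].to_numpy()
    sil = float(silhouette_samples(x, labels).mean())
    inter = _centroid_distances(x, labels, solution.k)
    return sil, inter
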