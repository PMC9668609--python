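"""End-to-end funnel orchestration on a cohort container.

Chains the stages: role-space tract means -> bootstrapped group tests with
Bonferroni FOI selection -> centered-profile clustering with elbow validation
-> per-tract normative manifolds with leave-one-out z-scoring -> lesion maps
and %RL. Each stage remains individually importable; this module only wires
them together with one master seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import lesions as lesion_mod
from . import profiling
from .cohort import Cohort
from .manifold import NormativeTractModel
from .registry import anatomical_for_role, load_tract_registry


def run_anomaly_stage(
    cohort: Cohort,
    roles: list[str],
    reducer: str = "umap",
    latent_dim: int = 2,
    seed: int | None = None,
    z_threshold: float | None = None,
    direction: str = "two-sided",
    family_alpha: float = 0.05,
    refit_embedding: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-patient %RL for the given role tracts via normative manifolds.

    One normative model is fitted per anatomical bundle on HC subjects; each
    patient's matched-side vector is projected, back-projected and
    standardized by the leave-one-out HC residual SD. The z threshold is the
    Bonferroni-adjusted quantile for the bundle's own voxel count unless an
    explicit override (e.g. 4.8) is given.

    Returns (%RL table patients x roles, {(role, patient): LesionMap}).
    """
    man = cohort.manifest
    pat_ids = man.patient_ids
    needed: set[str] = set()
    for role in roles:
        for sid in pat_ids:
            needed.add(anatomical_for_role(role, man.side_of(sid)))
    rng = np.random.default_rng(seed)
    fitted: dict[str, tuple] = {}
    for anat in sorted(needed):
        model = NormativeTractModel.from_cohort(
            cohort, anat, reducer=reducer, latent_dim=latent_dim,
            seed=int(rng.integers(2**31 - 1)),
        )
        res = model.fit()
        scale = res.loo_residual_scale(refit_embedding=refit_embedding)
        zs = z_threshold if z_threshold is not None else \
            lesion_mod.bonferroni_z_threshold(model.endog.shape[1], family_alpha)
        fitted[anat] = (res, scale, zs)

    rl = pd.DataFrame(index=pat_ids, columns=roles, dtype=float)
    maps: dict[tuple[str, str], lesion_mod.LesionMap] = {}
    for role in roles:
        for sid in pat_ids:
            anat = anatomical_for_role(role, man.side_of(sid))
            res, scale, zs = fitted[anat]
            vec = cohort.matrices[anat].row(sid)
            anomaly = res.anomaly(vec, scale, subject_id=sid)
            lm = lesion_mod.threshold_zmap(anomaly, zs, direction=direction)
            rl.loc[sid, role] = lm.rl_percent
            maps[(role, sid)] = lm
    return rl, maps


def run_funnel(
    cohort: Cohort,
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
    k_range=range(2, 9),
    reducer: str = "umap",
    latent_dim: int = 2,
    z_threshold: float | None = None,
    anomaly: bool = True,
    hc_side: str = "average",
) -> dict:
    """Run the full global-to-specific funnel; returns a result dictionary.

    Keys: ``tests`` (per-tract stats frame), ``fois`` (selected role labels),
    ``profiles`` (centered tract x patient frame), ``k``, ``clusters``
    (ClusterSolution or None), ``rl_percent`` (patients x FOIs) and
    ``mean_rl_percent`` when the anomaly stage runs.
    """
    registry = load_tract_registry()
    rng = np.random.default_rng(seed)
    hc_table, pat_table = profiling.role_tract_means(cohort, registry, hc_side=hc_side)
    tests = profiling.group_tract_tests(
        hc_table, pat_table, n_boot=n_boot, seed=int(rng.integers(2**31 - 1))
    )
    tests = profiling.select_fois(tests, alpha=alpha)
    fois = list(tests.index[tests["selected"]])
    out: dict = {"tests": tests, "fois": fois, "profiles": None, "k": None,
                 "clusters": None}
    if len(fois) >= 4:
        profiles = profiling.centered_profiles(hc_table, pat_table, fois)
        ks = [k for k in k_range if k <= len(fois) - 1]
        if len(ks) >= 2:
            k = profiling.select_k_elbow(profiles, ks)
            out["clusters"] = profiling.hierarchical_cluster(profiles, k=k)
            out["k"] = k
        out["profiles"] = profiles
    if anomaly and fois:
        rl, maps = run_anomaly_stage(
            cohort, fois, reducer=reducer, latent_dim=latent_dim,
            seed=int(rng.integers(2**31 - 1)), z_threshold=z_threshold,
        )
        out["rl_percent"] = rl
        out["lesion_maps"] = maps
        out["mean_rl_percent"] = float(rl.to_numpy(dtype=float).mean())
    return out
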