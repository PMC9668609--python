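"""Cohort data model and I/O: manifests, per-tract voxel matrices, trimming.

Everything downstream of image extraction operates on `TractVoxelMatrix`
objects — one subjects x voxels array per bundle and metric, with a shared
voxel index in template space. Voxel correspondence across subjects is
assumed (template-space inputs); the array container is the canonical path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import h5py
import numpy as np
import pandas as pd

GROUPS = ("HC", "LTLE", "RTLE")

COVARIATE_NAMES = (
    "AGE", "GEN", "EDU", "ASO", "DUR", "FRQ", "AED", "HS", "ASY", "LI",
    "VCI", "PRI", "NAM", "PFL", "SFL", "AMI", "VMI", "STR", "TMT",
)

_CONTAINER_VERSION = 1


class CohortIOError(IOError):
    """Raised when the on-disk cohort container is unreadable or mismatched."""


@dataclass
class CohortManifest:
    """Subject table: group membership, epileptogenic side, covariates.

    Wraps a DataFrame indexed by subject_id with columns ``group``,
    ``epileptogenic_side`` and one column per covariate. Missing covariate
    values are kept as NaN (explicit missing, pairwise-deleted downstream),
    never dropped silently.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("group", "epileptogenic_side"):
            if col not in t.columns:
                raise ValueError(f"manifest missing required column {col!r}")
        bad = set(t["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        hc = t["group"] == "HC"
        if not (t.loc[hc, "epileptogenic_side"] == "none").all():
            raise ValueError("HC subjects must have epileptogenic_side='none'")
        for grp, side in (("LTLE", "left"), ("RTLE", "right")):
            sel = t["group"] == grp
            if not (t.loc[sel, "epileptogenic_side"] == side).all():
                raise ValueError(f"{grp} subjects must have epileptogenic_side={side!r}")
        if t.index.has_duplicates:
            raise ValueError("duplicate subject ids")
        t.index.name = "subject_id"

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.table.drop(columns=["group", "epileptogenic_side"])

    def ids_in_group(self, *groups: str) -> list[str]:
        return list(self.table.index[self.table["group"].isin(groups)])

    @property
    def hc_ids(self) -> list[str]:
        return self.ids_in_group("HC")

    @property
    def patient_ids(self) -> list[str]:
        return self.ids_in_group("LTLE", "RTLE")

    def side_of(self, subject_id: str) -> str:
        return str(self.table.loc[subject_id, "epileptogenic_side"])

    def iter_subjects(self) -> Iterator[tuple[str, str, str]]:
        for sid, row in self.table.iterrows():
            yield str(sid), str(row["group"]), str(row["epileptogenic_side"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CohortManifest":
        return cls(pd.read_csv(path, sep="\t", index_col="subject_id"))


@dataclass
class MetricVolume:
    """A scalar microstructure map on the template grid."""

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    metric_name: str = "FA"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("metric volume must be 3-D")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")


@dataclass
class TractVoxelMatrix:
    """subjects x voxels values of one metric for one bundle.

    ``voxel_index`` holds 0-based (i, j, k) template coordinates in a fixed
    lexicographic order; all subjects share the identical voxel set.
    ``trim_fraction`` records the retention fraction if the matrix has been
    endpoint-trimmed (trimming is defined once, relative to the untrimmed
    tract, so re-trimming at the same fraction is a no-op).
    """

    tract_label: str
    voxel_index: np.ndarray
    values: np.ndarray
    subject_ids: list[str]
    metric_name: str = "FA"
    trim_fraction: float | None = None

    def __post_init__(self) -> None:
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.voxel_index.ndim != 2 or self.voxel_index.shape[1] != 3:
            raise ValueError("voxel_index must be (V, 3)")
        if self.values.ndim != 2:
            raise ValueError("values must be subjects x voxels")
        if self.values.shape[1] != self.voxel_index.shape[0]:
            raise ValueError(
                f"{self.tract_label}: {self.values.shape[1]} value columns vs "
                f"{self.voxel_index.shape[0]} voxels"
            )
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("row count must equal number of subject ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.tract_label}: non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def rows(self, subject_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        return self.values[[pos[s] for s in subject_ids]]

    def row(self, subject_id: str) -> np.ndarray:
        return self.values[self.subject_ids.index(subject_id)]


def extract_tract_values(volume: MetricVolume, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract the masked voxel values of a scalar map in a stable order.

    Ordering is lexicographic in 0-based (i, j, k) — a pure function of the
    coordinates, independent of how the mask was produced or iterated.

    Returns (values, voxel_index) with ``len(values) == voxel_index.shape[0]``.
    """
    mask = np.asarray(mask)
    if mask.shape != volume.grid.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.grid.shape}")
    idx = np.argwhere(mask != 0)  # argwhere is C-ordered == lexicographic (i, j, k)
    if idx.shape[0] == 0:
        raise ValueError("tract mask is empty (no nonzero voxels)")
    values = volume.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
    return values, idx


def trim_track_weighted(
    matrix: TractVoxelMatrix,
    hc_ids: list[str] | None = None,
    retain_fraction: float = 0.8,
) -> TractVoxelMatrix:
    """Drop voxels in the tails of the HC-mean distribution.

    Track-weighted maps are noisiest at cortical endpoints; retaining only the
    central ``retain_fraction`` of voxels by mean HC value proxies endpoint
    removal without needing streamline geometry. The column set is fixed on HC
    subjects and applied to everyone (voxel correspondence must survive).

    floor((1-f)/2 * V) columns are dropped at each tail, so at least
    ceil(f*V) columns survive. A matrix already trimmed at this fraction is
    returned unchanged.
    """
    if not (0.0 < retain_fraction <= 1.0):
        raise ValueError(f"retain_fraction must be in (0, 1], got {retain_fraction}")
    if matrix.trim_fraction is not None and np.isclose(matrix.trim_fraction, retain_fraction):
        return matrix
    if retain_fraction == 1.0:
        return replace(matrix, trim_fraction=1.0)
    ref = matrix.values if hc_ids is None else matrix.rows(hc_ids)
    col_means = ref.mean(axis=0)
    v = matrix.n_voxels
    k = int(np.floor((1.0 - retain_fraction) / 2.0 * v + 1e-9))
    if k == 0:
        return replace(matrix, trim_fraction=retain_fraction)
    order = np.argsort(col_means, kind="stable")
    keep = np.sort(order[k : v - k])
    return TractVoxelMatrix(
        tract_label=matrix.tract_label,
        voxel_index=matrix.voxel_index[keep],
        values=matrix.values[:, keep],
        subject_ids=list(matrix.subject_ids),
        metric_name=matrix.metric_name,
        trim_fraction=retain_fraction,
    )


@dataclass
class Cohort:
    """Manifest plus all per-tract voxel matrices (and optional ground truth)."""

    manifest: CohortManifest
    matrices: dict[str, TractVoxelMatrix]
    ground_truth: dict | None = None

    @property
    def tract_labels(self) -> list[str]:
        return list(self.matrices)

    def trimmed(self, retain_fraction: float = 0.8) -> "Cohort":
        hc = self.manifest.hc_ids
        return Cohort(
            manifest=self.manifest,
            matrices={
                lab: trim_track_weighted(m, hc, retain_fraction)
                for lab, m in self.matrices.items()
            },
            ground_truth=self.ground_truth,
        )


def save_cohort(cohort: Cohort, path) -> None:
    """Write the cohort to a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["container_version"] = _CONTAINER_VERSION
        f.attrs["manifest_json"] = cohort.manifest.table.to_json(orient="split")
        if cohort.ground_truth is not None:
            f.attrs["ground_truth_json"] = json.dumps(cohort.ground_truth, default=_jsonable)
        g = f.create_group("tracts")
        for label, m in cohort.matrices.items():
            tg = g.create_group(label)
            tg.create_dataset("voxel_index", data=m.voxel_index)
            tg.create_dataset("values", data=m.values)
            tg.create_dataset(
                "subject_ids", data=np.array(m.subject_ids, dtype=h5py.string_dtype())
            )
            tg.attrs["metric_name"] = m.metric_name
            tg.attrs["trim_fraction"] = -1.0 if m.trim_fraction is None else m.trim_fraction


def load_cohort(path) -> Cohort:
    """Read a cohort container written by :func:`save_cohort`.

    Fails loudly (never returns partial data) on truncation or on a container
    version this code does not understand.
    """
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("container_version", -1))
            if version != _CONTAINER_VERSION:
                raise CohortIOError(
                    f"container version {version} unsupported (expected {_CONTAINER_VERSION})"
                )
            manifest = CohortManifest(pd.read_json(
                __import__("io").StringIO(f.attrs["manifest_json"]), orient="split"
            ))
            gt = None
            if "ground_truth_json" in f.attrs:
                gt = json.loads(f.attrs["ground_truth_json"])
            matrices: dict[str, TractVoxelMatrix] = {}
            for label in f["tracts"]:
                tg = f["tracts"][label]
                tf = float(tg.attrs["trim_fraction"])
                matrices[label] = TractVoxelMatrix(
                    tract_label=label,
                    voxel_index=tg["voxel_index"][()],
                    values=tg["values"][()],
                    subject_ids=[s.decode() for s in tg["subject_ids"][()]],
                    metric_name=str(tg.attrs["metric_name"]),
                    trim_fraction=None if tf < 0 else tf,
                )
    except (OSError, KeyError) as exc:
        if isinstance(exc, CohortIOError):
            raise
        raise CohortIOError(f"cannot read cohort container {path}: {exc}") from exc
    return Cohort(manifest=manifest, matrices=matrices, ground_truth=gt)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not JSON-serialisable: {type(o)}")
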