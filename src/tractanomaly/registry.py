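"""Fixed catalogue of white-matter bundles and epileptogenic-side relabeling.

The registry enumerates the 71 bundles of a whole-brain bundle-segmentation
atlas (TractSeg-style nomenclature), with the corpus callosum represented only
by its seven subparts (CC_1..CC_7) because callosal subregions are altered
differentially in epilepsy; the whole-CC bundle is deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Hemisphere = Literal["left", "right", "commissural"]
Category = Literal["association", "projection", "commissural"]

#: (stem, category) for every lateralized bundle; each yields _left and _right.
_LATERALIZED: tuple[tuple[str, str], ...] = (
    ("AF", "association"),       # arcuate fascicle
    ("ATR", "projection"),       # anterior thalamic radiation
    ("CG", "association"),       # cingulum
    ("CST", "projection"),       # corticospinal tract
    ("FPT", "projection"),       # fronto-pontine tract
    ("FX", "association"),       # fornix (limbic)
    ("ICP", "projection"),       # inferior cerebellar peduncle
    ("IFO", "association"),      # inferior occipito-frontal fascicle
    ("ILF", "association"),      # inferior longitudinal fascicle
    ("MLF", "association"),      # middle longitudinal fascicle
    ("OR", "projection"),        # optic radiation
    ("POPT", "projection"),      # parieto-occipito-pontine tract
    ("SCP", "projection"),       # superior cerebellar peduncle
    ("SLF_I", "association"),
    ("SLF_II", "association"),
    ("SLF_III", "association"),
    ("STR", "projection"),       # superior thalamic radiation
    ("ST_FO", "projection"),     # striato-fronto-orbital
    ("ST_OCC", "projection"),
    ("ST_PAR", "projection"),
    ("ST_POSTC", "projection"),
    ("ST_PREC", "projection"),
    ("ST_PREF", "projection"),
    ("ST_PREM", "projection"),
    ("T_OCC", "projection"),     # thalamo-occipital
    ("T_PAR", "projection"),
    ("T_POSTC", "projection"),
    ("T_PREC", "projection"),
    ("T_PREF", "projection"),
    ("T_PREM", "projection"),
    ("UF", "association"),       # uncinate fascicle
)

_COMMISSURAL: tuple[str, ...] = (
    "CA", "CC_1", "CC_2", "CC_3", "CC_4", "CC_5", "CC_6", "CC_7", "MCP",
)


@dataclass(frozen=True)
class TractEntry:
    label: str
    hemisphere: Hemisphere
    category: Category


@dataclass(frozen=True)
class TractRegistry:
    """The fixed 71-bundle catalogue.

    Invariants (enforced at construction): exactly 71 unique labels, the
    corpus callosum present only as CC_1..CC_7, and every left label having a
    right counterpart.
    """

    entries: tuple[TractEntry, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(labels) != 71:
            raise ValueError(f"registry must hold exactly 71 bundles, got {len(labels)}")
        if len(set(labels)) != len(labels):
            raise ValueError("registry labels must be unique")
        if "CC" in labels:
            raise ValueError("whole corpus callosum must not appear; only CC_1..CC_7")
        missing_cc = [f"CC_{i}" for i in range(1, 8) if f"CC_{i}" not in labels]
        if missing_cc:
            raise ValueError(f"missing corpus-callosum subparts: {missing_cc}")
        label_set = set(labels)
        for e in self.entries:
            if e.hemisphere == "left":
                other = e.label[:-5] + "_right"
            elif e.hemisphere == "right":
                other = e.label[:-6] + "_left"
            else:
                continue
            if other not in label_set:
                raise ValueError(f"{e.label} has no contralateral counterpart {other}")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, label: str) -> TractEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)

    def hemisphere(self, label: str) -> Hemisphere:
        return self[label].hemisphere

    def is_commissural(self, label: str) -> bool:
        return self[label].hemisphere == "commissural"


def load_tract_registry() -> TractRegistry:
    """Return the packaged 71-bundle registry."""
    entries: list[TractEntry] = []
    for stem, cat in _LATERALIZED:
        entries.append(TractEntry(f"{stem}_left", "left", cat))  # type: ignore[arg-type]
        entries.append(TractEntry(f"{stem}_right", "right", cat))  # type: ignore[arg-type]
    for label in _COMMISSURAL:
        entries.append(TractEntry(label, "commissural", "commissural"))
    entries.sort(key=lambda e: e.label)
    return TractRegistry(tuple(entries))


def role_label(anatomical: str, side: str, registry: TractRegistry) -> str:
    """Map one anatomical label to its epileptogenic-role label.

    For a left-sided focus, ``*_left`` becomes ``*_ipsi`` and ``*_right``
    becomes ``*_contra``; mirrored for a right focus. Commissural bundles keep
    their anatomical label. The map is an involution at fixed side: role
    labels are mapped back to the anatomical ones.
    """
    if side not in ("left", "right"):
        raise ValueError(f"epileptogenic side must be 'left' or 'right', got {side!r}")
    ipsi, contra = (("_left", "_right") if side == "left" else ("_right", "_left"))
    for anat_suffix, role_suffix in ((ipsi, "_ipsi"), (contra, "_contra")):
        if anatomical.endswith(anat_suffix):
            return anatomical[: -len(anat_suffix)] + role_suffix
        if anatomical.endswith(role_suffix):
            return anatomical[: -len(role_suffix)] + anat_suffix
    if anatomical in registry.labels and registry.is_commissural(anatomical):
        return anatomical
    raise KeyError(f"label {anatomical!r} is neither lateralized nor a known commissural bundle")


def relabel_ipsi_contra(manifest, registry: TractRegistry) -> dict[str, dict[str, str]]:
    """Per-patient map from anatomical tract label to ipsi/contra role label.

    Only patient subjects are mapped; healthy controls keep anatomical labels
    (the comparison pairing is side-preserving: a patient's ipsi tract is
    compared to the HC tract on the same anatomical side as the focus).

    Raises if a patient has no recorded epileptogenic side.
    """
    out: dict[str, dict[str, str]] = {}
    for sid, group, side in manifest.iter_subjects():
        if group == "HC":
            continue
        if side not in ("left", "right"):
            raise ValueError(f"patient {sid} has epileptogenic_side={side!r}")
        out[sid] = {lab: role_label(lab, side, registry) for lab in registry.labels}
    return out


def role_registry_labels(registry: TractRegistry) -> list[str]:
    """The 71 role-space labels: *_ipsi/*_contra stems plus commissural bundles."""
    out: list[str] = []
    seen: set[str] = set()
    for e in registry.entries:
        if e.hemisphere == "commissural":
            out.append(e.label)
        else:
            stem = e.label.rsplit("_", 1)[0]
            if stem not in seen:
                seen.add(stem)
                out.append(stem + "_ipsi")
                out.append(stem + "_contra")
    return out


def anatomical_for_role(role: str, side: str) -> str:
    """Anatomical label realising a role label for a patient with the given focus side."""
    if role.endswith("_ipsi"):
        return role[: -len("_ipsi")] + ("_left" if side == "left" else "_right")
    if role.endswith("_contra"):
        return role[: -len("_contra")] + ("_right" if side == "left" else "_left")
    return role
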