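"""Region vocabulary and loop-edge manifests for cortico-basal ganglia-thalamo-cortical (CBTC) circuits.

Two parallel intrahemispheric loops are modelled: the "long"
cortico-striato-pallido-thalamo-cortical loop and the "short"
cortico-striato-thalamo-cortical loop (no pallidal relay).  Subcortical
structures are subdivided by their dominant cortical target (e.g. ``CAU_M1``
is the caudate territory connected to M1), so loop edges join a cortical
region either to one of its subdivisions or join two subdivisions sharing a
cortical target.  A third "atlas" edge set treats each subcortical structure
as an undivided whole: all 5x4 cortico-subcortical pairs plus the C(4,2)=6
subcortical-subcortical pairs.

Per hemisphere the validated edge counts are fixed: 19 (short) + 21 (long)
= 40 loop edges, and 26 atlas edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterable, Literal

import pandas as pd

CORTICAL: tuple[str, ...] = ("MPFC", "DLPFC", "M1", "PMC", "OFC")
SUBCORTICAL: tuple[str, ...] = ("CAU", "PUT", "PAL", "THA")
HEMISPHERES: tuple[str, ...] = ("L", "R")

Hemisphere = Literal["L", "R"]
LoopName = Literal["short", "long", "atlas"]

#: Expected edge counts per hemisphere for a valid manifest.
EXPECTED_COUNTS: dict[str, int] = {"short": 19, "long": 21, "atlas": 26}


class ManifestError(ValueError):
    """Raised when a loop manifest fails parsing or count/uniqueness validation."""


@dataclass(frozen=True)
class RegionLabel:
    """A named region: cortical, subcortical parent, or a connectivity-defined subdivision."""

    name: str
    kind: Literal["cortical", "subcortical", "subdivision"]
    hemisphere: Hemisphere
    parent: str | None = None   # subdivisions only: CAU/PUT/PAL/THA
    tag: str | None = None      # subdivisions only: the cortical target

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be L or R, got {self.hemisphere!r}")
        if self.kind == "subdivision":
            if self.parent not in SUBCORTICAL:
                raise ValueError(f"subdivision parent {self.parent!r} not a subcortical structure")
            if self.tag not in CORTICAL:
                raise ValueError(f"subdivision tag {self.tag!r} not a cortical target")
        elif self.kind == "cortical":
            if self.name not in CORTICAL:
                raise ValueError(f"unknown cortical region {self.name!r}")
        elif self.kind == "subcortical":
            if self.name not in SUBCORTICAL:
                raise ValueError(f"unknown subcortical structure {self.name!r}")
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")


def parse_region(name: str, hemisphere: Hemisphere) -> RegionLabel:
    """Resolve a bare region name (``M1``, ``CAU``, ``CAU_M1``) to a :class:`RegionLabel`."""
    if name in CORTICAL:
        return RegionLabel(name, "cortical", hemisphere)
    if name in SUBCORTICAL:
        return RegionLabel(name, "subcortical", hemisphere)
    if "_" in name:
        parent, _, tag = name.partition("_")
        if parent in SUBCORTICAL and tag in CORTICAL:
            return RegionLabel(name, "subdivision", hemisphere, parent=parent, tag=tag)
    raise ManifestError(f"unresolvable region name {name!r}")


@dataclass(frozen=True)
class LoopEdge:
    """One intrahemispheric connection of a loop or of the atlas edge set."""

    loop: LoopName
    hemisphere: Hemisphere
    a: RegionLabel
    b: RegionLabel

    def __post_init__(self) -> None:
        if self.a.hemisphere != self.b.hemisphere or self.a.hemisphere != self.hemisphere:
            raise ValueError("loop edges are intrahemispheric")
        if self.a.name == self.b.name:
            raise ValueError(f"self-edge {self.a.name} in {self.loop}/{self.hemisphere}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.a.name, self.b.name))

    @property
    def key(self) -> str:
        """Stable column name ``loop:hemisphere:regionA-regionB`` (endpoints sorted)."""
        a, b = sorted((self.a.name, self.b.name))
        return f"{self.loop}:{self.hemisphere}:{a}-{b}"


@dataclass
class LoopManifest:
    """A validated collection of loop and atlas edges with provenance."""

    edges: list[LoopEdge]
    provenance: str = ""

    def validate(self) -> None:
        for hemi in HEMISPHERES:
            for loop, expected in EXPECTED_COUNTS.items():
                subset = self.edges_for(loop, hemi)
                seen: set[frozenset[str]] = set()
                for e in subset:
                    if e.pair in seen:
                        raise ManifestError(
                            f"duplicate pair {sorted(e.pair)} in loop {loop}, hemisphere {hemi}"
                        )
                    seen.add(e.pair)
                if len(subset) != expected:
                    raise ManifestError(
                        f"{loop}, {hemi}: {len(subset)} != {expected}"
                    )

    def edges_for(self, loop: str | None = None, hemisphere: str | None = None) -> list[LoopEdge]:
        out = self.edges
        if loop is not None:
            loops = {"loops": ("short", "long")}.get(loop, (loop,))
            out = [e for e in out if e.loop in loops]
        if hemisphere is not None:
            out = [e for e in out if e.hemisphere == hemisphere]
        return out

    def scheme_edges(self, scheme: str) -> list[LoopEdge]:
        """Edges of a feature scheme: ``loops`` (40/hemisphere) or ``atlas`` (26/hemisphere)."""
        if scheme == "loops":
            return self.edges_for("loops")
        if scheme == "atlas":
            return self.edges_for("atlas")
        raise ValueError(f"unknown scheme {scheme!r}; expected 'loops' or 'atlas'")

    def regions(self, kinds: Iterable[str] = ("cortical", "subdivision")) -> list[RegionLabel]:
        """Unique regions of the given kinds referenced by the manifest, in stable order."""
        kinds = set(kinds)
        seen: dict[tuple[str, str], RegionLabel] = {}
        for e in self.edges:
            for r in (e.a, e.b):
                if r.kind in kinds:
                    seen.setdefault((r.hemisphere, r.name), r)
        return [seen[k] for k in sorted(seen)]


def enumerate_atlas_edges(hemisphere: Hemisphere) -> list[LoopEdge]:
    """All 26 atlas edges of one hemisphere: 20 cortico-subcortical + 6 subcortical pairs."""
    edges = []
    for c in CORTICAL:
        for s in SUBCORTICAL:
            edges.append(
                LoopEdge("atlas", hemisphere, parse_region(c, hemisphere), parse_region(s, hemisphere))
            )
    for s1, s2 in combinations(SUBCORTICAL, 2):
        edges.append(
            LoopEdge("atlas", hemisphere, parse_region(s1, hemisphere), parse_region(s2, hemisphere))
        )
    return edges


# ---------------------------------------------------------------------------
# Default manifest (reconstruction).
#
# The per-target candidate chains below enumerate every edge a cortical target
# c contributes to each loop; the exclusion lists then trim prefrontal/limbic
# putamen and pallidal branches (MPFC, OFC) until the per-hemisphere counts
# are exactly 19 (short) and 21 (long).  This composition is a documented
# reconstruction by rule, not a published edge list; supply your own manifest
# TSV to override it.
# ---------------------------------------------------------------------------

_SHORT_CHAIN = ("{c}-CAU_{c}", "{c}-PUT_{c}", "CAU_{c}-THA_{c}", "PUT_{c}-THA_{c}", "{c}-THA_{c}")
_LONG_CHAIN = (
    "{c}-CAU_{c}", "{c}-PUT_{c}", "CAU_{c}-PAL_{c}", "PUT_{c}-PAL_{c}",
    "PAL_{c}-THA_{c}", "{c}-THA_{c}",
)
_SHORT_EXCLUDE = {
    frozenset(p) for p in [
        ("MPFC", "PUT_MPFC"), ("PUT_MPFC", "THA_MPFC"),
        ("OFC", "PUT_OFC"), ("PUT_OFC", "THA_OFC"),
        ("CAU_OFC", "THA_OFC"), ("OFC", "THA_OFC"),
    ]
}
_LONG_EXCLUDE = {
    frozenset(p) for p in [
        ("MPFC", "PUT_MPFC"), ("PUT_MPFC", "PAL_MPFC"),
        ("PAL_MPFC", "THA_MPFC"), ("MPFC", "THA_MPFC"),
        ("OFC", "PUT_OFC"), ("PUT_OFC", "PAL_OFC"),
        ("CAU_OFC", "PAL_OFC"), ("PAL_OFC", "THA_OFC"), ("OFC", "THA_OFC"),
    ]
}


def build_default_manifest() -> LoopManifest:
    """Construct the shipped default manifest programmatically (rule + exclusions)."""
    edges: list[LoopEdge] = []
    for hemi in HEMISPHERES:
        for loop, chain, exclude in (
            ("short", _SHORT_CHAIN, _SHORT_EXCLUDE),
            ("long", _LONG_CHAIN, _LONG_EXCLUDE),
        ):
            for c in CORTICAL:
                for tmpl in chain:
                    a_name, b_name = tmpl.format(c=c).split("-")
                    if frozenset((a_name, b_name)) in exclude:
                        continue
                    edges.append(
                        LoopEdge(loop, hemi, parse_region(a_name, hemi), parse_region(b_name, hemi))
                    )
        edges.extend(enumerate_atlas_edges(hemi))
    manifest = LoopManifest(edges, provenance="built-in default (reconstruction by rule)")
    manifest.validate()
    return manifest


def load_loop_manifest(path) -> LoopManifest:
    """Load and validate a manifest TSV with columns ``loop hemisphere region_a region_b``."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ManifestError(f"cannot parse manifest {path}: {exc}") from exc
    required = {"loop", "hemisphere", "region_a", "region_b"}
    if not required.issubset(df.columns):
        raise ManifestError(f"manifest {path} missing columns {sorted(required - set(df.columns))}")
    edges = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            hemi = str(row.hemisphere)
            if hemi not in HEMISPHERES:
                raise ManifestError(f"bad hemisphere {hemi!r}")
            if row.loop not in EXPECTED_COUNTS:
                raise ManifestError(f"bad loop {row.loop!r}")
            edges.append(
                LoopEdge(row.loop, hemi, parse_region(str(row.region_a), hemi),
                         parse_region(str(row.region_b), hemi))
            )
        except (ManifestError, ValueError) as exc:
            raise ManifestError(f"manifest {path}, line {i}: {exc}") from exc
    manifest = LoopManifest(edges, provenance=str(path))
    manifest.validate()
    return manifest


def save_loop_manifest(manifest: LoopManifest, path) -> None:
    rows = [
        {"loop": e.loop, "hemisphere": e.hemisphere, "region_a": e.a.name, "region_b": e.b.name}
        for e in manifest.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_manifest() -> LoopManifest:
    """The shipped default manifest (loaded from package data, validated)."""
    with resources.as_file(resources.files("cbtc.data").joinpath("loop_manifest.tsv")) as p:
        return load_loop_manifest(p)


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """Phenotype record for one participant.

    After left-right flipping, every patient's ipsilesional hemisphere is R;
    ``flipped`` records whether the subject's imaging was mirrored to enforce
    that convention.  ``ue_fma`` is the Upper Extremity Fugl-Meyer Assessment
    total (33 items, 0-66, higher = better motor function); controls have none.
    """

    id: str
    group: Literal["patient", "control"]
    age: float
    sex: Literal["male", "female"]
    lesion_side: Literal["L", "R", "none"] = "none"
    ue_fma: int | None = None
    flipped: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"bad group {self.group!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.group == "control":
            if self.lesion_side != "none" or self.ue_fma is not None:
                raise ValueError(f"control {self.id}: lesion_side must be none and ue_fma absent")
        else:
            if self.lesion_side not in ("L", "R"):
                raise ValueError(f"patient {self.id}: lesion_side must be L or R")
            if self.ue_fma is None or not (0 <= self.ue_fma <= 66):
                raise ValueError(f"patient {self.id}: ue_fma must be an integer in [0, 66]")


def subjects_to_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append({
            "id": s.id, "group": s.group, "age": s.age, "sex": s.sex,
            "lesion_side": s.lesion_side,
            "ue_fma": "" if s.ue_fma is None else s.ue_fma,
            "flipped": int(s.flipped),
        })
    return pd.DataFrame(rows)


def load_phenotype(path) -> list[SubjectRecord]:
    """Read a phenotype TSV (``id group age sex lesion_side ue_fma [flipped]``)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    subjects = []
    for row in df.itertuples(index=False):
        fma = getattr(row, "ue_fma", "")
        subjects.append(SubjectRecord(
            id=str(row.id), group=row.group, age=float(row.age), sex=row.sex,
            lesion_side=getattr(row, "lesion_side", "none") or "none",
            ue_fma=None if fma in ("", "NA") else int(float(fma)),
            flipped=bool(int(getattr(row, "flipped", 0) or 0)),
        ))
    return subjects


def save_phenotype(subjects: list[SubjectRecord], path) -> None:
    subjects_to_frame(subjects).to_csv(path, sep="\t", index=False)
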