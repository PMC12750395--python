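"""Phyllobilin candidate annotation.

Four evidence layers mark network nodes as chlorophyll-catabolite
candidates:

* **MS¹ database matching** — feature m/z against the [M+H]+ masses of a
  reference phyllobilin table within a ppm tolerance (5 ppm default).
* **Neutral-loss signatures** — presence of the class-characteristic losses
  (water, methanol, methanol+CO₂, ring A, ring C+D) in the MS² spectrum.
* **Analog propagation** — a matched anchor node extends to its network
  neighbours when the neutral-mass difference equals a known modification
  delta (malonylation +86.0004 Da, ±H₂ for the phylloleuco-/phylloroseobilin
  redox pair, +O for an extra carbonyl), optionally verified by checking
  that fragment peaks shift consistently with the delta while scaffold
  fragments stay put.
* **In-source-fragment flagging** — a feature whose precursor coincides
  (1 ppm) with a fragment of a co-eluting parent is marked as a likely
  electrospray in-source artifact. The flag is advisory only: an apparent
  artifact can also be a genuine metabolite eluting elsewhere, so nodes are
  never removed.

All species are assumed singly protonated ([M+H]+); other charge states are
rejected explicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ms_io import FeatureRecord, Spectrum
from .spectral_similarity import ProcessedSpectrum

__all__ = [
    "PROTON_MASS",
    "PBRecord",
    "ModificationDelta",
    "LossTable",
    "Annotation",
    "IsomerGroup",
    "default_pb_database",
    "default_deltas",
    "read_pb_database",
    "read_delta_table",
    "ppm_error",
    "neutral_mass_from_mh",
    "mh_from_neutral_mass",
    "ms1_match",
    "detect_signature",
    "propagate_analog",
    "verify_shift_consistency",
    "detect_insource",
    "count_isomer_nodes",
]

#: Monoisotopic mass of a proton (Da); [M+H]+ = M + PROTON_MASS.
PROTON_MASS = 1.007276

PB_CLASSES = frozenset({"PleB", "PxB", "PrB", "other"})


@dataclass(frozen=True)
class PBRecord:
    """One reference phyllobilin: name, class and neutral monoisotopic mass."""

    name: str
    pb_class: str
    neutral_mass: float
    formula: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be positive")
        if self.pb_class not in PB_CLASSES:
            raise ValueError(f"unknown phyllobilin class {self.pb_class!r}")

    @property
    def mh(self) -> float:
        return self.neutral_mass + PROTON_MASS


@dataclass(frozen=True)
class ModificationDelta:
    """A named neutral-mass shift used for analog propagation."""

    name: str
    formula: str
    exact_mass: float
    nominal_mass: int
    pb_class_hint: str = "other"

    def __post_init__(self) -> None:
        if round(self.exact_mass) != self.nominal_mass:
            raise ValueError(f"nominal mass {self.nominal_mass} != round({self.exact_mass})")

    def inverse(self) -> "ModificationDelta":
        name = {"hydrogenation": "dehydrogenation", "dehydrogenation": "hydrogenation"}.get(
            self.name, f"loss of {self.name.removesuffix('ation')}"
        )
        return ModificationDelta(
            name=name,
            formula=f"-{self.formula}" if not self.formula.startswith("-") else self.formula[1:],
            exact_mass=-self.exact_mass,
            nominal_mass=-self.nominal_mass,
            pb_class_hint=self.pb_class_hint,
        )


@dataclass(frozen=True)
class LossTable:
    """Named neutral losses checked against a spectrum (all optional).

    Water, methanol and methanol+CO₂ masses are fixed small molecules; the
    ring-A and ring-C+D losses depend on the scaffold's substitution and are
    supplied by the caller (or the synthetic generator) rather than being
    hard-coded.
    """

    losses: Mapping[str, float] = field(
        default_factory=lambda: {"water": 18.0106, "methanol": 32.0262, "methanol+CO2": 76.0160}
    )

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.losses.values()):
            raise ValueError("loss masses must be positive")


@dataclass(frozen=True)
class Annotation:
    """An evidence-bearing claim about one network node."""

    node_id: str
    kind: str  # library_match | ms1_match | analog | insource_artifact
    name: str
    ppm_error: float | None = None
    evidence: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class IsomerGroup:
    """Nodes sharing a compound annotation at distinct retention times."""

    compound: str
    node_ids: tuple[str, ...]
    rts: tuple[float, ...]
    flagged: bool


# ---------------------------------------------------------------------------
# Reference data
# ---------------------------------------------------------------------------


def _load_csv(path_or_text: Iterable[str]) -> list[dict[str, str]]:
    return [row for row in csv.DictReader(path_or_text)]


def read_pb_database(path: str | Path) -> list[PBRecord]:
    """Load a phyllobilin reference table (name, pb_class, neutral_mass, …)."""
    with open(path, newline="") as handle:
        rows = _load_csv(handle)
    return [
        PBRecord(
            name=r["name"].strip(),
            pb_class=r["pb_class"].strip(),
            neutral_mass=float(r["neutral_mass"]),
            formula=r.get("formula") or None,
            source=r.get("source") or None,
        )
        for r in rows
    ]


def read_delta_table(path: str | Path, include_disabled: bool = False) -> list[ModificationDelta]:
    """Load the modification-delta vocabulary from a delimited file."""
    with open(path, newline="") as handle:
        rows = _load_csv(handle)
    deltas = []
    for r in rows:
        if not include_disabled and r.get("enabled", "1").strip() == "0":
            continue
        deltas.append(
            ModificationDelta(
                name=r["name"].strip(),
                formula=r["formula"].strip(),
                exact_mass=float(r["exact_mass"]),
                nominal_mass=int(r["nominal_mass"]),
                pb_class_hint=r.get("pb_class_hint", "other").strip(),
            )
        )
    return deltas


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pbnet").joinpath("data", name)))


def default_pb_database() -> list[PBRecord]:
    """The built-in mini-database: only masses derivable from [M+H]+ 643.2754.

    Ep-PxB-1…5 require a user-supplied reference table.
    """
    return read_pb_database(_data_path("pb_database.csv"))


def default_deltas(include_disabled: bool = False) -> list[ModificationDelta]:
    """Shipped modification vocabulary (glycosylation disabled by default)."""
    return read_delta_table(_data_path("modification_deltas.csv"), include_disabled=include_disabled)


# ---------------------------------------------------------------------------
# Mass arithmetic
# ---------------------------------------------------------------------------


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed parts-per-million deviation of an observed from a theoretical mass."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("masses must be positive")
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


def neutral_mass_from_mh(precursor_mz: float) -> float:
    """Neutral monoisotopic mass of a singly protonated species."""
    return precursor_mz - PROTON_MASS


def mh_from_neutral_mass(neutral_mass: float, charge: int = 1) -> float:
    """[M+H]+ m/z from a neutral mass; only singly charged ions are supported."""
    if charge != 1:
        raise ValueError(f"only [M+H]+ (charge 1) species are supported, got charge {charge}")
    return neutral_mass + PROTON_MASS


# ---------------------------------------------------------------------------
# Annotation operations
# ---------------------------------------------------------------------------


def ms1_match(
    feature: FeatureRecord, db: Sequence[PBRecord], tol_ppm: float = 5.0
) -> list[Annotation]:
    """All database records whose [M+H]+ lies within tol_ppm of the feature m/z.

    Hits are sorted by absolute ppm error, best first; an empty list means
    no hit.
    """
    hits = []
    for record in db:
        err = ppm_error(feature.mz, record.mh)
        if abs(err) <= tol_ppm:
            hits.append(
                Annotation(
                    node_id=feature.feature_id,
                    kind="ms1_match",
                    name=record.name,
                    ppm_error=err,
                    evidence={"pb_class": record.pb_class, "neutral_mass": record.neutral_mass},
                )
            )
    hits.sort(key=lambda a: (abs(a.ppm_error), a.name))
    return hits


def detect_signature(
    spectrum: Spectrum | ProcessedSpectrum, loss_table: LossTable = LossTable(), tol: float = 0.02
) -> dict[str, bool]:
    """Which named neutral losses appear as fragment peaks of the spectrum.

    A loss L matches iff some peak lies within ``tol`` Th of precursor − L.
    """
    mz = spectrum.mz_array if isinstance(spectrum, Spectrum) else spectrum.mz
    prec = spectrum.precursor_mz
    return {
        name: bool(mz.size and np.any(np.abs(mz - (prec - loss)) <= tol))
        for name, loss in loss_table.losses.items()
    }


def propagate_analog(
    anchor: Annotation,
    anchor_mz: float,
    neighbor: FeatureRecord,
    delta_table: Sequence[ModificationDelta],
    tol_ppm: float = 5.0,
) -> Annotation | None:
    """Extend an anchor's annotation to a connected neighbour via a mass delta.

    The neutral-mass difference neighbour − anchor is compared with each
    modification's exact mass; the ppm tolerance is applied on the
    neighbour's absolute neutral mass. Returns the analog annotation naming
    the modification, or None if no delta matches.
    """
    if anchor.kind not in ("ms1_match", "library_match"):
        raise ValueError("analog propagation requires a library or MS1 anchor")
    anchor_neutral = neutral_mass_from_mh(anchor_mz)
    neigh_neutral = neutral_mass_from_mh(neighbor.mz)
    observed = neigh_neutral - anchor_neutral
    tol_da = tol_ppm * 1e-6 * neigh_neutral
    best: tuple[float, ModificationDelta] | None = None
    for delta in delta_table:
        dev = abs(observed - delta.exact_mass)
        if dev <= tol_da and (best is None or dev < best[0]):
            best = (dev, delta)
    if best is None:
        return None
    delta = best[1]
    return Annotation(
        node_id=neighbor.feature_id,
        kind="analog",
        name=f"{anchor.name} + {delta.name}",
        ppm_error=1e6 * (observed - delta.exact_mass) / neigh_neutral,
        evidence={
            "anchor": anchor.name,
            "anchor_node": anchor.node_id,
            "modification": delta.name,
            "formula": delta.formula,
            "delta_mass": delta.exact_mass,
            "pb_class_hint": delta.pb_class_hint,
            "neutral_mass": neigh_neutral,
        },
    )


def verify_shift_consistency(
    spec_parent: Spectrum | ProcessedSpectrum,
    spec_analog: Spectrum | ProcessedSpectrum,
    delta: float,
    tol: float = 0.02,
) -> tuple[int, int, int]:
    """Classify analog fragments as shifted, conserved or unexplained.

    Each analog peak is *conserved* if it matches a parent peak within
    ``tol``, otherwise *shifted* if it matches a parent peak + delta, and
    *unexplained* otherwise. Conserved takes precedence so a zero delta
    counts every identical peak once.
    """
    pmz = spec_parent.mz_array if isinstance(spec_parent, Spectrum) else spec_parent.mz
    amz = spec_analog.mz_array if isinstance(spec_analog, Spectrum) else spec_analog.mz
    n_shifted = n_conserved = n_unexplained = 0
    for mz in amz:
        if pmz.size and np.any(np.abs(pmz - mz) <= tol):
            n_conserved += 1
        elif pmz.size and np.any(np.abs(pmz + delta - mz) <= tol):
            n_shifted += 1
        else:
            n_unexplained += 1
    return n_shifted, n_conserved, n_unexplained


def detect_insource(
    parent_feature: FeatureRecord,
    parent_spectrum: Spectrum | ProcessedSpectrum,
    candidate: FeatureRecord,
    mz_tol_ppm: float = 1.0,
    rt_tol: float = 0.1,
) -> Annotation | None:
    """Flag a feature as a likely in-source fragment of a co-eluting parent.

    Requires (a) the candidate precursor m/z to coincide with a fragment
    peak of the parent's MS² within ``mz_tol_ppm`` and (b) co-elution within
    ``rt_tol`` minutes. The flag is advisory metadata; the caller must never
    delete flagged nodes automatically (the same species may also occur
    genuinely at another retention time).
    """
    if abs(candidate.rt - parent_feature.rt) > rt_tol:
        return None
    pmz = parent_spectrum.mz_array if isinstance(parent_spectrum, Spectrum) else parent_spectrum.mz
    if pmz.size == 0:
        return None
    errs = 1e6 * np.abs(pmz - candidate.mz) / candidate.mz
    idx = int(np.argmin(errs))
    if errs[idx] > mz_tol_ppm:
        return None
    return Annotation(
        node_id=candidate.feature_id,
        kind="insource_artifact",
        name=f"in-source fragment of {parent_feature.feature_id}",
        ppm_error=float(1e6 * (candidate.mz - pmz[idx]) / pmz[idx]),
        evidence={
            "parent": parent_feature.feature_id,
            "fragment_mz": float(pmz[idx]),
            "delta_rt": abs(candidate.rt - parent_feature.rt),
        },
    )


def count_isomer_nodes(
    annotations: Iterable[Annotation],
    features: Mapping[str, FeatureRecord],
    max_expected: int = 4,
) -> dict[str, IsomerGroup]:
    """Group compound annotations into isomer sets and flag oversized ones.

    Stereoisomers (cis/trans at C15, epimers at C8²) give at most four nodes
    per compound; groups beyond ``max_expected`` are flagged as possible
    artifacts of broad chromatographic peaks or ester hydrolysis.
    """
    by_compound: dict[str, list[str]] = {}
    for ann in annotations:
        if ann.kind in ("ms1_match", "library_match"):
            by_compound.setdefault(ann.name, []).append(ann.node_id)
    report: dict[str, IsomerGroup] = {}
    for compound, node_ids in sorted(by_compound.items()):
        ids = tuple(sorted(set(node_ids)))
        rts = tuple(features[nid].rt for nid in ids if nid in features)
        report[compound] = IsomerGroup(
            compound=compound, node_ids=ids, rts=rts, flagged=len(ids) > max_expected
        )
    return report
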