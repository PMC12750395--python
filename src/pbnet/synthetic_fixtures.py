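"""Synthetic LC-MS/MS datasets with a ground-truth manifest.

Emulates the structures the annotation workflow exploits, without any
instrument data: families of phyllobilin-like spectra share a conserved
fragment scaffold (the ring-A-loss fragment keeps its absolute m/z across
ring-A-modified analogs) while modification analogs shift their precursor
and the scaffold-retaining fragments by the modification's exact mass;
stereoisomer copies recur at distinct retention times with identical mass;
one co-eluting in-source fragment feature per family mimics electrospray
ester-bond cleavage; a 420 nm trace peaks at the elution times of the
yellow (PxB-class) features only; and intensity is concentrated in one to
three adjacent polarity fractions whose antioxidant-activity classes follow
the published four-class FRAP pattern of a 13-fraction separation.

Everything is driven by a single integer seed; identical seeds give
byte-identical files. Truth (family membership, planted modification,
in-source and PxB flags, fraction classes) is defined by the manifest, not
by chemistry: the scaffold masses are fixed arbitrary constants.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .informed_overlay import BioactivityTable
from .ms_io import DADTrace, FeatureRecord, Peak, SampleManifest, Spectrum, write_mgf
from .pb_annotation import PROTON_MASS, ModificationDelta, PBRecord, default_deltas

__all__ = [
    "GeneratorConfig",
    "FeatureTruth",
    "TruthManifest",
    "SyntheticDataset",
    "make_pb_family",
    "make_decoys",
    "make_dad_trace",
    "make_fraction_matrix",
    "generate_dataset",
    "write_dataset",
]

#: published four-class FRAP pattern for the 13-fraction separation
FRAP_CLASSES_13 = {
    "F1": 0, "F2": 0, "F3": 1, "F4": 3, "F5": 3, "F6": 2, "F7": 2,
    "F8": 1, "F9": 0, "F10": 0, "F11": 1, "F12": 2, "F13": 0,
}

#: fixed fragment scaffold: neutral losses whose fragments shift with the
#: precursor when the modification sits on the lost-ring side
SHIFTABLE_LOSSES = (18.0106, 32.0262, 76.0160, 104.0473, 146.0579, 188.0685)
#: ring-A-side losses: their fragments keep an absolute m/z across analogs
CONSERVED_LOSSES = (108.0211, 126.0317)

_SHIFTABLE_PATTERN = (100.0, 85.0, 70.0, 55.0, 45.0, 35.0)
_CONSERVED_PATTERN = (90.0, 50.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic benchmark.

    Defaults mirror the 13-fraction study design: [M+H]+ 643.2754 for the
    first family core (the Ep-PxB-6 ion), up to four modification analogs
    per family (malonylation, ±H₂, +O), three stereoisomer nodes per anchor
    spaced 0.3 min apart, one in-source artifact per family, 2 ppm m/z
    jitter (inside the 5 ppm MS¹ tolerance, outside the 1 ppm co-elution
    window for uncorrelated ions) and a 20 min run sampled at 1 Hz by the
    detector.
    """

    seed: int = 0
    n_pb_families: int = 2
    modifications: tuple[str, ...] = ("malonylation", "hydrogenation", "dehydrogenation", "oxygenation")
    n_decoys: int = 48
    decoy_family_size: int = 4
    n_fractions: int = 13
    ppm_jitter_sd: float = 2.0
    intensity_cv: float = 0.1
    n_noise_peaks: int = 3
    insource_rate: float = 1.0
    isomers_per_compound: int = 3
    isomer_rt_spacing: float = 0.3
    run_length_min: float = 20.0
    dad_baseline_mau: float = 1.0
    dad_peak_sigma_min: float = 0.05

    def __post_init__(self) -> None:
        if self.isomers_per_compound < 1 or self.isomers_per_compound > 4:
            raise ValueError("isomers_per_compound must be in 1..4")
        if not (0 <= self.insource_rate <= 1):
            raise ValueError("insource_rate must be in [0, 1]")

    def fraction_classes(self) -> dict[str, int]:
        if self.n_fractions == 13:
            return dict(FRAP_CLASSES_13)
        # non-default layouts: highest activity in the fractions the PB
        # features elute into, inactive elsewhere
        classes = {f"F{i}": 0 for i in range(1, self.n_fractions + 1)}
        for frac in self._pb_fractions():
            classes[frac] = 3
        return classes

    def _pb_fractions(self) -> list[str]:
        width = self.run_length_min / self.n_fractions
        idx = {int(rt // width) for rt in (5.0, 7.0)}
        return [f"F{i + 1}" for i in sorted(idx)]


@dataclass(frozen=True)
class FeatureTruth:
    """Ground truth for one generated feature."""

    feature_id: str
    compound: str
    family: int  # -1 for decoys
    pb_class: str  # PxB | PleB | PrB | other | decoy
    modification: str | None
    is_pb: bool
    is_insource: bool
    is_pxb_chromophore: bool  # elutes under a 420 nm band
    isomer_index: int
    rt: float
    mh_theoretical: float


@dataclass
class TruthManifest:
    """Everything the generator planted, for recovery checks."""

    features: dict[str, FeatureTruth] = field(default_factory=dict)
    fraction_classes: dict[str, int] = field(default_factory=dict)
    families: dict[int, tuple[str, ...]] = field(default_factory=dict)
    pb_database: list[PBRecord] = field(default_factory=list)

    def pb_feature_ids(self) -> set[str]:
        return {fid for fid, t in self.features.items() if t.is_pb}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "features": {fid: dataclasses.asdict(t) for fid, t in sorted(self.features.items())},
            "fraction_classes": self.fraction_classes,
            "families": {str(k): list(v) for k, v in sorted(self.families.items())},
            "pb_database": [dataclasses.asdict(r) for r in self.pb_database],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            features={fid: FeatureTruth(**t) for fid, t in payload["features"].items()},
            fraction_classes=dict(payload["fraction_classes"]),
            families={int(k): tuple(v) for k, v in payload["families"].items()},
            pb_database=[PBRecord(**r) for r in payload["pb_database"]],
        )


@dataclass
class SyntheticDataset:
    """In-memory view of one generated benchmark."""

    spectra: list[Spectrum]
    features: list[FeatureRecord]
    manifest: SampleManifest
    truth: TruthManifest
    trace: DADTrace
    bioactivity: BioactivityTable


def _jitter(rng: np.random.Generator, mz: float, ppm_sd: float) -> float:
    return mz * (1.0 + rng.normal(0.0, ppm_sd * 1e-6))


def _family_core_mh(family: int) -> float:
    # first family is the Ep-PxB-6-like ion; others at fixed arbitrary offsets
    return 643.2754 if family == 0 else 643.2754 - 26.0157 * family - 11.0184


def _delta_lookup() -> dict[str, ModificationDelta]:
    return {d.name: d for d in default_deltas(include_disabled=True)}


def _make_spectrum(
    rng: np.random.Generator,
    feature_id: str,
    mh_theoretical: float,
    rt: float,
    shiftable_mz: Sequence[float],
    conserved_mz: Sequence[float],
    config: GeneratorConfig,
) -> Spectrum:
    peaks = []
    for mz, base in zip(shiftable_mz, _SHIFTABLE_PATTERN):
        peaks.append(Peak(_jitter(rng, mz, config.ppm_jitter_sd), base * rng.lognormal(0.0, config.intensity_cv)))
    for mz, base in zip(conserved_mz, _CONSERVED_PATTERN):
        peaks.append(Peak(_jitter(rng, mz, config.ppm_jitter_sd), base * rng.lognormal(0.0, config.intensity_cv)))
    for _ in range(config.n_noise_peaks):
        peaks.append(Peak(rng.uniform(120.0, mh_theoretical - 25.0), rng.uniform(0.5, 2.0)))
    return Spectrum(
        feature_id=feature_id,
        precursor_mz=_jitter(rng, mh_theoretical, config.ppm_jitter_sd),
        charge=1,
        rt=rt,
        peaks=tuple(peaks),
    )


def make_pb_family(
    core_mh: float,
    core_fragments: Mapping[str, Sequence[float]],
    modifications: Sequence[ModificationDelta],
    config: GeneratorConfig,
    rng: np.random.Generator,
    family: int = 0,
) -> tuple[list[Spectrum], list[FeatureTruth]]:
    """One phyllobilin family: isomeric anchors, analogs, in-source artifact.

    ``core_fragments`` maps ``"shiftable_losses"`` (≥2 entries; fragments
    that move with the precursor) and ``"conserved_losses"`` (≥1 entry;
    ring-A-side fragments with invariant absolute m/z). RT slots advance in
    ``isomer_rt_spacing`` steps from 5.0 min: isomers first, then one analog
    per modification; the in-source artifact co-elutes with the first
    anchor.
    """
    shift_losses = list(core_fragments.get("shiftable_losses", ()))
    cons_losses = list(core_fragments.get("conserved_losses", ()))
    if not shift_losses and not cons_losses:
        raise ValueError("core fragment list is empty")
    if len(shift_losses) < 2 or len(cons_losses) < 1:
        raise ValueError("need >=2 shiftable and >=1 conserved fragment")

    conserved_mz = [core_mh - l for l in cons_losses]
    anchor_name = f"PB{family}-core"
    spectra: list[Spectrum] = []
    truths: list[FeatureTruth] = []
    slot = 0

    def slot_rt(k: int) -> float:
        return 5.0 + k * config.isomer_rt_spacing

    for iso in range(config.isomers_per_compound):
        fid = f"PB{family}_iso{iso}"
        rt = slot_rt(slot)
        slot += 1
        spectra.append(
            _make_spectrum(rng, fid, core_mh, rt, [core_mh - l for l in shift_losses], conserved_mz, config)
        )
        truths.append(
            FeatureTruth(
                feature_id=fid, compound=anchor_name, family=family, pb_class="PxB",
                modification=None, is_pb=True, is_insource=False, is_pxb_chromophore=True,
                isomer_index=iso, rt=rt, mh_theoretical=core_mh,
            )
        )

    for delta in modifications:
        fid = f"PB{family}_{delta.name}"
        rt = slot_rt(slot)
        slot += 1
        mh = core_mh + delta.exact_mass
        # a ring-A-side modification shifts the precursor and the fragments
        # retaining the modified ring; ring-A-loss fragments stay put
        spectra.append(
            _make_spectrum(rng, fid, mh, rt, [mh - l for l in shift_losses], conserved_mz, config)
        )
        pb_class = delta.pb_class_hint if delta.pb_class_hint in ("PxB", "PleB", "PrB") else "other"
        truths.append(
            FeatureTruth(
                feature_id=fid, compound=f"{anchor_name}+{delta.name}", family=family, pb_class=pb_class,
                modification=delta.name, is_pb=True, is_insource=False,
                is_pxb_chromophore=pb_class == "PxB", isomer_index=0, rt=rt, mh_theoretical=mh,
            )
        )

    if rng.random() < config.insource_rate:
        # the artifact ion is the ring-A-loss fragment itself; measured in the
        # same acquisition as its parent, so its m/z tracks the parent's
        # fragment with only a small residual error (well inside 1 ppm)
        parent = spectra[0]
        frag_mz = min(parent.peaks, key=lambda p: abs(p.mz - conserved_mz[0])).mz
        fid = f"PB{family}_insource"
        rt = parent.rt + rng.uniform(-0.02, 0.02)
        sub_shift = [conserved_mz[0] - l for l in shift_losses]
        sub_spec = _make_spectrum(rng, fid, conserved_mz[0], rt, sub_shift, [], config)
        sub_spec = Spectrum(
            feature_id=fid, precursor_mz=_jitter(rng, frag_mz, 0.2), charge=1, rt=rt, peaks=sub_spec.peaks
        )
        spectra.append(sub_spec)
        truths.append(
            FeatureTruth(
                feature_id=fid, compound=f"{anchor_name} fragment", family=family, pb_class="PxB",
                modification=None, is_pb=True, is_insource=True, is_pxb_chromophore=True,
                isomer_index=0, rt=rt, mh_theoretical=conserved_mz[0],
            )
        )
    return spectra, truths


def make_decoys(config: GeneratorConfig, rng: np.random.Generator) -> tuple[list[Spectrum], list[FeatureTruth]]:
    """Background metabolome stand-in: decoy families with shared scaffolds.

    Random-walk peak lists; members of a decoy family share scaffold and
    precursor (so decoy clusters form) but carry no phyllobilin deltas or
    loss signatures. Decoy RTs avoid the 420 nm chromophore bands so the
    absorbance truth stays crisp.
    """
    spectra: list[Spectrum] = []
    truths: list[FeatureTruth] = []
    if config.n_decoys <= 0:
        return spectra, truths
    pxb_rts = _pxb_band_rts(config)
    n_families = max(1, config.n_decoys // config.decoy_family_size)
    made = 0
    for fam in range(n_families):
        start = rng.uniform(150.0, 250.0)
        steps = rng.uniform(30.0, 60.0, size=7)
        scaffold = start + np.concatenate(([0.0], np.cumsum(steps)))
        precursor = float(scaffold[-1] + rng.uniform(50.0, 100.0))
        base_pattern = rng.uniform(20.0, 100.0, size=scaffold.size)
        while True:
            fam_rt = rng.uniform(0.5, config.run_length_min - 0.5)
            if all(abs(fam_rt - r) > 0.3 for r in pxb_rts):
                break
        size = min(config.decoy_family_size, config.n_decoys - made)
        for member in range(size):
            fid = f"D{fam}_{member}"
            rt = fam_rt + member * 0.2
            peaks = [
                Peak(_jitter(rng, mz, config.ppm_jitter_sd), b * rng.lognormal(0.0, 0.3))
                for mz, b in zip(scaffold, base_pattern)
            ]
            peaks += [
                Peak(rng.uniform(120.0, precursor - 25.0), rng.uniform(1.0, 10.0))
                for _ in range(2)
            ]
            spectra.append(
                Spectrum(
                    feature_id=fid,
                    precursor_mz=_jitter(rng, precursor, config.ppm_jitter_sd),
                    charge=1,
                    rt=rt,
                    peaks=tuple(peaks),
                )
            )
            truths.append(
                FeatureTruth(
                    feature_id=fid, compound=f"decoy-{fam}", family=-1, pb_class="decoy",
                    modification=None, is_pb=False, is_insource=False, is_pxb_chromophore=False,
                    isomer_index=member, rt=rt, mh_theoretical=precursor,
                )
            )
            made += 1
        if made >= config.n_decoys:
            break
    return spectra, truths


def _pxb_band_rts(config: GeneratorConfig) -> list[float]:
    n_slots = config.isomers_per_compound + len(config.modifications)
    return [5.0 + k * config.isomer_rt_spacing for k in range(n_slots)]


def make_dad_trace(
    truths: Sequence[FeatureTruth],
    feature_intensity: Mapping[str, float],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> DADTrace:
    """420 nm trace: Gaussian bands at PxB elution times over a low baseline.

    Sampled at 1 Hz over the full run; band amplitude scales with the
    feature's total ion intensity.
    """
    times = np.arange(0.0, config.run_length_min, 1.0 / 60.0)
    absorbance = np.full_like(times, config.dad_baseline_mau)
    absorbance += rng.normal(0.0, 0.02 * config.dad_baseline_mau, size=times.size)
    max_intensity = max(feature_intensity.values(), default=1.0)
    for t in truths:
        if not t.is_pxb_chromophore:
            continue
        amp = 30.0 + 170.0 * feature_intensity.get(t.feature_id, 0.0) / max_intensity
        absorbance += amp * np.exp(-0.5 * ((times - t.rt) / config.dad_peak_sigma_min) ** 2)
    return DADTrace(times=times, absorbance=np.abs(absorbance), wavelength=420.0)


def make_fraction_matrix(
    truths: Sequence[FeatureTruth],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[list[FeatureRecord], BioactivityTable]:
    """Per-fraction intensities (polarity-gradient mimicry) and FRAP classes.

    Each compound's intensity concentrates in the fraction its RT maps to,
    with 20% spilling into each existing neighbour; total intensities are
    log-normal. PB features draw higher totals than decoys.
    """
    fractions = [f"F{i}" for i in range(1, config.n_fractions + 1)]
    width = config.run_length_min / config.n_fractions
    records: list[FeatureRecord] = []
    for t in truths:
        total = rng.lognormal(np.log(1e6) if t.is_pb else np.log(3e5), 0.3 if t.is_pb else 0.8)
        center = min(int(t.rt // width), config.n_fractions - 1)
        weights = np.zeros(config.n_fractions)
        weights[center] = 0.6
        for nb in (center - 1, center + 1):
            if 0 <= nb < config.n_fractions:
                weights[nb] = 0.2
        weights /= weights.sum()
        intensities = {frac: float(total * w) for frac, w in zip(fractions, weights)}
        records.append(
            FeatureRecord(
                feature_id=t.feature_id,
                mz=t.mh_theoretical,  # refined to the measured precursor later
                rt=t.rt,
                intensities=intensities,
            )
        )
    bio = BioactivityTable(classes=config.fraction_classes(), assay="FRAP")
    return records, bio


def generate_dataset(config: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Build the complete benchmark in memory (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    deltas = _delta_lookup()
    mods = [deltas[name] for name in config.modifications]
    core_fragments = {"shiftable_losses": SHIFTABLE_LOSSES, "conserved_losses": CONSERVED_LOSSES}

    spectra: list[Spectrum] = []
    truths: list[FeatureTruth] = []
    families: dict[int, tuple[str, ...]] = {}
    db: list[PBRecord] = []
    for fam in range(config.n_pb_families):
        core_mh = _family_core_mh(fam)
        fam_spectra, fam_truths = make_pb_family(core_mh, core_fragments, mods, config, rng, family=fam)
        spectra += fam_spectra
        truths += fam_truths
        families[fam] = tuple(t.feature_id for t in fam_truths)
        db.append(
            PBRecord(
                name=f"PB{fam}-core", pb_class="PxB",
                neutral_mass=round(core_mh - PROTON_MASS, 4), source="synthetic anchor",
            )
        )

    decoy_spectra, decoy_truths = make_decoys(config, rng)
    spectra += decoy_spectra
    truths += decoy_truths

    records, bio = make_fraction_matrix(truths, config, rng)
    # quant-table m/z is the measured precursor of the corresponding scan
    by_id = {s.feature_id: s for s in spectra}
    records = [
        FeatureRecord(r.feature_id, by_id[r.feature_id].precursor_mz, r.rt, r.intensities) for r in records
    ]
    trace = make_dad_trace(truths, {r.feature_id: r.total_intensity for r in records}, config, rng)

    truth = TruthManifest(
        features={t.feature_id: t for t in truths},
        fraction_classes=config.fraction_classes(),
        families=families,
        pb_database=db,
    )
    return SyntheticDataset(
        spectra=spectra,
        features=records,
        manifest=SampleManifest.default(config.n_fractions),
        truth=truth,
        trace=trace,
        bioactivity=bio,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as the same text files the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mgf": outdir / "spectra.mgf",
        "quant": outdir / "quant_table.csv",
        "dad": outdir / "dad_420nm.csv",
        "bioactivity": outdir / "bioactivity.csv",
        "pb_db": outdir / "pb_database.csv",
        "manifest": outdir / "truth_manifest.json",
    }
    write_mgf(dataset.spectra, paths["mgf"])
    frame = pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "mz": round(r.mz, 4),
                "rt": round(r.rt, 4),
                **{f: round(v, 2) for f, v in r.intensities.items()},
            }
            for r in dataset.features
        ]
    )
    frame.to_csv(paths["quant"], index=False)
    pd.DataFrame(
        {"time_min": np.round(dataset.trace.times, 6), "absorbance_mau": np.round(dataset.trace.absorbance, 4)}
    ).to_csv(paths["dad"], index=False)
    pd.DataFrame(
        {"fraction": list(dataset.bioactivity.classes), "activity_class": list(dataset.bioactivity.classes.values())}
    ).to_csv(paths["bioactivity"], index=False)
    pd.DataFrame(
        [
            {"name": r.name, "pb_class": r.pb_class, "neutral_mass": r.neutral_mass,
             "formula": r.formula or "", "source": r.source or ""}
            for r in dataset.truth.pb_database
        ]
    ).to_csv(paths["pb_db"], index=False)
    dataset.truth.to_json(paths["manifest"])
    return paths
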