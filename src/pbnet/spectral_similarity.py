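"""Modified-cosine MS² similarity, the edge weight of the molecular network.

The modified cosine extends the plain spectral cosine by also allowing
fragment pairs whose m/z difference equals the precursor mass difference
("shifted" matches), which is what links structural analogs such as a
phylloxanthobilin and its malonylated derivative: fragments retaining the
modified ring shift with the precursor while fragments that lost it align
directly.

Peak assignment is greedy by descending intensity product under a one-to-one
constraint (the GNPS-compatible behaviour); the exhaustive optimum over all
assignments exists in the test-suite as an oracle only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ms_io import Spectrum

__all__ = [
    "SimilarityParams",
    "ProcessedSpectrum",
    "SimilarityResult",
    "preprocess",
    "modified_cosine",
]


@dataclass(frozen=True)
class SimilarityParams:
    """Knobs of spectrum preprocessing and modified-cosine matching.

    fragment_tol
        Absolute fragment matching tolerance in Th (default 0.02, the
        community FBMN default).
    allow_precursor_shift
        Whether precursor-difference-shifted fragment matches count.
    intensity_power
        Exponent applied to intensities before unit-norm scaling; 0.5
        (square root) tempers dominance of base peaks.
    min_peaks_per_spectrum
        Spectra with fewer surviving peaks after preprocessing are flagged
        unusable: excluded from pair scoring but kept as network nodes.
    precursor_exclusion
        Half-window (Th) around the precursor removed before scoring.
    rel_intensity_floor
        Peaks below this fraction of the base peak are dropped.
    """

    fragment_tol: float = 0.02
    allow_precursor_shift: bool = True
    intensity_power: float = 0.5
    min_peaks_per_spectrum: int = 2
    precursor_exclusion: float = 17.0
    rel_intensity_floor: float = 0.001

    def __post_init__(self) -> None:
        if self.fragment_tol <= 0:
            raise ValueError("fragment_tol must be positive")
        if not (0 < self.intensity_power <= 1):
            raise ValueError("intensity_power must be in (0, 1]")


@dataclass(frozen=True)
class ProcessedSpectrum:
    """A spectrum after filtering, intensity weighting and unit-norm scaling."""

    feature_id: str
    precursor_mz: float
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    usable: bool

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class SimilarityResult:
    """Score in [0, 1] plus the selected one-to-one peak assignment.

    ``matched_pairs`` holds ``(index_in_a, index_in_b, shifted)`` triples.
    """

    score: float
    matched_pairs: tuple[tuple[int, int, bool], ...] = field(default_factory=tuple)

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)


def preprocess(spectrum: Spectrum, params: SimilarityParams = SimilarityParams()) -> ProcessedSpectrum:
    """Filter and normalize one spectrum for cosine scoring.

    Removes peaks within ``precursor_exclusion`` Th of the precursor and
    below the relative-intensity floor, raises intensities to
    ``intensity_power`` and scales the vector to unit Euclidean norm.
    """
    mz = spectrum.mz_array
    inten = spectrum.intensity_array
    keep = np.abs(mz - spectrum.precursor_mz) > params.precursor_exclusion
    if inten.size:
        base = inten.max()
        if base > 0:
            keep &= inten >= params.rel_intensity_floor * base
    keep &= inten > 0
    mz, inten = mz[keep], inten[keep]
    usable = mz.size >= params.min_peaks_per_spectrum
    if mz.size:
        weighted = np.power(inten, params.intensity_power)
        norm = np.linalg.norm(weighted)
        weighted = weighted / norm if norm > 0 else weighted
    else:
        weighted = inten
    return ProcessedSpectrum(
        feature_id=spectrum.feature_id,
        precursor_mz=spectrum.precursor_mz,
        rt=spectrum.rt,
        mz=mz,
        intensity=weighted,
        usable=usable,
    )


def _candidate_pairs(a: ProcessedSpectrum, b: ProcessedSpectrum, params: SimilarityParams):
    """All (i, j, product, |Δ|, shifted) fragment pairs within tolerance.

    A pair within tolerance both directly and after the precursor shift is
    counted once, as direct.
    """
    tol = params.fragment_tol
    prec_delta = a.precursor_mz - b.precursor_mz
    diff = a.mz[:, None] - b.mz[None, :]
    direct = np.abs(diff) <= tol
    pairs = []
    for i, j in zip(*np.nonzero(direct)):
        pairs.append((int(i), int(j), float(a.intensity[i] * b.intensity[j]), abs(float(diff[i, j])), False))
    if params.allow_precursor_shift and abs(prec_delta) > tol:
        shifted = np.abs(diff - prec_delta) <= tol
        for i, j in zip(*np.nonzero(shifted & ~direct)):
            pairs.append(
                (int(i), int(j), float(a.intensity[i] * b.intensity[j]), abs(float(diff[i, j] - prec_delta)), True)
            )
    return pairs


def modified_cosine(
    a: ProcessedSpectrum, b: ProcessedSpectrum, params: SimilarityParams = SimilarityParams()
) -> SimilarityResult:
    """Greedy one-to-one modified-cosine similarity of two processed spectra.

    Candidate pairs are sorted by descending intensity product, ties broken
    by smaller |Δm/z| then lower peak indices (a determinism requirement),
    and accepted greedily subject to each peak matching at most once. With
    unit-norm inputs the accepted product sum is the score. Unusable spectra
    score 0 by definition.
    """
    if not (a.usable and b.usable):
        return SimilarityResult(score=0.0)
    pairs = _candidate_pairs(a, b, params)
    pairs.sort(key=lambda p: (-p[2], p[3], p[0], p[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    selected: list[tuple[int, int, bool]] = []
    score = 0.0
    for i, j, prod, _, shifted in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        selected.append((i, j, shifted))
        score += prod
    return SimilarityResult(score=float(min(score, 1.0)), matched_pairs=tuple(selected))
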