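"""Readers, writers and core record types shared across the toolkit.

External formats handled here: MGF (GNPS feature-based-molecular-networking
dialect, via :mod:`pyteomics.mgf`), delimited feature quantification tables,
DAD/VWD chromatogram traces, bioactivity tables and GraphML network export
(via :mod:`networkx`). Retention times are held in **minutes** throughout;
``RTINSECONDS`` is converted on read.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _pymgf

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Spectrum",
    "FeatureRecord",
    "SampleManifest",
    "DADTrace",
    "MGFParseError",
    "QuantTableError",
    "read_mgf",
    "write_mgf",
    "read_quant_table",
    "read_dad_trace",
    "read_bioactivity_table",
    "write_graphml",
    "read_graphml",
]


class MGFParseError(ValueError):
    """Raised when an MGF block cannot be interpreted."""


class QuantTableError(ValueError):
    """Raised for malformed feature quantification tables."""


class Peak(NamedTuple):
    """One fragment ion: m/z in Th, intensity in arbitrary counts."""

    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """One MS² scan attached to an LC-MS feature.

    Peaks are kept sorted ascending by m/z; ``rt`` is in minutes and the
    precursor is assumed to be the [M+H]+ species (singly protonated).
    """

    feature_id: str
    precursor_mz: float
    charge: int
    rt: float
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if self.rt < 0:
            raise ValueError(f"rt must be non-negative, got {self.rt}")
        pk = tuple(sorted((Peak(float(m), float(i)) for m, i in self.peaks), key=lambda p: p.mz))
        for p in pk:
            if p.mz <= 0 or p.intensity < 0:
                raise ValueError(f"invalid peak {p}")
        object.__setattr__(self, "peaks", pk)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


@dataclass(frozen=True)
class FeatureRecord:
    """One LC-MS feature with its per-fraction intensity vector."""

    feature_id: str
    mz: float
    rt: float
    intensities: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError(f"negative intensity in feature {self.feature_id}")

    @property
    def total_intensity(self) -> float:
        return float(sum(self.intensities.values()))


@dataclass(frozen=True)
class SampleManifest:
    """Ordered list of fraction identifiers (F1…F13 for a 13-fraction run)."""

    fraction_ids: tuple[str, ...]
    metadata: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = tuple(self.fraction_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("fraction ids must be unique")
        object.__setattr__(self, "fraction_ids", ids)

    @classmethod
    def default(cls, n_fractions: int = 13) -> "SampleManifest":
        return cls(tuple(f"F{i}" for i in range(1, n_fractions + 1)))


@dataclass(frozen=True)
class DADTrace:
    """UV/vis absorbance trace at a single detection wavelength.

    ``times`` (minutes) are strictly increasing; absorbance is in mAU.
    """

    times: np.ndarray
    absorbance: np.ndarray
    wavelength: float = 420.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.shape != a.shape:
            raise ValueError("times and absorbance must have equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return int(self.times.size)

    def window_max(self, t_lo: float, t_hi: float) -> float:
        """Maximum absorbance on [t_lo, t_hi]; 0 if the window is off-trace."""
        sel = (self.times >= t_lo) & (self.times <= t_hi)
        if not np.any(sel):
            return 0.0
        return float(self.absorbance[sel].max())


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read a GNPS-dialect MGF file into :class:`Spectrum` records.

    Feature ids are taken from ``SCANS`` or ``FEATURE_ID``; retention time from
    ``RTINSECONDS`` (divided by 60) or ``RTINMINUTES``. Blocks without a
    precursor mass are skipped with a log entry; structurally malformed blocks
    raise :class:`MGFParseError` naming the block index.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    with _pymgf.MGF(str(path), convert_arrays=1, read_charges=True) as reader:
        index = 0
        while True:
            try:
                entry = next(reader)
            except StopIteration:
                break
            except Exception as exc:  # noqa: BLE001 - reported with block index
                raise MGFParseError(f"malformed MGF block {index} in {path.name}: {exc}") from exc
            index += 1
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                logger.warning("MGF block %d in %s has no PEPMASS; skipped", index - 1, path.name)
                continue
            precursor = float(pepmass[0])
            fid = params.get("scans") or params.get("feature_id")
            if fid is None:
                raise MGFParseError(f"malformed MGF block {index - 1} in {path.name}: no SCANS/FEATURE_ID")
            if "rtinseconds" in params:
                rt = float(params["rtinseconds"]) / 60.0
            elif "rtinminutes" in params:
                rt = float(params["rtinminutes"])
            else:
                rt = 0.0
            charge = params.get("charge")
            charge_val = int(charge[0]) if charge else 1
            peaks = tuple(
                Peak(float(m), float(i))
                for m, i in zip(entry.get("m/z array", []), entry.get("intensity array", []))
            )
            spectra.append(
                Spectrum(feature_id=str(fid), precursor_mz=precursor, charge=charge_val, rt=rt, peaks=peaks)
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as a GNPS-compatible MGF (feature id emitted as SCANS)."""
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": np.round(np.array([p.mz for p in s.peaks]), 4),
                "intensity array": np.round(np.array([p.intensity for p in s.peaks]), 4),
                "params": {
                    "scans": s.feature_id,
                    "pepmass": round(s.precursor_mz, 4),
                    "charge": f"{s.charge}+",
                    "rtinseconds": round(s.rt * 60.0, 4),
                    "mslevel": 2,
                },
            }
        )
    with open(path, "w") as handle:
        _pymgf.write(entries, handle, key_order=["scans", "pepmass", "charge", "rtinseconds", "mslevel"])


# ---------------------------------------------------------------------------
# Quantification table
# ---------------------------------------------------------------------------

#: default column map; the GNPS export convention ("row ID", "row m/z",
#: "row retention time", "<fraction> Peak area") is detected automatically.
DEFAULT_COLUMNS = {"id": "feature_id", "mz": "mz", "rt": "rt"}


def _sniff_sep(path: Path) -> str:
    sample = path.read_text().splitlines()[0] if path.stat().st_size else ""
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_quant_table(
    path: str | Path,
    manifest: SampleManifest,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[FeatureRecord]:
    """Read a feature quantification table joined-ready by feature id.

    One intensity column is expected per manifest fraction (named either as
    the bare fraction id or ``"<id> Peak area"``). Missing or non-numeric
    intensities are zero-filled with a warning; duplicate feature ids and
    intensity columns absent from the manifest are errors.
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMNS if columns is None else columns)
    # ids stay strings ("7", not "7.0"); numeric columns convert explicitly
    df = pd.read_csv(path, sep=sep if sep is not None else _sniff_sep(path), dtype=str)
    df.columns = [str(c).strip() for c in df.columns]

    # GNPS export detection
    renames = {}
    for gnps, ours in (("row ID", colmap["id"]), ("row m/z", colmap["mz"]), ("row retention time", colmap["rt"])):
        if gnps in df.columns:
            renames[gnps] = ours
    df = df.rename(columns=renames)
    for key in ("id", "mz", "rt"):
        if colmap[key] not in df.columns:
            raise QuantTableError(f"required column {colmap[key]!r} missing from {path.name}")

    frac_cols: dict[str, str] = {}
    known = set(manifest.fraction_ids)
    for col in df.columns:
        if col in (colmap["id"], colmap["mz"], colmap["rt"]):
            continue
        base = col[: -len(" Peak area")] if col.endswith(" Peak area") else col
        base = base.strip()
        if base in known:
            frac_cols[base] = col
        else:
            raise QuantTableError(f"intensity column {col!r} not in sample manifest")

    ids = df[colmap["id"]].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise QuantTableError(f"duplicate feature ids: {dupes}")

    records: list[FeatureRecord] = []
    for _, row in df.iterrows():
        intensities: dict[str, float] = {}
        for frac in manifest.fraction_ids:
            col = frac_cols.get(frac)
            val = row[col] if col is not None else np.nan
            val = pd.to_numeric(val, errors="coerce")
            if pd.isna(val):
                logger.warning(
                    "feature %s fraction %s: missing intensity treated as 0", row[colmap["id"]], frac
                )
                val = 0.0
            intensities[frac] = float(val)
        records.append(
            FeatureRecord(
                feature_id=str(row[colmap["id"]]),
                mz=float(row[colmap["mz"]]),
                rt=float(row[colmap["rt"]]),
                intensities=intensities,
            )
        )
    return records


# ---------------------------------------------------------------------------
# DAD trace & bioactivity
# ---------------------------------------------------------------------------


def read_dad_trace(path: str | Path, wavelength: float = 420.0, sep: str | None = None) -> DADTrace:
    """Read a two-column (time, absorbance) trace; duplicates collapse by max."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep if sep is not None else _sniff_sep(path), comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: expected two columns (time, absorbance)")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    a = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = t.isna() | a.isna()
    if bad.any():
        # +2: one for the header line, one for 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad]]
        raise ValueError(f"{path.name}: non-numeric rows at lines {lines}")
    collapsed = pd.DataFrame({"t": t, "a": a}).groupby("t", sort=True)["a"].max()
    return DADTrace(times=collapsed.index.to_numpy(), absorbance=collapsed.to_numpy(), wavelength=wavelength)


def read_bioactivity_table(path: str | Path, sep: str | None = None) -> dict[str, float]:
    """Read a fraction→value table (raw assay readout or pre-assigned class)."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep if sep is not None else _sniff_sep(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: expected columns (fraction, value)")
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        val = pd.to_numeric(row.iloc[1], errors="coerce")
        if pd.isna(val):
            raise ValueError(f"{path.name}: non-numeric bioactivity for {row.iloc[0]!r}")
        out[str(row.iloc[0]).strip()] = float(val)
    return out


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------


def _clean_attrs(attrs: Mapping[str, object]) -> dict[str, object]:
    out: dict[str, object] = {}
    for k in sorted(attrs):
        v = attrs[k]
        if v is None:
            continue
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        if isinstance(v, float) and math.isnan(v):
            continue
        if isinstance(v, bool) or isinstance(v, (int, float, str)):
            out[k] = v
        else:
            out[k] = str(v)
    return out


def write_graphml(network, path: str | Path) -> None:
    """Export a network as GraphML with deterministic node/edge ordering.

    Accepts either a :class:`networkx.Graph` or any object exposing
    ``to_networkx()`` (as :class:`pbnet.network_builder.MolecularNetwork` does).
    Identical networks produce byte-identical files.
    """
    g = network.to_networkx() if hasattr(network, "to_networkx") else network
    ordered = nx.Graph()
    for node in sorted(g.nodes, key=str):
        ordered.add_node(node, **_clean_attrs(g.nodes[node]))
    for u, v in sorted((tuple(sorted((str(a), str(b)))) for a, b in g.edges), key=lambda e: e):
        ordered.add_edge(u, v, **_clean_attrs(g.edges[u, v]))
    nx.write_graphml(ordered, str(path), infer_numeric_types=False)


def read_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML file written by :func:`write_graphml`."""
    return nx.read_graphml(str(path))
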