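"""Peak lists, profile traces, and replicate sets.

The interchange format is two-column delimited text (m/z, area) with
'#' comments; spectrum metadata (strand and ligand concentrations,
ligand/counter-ion identity, replicate id) travels in header comments or
in a sidecar manifest, never in filenames.  An optional mzML reader is
provided for centroided scans.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Peak",
    "SpectrumMetadata",
    "Spectrum",
    "ReplicateSet",
    "read_peaklist",
    "write_peaklist",
    "centroid_profile",
    "read_mzml",
]


@dataclass(frozen=True)
class Peak:
    mz: float
    area: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


_METADATA_FIELDS = ("c_q", "c_l", "ligand", "counterion", "replicate_id", "buffer")


@dataclass(frozen=True)
class SpectrumMetadata:
    """Experimental context of one spectrum.

    Concentrations are mol/L of total strand (``c_q``) and total ligand
    (``c_l``); they must be positive before binding inference is run.
    """

    c_q: float | None = None
    c_l: float | None = None
    ligand: str | None = None
    counterion: str | None = None
    replicate_id: str | None = None
    buffer: str | None = None
    polarity: str = "negative"


@dataclass(frozen=True)
class Spectrum:
    peaks: tuple[Peak, ...]
    metadata: SpectrumMetadata = field(default_factory=SpectrumMetadata)

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peaks must be sorted strictly ascending in m/z")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def total_area(self) -> float:
        return float(sum(p.area for p in self.peaks))

    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    def area_array(self) -> np.ndarray:
        return np.array([p.area for p in self.peaks])


@dataclass(frozen=True)
class ReplicateSet:
    """Spectra sharing oligo/ligand/concentration metadata."""

    spectra: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("replicate set must contain at least one spectrum")
        ref = self.spectra[0].metadata
        for s in self.spectra[1:]:
            m = s.metadata
            if (m.c_q, m.c_l, m.ligand, m.counterion) != (
                ref.c_q,
                ref.c_l,
                ref.ligand,
                ref.counterion,
            ):
                raise ValueError(
                    "replicates disagree on concentrations or ligand identity"
                )

    def __len__(self) -> int:
        return len(self.spectra)


def _peaks_from_rows(rows: list[tuple[float, float]]) -> tuple[Peak, ...]:
    # duplicate m/z rows are the same centroid split across exports: sum them
    merged: dict[float, float] = {}
    for mz, area in rows:
        merged[mz] = merged.get(mz, 0.0) + area
    return tuple(Peak(mz, a) for mz, a in sorted(merged.items()))


def read_peaklist(
    path: str | Path | io.TextIOBase,
    metadata: SpectrumMetadata | None = None,
) -> Spectrum:
    """Read a two-column (m/z, area) delimited text file into a Spectrum.

    Header comments of the form ``# key: value`` for keys c_q, c_l,
    ligand, counterion, replicate_id, buffer populate the metadata when
    no explicit metadata is given.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    rows: list[tuple[float, float]] = []
    header: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                header[key.strip().lower()] = value.strip()
            continue
        fields = line.replace(",", "\t").split()
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected two columns, got {line!r}")
        try:
            mz, area = float(fields[0]), float(fields[1])
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric row {line!r}") from None
        rows.append((mz, area))
    if not rows:
        raise ValueError("empty peak list (no data rows)")
    if metadata is None:
        kwargs = {}
        for key in _METADATA_FIELDS:
            if key in header:
                val = header[key]
                kwargs[key] = float(val) if key in ("c_q", "c_l") else val
        metadata = SpectrumMetadata(**kwargs)
    return Spectrum(peaks=_peaks_from_rows(rows), metadata=metadata)


def write_peaklist(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a Spectrum as tab-separated (m/z, area) text with metadata header."""
    if len(spectrum) == 0:
        raise ValueError("refusing to write a spectrum with no peaks")
    path = Path(path)
    lines = ["# gqbind peak list", "# columns: mz\tarea"]
    md = spectrum.metadata
    for key in _METADATA_FIELDS:
        value = getattr(md, key)
        if value is not None:
            lines.append(f"# {key}: {value}")
    for p in spectrum.peaks:
        # repr round-trips float64 exactly
        lines.append(f"{p.mz!r}\t{p.area!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def centroid_profile(
    mz: Sequence[float],
    intensity: Sequence[float],
    noise_threshold: float,
    metadata: SpectrumMetadata | None = None,
) -> Spectrum:
    """Centroid a profile trace by thresholding.

    Contiguous runs of points with intensity above ``noise_threshold``
    become peaks; the centroid is the intensity-weighted mean m/z of the
    run and the area its trapezoidal integral.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.ndim != 1 or mz.shape != intensity.shape:
        raise ValueError("mz and intensity must be 1-D arrays of equal length")
    if np.any(np.diff(mz) <= 0):
        raise ValueError("profile m/z grid must be strictly increasing")

    above = intensity > noise_threshold
    peaks: list[Peak] = []
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [int(i) + 1 for i in edges if not above[i]]
    for start in starts:
        end = start
        while end + 1 < len(above) and above[end + 1]:
            end += 1
        seg = slice(start, end + 1)
        w = intensity[seg]
        centroid = float(np.average(mz[seg], weights=w))
        if end > start:
            area = float(np.trapezoid(w, mz[seg]))
        else:  # single-point run: rectangle over the local grid spacing
            spacing = mz[min(start + 1, len(mz) - 1)] - mz[max(start - 1, 0)]
            area = float(w[0] * spacing / 2)
        peaks.append(Peak(centroid, area))
    peaks.sort(key=lambda p: p.mz)
    return Spectrum(peaks=tuple(peaks), metadata=metadata or SpectrumMetadata())


def read_mzml(
    path: str | Path, metadata: SpectrumMetadata | None = None
) -> list[Spectrum]:
    """Read centroided scans from an mzML file (requires pyteomics)."""
    from pyteomics import mzml  # optional dependency

    spectra = []
    with mzml.MzML(str(path)) as reader:
        for scan in reader:
            mzs = scan.get("m/z array")
            ints = scan.get("intensity array")
            if mzs is None or ints is None or len(mzs) == 0:
                continue
            rows = list(zip(map(float, mzs), map(float, ints)))
            spectra.append(
                Spectrum(
                    peaks=_peaks_from_rows(rows),
                    metadata=metadata or SpectrumMetadata(),
                )
            )
    return spectra
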