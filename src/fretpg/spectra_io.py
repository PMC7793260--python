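"""Reading, validating, resampling and writing fluorimeter emission scans.

A scan is a two-column delimited text table (wavelength in nm, intensity in
arbitrary counts) with optional ``#``-prefixed ``key: value`` header lines.
Experiments are batched by a manifest: one row per scan with its path, sample
id, role, excitation wavelength and replicate number.  Every experiment must
carry its own reference scans (PBS buffer, empty-cell autofluorescence,
donor-only and acceptor-only fusions) because the unmixing basis is rebuilt
per experiment.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    GridRangeError,
    InsufficientDataError,
    ManifestError,
    SpectrumFormatError,
)

#: Roles a scan can play in an experiment.
ROLES = frozenset(
    {"buffer", "empty_cell", "donor_ref", "acceptor_ref", "fret_sample", "tandem", "negative"}
)

#: Roles that denote a measured FRET pair (must appear in both excitation channels).
SAMPLE_ROLES = frozenset({"fret_sample", "tandem", "negative"})

MIN_POINTS = 10


@dataclass(frozen=True)
class EmissionSpectrum:
    """One wavelength-indexed emission scan with excitation metadata.

    Wavelengths must be strictly increasing and lie red of the excitation
    wavelength (emission is collected through long-pass filters).
    """

    sample_id: str
    excitation_nm: float
    wavelengths: np.ndarray
    intensities: np.ndarray
    role: str = "fret_sample"
    replicate: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise SpectrumFormatError(
                f"{self.sample_id}: wavelengths and intensities must be 1-D of equal length"
            )
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise SpectrumFormatError(f"{self.sample_id}: wavelengths not strictly increasing")
        if self.role not in ROLES:
            raise SpectrumFormatError(f"{self.sample_id}: unknown role {self.role!r}")
        if wl.size and self.excitation_nm >= wl[0]:
            raise SpectrumFormatError(
                f"{self.sample_id}: excitation {self.excitation_nm} nm not below the "
                f"emission window starting at {wl[0]} nm"
            )
        if self.replicate < 1:
            raise SpectrumFormatError(f"{self.sample_id}: replicate must be >= 1")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def with_intensities(self, intensities: np.ndarray, **meta) -> "EmissionSpectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return replace(self, intensities=np.asarray(intensities, dtype=float), meta=new_meta)


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    sample_id: str
    role: str
    excitation_nm: float
    replicate: int = 1

    def __post_init__(self):
        if self.role not in ROLES:
            raise ManifestError(f"{self.sample_id}: unknown role {self.role!r}")


@dataclass
class ExperimentManifest:
    """One experiment: the set of scans needed to build a basis and unmix samples."""

    entries: list[ManifestEntry]
    #: optional per-channel target grid, excitation nm -> (start, stop, step)
    grids: dict[float, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def channels(self) -> list[float]:
        return sorted({e.excitation_nm for e in self.entries})

    @property
    def donor_channel(self) -> float:
        return self.channels[0]

    @property
    def acceptor_channel(self) -> float:
        return self.channels[-1]

    def by_role(self, role: str, channel: float | None = None) -> list[ManifestEntry]:
        out = [e for e in self.entries if e.role == role]
        if channel is not None:
            out = [e for e in out if e.excitation_nm == channel]
        return out

    def sample_ids(self) -> list[str]:
        seen: list[str] = []
        for e in self.entries:
            if e.role in SAMPLE_ROLES and e.sample_id not in seen:
                seen.append(e.sample_id)
        return seen

    def validate(self) -> None:
        if len(self.channels) != 2:
            raise ManifestError(
                f"expected exactly two excitation channels, found {self.channels}"
            )
        donor, acceptor = self.donor_channel, self.acceptor_channel
        for ch in (donor, acceptor):
            for role in ("buffer", "empty_cell"):
                n = len(self.by_role(role, ch))
                if n != 1:
                    raise ManifestError(
                        f"need exactly one {role} scan at {ch:g} nm excitation, found {n}"
                    )
        if not self.by_role("donor_ref", donor):
            raise ManifestError(f"missing donor_ref at {donor:g} nm excitation")
        for ch in (donor, acceptor):
            if not self.by_role("acceptor_ref", ch):
                raise ManifestError(f"missing acceptor_ref at {ch:g} nm excitation")
        for sid in self.sample_ids():
            chans = {e.excitation_nm for e in self.entries
                     if e.sample_id == sid and e.role in SAMPLE_ROLES}
            if chans != {donor, acceptor}:
                raise ManifestError(
                    f"sample {sid!r} must be measured in both channels; has {sorted(chans)}"
                )


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_spectrum(path: str | Path, meta: ManifestEntry | Mapping | None = None) -> EmissionSpectrum:
    """Read a two-column scan file; manifest metadata overrides file headers."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    header[k.strip()] = v.strip()
                continue
            parts = [p for p in line.replace(_sniff_delimiter(line), " ").split() if p]
            if len(parts) < 2:
                raise SpectrumFormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if len(rows) < MIN_POINTS:
        raise InsufficientDataError(f"{path}: only {len(rows)} points (need >= {MIN_POINTS})")

    def pick(key, cast, default):
        if meta is not None:
            if isinstance(meta, ManifestEntry):
                return getattr(meta, key)
            if key in meta:
                return cast(meta[key])
        if key in header:
            return cast(header.pop(key))
        if default is None:
            raise SpectrumFormatError(f"{path}: missing required metadata {key!r}")
        return default

    wl, it = (np.array(c, dtype=float) for c in zip(*rows))
    return EmissionSpectrum(
        sample_id=pick("sample_id", str, path.stem),
        excitation_nm=pick("excitation_nm", float, None),
        wavelengths=wl,
        intensities=it,
        role=pick("role", str, "fret_sample"),
        replicate=pick("replicate", int, 1),
        meta=header,
    )


def write_spectrum(s: EmissionSpectrum, path: str | Path) -> None:
    """Write a scan in the canonical comma-separated format with metadata header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# sample_id: {s.sample_id}\n")
        fh.write(f"# excitation_nm: {s.excitation_nm:g}\n")
        fh.write(f"# role: {s.role}\n")
        fh.write(f"# replicate: {s.replicate}\n")
        for k, v in s.meta.items():
            fh.write(f"# {k}: {v}\n")
        for wl, it in zip(s.wavelengths, s.intensities):
            fh.write(f"{wl:.17g},{it:.17g}\n")


def make_grid(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def resample_to_grid(s: EmissionSpectrum, grid: tuple[float, float, float]) -> EmissionSpectrum:
    """Linearly interpolate a scan onto (start, stop, step).  No extrapolation."""
    start, stop, step = grid
    if step <= 0 or stop < start:
        raise GridRangeError(f"invalid grid {grid}")
    if start < s.wavelengths[0] or stop > s.wavelengths[-1]:
        raise GridRangeError(
            f"grid [{start}, {stop}] outside measured range "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}]"
        )
    new_wl = make_grid(start, stop, step)
    new_it = np.interp(new_wl, s.wavelengths, s.intensities)
    return replace(s, wavelengths=new_wl, intensities=new_it)


def require_same_grid(a: EmissionSpectrum, b: EmissionSpectrum) -> None:
    if a.excitation_nm != b.excitation_nm:
        raise AlignmentError(
            f"excitation mismatch: {a.sample_id} at {a.excitation_nm:g} nm vs "
            f"{b.sample_id} at {b.excitation_nm:g} nm"
        )
    if len(a) != len(b) or not np.allclose(a.wavelengths, b.wavelengths):
        raise AlignmentError(f"wavelength grids of {a.sample_id} and {b.sample_id} differ")


# -- manifest ---------------------------------------------------------------

_MANIFEST_COLUMNS = ["path", "sample_id", "role", "excitation_nm", "replicate"]


def load_manifest(path: str | Path) -> ExperimentManifest:
    """Load and validate a delimited manifest (one row per scan)."""
    path = Path(path)
    grids: dict[float, tuple[float, float, float]] = {}
    lines = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("grid"):
                    # "# grid 541: 550,700,1"
                    head, _, spec_ = body.partition(":")
                    ch = float(head.split()[1])
                    start, stop, step = (float(x) for x in spec_.replace(",", " ").split())
                    grids[ch] = (start, stop, step)
                continue
            lines.append(line)
    if not lines:
        raise ManifestError(f"{path}: empty manifest")
    delim = _sniff_delimiter(lines[0])
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter=delim)
    missing = set(_MANIFEST_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise ManifestError(f"{path}: manifest missing columns {sorted(missing)}")
    entries = []
    for row in reader:
        entries.append(
            ManifestEntry(
                path=row["path"],
                sample_id=row["sample_id"],
                role=row["role"],
                excitation_nm=float(row["excitation_nm"]),
                replicate=int(row["replicate"]),
            )
        )
    manifest = ExperimentManifest(entries=entries, grids=grids)
    manifest.validate()
    return manifest


def write_manifest(manifest: ExperimentManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for ch, (start, stop, step) in sorted(manifest.grids.items()):
            fh.write(f"# grid {ch:g}: {start:g},{stop:g},{step:g}\n")
        fh.write(",".join(_MANIFEST_COLUMNS) + "\n")
        for e in manifest.entries:
            fh.write(f"{e.path},{e.sample_id},{e.role},{e.excitation_nm:g},{e.replicate}\n")


def load_entry(entry: ManifestEntry, base_dir: str | Path = ".") -> EmissionSpectrum:
    return read_spectrum(Path(base_dir) / entry.path, entry)
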