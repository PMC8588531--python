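"""Spectral data model and file I/O.

The whole toolkit works on per-pixel reflectance spectra sampled on a shared
wavelength grid.  This module defines the containers (:class:`WavelengthGrid`,
:class:`Spectrum`, :class:`SpectraSet`, :class:`Cube`), readers/writers for
spectral-library CSV files and ENVI cubes, and the grid operations used to
make data from different sensors inter-operable: clipping to a common
wavelength range and nearest-band resampling.

Resampling is deliberately *band selection*, not interpolation: a multispectral
instrument measures existing bands of the denser sensor, so the matching band
is picked (ties break to the lower wavelength) rather than synthesized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DegenerateGridError,
    DimensionError,
    FormatError,
    UnsupportedDialectError,
)

#: Default working wavelength range (nm): the intersection of typical
#: air- and ground-sensor coverage used throughout the toolkit.
DEFAULT_RANGE_NM = (406.0, 1100.0)

#: Reflectance is unitless and physically bounded; values outside this range
#: trigger a warning but are kept (sensor calibration can overshoot 1).
REFLECTANCE_WARN_RANGE = (0.0, 1.5)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths (nm) defining the N spectral bands."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        if w.ndim != 1 or w.size == 0:
            raise FormatError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(w)):
            raise FormatError("wavelength grid contains non-finite values")
        if np.any(np.diff(w) <= 0):
            raise FormatError("wavelengths must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return int(self.wavelengths_nm.size)

    def __len__(self) -> int:
        return self.n_bands

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths_nm, other.wavelengths_nm)

    def __hash__(self) -> int:
        return hash(self.wavelengths_nm.tobytes())

    def fingerprint(self) -> dict:
        """Compact identity used when serializing band sets / dictionaries."""
        w = self.wavelengths_nm
        return {"n_bands": self.n_bands, "first_nm": float(w[0]), "last_nm": float(w[-1])}


def _check_reflectance(values: np.ndarray) -> None:
    lo, hi = REFLECTANCE_WARN_RANGE
    if values.size and (values.min() < lo or values.max() > hi):
        warnings.warn(
            f"reflectance values outside [{lo}, {hi}] "
            f"(min={values.min():.3g}, max={values.max():.3g})",
            stacklevel=3,
        )


@dataclass(frozen=True)
class Spectrum:
    """One reflectance spectrum on a wavelength grid."""

    grid: WavelengthGrid
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "reflectance", r)
        if r.shape != (self.grid.n_bands,):
            raise DimensionError(
                f"reflectance length {r.shape} does not match grid ({self.grid.n_bands} bands)"
            )
        if not np.all(np.isfinite(r)):
            raise DimensionError("reflectance contains non-finite values")
        _check_reflectance(r)


@dataclass
class SpectraSet:
    """A collection of spectra sharing one grid.

    ``values`` is a (P, N) array (one row per pixel).  ``coords`` optionally
    carries (row, col) image coordinates, ``labels`` a per-pixel land-cover
    class (``vegetation | soil | water | other``), and ``ids`` free-form
    identifiers (e.g. CSV column names).
    """

    grid: WavelengthGrid
    values: np.ndarray
    coords: np.ndarray | None = None
    labels: list[str] | None = None
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != self.grid.n_bands:
            raise DimensionError(
                f"values shape {v.shape} incompatible with {self.grid.n_bands}-band grid"
            )
        if not np.all(np.isfinite(v)):
            raise DimensionError("spectra contain non-finite values")
        self.values = v
        if self.coords is not None:
            c = np.asarray(self.coords, dtype=int)
            if c.shape != (len(self), 2):
                raise DimensionError("coords must be (P, 2)")
            if len({tuple(rc) for rc in c.tolist()}) != len(self):
                raise DimensionError("pixel coordinates must be unique")
            self.coords = c
        if self.labels is not None and len(self.labels) != len(self):
            raise DimensionError("labels length must match number of spectra")
        if self.ids is not None and len(self.ids) != len(self):
            raise DimensionError("ids length must match number of spectra")
        _check_reflectance(v)

    def __len__(self) -> int:
        return int(self.values.shape[0])

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.values[i])

    def subset(self, index: np.ndarray) -> "SpectraSet":
        index = np.asarray(index)
        return SpectraSet(
            self.grid,
            self.values[index],
            coords=None if self.coords is None else self.coords[index],
            labels=None if self.labels is None else [self.labels[i] for i in index],
            ids=None if self.ids is None else [self.ids[i] for i in index],
        )


@dataclass
class Cube:
    """A rows x cols x N reflectance image, convertible to/from a SpectraSet."""

    grid: WavelengthGrid
    values: np.ndarray
    labels: np.ndarray | None = field(default=None)  # rows x cols of strings

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != self.grid.n_bands:
            raise DimensionError(f"cube shape {v.shape} incompatible with grid")
        if not np.all(np.isfinite(v)):
            raise DimensionError("cube contains non-finite values")
        self.values = v
        _check_reflectance(v)
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape != v.shape[:2]:
                raise DimensionError("label map shape must equal (rows, cols)")
            self.labels = lab

    @property
    def rows(self) -> int:
        return int(self.values.shape[0])

    @property
    def cols(self) -> int:
        return int(self.values.shape[1])

    def to_spectra_set(self) -> SpectraSet:
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        coords = np.stack([rr.ravel(), cc.ravel()], axis=1)
        labels = None if self.labels is None else list(self.labels.ravel())
        return SpectraSet(
            self.grid,
            self.values.reshape(-1, self.grid.n_bands),
            coords=coords,
            labels=labels,
        )

    @classmethod
    def from_spectra_set(cls, spectra: SpectraSet, rows: int, cols: int) -> "Cube":
        if spectra.coords is None:
            raise DimensionError("SpectraSet needs coordinates to form a cube")
        if len(spectra) != rows * cols:
            raise DimensionError("SpectraSet does not fill the cube")
        values = np.empty((rows, cols, spectra.grid.n_bands))
        values[spectra.coords[:, 0], spectra.coords[:, 1]] = spectra.values
        labels = None
        if spectra.labels is not None:
            labels = np.empty((rows, cols), dtype=object)
            labels[spectra.coords[:, 0], spectra.coords[:, 1]] = spectra.labels
        return cls(spectra.grid, values, labels=labels)


# ---------------------------------------------------------------------------
# spectral-library CSV
# ---------------------------------------------------------------------------

def read_spectral_library(path: str | Path) -> SpectraSet:
    """Read a spectral-library CSV (wavelength column + one column per spectrum)."""
    df = pd.read_csv(path)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: no columns")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows / missing values")
    wavelengths = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(wavelengths) <= 0):
        raise FormatError(f"{path}: wavelengths not strictly increasing")
    grid = WavelengthGrid(wavelengths)
    values = df.iloc[:, 1:].to_numpy(dtype=float).T  # (P, N)
    ids = list(df.columns[1:])
    return SpectraSet(grid, values, ids=ids or None)


def write_spectral_library(spectra: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet as a spectral-library CSV readable by the reader above."""
    ids = spectra.ids or [f"spectrum_{i}" for i in range(len(spectra))]
    df = pd.DataFrame({"wavelength_nm": spectra.grid.wavelengths_nm})
    for name, row in zip(ids, spectra.values):
        df[name] = row
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# ENVI cubes (BSQ/BIL subset)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5, np.dtype(np.uint16): 12}


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    body = text
    if body.lstrip().lower().startswith("envi"):
        body = body.lstrip()[4:]
    # join brace-delimited multi-line values before splitting into lines
    merged: list[str] = []
    buf = ""
    depth = 0
    for line in body.splitlines():
        buf = f"{buf} {line}" if depth else line
        depth += line.count("{") - line.count("}")
        if depth == 0 and buf.strip():
            merged.append(buf)
            buf = ""
    for line in merged:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi_cube(header_path: str | Path) -> Cube:
    """Read an ENVI cube (``.hdr`` + binary; BSQ or BIL; float32/float64/uint16).

    A ``reflectance scale factor`` in the header divides integer counts back
    to unitless reflectance.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in fields:
            raise FormatError(f"{header_path}: missing ENVI field '{key}'")
    if "wavelength" not in fields:
        raise FormatError(f"{header_path}: no wavelength list in header")
    cols = int(fields["samples"])
    rows = int(fields["lines"])
    bands = int(fields["bands"])
    interleave = fields["interleave"].lower()
    if interleave not in ("bsq", "bil"):
        raise UnsupportedDialectError(f"interleave '{interleave}' not supported (BSQ/BIL only)")
    code = int(fields["data type"])
    if code not in _ENVI_DTYPES:
        raise UnsupportedDialectError(f"ENVI data type {code} not supported")
    dtype = _ENVI_DTYPES[code]
    wavelengths = np.array(
        [float(t) for t in fields["wavelength"].strip("{} \n").replace(",", " ").split()]
    )
    if wavelengths.size != bands:
        raise FormatError(f"{header_path}: {wavelengths.size} wavelengths for {bands} bands")

    data_path = header_path.with_suffix("")  # foo.hdr -> foo
    if not data_path.exists():
        for ext in (".bsq", ".bil", ".img", ".dat"):
            cand = header_path.with_suffix(ext)
            if cand.exists():
                data_path = cand
                break
    raw = np.fromfile(data_path, dtype=dtype)
    if raw.size != rows * cols * bands:
        raise FormatError(
            f"{data_path}: {raw.size} samples on disk, header implies {rows * cols * bands}"
        )
    if interleave == "bsq":
        values = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:  # bil
        values = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    values = values.astype(float)
    scale = float(fields.get("reflectance scale factor", 1.0))
    if scale != 1.0:
        values = values / scale
    return Cube(WavelengthGrid(wavelengths), values)


def write_envi_cube(cube: Cube, path: str | Path) -> None:
    """Write a cube as BSQ float32 with a ``.hdr`` carrying the wavelength list."""
    path = Path(path)
    data_path = path if path.suffix == ".bsq" else path.with_suffix(".bsq")
    header_path = data_path.with_suffix(".hdr")
    bsq = cube.values.transpose(2, 0, 1).astype(np.float32)
    bsq.tofile(data_path)
    wl = ", ".join(f"{w:.6f}" for w in cube.grid.wavelengths_nm)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cube.cols}\n"
        f"lines = {cube.rows}\n"
        f"bands = {cube.grid.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(np.float32)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )


# ---------------------------------------------------------------------------
# grid operations
# ---------------------------------------------------------------------------

def clip_to_range(data: SpectraSet | Cube, lo_nm: float, hi_nm: float):
    """Keep only bands with ``lo_nm <= wavelength <= hi_nm`` (order preserved)."""
    if not lo_nm < hi_nm:
        raise DegenerateGridError(f"invalid range [{lo_nm}, {hi_nm}]")
    w = data.grid.wavelengths_nm
    mask = (w >= lo_nm) & (w <= hi_nm)
    if not mask.any():
        raise DegenerateGridError(f"no bands remain in [{lo_nm}, {hi_nm}] nm")
    grid = WavelengthGrid(w[mask])
    if isinstance(data, Cube):
        return Cube(grid, data.values[:, :, mask], labels=data.labels)
    return SpectraSet(
        grid,
        data.values[:, mask],
        coords=data.coords,
        labels=data.labels,
        ids=data.ids,
    )


def nearest_band_indices(
    source: WavelengthGrid, target: WavelengthGrid, max_gap_nm: float = 10.0
) -> np.ndarray:
    """For each target band, the index of the nearest source band (ties → lower λ)."""
    src = source.wavelengths_nm
    tgt = target.wavelengths_nm
    pos = np.searchsorted(src, tgt)
    pos_hi = np.clip(pos, 0, src.size - 1)
    pos_lo = np.clip(pos - 1, 0, src.size - 1)
    d_lo = np.abs(tgt - src[pos_lo])
    d_hi = np.abs(src[pos_hi] - tgt)
    idx = np.where(d_lo <= d_hi, pos_lo, pos_hi)  # tie -> lower wavelength
    gaps = np.abs(src[idx] - tgt)
    if np.any(gaps > max_gap_nm):
        worst = int(np.argmax(gaps))
        raise CoverageError(
            f"target band {tgt[worst]:.1f} nm is {gaps[worst]:.1f} nm from the "
            f"nearest source band (max gap {max_gap_nm} nm)"
        )
    return idx


def resample_to_grid(
    spectra: SpectraSet, target: WavelengthGrid, max_gap_nm: float = 10.0
) -> SpectraSet:
    """Resample onto ``target`` by nearest-band selection (no interpolation)."""
    idx = nearest_band_indices(spectra.grid, target, max_gap_nm=max_gap_nm)
    return SpectraSet(
        target,
        spectra.values[:, idx],
        coords=spectra.coords,
        labels=spectra.labels,
        ids=spectra.ids,
    )


def default_grid(n_bands: int = 40, lo_nm: float | None = None, hi_nm: float | None = None) -> WavelengthGrid:
    """Evenly spaced working grid over the default 406–1100 nm range."""
    lo = DEFAULT_RANGE_NM[0] if lo_nm is None else lo_nm
    hi = DEFAULT_RANGE_NM[1] if hi_nm is None else hi_nm
    return WavelengthGrid(np.linspace(lo, hi, n_bands))
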