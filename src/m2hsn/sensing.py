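"""Band sets and the band-subsampling measurement model.

A multispectral sensor node measures M of the N hyperspectral bands.  The
sensing operator is therefore a row-selection matrix Φ (one 1 per row); a
network can be *homogeneous* (every node shares one band set) or
*heterogeneous* (independent random band sets per node).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, SizeError
from .spectral_io import Spectrum, WavelengthGrid


@dataclass(frozen=True)
class BandSet:
    """Sorted, unique 0-based indices of the measured bands."""

    indices: np.ndarray
    n_bands: int

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)
        if idx.size == 0:
            raise SizeError("band set must contain at least one band")
        if idx.size != np.asarray(self.indices).size:
            pass  # duplicates collapsed by np.unique
        if idx[0] < 0 or idx[-1] >= self.n_bands:
            raise SizeError(f"band indices out of range [0, {self.n_bands})")

    @property
    def m(self) -> int:
        return int(self.indices.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandSet):
            return NotImplemented
        return self.n_bands == other.n_bands and np.array_equal(self.indices, other.indices)

    def __hash__(self) -> int:
        return hash((self.n_bands, self.indices.tobytes()))

    def sort_key(self) -> tuple:
        return tuple(self.indices.tolist())

    def to_json(self, grid: WavelengthGrid | None = None) -> str:
        payload: dict = {"indices": self.indices.tolist(), "n_bands": self.n_bands}
        if grid is not None:
            payload["grid"] = grid.fingerprint()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str | Path) -> "BandSet":
        if isinstance(text, Path):
            text = text.read_text()
        payload = json.loads(text)
        return cls(np.array(payload["indices"]), payload["n_bands"])


@dataclass(frozen=True)
class SensingOperator:
    """The M x N row-selection map Φ for one band set."""

    band_set: BandSet

    @property
    def matrix(self) -> np.ndarray:
        phi = np.zeros((self.band_set.m, self.band_set.n_bands))
        phi[np.arange(self.band_set.m), self.band_set.indices] = 1.0
        return phi

    def select(self, values: np.ndarray) -> np.ndarray:
        """Apply Φ along the last axis (works on vectors, matrices, dictionaries)."""
        return np.take(values, self.band_set.indices, axis=-1)


@dataclass(frozen=True)
class Measurement:
    """M reflectance readings from one node."""

    band_set: BandSet
    values: np.ndarray
    node_id: int | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (self.band_set.m,):
            raise DimensionError(
                f"measurement length {v.shape} != band-set size {self.band_set.m}"
            )
        if not np.all(np.isfinite(v)):
            raise DimensionError("measurement contains non-finite values")


def random_band_set(n_bands: int, m: int, seed: int) -> BandSet:
    """M band indices drawn uniformly without replacement (seeded)."""
    if not 1 <= m <= n_bands:
        raise SizeError(f"need 1 <= M <= N, got M={m}, N={n_bands}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_bands, size=m, replace=False)
    return BandSet(np.sort(idx), n_bands)


def apply_sensing(op: SensingOperator, spectrum: Spectrum) -> Measurement:
    """Measure a spectrum: exact selection of the band-set entries, no mixing."""
    if spectrum.grid.n_bands != op.band_set.n_bands:
        raise DimensionError(
            f"spectrum has {spectrum.grid.n_bands} bands, operator expects "
            f"{op.band_set.n_bands}"
        )
    return Measurement(op.band_set, op.select(spectrum.reflectance))


def assign_heterogeneous(
    n_nodes: int, n_bands: int, m: int, seed: int, homogeneous: bool = False
) -> list[BandSet]:
    """Per-node band sets: independent random draws, or one shared set."""
    if homogeneous:
        return [random_band_set(n_bands, m, seed)] * n_nodes
    root = np.random.SeedSequence(seed)
    return [
        random_band_set(n_bands, m, int(child.generate_state(1)[0] % 2**31))
        for child in root.spawn(n_nodes)
    ]
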