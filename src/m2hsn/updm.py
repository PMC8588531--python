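"""Universal Pattern Decomposition (UPDM) baseline.

Each pixel's spectrum is modelled as a linear mixture of three base
materials — water, vegetation and soil — whose high-resolution spectra are
known.  From an M-band measurement the three mixing fractions are estimated
by least squares on the band-subsampled bases, and the hyperspectral
spectrum is recomposed as the same combination of the full-resolution bases.

The method is exact for spectra inside the 3-dimensional span of the bases
and has an irreducible error floor — the distance to that span — for
anything else (built-up anomalies, unusual canopies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .errors import ConditioningError, DimensionError, InputError
from .sensing import BandSet, Measurement, SensingOperator
from .spectral_io import SpectraSet, Spectrum, WavelengthGrid

_BASE_CLASSES = ("water", "vegetation", "soil")


@dataclass
class UPDMBases:
    """The three base spectra on the working grid (columns: water, vegetation, soil)."""

    grid: WavelengthGrid
    water: Spectrum
    vegetation: Spectrum
    soil: Spectrum

    def __post_init__(self) -> None:
        for s in (self.water, self.vegetation, self.soil):
            if s.grid != self.grid:
                raise DimensionError("base spectra must share the working grid")

    @property
    def matrix(self) -> np.ndarray:
        """N x 3 matrix of the base spectra."""
        return np.stack(
            [self.water.reflectance, self.vegetation.reflectance, self.soil.reflectance],
            axis=1,
        )

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix.T @ self.matrix))


@dataclass(frozen=True)
class Fractions:
    """Estimated material fractions (unconstrained unless NNLS was used)."""

    f_water: float
    f_vegetation: float
    f_soil: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_water, self.f_vegetation, self.f_soil])


def extract_bases(labeled: SpectraSet) -> UPDMBases:
    """Base spectra as the per-class mean of labelled pure pixels."""
    if labeled.labels is None:
        raise InputError("labelled spectra required to extract bases")
    means: dict[str, np.ndarray] = {}
    for cls in _BASE_CLASSES:
        rows = [i for i, lab in enumerate(labeled.labels) if lab == cls]
        if rows:
            means[cls] = labeled.values[rows].mean(axis=0)
    missing = [cls for cls in _BASE_CLASSES if cls not in means]
    if missing:
        raise InputError(f"no labelled pixels for class(es): {', '.join(missing)}")
    g = labeled.grid
    return UPDMBases(
        g,
        Spectrum(g, means["water"]),
        Spectrum(g, means["vegetation"]),
        Spectrum(g, means["soil"]),
    )


def updm_decompose(
    meas: Measurement, bases: UPDMBases, nonnegative: bool = False
) -> Fractions:
    """Estimate the water/vegetation/soil fractions from an M-band measurement.

    Default is unconstrained least squares on the M x 3 subsampled-bases
    system; ``nonnegative=True`` switches to NNLS.
    """
    f = _decompose_batch(meas.values[None, :], meas.band_set, bases, nonnegative)[0]
    return Fractions(*f)


def reconstruct_updm(fractions: Fractions, bases: UPDMBases) -> Spectrum:
    """Recompose the full-grid spectrum from the estimated fractions."""
    return Spectrum(bases.grid, bases.matrix @ fractions.as_array())


def reconstruct_updm_set(
    spectra_values: np.ndarray,
    band_set: BandSet,
    bases: UPDMBases,
    nonnegative: bool = False,
) -> np.ndarray:
    """Batched measure-decompose-recompose over a (P, N) array of spectra."""
    Y = SensingOperator(band_set).select(spectra_values)  # P x M
    F = _decompose_batch(Y, band_set, bases, nonnegative)  # P x 3
    return F @ bases.matrix.T


def span_distance(spectrum_values: np.ndarray, bases: UPDMBases) -> float:
    """RMS distance of a spectrum from the span of the bases.

    This is the irreducible UPDM reconstruction error for that spectrum —
    no band set can do better.
    """
    B = bases.matrix
    coef, *_ = np.linalg.lstsq(B, spectrum_values, rcond=None)
    resid = spectrum_values - B @ coef
    return float(np.sqrt(np.mean(resid**2)))


def _decompose_batch(
    Y: np.ndarray, band_set: BandSet, bases: UPDMBases, nonnegative: bool
) -> np.ndarray:
    if band_set.n_bands != bases.grid.n_bands:
        raise DimensionError("band set and bases are on different grids")
    sub = SensingOperator(band_set).select(bases.matrix.T).T  # M x 3
    if band_set.m < 3 and not nonnegative:
        raise InputError(
            f"unconstrained UPDM needs M >= 3 bands, got M={band_set.m}"
        )
    gram = sub.T @ sub
    if np.linalg.cond(gram) > 1e12:
        raise ConditioningError(
            "subsampled base spectra are (near-)collinear at these bands"
        )
    if nonnegative:
        return np.stack([scipy.optimize.nnls(sub, y)[0] for y in Y])
    return np.linalg.solve(gram, sub.T @ Y.T).T
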