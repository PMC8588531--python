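"""Distributed compressive sensing with the JSM-1 joint sparsity model.

A group of J nodes (pixels) is modelled as one *common* spectrum shared by
the whole group plus a per-node *innovation*; both are assumed sparse in the
first-derivative domain, which holds because reflectance spectra are smooth.

Because the first-difference operator annihilates constants, signals are
synthesized as ``x = S·θ`` with ``S = [1 | L]``: an explicit constant column
plus the lower-triangular cumulative-sum matrix, so the non-constant part of
θ *is* the first derivative of x.  Stacking the per-node measurement
equations ``Φ_j S θ_c + Φ_j S θ_j = y_j`` gives one underdetermined system
solved jointly with SL0.

Group-median aggregation (DCS-GM) runs the grouping L times and takes the
per-band median of the L estimates for each pixel, discarding the occasional
bad group estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, InputError
from .sensing import BandSet, Measurement, SensingOperator
from .sparse_solvers import SL0Params, sl0
from .spectral_io import SpectraSet, Spectrum, WavelengthGrid

#: Default number of spectra reconstructed jointly (keeps solve times bounded).
DEFAULT_GROUP_SIZE = 64

#: Default number of independent groupings aggregated by DCS-GM.
DEFAULT_N_GROUPINGS = 5


def difference_matrix(n: int) -> np.ndarray:
    """The (N-1) x N first-difference operator (rows ... -1, +1 ...)."""
    return np.diff(np.eye(n), axis=0)


def synthesis_matrix(n: int) -> np.ndarray:
    """N x N synthesis map S = [constant column | cumulative-sum matrix].

    ``x = S @ theta`` where ``theta[0]`` is the offset and ``theta[1:]`` the
    first differences of x; S is the (completed) inverse of the
    first-difference analysis operator.
    """
    S = np.zeros((n, n))
    S[:, 0] = 1.0
    S[:, 1:] = np.tril(np.ones((n, n - 1)), k=-1)[:, : n - 1]
    return S


@dataclass
class JSM1Problem:
    """One group: per-node band sets and measurements on a shared grid."""

    grid: WavelengthGrid
    measurements: list[Measurement]

    def __post_init__(self) -> None:
        if not self.measurements:
            raise InputError("a JSM-1 problem needs at least one node")
        n = self.grid.n_bands
        for meas in self.measurements:
            if meas.band_set.n_bands != n:
                raise DimensionError("measurement band set does not match the grid")

    @property
    def n_nodes(self) -> int:
        return len(self.measurements)


@dataclass
class JSM1Solution:
    """Common spectrum, per-node innovations, and their sums (the estimates)."""

    common: Spectrum
    innovations: list[Spectrum]

    @property
    def reconstructions(self) -> list[Spectrum]:
        with warnings.catch_warnings():
            # imperfect estimates may dip slightly outside the physical range
            warnings.simplefilter("ignore", UserWarning)
            return [
                Spectrum(self.common.grid, self.common.reflectance + z.reflectance)
                for z in self.innovations
            ]


def build_jsm1_system(problem: JSM1Problem) -> tuple[np.ndarray, np.ndarray]:
    """Stack the per-node equations into one (ΣM_j) x ((J+1)·N) system.

    Unknowns are ordered ``[θ_common; θ_1; ...; θ_J]``.
    """
    n = problem.grid.n_bands
    j_nodes = problem.n_nodes
    S = synthesis_matrix(n)
    rows = sum(m.band_set.m for m in problem.measurements)
    A = np.zeros((rows, (j_nodes + 1) * n))
    y = np.zeros(rows)
    r = 0
    for j, meas in enumerate(problem.measurements):
        phi_s = SensingOperator(meas.band_set).select(S.T).T  # M_j x N
        block = slice(r, r + meas.band_set.m)
        A[block, :n] = phi_s
        A[block, (j + 1) * n : (j + 2) * n] = phi_s
        y[block] = meas.values
        r += meas.band_set.m
    return A, y


def solve_jsm1(problem: JSM1Problem, sl0_params: SL0Params | None = None) -> JSM1Solution:
    """Jointly reconstruct a group with SL0 on the stacked JSM-1 system."""
    A, y = build_jsm1_system(problem)
    theta = sl0(A, y, sl0_params)
    n = problem.grid.n_bands
    S = synthesis_matrix(n)
    with warnings.catch_warnings():
        # innovations are difference signals, not reflectances; the
        # physical-range warning does not apply to them
        warnings.simplefilter("ignore", UserWarning)
        common = Spectrum(problem.grid, S @ theta[:n])
        innovations = [
            Spectrum(problem.grid, S @ theta[(j + 1) * n : (j + 2) * n])
            for j in range(problem.n_nodes)
        ]
    return JSM1Solution(common, innovations)


def group_pixels(
    n_pixels: int, group_size: int = DEFAULT_GROUP_SIZE, seed: int = 0
) -> list[np.ndarray]:
    """Random partition into groups of at most ``group_size`` (last may be smaller)."""
    if n_pixels < 1:
        raise InputError("cannot group an empty pixel set")
    if group_size < 1:
        raise InputError("group_size must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_pixels)
    return [order[i : i + group_size] for i in range(0, n_pixels, group_size)]


def reconstruct_dcs_set(
    spectra_values: np.ndarray,
    band_sets: list[BandSet],
    group_size: int = DEFAULT_GROUP_SIZE,
    grouping_seed: int = 0,
    grid: WavelengthGrid | None = None,
    sl0_params: SL0Params | None = None,
) -> np.ndarray:
    """DCS reconstruction of a whole pixel set (one grouping pass).

    ``band_sets`` holds one (heterogeneous) band set per pixel; pixels are
    partitioned into groups of ``group_size`` and each group is solved
    jointly.  Returns the (P, N) estimates.
    """
    p, n = spectra_values.shape
    if len(band_sets) != p:
        raise DimensionError("need one band set per pixel")
    if grid is None:
        raise InputError("a wavelength grid is required")
    out = np.empty((p, n))
    for group in group_pixels(p, group_size, grouping_seed):
        measurements = [
            Measurement(band_sets[i], SensingOperator(band_sets[i]).select(spectra_values[i]))
            for i in group
        ]
        solution = solve_jsm1(JSM1Problem(grid, measurements), sl0_params)
        for local, i in enumerate(group):
            out[i] = solution.reconstructions[local].reflectance
    return out


def dcs_gm(estimates: np.ndarray) -> np.ndarray:
    """Per-band median across L independent estimates of the same pixels.

    ``estimates`` has shape (L, P, N) (or (L, N) for a single pixel); the
    median is taken over the first axis, with even L averaging the two
    central values (the numpy convention).
    """
    estimates = np.asarray(estimates, dtype=float)
    if estimates.ndim not in (2, 3):
        raise DimensionError("estimates must be (L, N) or (L, P, N)")
    return np.median(estimates, axis=0)


def check_consistency(solution: JSM1Solution, problem: JSM1Problem) -> float:
    """Max over nodes of the ∞-norm measurement mismatch (diagnostics)."""
    worst = 0.0
    for meas, rec in zip(problem.measurements, solution.reconstructions):
        predicted = SensingOperator(meas.band_set).select(rec.reflectance)
        worst = max(worst, float(np.max(np.abs(predicted - meas.values))))
    return worst
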