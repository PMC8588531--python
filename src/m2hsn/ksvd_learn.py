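"""K-SVD dictionary learning and dictionary-based spectrum reconstruction.

This is the core of the homogeneous network: a small dictionary of unit-norm
"atom" spectra is learned from high-resolution training spectra, and each
node's few-band measurement is then lifted back to the full grid by sparse
recovery in that dictionary (SL0 on the subsampled dictionary ΦD).

Training alternates two steps until convergence: (1) sparse-code every
training spectrum with OMP at sparsity target T; (2) update each atom (and
the coefficients using it) with the leading singular pair of the residual
restricted to the spectra that use the atom.  Atoms that end up unused are
replaced by the currently worst-represented training spectrum.

The default sparsity target follows the 10%-of-bands rule, capped at the
dictionary size: ``T = min(K, max(1, round(0.10 N)))``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DimensionError, InputError
from .sensing import BandSet, Measurement, SensingOperator
from .sparse_solvers import SL0Params, omp_batch, sl0
from .spectral_io import SpectraSet, Spectrum, WavelengthGrid


def default_sparsity_target(n_bands: int, dictionary_size: int) -> int:
    """The 10 %-of-bands rule, floored at 1 and capped at the dictionary size."""
    if n_bands < 1 or dictionary_size < 1:
        raise InputError("need N >= 1 and K >= 1")
    return min(dictionary_size, max(1, round(0.10 * n_bands)))


@dataclass
class Dictionary:
    """K unit-norm atoms of length N, with the training configuration."""

    grid: WavelengthGrid
    atoms: np.ndarray  # N x K, unit-norm columns
    sparsity_target: int
    n_iterations: int = 0
    seed: int | None = None
    training_fingerprint: dict = field(default_factory=dict)
    residual_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.atoms, dtype=float)
        if a.ndim != 2 or a.shape[0] != self.grid.n_bands:
            raise DimensionError(f"atoms shape {a.shape} incompatible with grid")
        self.atoms = a
        if not 1 <= self.sparsity_target <= self.k:
            raise InputError("need 1 <= T <= K")

    @property
    def k(self) -> int:
        return int(self.atoms.shape[1])

    def to_spectra_set(self) -> SpectraSet:
        return SpectraSet(
            self.grid, self.atoms.T, ids=[f"atom_{i}" for i in range(self.k)]
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "wavelengths_nm": self.grid.wavelengths_nm.tolist(),
            "atoms": self.atoms.tolist(),
            "sparsity_target": self.sparsity_target,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "training_fingerprint": self.training_fingerprint,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "Dictionary":
        payload = json.loads(Path(path).read_text())
        return cls(
            WavelengthGrid(np.array(payload["wavelengths_nm"])),
            np.array(payload["atoms"]),
            payload["sparsity_target"],
            n_iterations=payload.get("n_iterations", 0),
            seed=payload.get("seed"),
            training_fingerprint=payload.get("training_fingerprint", {}),
        )


def _canonical_sign(atoms: np.ndarray) -> np.ndarray:
    """Flip each atom so its largest-magnitude entry is positive."""
    peaks = atoms[np.abs(atoms).argmax(axis=0), np.arange(atoms.shape[1])]
    signs = np.where(peaks < 0, -1.0, 1.0)
    return atoms * signs


def _duplicate_atoms(atoms: np.ndarray, coherence: float = 0.999) -> list[int]:
    """Indices of atoms nearly collinear with an earlier atom."""
    gram = np.abs(atoms.T @ atoms)
    dup = []
    for j in range(1, atoms.shape[1]):
        if np.any(gram[j, :j] > coherence):
            dup.append(j)
    return dup


def _init_atoms(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded initialization from K distinct training spectra, normalized."""
    n_samples = X.shape[1]
    order = rng.permutation(n_samples)
    atoms = X[:, order[:k]].copy()
    norms = np.linalg.norm(atoms, axis=0)
    # skip any zero spectra that slipped into the draw
    pos = k
    for j in np.flatnonzero(norms == 0):
        while pos < n_samples and np.linalg.norm(X[:, order[pos]]) == 0:
            pos += 1
        if pos >= n_samples:
            raise InputError("not enough nonzero training spectra to seed atoms")
        atoms[:, j] = X[:, order[pos]]
        pos += 1
    atoms /= np.linalg.norm(atoms, axis=0)
    return _canonical_sign(atoms)


def train_dictionary(
    train: SpectraSet,
    dictionary_size: int,
    sparsity_target: int | None = None,
    n_iterations: int = 20,
    seed: int = 0,
    early_stop_rel: float = 1e-5,
) -> Dictionary:
    """Learn a K-atom dictionary from training spectra with K-SVD.

    Runs exactly ``n_iterations`` sweeps or stops early once the relative
    improvement of the coding residual falls below ``early_stop_rel``.
    Deterministic for a fixed (train, K, T, n_iterations, seed).
    """
    X = train.values.T  # N x P
    n, p = X.shape
    if not np.any(np.linalg.norm(X, axis=0) > 0):
        raise InputError("training set contains only zero spectra")
    k = dictionary_size
    if p < k:
        warnings.warn(f"only {p} training spectra; reducing K from {k} to {p}", stacklevel=2)
        k = p
    T = sparsity_target if sparsity_target is not None else default_sparsity_target(n, k)
    if T > k:
        raise InputError(f"sparsity target {T} exceeds dictionary size {k}")

    rng = np.random.default_rng(seed)
    atoms = _init_atoms(X, k, rng)
    history: list[float] = []
    gamma: np.ndarray | None = None
    for _ in range(n_iterations):
        # --- sparse coding; the carried-over code is kept wherever fresh OMP
        #     would regress, so the objective cannot increase
        gamma_new = omp_batch(atoms, X, T)  # K x P
        if gamma is None:
            gamma = gamma_new
        else:
            err_new = np.linalg.norm(X - atoms @ gamma_new, axis=0)
            err_old = np.linalg.norm(X - atoms @ gamma, axis=0)
            keep_new = err_new <= err_old
            gamma = np.where(keep_new[None, :], gamma_new, gamma)
        err = float(np.linalg.norm(X - atoms @ gamma))

        # --- clear near-duplicate atoms (the classic absorbing local minimum):
        #     try replacing them with the worst-represented samples, but keep
        #     the cleared dictionary only when it actually lowers the objective
        dup = _duplicate_atoms(atoms)
        if dup:
            atoms_c = atoms.copy()
            sample_errs = np.linalg.norm(X - atoms @ gamma, axis=0)
            worst = np.argsort(-sample_errs)
            for slot, j in enumerate(dup):
                candidate = X[:, worst[slot % worst.size]]
                norm = np.linalg.norm(candidate)
                if norm > 0:
                    atoms_c[:, j] = candidate / norm
            atoms_c = _canonical_sign(atoms_c)
            gamma_c = omp_batch(atoms_c, X, T)
            err_c = float(np.linalg.norm(X - atoms_c @ gamma_c))
            if err_c < err:
                atoms, gamma, err = atoms_c, gamma_c, err_c
        if history and (history[-1] - err) < early_stop_rel * max(history[-1], 1e-300):
            history.append(err)
            break
        history.append(err)

        # --- atom update (one SVD per atom, coefficients updated in place)
        for j in range(k):
            users = np.flatnonzero(gamma[j] != 0)
            if users.size == 0:
                # revive dead atom with the worst-represented sample;
                # its coefficients are zero, so the residual is unchanged
                errs = np.linalg.norm(X - atoms @ gamma, axis=0)
                candidate = X[:, int(np.argmax(errs))]
                norm = np.linalg.norm(candidate)
                if norm > 0:
                    atoms[:, j] = candidate / norm
                continue
            # residual without atom j's contribution, restricted to its users
            Ej = X[:, users] - atoms @ gamma[:, users] + np.outer(atoms[:, j], gamma[j, users])
            U, s, Vt = np.linalg.svd(Ej, full_matrices=False)
            atom = U[:, 0]
            coefs = s[0] * Vt[0]
            if atom[np.abs(atom).argmax()] < 0:  # canonical sign, product unchanged
                atom, coefs = -atom, -coefs
            atoms[:, j] = atom
            gamma[j, users] = coefs
    if gamma is not None:
        history.append(float(np.linalg.norm(X - atoms @ gamma)))

    return Dictionary(
        train.grid,
        atoms,
        T,
        n_iterations=n_iterations,
        seed=seed,
        training_fingerprint={"n_spectra": p, "n_bands": n, "k": k},
        residual_history=history,
    )


def reconstruct_ksvd(
    meas: Measurement,
    dictionary: Dictionary,
    sl0_params: SL0Params | None = None,
) -> Spectrum:
    """Reconstruct one spectrum from a multispectral measurement.

    Solves the subsampled system (ΦD)·α = y with SL0 and synthesizes D·α.
    """
    alpha = _solve_codes(meas.band_set, meas.values[:, None], dictionary, sl0_params)
    return Spectrum(dictionary.grid, dictionary.atoms @ alpha[:, 0])


def reconstruct_ksvd_set(
    spectra_values: np.ndarray,
    band_set: BandSet,
    dictionary: Dictionary,
    sl0_params: SL0Params | None = None,
) -> np.ndarray:
    """Batched reconstruction: measure every row of a (P, N) array at
    ``band_set`` and reconstruct; returns the (P, N) estimates."""
    Y = SensingOperator(band_set).select(spectra_values).T  # M x P
    alpha = _solve_codes(band_set, Y, dictionary, sl0_params)
    return (dictionary.atoms @ alpha).T


def _solve_codes(
    band_set: BandSet,
    Y: np.ndarray,
    dictionary: Dictionary,
    sl0_params: SL0Params | None,
) -> np.ndarray:
    if band_set.n_bands != dictionary.grid.n_bands:
        raise DimensionError("band set and dictionary are on different grids")
    if band_set.m < 1:
        raise InputError("need at least one measured band")
    if dictionary.k == band_set.m:
        warnings.warn(
            "dictionary size equals the number of measured bands: SL0 reduces "
            "to the l2 solution and reconstruction quality degrades",
            stacklevel=3,
        )
    sub = SensingOperator(band_set).select(dictionary.atoms.T).T  # M x K
    return np.atleast_2d(sl0(sub, Y, sl0_params))
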