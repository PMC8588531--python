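"""Synthetic hyperspectral scenes for vegetation monitoring experiments.

Field and airborne reflectance campaigns are rarely redistributable, so the
toolkit ships a generator that reproduces the statistical structure the
reconstruction methods rely on:

* vegetation spectra with a logistic red edge near 700 nm (low red
  reflectance, high NIR plateau) plus a small green-peak bump,
* smooth, slowly increasing bare-soil spectra,
* dark, slightly decreasing water spectra,
* occasional "built-up" anomaly pixels with a random smooth broadband shape.

All spectra are smooth, hence sparse under a first-difference transform —
the assumption the JSM-1 solver exploits — and vegetation-dominated scenes
give dictionary learning its red-edge-dominated atoms.

Scenes are laid out as rectangular land-use patches.  Every random draw is
keyed on ``(seed, purpose, pixel index)`` so a given pixel renders with the
same endmember parameters on *any* wavelength grid; this is what lets
:func:`make_splits` emulate a two-sensor campaign by rendering the evaluation
split on a denser grid and resampling it onto the working grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import InputError, SizeError
from .spectral_io import Cube, SpectraSet, WavelengthGrid, default_grid, resample_to_grid

CLASSES = ("vegetation", "soil", "water", "builtup")


# ---------------------------------------------------------------------------
# endmember models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VegetationParams:
    """Logistic red-edge model: visible floor rising to a NIR plateau.

    ``red_edge_nm`` is the inflection wavelength, ``red_edge_width_nm`` the
    logistic scale; the green peak is a Gaussian bump at 550 nm.
    """

    visible_level: float = 0.05
    green_peak_amplitude: float = 0.03
    red_edge_nm: float = 700.0
    red_edge_width_nm: float = 15.0
    nir_plateau: float = 0.50

    cls = "vegetation"

    def evaluate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        lam = wavelengths_nm
        edge = 1.0 / (1.0 + np.exp(-(lam - self.red_edge_nm) / self.red_edge_width_nm))
        green = self.green_peak_amplitude * np.exp(-0.5 * ((lam - 550.0) / 25.0) ** 2)
        return self.visible_level + green + (self.nir_plateau - self.visible_level) * edge

    def jittered(self, rng: np.random.Generator, scale: float) -> "VegetationParams":
        return replace(
            self,
            visible_level=self.visible_level * (1 + scale * rng.standard_normal()),
            green_peak_amplitude=self.green_peak_amplitude * (1 + scale * rng.standard_normal()),
            red_edge_nm=self.red_edge_nm + 40.0 * scale * rng.standard_normal(),
            nir_plateau=self.nir_plateau * (1 + scale * rng.standard_normal()),
        )


@dataclass(frozen=True)
class SoilParams:
    """Smooth bare-soil curve: linear increase with wavelength."""

    intercept: float = 0.10
    slope: float = 0.25  # total rise over the 406-1100 nm span

    cls = "soil"

    def evaluate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        t = (wavelengths_nm - 406.0) / (1100.0 - 406.0)
        return self.intercept + self.slope * t

    def jittered(self, rng: np.random.Generator, scale: float) -> "SoilParams":
        return replace(
            self,
            intercept=self.intercept * (1 + scale * rng.standard_normal()),
            slope=self.slope * (1 + scale * rng.standard_normal()),
        )


@dataclass(frozen=True)
class WaterParams:
    """Dark water: low reflectance slowly decreasing into the NIR."""

    level: float = 0.06
    decay_nm: float = 500.0

    cls = "water"

    def evaluate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        return self.level * np.exp(-(wavelengths_nm - 406.0) / self.decay_nm)

    def jittered(self, rng: np.random.Generator, scale: float) -> "WaterParams":
        return replace(self, level=self.level * (1 + scale * rng.standard_normal()))


@dataclass(frozen=True)
class BuiltupParams:
    """Anomaly pixels: a random smooth broadband curve (roofs, roads, walls).

    The shape is a low-order cosine series keyed on ``shape_seed`` so the
    endmember itself is deterministic.
    """

    base_level: float = 0.30
    variation: float = 0.10
    n_harmonics: int = 3
    shape_seed: int = 0

    cls = "builtup"

    def evaluate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.shape_seed)
        t = (wavelengths_nm - 406.0) / (1100.0 - 406.0)
        out = np.full_like(t, self.base_level, dtype=float)
        for h in range(1, self.n_harmonics + 1):
            amp = self.variation * rng.standard_normal() / h
            phase = rng.uniform(0, 2 * np.pi)
            out += amp * np.cos(np.pi * h * t + phase)
        return out

    def jittered(self, rng: np.random.Generator, scale: float) -> "BuiltupParams":
        return replace(
            self,
            base_level=self.base_level * (1 + scale * rng.standard_normal()),
            shape_seed=int(rng.integers(0, 2**31 - 1)),
        )


EndmemberParams = VegetationParams | SoilParams | WaterParams | BuiltupParams

DEFAULT_ENDMEMBERS: dict[str, EndmemberParams] = {
    "vegetation": VegetationParams(),
    "soil": SoilParams(),
    "water": WaterParams(),
    "builtup": BuiltupParams(),
}


def make_endmember(params: EndmemberParams, grid: WavelengthGrid):
    """Evaluate an endmember model on a grid, clamping to physical [0, 1]."""
    from .spectral_io import Spectrum

    r = params.evaluate(grid.wavelengths_nm)
    if r.min() < 0 or r.max() > 1:
        import warnings

        warnings.warn(f"{params.cls} endmember clamped to [0, 1]", stacklevel=2)
        r = np.clip(r, 0.0, 1.0)
    return Spectrum(grid, r)


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Layout and noise model of a synthetic scene.

    ``class_weights`` govern the patch-level land-use draw; ``jitter_scale``
    is the relative sd of per-pixel endmember-parameter perturbations;
    ``noise_sd`` is additive Gaussian noise in reflectance units.
    """

    grid: WavelengthGrid = field(default_factory=default_grid)
    rows: int = 32
    cols: int = 32
    patch_size: int = 8
    class_weights: dict[str, float] = field(
        default_factory=lambda: {"vegetation": 0.6, "soil": 0.25, "water": 0.15}
    )
    endmembers: dict[str, EndmemberParams] = field(
        default_factory=lambda: dict(DEFAULT_ENDMEMBERS)
    )
    jitter_scale: float = 0.05
    noise_sd: float = 0.005
    anomaly_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.patch_size < 1:
            raise InputError("rows, cols and patch_size must be positive")
        if not 0.0 <= self.anomaly_fraction <= 1.0:
            raise InputError("anomaly_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        total = sum(self.class_weights.values())
        if total <= 0:
            raise InputError("class weights must sum to a positive value")
        self.class_weights = {k: v / total for k, v in self.class_weights.items()}


def _class_map(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Rectangular-patch land-use layout."""
    names = list(config.class_weights)
    probs = np.array([config.class_weights[n] for n in names])
    n_pr = -(-config.rows // config.patch_size)
    n_pc = -(-config.cols // config.patch_size)
    patch_cls = rng.choice(len(names), size=(n_pr, n_pc), p=probs)
    full = np.repeat(np.repeat(patch_cls, config.patch_size, 0), config.patch_size, 1)
    return np.array(names, dtype=object)[full[: config.rows, : config.cols]]


def _pixel_rng(seed: int, purpose: int, pixel: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, purpose, pixel]))


def _render_pixel(
    config: SceneConfig, cls: str, pixel: int, grid: WavelengthGrid
) -> np.ndarray:
    """Jittered endmember + noise; draws depend only on (seed, pixel), not the grid."""
    base = config.endmembers[cls]
    if config.jitter_scale > 0:
        base = base.jittered(_pixel_rng(config.seed, 1, pixel), config.jitter_scale)
    r = np.clip(base.evaluate(grid.wavelengths_nm), 0.0, 1.0)
    if config.noise_sd > 0:
        noise_rng = _pixel_rng(config.seed, 2, pixel)
        r = r + config.noise_sd * noise_rng.standard_normal(grid.n_bands)
    return np.clip(r, 0.0, 1.0)


def _anomaly_pixels(config: SceneConfig) -> np.ndarray:
    n_pixels = config.rows * config.cols
    n_anom = int(round(config.anomaly_fraction * n_pixels))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    return rng.choice(n_pixels, size=n_anom, replace=False)


def make_scene(config: SceneConfig, grid: WavelengthGrid | None = None) -> Cube:
    """Generate a labelled scene cube; identical config (and seed) ⇒ identical cube."""
    grid = grid or config.grid
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    labels = _class_map(config, rng)
    flat_labels = labels.ravel().copy()
    for p in _anomaly_pixels(config):
        flat_labels[p] = "builtup"
    values = np.empty((config.rows * config.cols, grid.n_bands))
    for p, cls in enumerate(flat_labels):
        values[p] = _render_pixel(config, cls, p, grid)
    return Cube(
        grid,
        values.reshape(config.rows, config.cols, grid.n_bands),
        labels=flat_labels.reshape(config.rows, config.cols),
    )


def make_splits(
    config: SceneConfig,
    sizes: dict[str, int],
    seed: int | None = None,
    eval_upsample: int = 8,
    max_gap_nm: float = 25.0,
) -> dict[str, SpectraSet]:
    """Split one scene into disjoint ``train`` / ``band_select`` / ``eval`` sets.

    The evaluation split mimics data from a *different, denser sensor*: its
    pixels are rendered on a grid ``eval_upsample`` times finer and then
    passed through nearest-band resampling onto the working grid, exactly as
    a ground spectrometer would be matched to airborne bands.
    """
    roles = ("train", "band_select", "eval")
    if set(sizes) != set(roles):
        raise InputError(f"sizes must specify exactly the roles {roles}")
    if seed is not None:
        config = replace(config, seed=seed)
    n_pixels = config.rows * config.cols
    total = sum(sizes.values())
    if total > n_pixels:
        raise SizeError(f"requested {total} pixels from a {n_pixels}-pixel scene")

    scene = make_scene(config)
    flat = scene.to_spectra_set()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    order = rng.permutation(n_pixels)
    splits: dict[str, SpectraSet] = {}
    start = 0
    w = config.grid.wavelengths_nm
    dense = WavelengthGrid(np.linspace(w[0], w[-1], config.grid.n_bands * eval_upsample))
    for role in roles:
        index = order[start : start + sizes[role]]
        start += sizes[role]
        if role == "eval":
            values = np.empty((index.size, dense.n_bands))
            for i, p in enumerate(index):
                values[i] = _render_pixel(config, flat.labels[p], int(p), dense)
            dense_set = SpectraSet(
                dense,
                values,
                coords=flat.coords[index],
                labels=[flat.labels[p] for p in index],
            )
            splits[role] = resample_to_grid(dense_set, config.grid, max_gap_nm=max_gap_nm)
        else:
            splits[role] = flat.subset(index)
    return splits


def class_subset(spectra: SpectraSet, classes: Iterable[str]) -> SpectraSet:
    """Pixels whose label is in ``classes`` (labels required)."""
    if spectra.labels is None:
        raise InputError("SpectraSet has no class labels")
    wanted = set(classes)
    index = np.array([i for i, lab in enumerate(spectra.labels) if lab in wanted], dtype=int)
    return spectra.subset(index)
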