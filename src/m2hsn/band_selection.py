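"""Best-band-set selection by rejection (the "-BBS" variants).

Rather than optimizing band positions, a handful of random candidate band
sets is scored on a held-out selection split (median per-pixel reconstruction
RMSE) and the worst are rejected.  Scores transfer between datasets well
enough to discard the bad sets, even though fine ranking among the good sets
is unstable — which is precisely why only rejection, not optimization, is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .errors import InputError
from .ksvd_learn import Dictionary, reconstruct_ksvd_set
from .sensing import BandSet, random_band_set
from .sparse_solvers import SL0Params
from .spectral_io import SpectraSet
from .updm import UPDMBases, reconstruct_updm_set

#: Candidate pool size and number of sets kept, the toolkit defaults.
DEFAULT_N_CANDIDATES = 20
DEFAULT_KEEP = 3


@dataclass(frozen=True)
class BandSetScore:
    """Median per-pixel RMSE of one candidate band set on the selection split."""

    band_set: BandSet
    median_rmse: float
    method: str  # "ksvd" | "updm"

    def __post_init__(self) -> None:
        if self.median_rmse < 0:
            raise InputError("median RMSE cannot be negative")


def reconstruct_with(
    context: Dictionary | UPDMBases,
    values: np.ndarray,
    band_set: BandSet,
    sl0_params: SL0Params | None = None,
) -> np.ndarray:
    """Dispatch batched reconstruction for a method context."""
    if isinstance(context, Dictionary):
        return reconstruct_ksvd_set(values, band_set, context, sl0_params)
    if isinstance(context, UPDMBases):
        return reconstruct_updm_set(values, band_set, context)
    raise InputError(f"unsupported method context: {type(context).__name__}")


def score_band_sets(
    candidates: list[BandSet],
    context: Dictionary | UPDMBases,
    selection_set: SpectraSet,
    sl0_params: SL0Params | None = None,
) -> list[BandSetScore]:
    """Score every candidate (median per-pixel RMSE), sorted ascending.

    Ties break by lexicographic band-index order for determinism.
    """
    if not candidates:
        raise InputError("no candidate band sets")
    if len(selection_set) == 0:
        raise InputError("empty selection set")
    method = "ksvd" if isinstance(context, Dictionary) else "updm"
    scores = []
    for cand in candidates:
        est = reconstruct_with(context, selection_set.values, cand, sl0_params)
        per_pixel = np.sqrt(np.mean((est - selection_set.values) ** 2, axis=1))
        scores.append(BandSetScore(cand, float(np.median(per_pixel)), method))
    return sorted(scores, key=lambda s: (s.median_rmse, s.band_set.sort_key()))


def select_best(scores: list[BandSetScore], keep: int = DEFAULT_KEEP) -> list[BandSet]:
    """The ``keep`` lowest-RMSE band sets (scores are already sorted)."""
    if keep < 1:
        raise InputError("keep must be >= 1")
    if keep > len(scores):
        warnings.warn(
            f"asked to keep {keep} of {len(scores)} scored sets; returning all",
            stacklevel=2,
        )
    ranked = sorted(scores, key=lambda s: (s.median_rmse, s.band_set.sort_key()))
    return [s.band_set for s in ranked[:keep]]


def candidate_band_sets(
    n_bands: int, m: int, n_candidates: int = DEFAULT_N_CANDIDATES, seed: int = 0
) -> list[BandSet]:
    """A seeded pool of random candidate band sets (one sub-seed each)."""
    root = np.random.SeedSequence(seed)
    return [
        random_band_set(n_bands, m, int(child.generate_state(1)[0] % 2**31))
        for child in root.spawn(n_candidates)
    ]


def scores_to_table(scores: list[BandSetScore], wavelengths_nm: np.ndarray):
    """Score table (rank, band indices, wavelengths, median RMSE) as a DataFrame."""
    import pandas as pd

    rows = []
    for rank, s in enumerate(scores):
        rows.append(
            {
                "rank": rank,
                "method": s.method,
                "band_indices": " ".join(map(str, s.band_set.indices)),
                "wavelengths_nm": " ".join(
                    f"{wavelengths_nm[i]:.1f}" for i in s.band_set.indices
                ),
                "median_rmse": s.median_rmse,
            }
        )
    return pd.DataFrame(rows)
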