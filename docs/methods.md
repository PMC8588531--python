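# Methods

## Problem setting

A multispectral sensor node measures M point-sampled bands of an N-band
reflectance spectrum on a shared wavelength grid (default: 40 evenly spaced
bands over 406–1100 nm, the intersection of typical airborne and hand-held
sensor coverage; both the band count and the range are configurable).  The
sensing operator Φ is pure row selection — no filter-transmission
integration — so the measurement model is identical for every method and
noiseless by construction; sensor noise lives in the data generator.
Reconstruction means estimating all N bands from the M measured ones.

## K-SVD dictionary learning (the homogeneous-network core)

Training spectra X ∈ ℝ^(N×P) are approximated as X ≈ DΓ with D ∈ ℝ^(N×K)
unit-norm atoms and each column of Γ at most T-sparse.  Iterations alternate:

1. **Sparse coding** — OMP per training spectrum (greedy max-correlation
   selection, least-squares refit each step, stop at T atoms or residual
   < 1e-12).  The fresh OMP code is kept only where it does not regress
   against the carried-over code from the previous iteration, which makes
   the training objective non-increasing *by construction* (plain OMP alone
   does not guarantee this, being greedy rather than optimal).
2. **Atom update** — for each atom, the rank-1 SVD of the residual restricted
   to the spectra using it replaces the atom and its coefficients; sign is
   canonicalized (largest-magnitude entry positive) with the coefficient row
   flipped in tandem so the product is unchanged.  Unused atoms are replaced
   by the worst-represented training spectrum (cost-free: their coefficients
   are zero).  Near-duplicate atoms (pairwise coherence > 0.999) — the
   classic absorbing local minimum in which two atoms capture one cluster
   and another cluster goes unrepresented — are tentatively replaced by the
   worst-represented samples; the cleared dictionary is kept only if it
   lowers the objective, preserving monotonicity.

Defaults: 20 iterations with early stop when the relative residual
improvement drops below 1e-5; initialization from K distinct training
spectra chosen by the seed (standard practice for smooth spectra, and it
makes runs bit-reproducible); sparsity target T = min(K, max(1,
round(0.1·N))) — the 10 %-of-bands rule, capped at the dictionary size.

Reconstruction solves (ΦD)α = y with SL0 and synthesizes Dα.  When K equals
M the subsampled dictionary is square: the constraint set is a single point,
no sparsification is possible, and the solver returns the least-squares
solution (the implementation warns, because reconstruction quality visibly
degrades in exactly this configuration).

## SL0

The smoothed-ℓ0 solver maximises Σᵢ exp(−xᵢ²/2σ²) over {x : Ax = y},
annealing σ from 2·max|A⁺y| downward by a factor 0.5 with 3 gradient steps
(step size μ = 2) and a projection back onto the constraint per σ level,
down to σ_min = 1e-4.  Two implementation choices matter:

- **Overdetermined systems** (M ≥ K) return the least-squares solution
  directly — the constraint set is a point or empty, so iterating is
  meaningless.  This also realises the square-dictionary collapse above
  *exactly*.
- **Debias refit.** The annealed iterate occasionally carries sizeable
  spurious entries (a shallow local maximum of the smoothed objective).  A
  final pass ranks entries by magnitude and refits, by least squares, the
  smallest top-ranked support that reproduces y exactly (relative residual
  < 1e-9, support capped at M−1); if no strictly sparse support is exactly
  consistent — the generic case for noisy field data — the iterate is
  returned untouched.  On exactly sparse instances (M=8, K=16 Gaussian,
  sparsity ≤ 2) this raises support agreement with an exhaustive ℓ0 oracle
  from ≈ 85–92 % to ≈ 94–96 %; slower annealing schedules were measured
  *worse* (they converge more firmly to the wrong maximum), which is why the
  fast schedule stays the default.

Support is reported at a relative threshold of 1e-6 of the largest
coefficient.

## DCS with JSM-1

Heterogeneous groups of G = 64 pixels are modelled as x_j = common +
innovation_j, all sparse in the first-derivative domain (reflectance spectra
are smooth).  Because the first-difference operator annihilates constants,
signals are synthesized as x = Sθ with S = [1 | L] (constant column plus the
cumulative-sum matrix); the offset is thus an explicit coefficient.  The
stacked system over a group — (ΣM_j) rows, (J+1)·N unknowns, common and
innovation parts weighted equally — is solved with SL0.  For a single-node
group the common/innovation split of the offset is not identifiable (only
their sum is); reconstructions are unaffected.

DCS-GM repeats the grouping L = 5 times and takes the per-band median of the
L estimates per pixel, which discards the occasional bad group estimate.  In
the experiment driver the R = 20 DCS replications are structured as 5 group
selections × 4 band-set selections, so DCS-GM produces 4 median spectra of 5
estimates each per pixel; plain DCS statistics use all 20 runs.

A structural limitation worth stating: with *homogeneous* band sets the
joint model cannot determine unmeasured bands no matter how many nodes
participate (the test suite asserts this) — that regime is what the learned
dictionary is for.

## UPDM

Measurements are unmixed over the band-subsampled water/vegetation/soil base
spectra by unconstrained least squares (M ≥ 3 required; NNLS available
behind a flag — the literature varies on the constraints and the
unconstrained reading is the simplest; sum-to-one is not imposed).  Base
spectra are per-class means of labelled pure pixels — deterministic and
noise-robust; a single-pixel mode would be equivalent for noiseless data.
UPDM is exact for spectra in the span of the bases and floor-limited by the
distance to that span for everything else (built-up anomalies), which is the
mechanism behind its weakness on mixed scenes.

## Band selection by rejection (BBS)

R = 20 random candidate band sets are scored on a held-out split by the
median per-pixel reconstruction RMSE (single scoring pass per candidate —
cheaper than a nested replication and the same ranking logic); the best 3
are kept.  Ties break lexicographically on band indices for determinism.
Scores transfer across datasets asymmetrically: the worst sets are rejected
reliably, while fine ranking among the good sets is unstable — the test
suite asserts only the rejection half, by design.  No genetic or greedy band
optimizer is provided; rejection captures most of the benefit at a fraction
of the tuning surface.

## Evaluation protocol

Per-pixel RMSE over all N bands (measured bands included; an unmeasured-only
flag exists for diagnostics), median across pixels per replication, median
of the R replication medians.  Box statistics follow the Tukey convention;
outliers are suppressed in the plots but retained in the data export.
Pooled per-pixel distributions keep replication metadata so either pooled or
per-replication boxes can be rendered.

## Synthetic scenes

The generator reproduces the statistical structure the methods rely on, not
radiative-transfer physics:

- vegetation: visible floor 0.05, Gaussian green peak (amplitude 0.03 at
  550 nm), logistic red edge centred at 700 nm (width 15 nm), NIR plateau
  0.50 — NDVI ≈ 0.65 and > 98 % of first-difference energy within the 20 % of
  bands nearest the red edge;
- soil: linear rise 0.10 → 0.35 (NDVI ≈ 0.10); water: 0.06 decaying into the
  NIR; built-up anomalies: seeded low-order cosine series around 0.30;
- land use laid out as rectangular patches (default 8×8) with weights
  0.6/0.25/0.15 vegetation/soil/water; per-pixel parameter jitter (relative
  sd 0.05) and additive Gaussian noise (sd 0.005 reflectance — small enough
  to keep exact-recovery tests meaningful, large enough to set a realistic
  noise floor);
- every per-pixel draw is keyed on (seed, purpose, pixel), so the same pixel
  renders consistently on any grid; the evaluation split is rendered on an
  8× denser grid and nearest-band resampled (ties to the lower wavelength)
  onto the working grid, emulating a second sensor.

What passing tests on these scenes do **not** show: behaviour under
atmospheric or illumination effects, real canopy bidirectional effects,
sensor-specific filter shapes, or train/eval distribution shift beyond the
two-sensor band mismatch — pixel populations across splits are otherwise
identically distributed, which flatters memorization-style large
dictionaries relative to diverse field data.  For the dictionary-size
comparisons the training split is therefore drawn large (2000 pixels) from a
mixed scene with 5 % built-up anomalies, the regime in which a handful of
anomaly training pixels visibly drags down large dictionaries while K = 4
stays clean.

## Problem sizes used by the test suite and acceptance script

Benchmarks run at N = 40 bands: a vegetation scene with 400/200/500
train/select/eval pixels for the design-target check (KSVD-BBS at M = 8,
K = 8 reaching median RMSE ≤ 0.03), and a mixed 80×80 scene with
2000/256/2000 pixels for the method-ordering checks; the acceptance script
uses a 48×48 mixed scene with 1024/256/512 pixels.  These sizes were chosen
so a complete run of the method comparison, including the joint DCS solves,
stays in the minutes range on one CPU while every ordering it asserts is
stable to the replication seeds.

## Known limitations

- Greedy OMP misses the ℓ0-optimal support on a few percent of small
  Gaussian 2-sparse instances (our implementation matches
  scikit-learn's `orthogonal_mp` case for case); this is intrinsic to the
  algorithm, not fixable by parameters.
- The SL0 debias pass only helps on exactly sparse instances; noisy
  reconstructions inherit plain SL0 behaviour.
- ENVI support covers BSQ/BIL with float32/float64/uint16 (+scale) dialects
  only; no georeferencing, no GeoTIFF, no atmospheric correction.
- UPDM carries no normalization constants beyond the three base spectra;
  additional endmembers are out of scope.
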