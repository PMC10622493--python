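# Methods

## Pipeline overview

`mfspec` turns an absorbance spectrum into one scalar in four stages:

1. **Ingest** (`spectra_io`): two-column CSV or a JCAMP-DX subset
   (single-block AFFN `XYDATA`/`XYPOINTS`); wavenumbers stored descending
   (4000 → 650 cm⁻¹), strict monotonicity and finiteness enforced.
2. **Rasterize** (`rasterize`): amplitude normalization to [0, 1], then an
   axis-free render — wavenumber → column, absorbance → row
   (`row = floor((1−a)·(height−1) + 0.5)`, ties toward the top), dark 1-px
   polyline on white, consecutive columns joined by vertical runs —
   followed by thresholding to a binary mask.
3. **Estimate** (`mfa`): box-counting multifractal spectrum of the mask's
   mass distribution.
4. **Summarize** (`summary`): reduce to the multifractal number and run the
   experiment templates (group comparison, concentration invariance,
   dose response).

## Estimator

At each box edge ε the image is tiled from the grid origin; partial boxes
at the far edges are included (their mass counts — discarding them biases
the capacity dimension upward, by ~0.6 on trace images, because the box
population loses its deficit members). Occupied-box masses are normalized
to probabilities P_i(ε); empty boxes are excluded everywhere, which is
required for negative moments to exist. All moment sums are computed in log
space (`logsumexp`), so the full Q ∈ [−10, 10] grid is safe even when the
smallest P_i is a single pixel of the total mass.

Slopes of ln Σ P_i^Q (→ τ), Σ μ_i ln P_i (→ α) and Σ μ_i ln μ_i (→ f)
against ln ε are ordinary least squares over all generated scales, with
per-Q R² recorded. The identity ln Z = Q·S_num − S_den is used to derive
the third moment curve from the other two, which is exact and avoids a
second pass. D(1) never divides by Q−1; it is the slope of Σ P_i ln P_i
(the α(1) fit), the information-dimension limit.

The Legendre route (α = dτ/dQ by central differences, f = Qα − τ) is
attached to every result as a cross-check channel. On cascade fixtures the
two routes agree to < 0.004 over |Q| ≤ 5; the direct estimator is primary
because differentiating a noisy τ amplifies error.

### Configuration defaults

| parameter | default | why |
|---|---|---|
| Q range, step | [−10, 10], 0.25 | standard range for trace images; step fine enough for the finite-difference cross-check (O(step²) error) |
| box sizes | 100, geometric | spacing even in log ε, the regression abscissa; rounding duplicates removed |
| min box edge | 10 px | smaller boxes on a 1-px line carry almost no mass distribution |
| max box edge | 60% of the smaller image dimension | larger boxes leave too few samples per tiling |
| grid origins | 1 (origin (0,0)) | reproducibility; >1 averages log-moments over seeded random offsets per size |
| R² gate | 0.90 | α_min/α_max are extracted only from Q values whose α fit clears the gate; negative-Q tails on real images are noise-prone and would otherwise inflate Δα |
| canvas | 1024 × 128 px | height matches the 7-bit amplitude quantization this method is usually run at; width gives roughly one column per 3.3 cm⁻¹ |
| `dyadic_sizes` | off | on: box edges restricted to powers of two — the exact scales of cascade fixtures, where recovery is exact; used by the verification suite |

`include_partial_boxes`, `connect_columns`, `line_thickness`, thresholds
and normalization mode are all configurable; defaults are stated above and
in the dataclasses.

## The multifractal number

The scalar is deliberately pluggable (`method` field records which was
used):

- `delta_alpha` (default): Δα = α_max − α_min over gated Q — the width of
  the singularity spectrum, the most defensible reading of "how strong the
  multifractal is";
- `alpha0`, `d1`, `f_at_q(q*)`: alternative reductions;
- `aperture`: |f(α(1)) − f(α(−1))|, one reading of quantifying the hump
  between Q = ±1; labeled experimental because the definition in the
  motivating description is ambiguous.

A printed relation in the source literature, τ(Q) = Q·H(Q) − 128, cannot be
reconciled dimensionally with D(Q) = τ(Q)/(Q−1) (the −128 matches a 128-px
image convention of the original software rather than any scaling
exponent); τ here is the standard partition-function exponent, and
H(Q) = (τ(Q) + D(0))/Q is exposed on the result object so the quantity
remains inspectable.

## Synthetic data

**Cascades** are the verification oracle. A binomial (1-D) or multinomial
(2-D quadrant) cascade of depth n splits mass recursively by fixed positive
weights; closed forms: τ(Q) = −log₂ Σ w_i^Q, D(1) = −Σ w_i log₂ w_i,
α(Q) = −Σ w_i^Q ln w_i / (ln 2 · Σ w_i^Q), f = Qα − τ, with
α_min = −log₂ max w_i and α_max = −log₂ min w_i. The `shuffle` option
permutes child assignment per split (seeded); at dyadic scales the box-mass
multiset is permutation-invariant, so shuffled and deterministic cascades
have identical estimated spectra — a useful internal consistency check.

**Synthetic cell spectra** are a Gaussian band mixture — O–H/amide-A
(3300 cm⁻¹), C–H stretch (2925), amide I/II (1650, 1545), phosphate/sugar
(1080), amplitudes 0.3–0.9 AU — plus a fine-structure texture built from a
shuffled binomial cascade, rescaled to zero mean and added at amplitude
`roughness_amp`, clipped at zero. The cascade parameter `roughness_p`
(default 0.3, texture amplitude 0.08 AU, 1024 points) controls how skewed —
hence how strongly multifractal — the fine structure is; it is the knob
that stands in for the phenotype axis: population-mixing experiments blend
a mild-texture "healthy-like" spectrum (p = 0.45) with a skewed
"cancer-like" one (p = 0.20) at cancer fractions φ ∈ {0.2 … 1.0}, the
mixture being a pointwise affine blend on a shared wavenumber grid.

What the generator does **not** emulate: ATR penetration-depth physics, Mie
scatter, water-vapor lines, baseline drift, or any claim about which real
spectral features carry diagnostic information. Passing tests demonstrate
that the pipeline's geometry and statistics behave as designed, not that
the biological claim holds on real cells.

## Experiment templates

- **Concentration invariance**: min-max normalization makes the rendered
  image invariant under amplitude scaling c·s (c > 0); scalings
  ×{1, 2, 4, 10} produce byte-identical masks, hence an exactly zero spread
  of the multifractal number. Sub-ulp float differences from scaling are
  absorbed by pixel-row rounding; a fixed-range normalization with clipping
  (the unnormalized analogue) produces a positive, reported spread.
- **Group comparison**: Welch's t for two groups (one-way ANOVA beyond),
  on replicate multifractal numbers with matching method labels. At n = 3
  per group Welch is mildly conservative (measured type-I ≈ 0.035 at
  nominal 0.05 under equal variances); it is kept for robustness to
  variance inequality between cell lines.
- **Dose response**: Spearman rank correlation between φ and the
  multifractal number; direction reported, undefined on all-tied inputs.

## Numerical and degenerate-input behavior

- Constant spectra cannot be min-max normalized (error directs to fixed
  mode); empty traces, empty crop overlaps, infeasible box-size ranges and
  all-fits-failing gates raise typed errors rather than returning NaN.
- Invariant checks (D non-increasing, f apex = D(0), tangency
  f(α(1)) = α(1)) run on every `analyze` result and are attached as
  warnings, never silently dropped.
- Everything stochastic (shuffled cascades, texture seeds, extra grid
  origins) takes an explicit seed; `analyze` is bit-reproducible for fixed
  input and config, and outputs embed a config hash.

## Known limitations

**Generalized-dimension ordering on rasterized traces.** For a true
measure, D(Q) is non-increasing in Q, and the estimator reproduces this
exactly on cascade and uniform fields. A rasterized connected polyline,
however, is a *near-uniform* measure on a curve-like support: vertical runs
are uniform 1-px columns, so amplitude structure becomes support geometry
rather than mass heterogeneity, and what mass heterogeneity remains
(corner-clipping "deficit" boxes) decays with box size. Over the feasible
10–76 px window of a 1024 × 128 canvas the fitted slopes then cross,
producing a small systematic inversion D(0) < D(1) < D(2) of about
0.03–0.08 with R² > 0.9. This is a finite-scale property of binary-image
box counting itself — it persists under more grid origins, discarded
partial boxes, divisor-only box sizes, thicker lines, taller canvases, and
across texture settings — and is the reason the dimensional-ordering check
on rendered spectra fails while every measure-fixture check passes. The
amplitude quantization that causes it is intrinsic to the image-based
protocol. Δα, the default multifractal number, is extracted from the
gated α range and remains well-behaved and responsive to the roughness
phenotype (the dose–response experiment is positive), so the headline
score does not depend on the ordering property.

**Scale range on wide-short canvases.** With a 128-px amplitude axis the
box-size window spans less than one decade, so all fitted exponents are
effective (finite-scale) quantities; fixture verification therefore uses
dyadic scales where the estimates are exact, and image results should be
compared only across identically configured runs (the config hash in every
output enforces comparability).

**Scope.** No baseline/scatter correction is applied (none is part of the
protocol being modeled); wavelet-leader or MF-DFA estimators, 3-D fields
and lacunarity are out of scope. Fixture sizes used by the verification
suite (cascade depths 9–12, 20-spectrum property samples, 1000-rep
calibration) were chosen so the entire suite runs in seconds while keeping
estimator error far below the stated tolerances.
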