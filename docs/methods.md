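# Methods

## The measurement model

A hyperspectral SRS stack is a cube D indexed (wavenumber, row, column); SRS
signal is, to good approximation, linear in analyte concentration, so each
pixel's spectrum d ∈ ℝ^{N_λ} is treated as a nonnegative linear mixture of k
reference spectra S ∈ ℝ^{k×N_λ} plus noise, d = cS + e. The default basis has
three members: pure limonene (dominant 760 cm⁻¹ ring/CH₂ band), the wild-type
cell-body spectrum, and the non-cell background of the stack. The background
reference is estimated per stack as the mean spectrum of non-cell pixels
(mask supplied, or Otsu on the spectrally summed image), because slide,
medium and optical offsets vary between acquisitions.

Coefficients are estimated pixel-wise by the LASSO

    ĉ = argmin_c ½‖d − cS‖₂² + λ‖c‖₁  (optionally c ≥ 0),

the right prior when most pixels contain only background and cell body and
limonene is confined to small aggregates.

## Solver

Cyclic coordinate descent with the exact single-coordinate soft-threshold
update, c_j ← soft(s_j·r_{−j}, λ)/‖s_j‖², in fixed reference order from a
zero start, vectorized across all pixels but numerically identical to
per-pixel solving (each pixel is frozen once it individually converges).
With the nonnegativity flag (default on, since concentrations are physical)
each update is clipped at zero, which is the exact coordinate minimizer of
the constrained problem. The per-cycle objective uses the Gram form
½d·d − c·b + ½cGc + λ‖c‖₁ (k×k work per pixel rather than N_λ).

Convergence requires both the relative objective change and the coordinate
step to fall below `tol` (default 1e-8, max 1000 cycles). The objective test
alone would stop at roughly √machine-eps coefficient accuracy, because the
objective is quadratic around its minimum; the iterate test makes tight
tolerances (1e-15) deliver ~1e-10 coefficients, which the oracle-equivalence
tests rely on. An eps·(1+‖d‖²) floor on the objective change lets perfectly
fit pixels terminate instead of chasing rounding noise. Non-convergence
raises a `ConvergenceWarning` and returns the best iterate.

References are max-normalized before fitting by default, so channel values
read as fractions of pure-reference peak intensity; `normalize_refs="none"`
fits in raw units. λ is held fixed across stacks from one acquisition
condition; when asked to choose it (`lam="auto"`), the package picks the
largest grid value whose mean non-cell residual stays within 1.1× the
unpenalized value — penalizing as hard as possible without visibly
distorting pixels known to contain no analyte.

## Segmentation

Cells: Gaussian smooth (σ 1 px) → Otsu threshold → hole filling → optional
watershed split with markers from a disk-eroded foreground (erosion radius
3 px ≈ just under the cell half-width, so each rod keeps exactly one marker
and end-to-end contacts separate at the waist) → area filter (≥ 50 px) →
consecutive relabeling. Fully deterministic; 8-connectivity throughout;
row-major 0-based pixel coordinates with centers on integers.

Aggregates: white top-hat (disk radius 4 px) on the limonene map → threshold
(Otsu over in-cell top-hat values by default) → restriction to cell pixels →
connected components ≥ 4 px → parent = cell under the component centroid.
Components whose centroid lands on background are dropped with a warning
(importers treat a wholly-background aggregate as a validation error
instead, since a curated mask should not contain one).

This classical pipeline stands in for interactive pixel/object
classification; hand-corrected masks enter through `import_labels`, which
compacts labels and re-parents aggregates by the same centroid rule.

## The d/L localization metric

For an aggregate-containing cell, the central line is the skeleton of the
cell mask pruned to its longest geodesic path (Dijkstra, diagonal steps
√2) — well-defined for bent rods, where a straight major-axis chord is not.
A skeleton of a spherocylinder ends near the cap centers, not the poles, so
both endpoints are extended along the local path direction (0.5 px steps)
until they leave the mask; L is the pole-to-pole arclength of the extended
polyline. `centroid` mode (default) projects the aggregate centroid onto
the nearest polyline vertex and takes d as the arclength to the *furthest*
pole, so d/L ∈ [0.5, 1] up to ~1.5/L pixelation; `maxline` mode instead
takes the maximum-intensity vertex along the line. Both are recorded, and a
disagreement beyond 2 px is logged. Near-circular masks (inertia-ellipse
elongation < 1.3) have no defined major axis and raise.

## Limonene-rich classification

Per-aggregate mean limonene-channel values are normalized so the
control/cell-body level is 1, making the threshold a unitless ratio. The
threshold is chosen by sweeping a grid against a control population: for
each candidate the classified fraction in both populations is recorded, and
the chosen value is the smallest grid point where the control fraction
drops to ≤ α (default α = 0: zero control positives). The full curve is
returned for plotting; if no grid point qualifies, the sweep returns `None`
with a warning rather than a forced choice. In single-strain runs the
pipeline applies a fixed configurable ratio threshold (default 1.1) with
the in-cell rest-of-cell cell-body mean as the normalizer.

## Colocalization

MCC = Σᵢ Limᵢ·[LimSynᵢ ≥ T] / Σᵢ Limᵢ with an inclusive comparison,
evaluated inside cells by default (the biological question is intracellular
co-occurrence; whole-image mode exists). T defaults to Otsu over in-cell
fluorescence; a `quantile:q` rule is available. An all-zero limonene region
raises rather than returning NaN. MCC is invariant to positive rescaling of
either channel (with T scaled alongside LimSyn) and monotone non-increasing
in T; both are enforced by tests.

## Calibration and detection limit

The dilution series is fit by ordinary least squares; blank replicates give
σ_blank, and the limit of detection is 3σ_blank/slope (the conventional 3σ
criterion — the package's declared definition). A non-positive slope is an
invalid calibration. Concentration estimates invert the line,
(I − I_blank)/slope, floored at zero.

Population comparisons use the two-sided Wilcoxon rank-sum (Mann–Whitney U)
test with normal approximation and tie correction. No multiplicity
correction is applied by default (comparisons are reported singly);
`adjust_pvalues` applies Benjamini–Hochberg when many pairs are tested.

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces the statistical structure the analysis assumes:
2-D spherocylindrical cells (length 2–4 µm, width 0.8 µm, 0.1 µm/px —
plausible for a 1.2-NA system) placed without overlap by rejection
sampling; a Bernoulli(0.19) subpopulation carrying 1–2 aggregates
(weights 0.8/0.2); aggregate axial position drawn as a truncated normal on
d/L (mean 0.8, sd 0.08, support [0.5, 1]), i.e. a polar bias with its mode
in the 70–90% band; aggregate limonene coefficients uniform in [0.5, 1.5]
(pure-reference units); per-pixel spectra c·S with additive Gaussian noise
(σ 0.02, appropriate for lock-in detected SRS; a Poisson option exists for
shot-noise-dominated regimes); a fluorescence channel emitting from
aggregates with a controllable colocalized fraction, PSF blur and noise;
and a dilution series with slope 2 a.u./mM and blank σ 14 a.u., which puts
the 3σ detection limit at 21 mM — in the tens-of-mM regime relevant for
intracellular aggregates.

Deliberately not modeled: SRS contrast physics (cross-sections, chirp,
spectral focusing), 3-D sectioning, cell growth or movement, structured
backgrounds, spectral miscalibration, segmentation-hostile dense colonies.
Passing tests therefore demonstrate correctness of the *analysis* under the
stated statistical assumptions, not robustness to every real-microscope
artifact; the external-mask importer is the escape hatch when real data
defeats the bundled segmentation.

Everything is driven by `numpy.random.default_rng(seed)`; one seed fixes
scene, stack, fluorescence and series bit-for-bit, and the pipeline
manifest (SHA-256 per artifact) is reproducible byte for byte.

## Problem sizes and numerical choices

The verification suite runs the forward–inverse identity on a 24×256×256
noiseless stack (max abs error ≤ 1e-6) and the noisy-recovery study on a
500-cell 1408×1408 scene (limonene-map Pearson r ≥ 0.95, aggregate-bearing
fraction within 3 binomial SEs of 0.19, mean d/L within 0.03 of 0.8) —
sizes chosen to exercise the full chain at realistic density while keeping
a complete run in minutes on one CPU. Statistical checks on 2-SE bands are
asserted as coverage over replicate seeds (≥ 8/10), since a single draw
fails a 95% band one time in twenty by construction. Ties in peak lookup
break toward the lower wavenumber; spectral windows are inclusive on both
ends; labels are always compacted to 1..n preserving scan order.

## Known limitations

- The λ default (0.01 in normalized-reference units) suits the bundled
  noise model; real acquisitions should re-derive it per condition with
  `select_lambda`.
- Nonnegative unmixing rectifies noise, so limonene maps carry a small
  positive floor inside cells; MCC and mean-intensity statistics on very
  dim samples inherit it. Raising λ trades this floor against sensitivity.
- The centroid d/L of a strongly curved cell follows the curved central
  line, not the Euclidean chord; for nearly straight rods the two agree.
- `segment_cells` assumes isolated or pairwise-touching rods; dense
  multi-layer colonies need external masks.
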