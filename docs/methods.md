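# Methods

This note documents the measurement conventions, the estimator, the
synthetic-data generators, and the numerical choices behind `fundusquant`,
together with what the test suite does and does not establish.

## Coordinate and measurement conventions

Pixel coordinates are raster-native: origin top-left, x rightward,
y downward, 0-based; images are assumed oriented "superior is up"
(superior retina at smaller y). All landmarks are supplied in pixels by a
human annotator; the package performs no automatic disc segmentation or
vessel tracing.

**Temporal direction.** The temporal horizontal is the horizontal unit
vector from the disc centre toward the side of the fovea. Because it is
derived from the annotation rather than from the image side, right and
left eyes share one code path with no image flipping; `eye_side` is
recorded for provenance only.

**Disc geometry.** The disc centre is the area centroid of the convex hull
of the boundary annotation (robust to uneven point density, unlike the
mean of raw points). Diameters are caliper (Feret) widths of the hull:
`d_max` is the maximum pairwise vertex distance; `d_min` uses the
rotating-calipers fact that the minimum width is attained flush with a
hull edge. The ovality ratio is `d_max / d_min ≥ 1`, and the mean disc
radius `(d_max + d_min)/4` sets the scale for the sampling circles.

**Vessel angles** are unsigned magnitudes in [0°, 180°] between the
temporal ray and the centre→crossing ray. Magnitude (rather than signed)
semantics keep a single interpretation for superior and inferior vessels.
**PMP** is signed: positive when the fovea lies inferior to the horizontal
through the disc centre, which is the typical anatomy. The sign convention
is a package choice; only the sign, not the magnitude, of PMP correlations
depends on it.

**Colour sampling.** Eight circles sit at 45° steps on a ring of radius
2.0 × mean disc radius (default), starting temporal and rotating through
superior; each circle's radius is 0.6 × mean disc radius, and the ninth
circle is centred on the fovea with the same radius. These two factors are
not dimensioned in the source imagery and are exposed in `SamplingConfig`;
the defaults keep the circles outside the disc (2.0 > 1 + 0.6) and
non-overlapping (adjacent centres 1.53 × mean radius apart > 1.2 ×).
A pixel belongs to a circle iff its centre is within the radius — a rule
an enumeration oracle can check exactly. Circles partially off the image
average over in-image pixels only (a 45° photograph can clip the nasal
ring); a fully off-image circle is an error. `TFI = R/(R+G+B)` is computed
from the mean channel intensities and is scale-invariant in the channels.

## The penalized regression estimator

Features are standardized to zero mean and unit **population** standard
deviation (denominator N, consistent with the 1/2N loss) and the response
is centred, so the intercept vanishes during fitting. The objective is the
elastic-net-penalized least-squares criterion with mixing parameter α
(α = 1, pure LASSO, by default — the L1 path is the method of record here;
α is exposed for sensitivity analyses).

The solver is cyclic coordinate descent on the Gram matrix
(`G = XᵀX/N`, `c = Xᵀy/N`), so one coordinate update costs O(p) regardless
of N; the kernel is numba-compiled. Convergence is declared when the
largest absolute coefficient change in a sweep falls below 1e-8 (error
after 1e5 sweeps). At the solution the KKT stationarity conditions hold to
well below 1e-6, which the tests assert, alongside agreement with the
single-predictor soft-threshold closed form, with normal-equations OLS at
λ = 0, with a 1e-3-step exhaustive grid search on two-predictor problems,
and with an independent reference implementation. Coefficients are
back-transformed to original feature units (`β_orig = β_std / sd`), so
reported coefficients are comparable across models while the penalty is
applied on the fair standardized scale.

**Penalty path and selection.** The path has 100 log-spaced values from
`λ_max = max_j |⟨x_j, y⟩|/N` (the smallest penalty with an all-null model)
down to 1e-4 λ_max, solved warm-started. λ is chosen to minimise 10-fold
cross-validated MSE; among values within 1e-12 of the minimum the largest
(most parsimonious) λ wins. Fold assignment comes from a seeded
permutation, so runs are bit-for-bit reproducible.

**Leave-one-out.** Each eye is predicted by a model fitted on the other
N−1 eyes, with λ re-selected by an inner 10-fold CV on those rows (fold
seeds derive deterministically from the configured seed and the row
index). A `single_lambda` mode instead fixes λ once, chosen on the full
data, and only refits per fold — cheaper, and a plausible alternative
protocol. The "final optimal model" is fitted on all rows at the
full-data CV-chosen λ; its coefficients populate the per-feature report
(`N.S.` where the penalty removed a feature).

**A caveat on Pearson r for near-null models.** When the outcome carries
no signal, cross-validation correctly selects (near-)null models, and the
LOO prediction for eye i collapses to the training mean of the other N−1
eyes — which is *exactly* anti-correlated with y_i (r = −1) despite having
negligible amplitude (sd(y)/(N−1)). Pearson correlation between actual
values and LOO predictions is therefore unstable in the no-signal regime:
arbitrarily close-to-constant predictions can show large |r|. The
meaningful null statement is about amplitude — LOO predictions of a
signal-free outcome have a small standard deviation relative to the
outcome — and that is what the property suite asserts. For genuinely
predictive models (the regime of interest) r is stable and reported with
its t-distribution p-value; a fully constant prediction vector is flagged
and reported as undefined correlation rather than a number.

## Evaluation

Eligibility keeps eyes with refractive error in [−8, +5] diopters
(strict inequalities remove only values beyond the boundaries). The
thresholds are parameters because observed cohort ranges can straddle a
nominal cut. MAE is reported with the sample (n−1) standard deviation of
the absolute errors; Pearson r carries a two-sided p-value from
`t = r√((n−2)/(1−r²))`. The p < 0.001 convention is annotation only —
nothing is filtered by significance.

## Synthetic data

**Renderer.** A stylised fundus: uniform reddish background whose red
channel carries seeded multiplicative mottling (`R·(1 + s·U)`,
U ~ Uniform(0,1)), emulating tessellation — the expected red mean is
analytically `R·(1 + s/2)`, so expected TFI is known in closed form and
rises monotonically with strength `s` (keep `base_R·(1+s) ≤ 255` to avoid
clipping; the default base colour allows s up to 0.5). On top: the disc as
a bright rotated ellipse (known ovality a/b), a darker foveal disc, and
four dark vessel segments from the disc centre to the crossing points,
which sit exactly on a measurement circle of radius 2.0 × mean disc radius
at the specified angles. The emitted landmark set samples 36 points on the
true ellipse; a 36-gon underestimates caliper diameters by < 0.4%, well
inside the 2% closed-loop tolerance. Vessel segments crossing a sampling
circle perturb its colour means by design less than the 0.02 TFI
tolerance (vessel colours are chosen with TFI close to the background's).
The renderer produces geometry, not photorealism: no vessel branching,
no optical vignetting, no disease phenotypes — closed-loop passes validate
the measurement code, not performance on clinical photographs.

**Cohort generator.** AL is drawn from a normal truncated to
[20.92, 27.55] mm whose underlying (μ, σ) are solved numerically so the
*truncated* distribution has exactly the target mean 23.50 and sd 0.88 mm.
RE is `−0.14 + b·(AL − 23.50) + ε` with b set by a target corr(RE, AL) of
−0.6 (an assumption — this correlation is not part of the published
summaries) and ε scaled so the marginal sd is exactly 1.62 D; out-of-range
ε are redrawn. Each feature j is `μ_j + γ_j(AL − 23.50) + noise`, with
`γ_j = r_j σ_j / σ_AL` so corr(feature_j, AL) equals its target r_j
exactly in expectation; defaults take the published univariate
correlation signs and magnitudes. Feature means and sds are not published;
the defaults (vessel angles ≈ 55–70 ± 8–9°, PMP 4 ± 3.5°, ovality
1.18 ± 0.06, R/G/B ≈ 165/95/60, TFI ≈ 0.52 ± 0.04) are plausible for
8-bit fundus photographs and were fixed once. Values are clipped to their
physical domains; with these defaults clipping is ≲ 0.1% of draws.
The generator reproduces first/second moments and the feature–AL
correlation structure; it does not reproduce feature–feature partial
correlations of real retinas, so absolute prediction accuracy on synthetic
cohorts characterises the pipeline, not the clinical population.

## Problem sizes and determinism

Default validation sizes: closed-loop renderer checks use 50 random
configurations; LOO integrity checks use n = 500, p = 42; support-recovery
checks use 20 replicates at n = 1646, p = 42 with 6 planted effects at
SNR ≈ 1 (β = 1/√6, unit noise); generator moment checks use n = 1646 and
correlation-convergence checks n = 100,000. Every stochastic component
takes an explicit integer seed (NumPy `default_rng`), and identical
seeds give bit-identical outputs, including CLI artefacts.

## Known limitations

* Landmarks are inputs; annotation error propagates directly into the
  geometric parameters and is not modelled by the renderer (crossing
  points are emitted exactly on the measurement circle).
* Channel intensities are used as stored; no cross-camera colour
  calibration.
* The Pearson-r instability for near-null LOO models described above is
  inherent to the protocol, not fixable by solver accuracy.
* 8-bit RGB only; higher bit depths are rejected rather than rescaled.
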