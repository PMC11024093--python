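# Methods

## The transient model and its constraints

A stimulated cytosolic Ca²⁺ transient is modelled as the difference of
two exponentials relaxing to a plateau:

    f(t) = −(b+c)·e^(−τ_rise·t) + b·e^(−τ_decay·t) + c,
    τ_rise = τ_decay + τ_Δ,  τ_Δ ≥ 0,  a = b + c.

All rates are in s⁻¹ and amplitudes in fluorescence units. The two
reparameterisations are constraints, not conveniences: τ_Δ ≥ 0 forbids
a decay faster than the rise (the model must rise then decay), and
a = b + c pins f(0) = 0 so the fitted curve starts at the transient
onset with zero baseline-subtracted fluorescence. The derived
quantities a and τ_rise are always recomputed from (τ_decay, τ_Δ, b, c),
never stored, so a ≥ b and τ_rise ≥ τ_decay hold by construction. The
evaluation is grouped as `b(e^(−τ_decay t) − e^(−τ_rise t)) + c(1 − e^(−τ_rise t))`,
which is algebraically identical but makes f(0) = 0 exact in floating
point (the naive grouping leaves a cancellation residual of order 1 ulp
of b + c).

The interior peak, used for sanity checks and for relating the model to
ΔF/F₀ maxima, is at t* = ln(a·τ_rise / (b·τ_decay)) / τ_Δ; it exists
only when τ_Δ > 0 and b > 0, and the code signals the monotone case
distinctly rather than returning infinity.

## Acquisition geometry and preprocessing

The experiment the defaults mirror acquires one frame every 30 s for
30 minutes inclusive of t = 0 (61 frames), adds the agonist at the
tenth acquired frame, and discards the first frame before analysis.
After the drop, the retained series has 60 frames: frames 0–7 form the
pre-stimulus baseline and frame 8 is the transient onset (t = 0 for
fitting). Two baseline references are supported — ΔF/F₀ with
F₀ = mean(frames 0–7), and plain baseline subtraction
y′ = y[8:] − mean(y[0:8]) — with ΔF/F₀ the default for trajectory
analysis. No additional detrending is applied: baseline referencing is
the only normalization, a deliberate choice since any detrend would
alter the trajectory shapes the PCA is meant to compare.

Windowed summaries (area under the curve before and after a 750 s
boundary, peak and final ΔF/F₀) use the trapezoidal rule. The series is
split at the boundary, interpolating a sample there when the grid has
none, so both windows share the boundary point and early + late area
equals the full-window area exactly. The trapezoidal rule is the
standard choice for uniformly sampled series; the boundary convention
must be stated because half-open alternatives change nothing for the
shared-endpoint integral but would change frame-counting summaries.

## Eligibility criteria and fitting

A cell is fitted only if its transient y′ satisfies three criteria:

1. median(y′) ≥ 0 — otherwise the plateau initialiser (the median)
   would start outside the parameter bounds;
2. responsiveness — frames 8..N exceed frames 0..7 by a one-sided
   Wilcoxon rank-sum test at α = 0.005, computed with the normal
   approximation and tie correction (group sizes 8 vs ≈ 52 make exact
   enumeration unnecessary); an all-constant trace is declared
   non-responsive directly since the rank-sum statistic is undefined;
3. the argmax of y′ lies in the first half of the transient segment
   (index < ceil(length/2) of y′, the series the criterion inspects) —
   a late peak means the decay phase is essentially unobserved and
   τ_decay would not be identified.

Fitting is bounded nonlinear least squares (trust-region reflective)
with bounds τ_decay, τ_Δ, b ≥ 0 and 0 ≤ c ≤ max(y′) (inclusive upper
bound). Initialisation is a deterministic grid of 300 starts: 10
log-spaced decay rates with 1/τ_decay spanning 15–1500 s, 6 log-spaced
rate gaps over 10⁻⁶–10⁻¹, 5 log-spaced decay amplitudes over 0.1–1000,
and c = median(y′) everywhere, enumerated in lexicographic order.

Numerically, every start is optimized at a coarse tolerance (10⁻⁴ on
cost, step and gradient), the five best-screened starts are polished at
10⁻⁸, and the polished fit with the lowest sum of squared residuals
wins, ties broken by grid order so repeated fits of identical data are
bit-identical. Polishing several screened starts rather than one guards
against the rare case where two basins are indistinguishable at the
coarse tolerance. Each restart is capped at 1000 function evaluations.
The reported fit error is the raw sum of squared residuals.

On noise-free transients drawn from the default cohort kinetics the
pipeline recovers 1/τ_decay to machine precision (the acceptance suite
measures a median relative error ≈ 7 × 10⁻¹⁶ over 100 cells). At 5%-of-
peak Gaussian noise the measured median relative error is ≈ 0.146.
This number is close to the statistical information limit of the
design, not an optimizer artifact: truth-initialised fits at tolerance
10⁻¹⁰ give the same median, and the Cramér–Rao bound at these
conditions implies a median one-sigma relative error of ≈ 0.19 —
dominated by fast-decay round-cell kinetics whose decay times (30–150 s)
approach the 30 s frame interval, so only a few frames sample the decay.
Slow-decay elongated-cell kinetics are recovered several times more
precisely.

## Trajectory shape space

Each cell's normalized trajectory is one observation; the pooled set
(both geometries, all concentrations) is centred and decomposed with a
full singular value decomposition, keeping the three leading
components. Trajectories are centred but not variance-scaled: scaling
individual frames would distort the very shapes being compared. Since
the sign of a singular vector is arbitrary, each component is flipped
so its largest-magnitude loading is positive, which makes models
reproducible across runs and cell orderings.

Group comparisons run per agonist concentration: Wilks'-lambda MANOVA
on the 3-D scores with the standard F approximation (statsmodels; two
groups and three response dimensions give the 3-degree-of-freedom
numerator), with raw p-values Bonferroni-multiplied by the number of
concentration levels. An LDA with priors proportional to group sizes is
fitted on the same scores and its weight vector reported as the
separation direction. One caution, established on simulated cohorts:
with i.i.d. frame noise the discriminant loads heavily on the
low-variance third component (small within-group variance is exactly
what a Mahalanobis direction exploits), so the per-component sign
pattern of the weights is dataset-specific. The robust summaries are
the discriminant's group separation and the between-centroid direction
back-projected into trajectory space, whose late-time tail is elevated
on the slow-decay side.

Under label permutation of a null cohort the MANOVA rejects at the
nominal rate (the acceptance suite measures the 5%-level rejection rate
over 500 permutations and requires it to sit in [0.03, 0.07]).

## Single-cell quality control

Segmentation exports four per-well tables: calcium-channel cell objects
with area and perimeter, post-stain cell objects, nuclei with area and
nearest-neighbour spacing, and the cross-image region match. They are
outer-merged on the region identifier; a region absent from any table
is marked incomplete and excluded. Circularity is 4πA/P² (1 for a
perfect circle), the standard high-content shape factor. The five
inclusion rules, all independent so the cascade is order-free:

| rule | inclusion condition |
| --- | --- |
| shape window | O: shape factor ≥ 0.9; L: 0.5 ≤ sf ≤ 0.85 (inclusive) |
| single nucleus | exactly 1 nucleus in the region |
| nucleus spacing | nearest other nucleus ≥ 20 px |
| nucleus size | nucleus area < 300 μm² (strict) |
| centroid agreement | max pairwise gap of the three centroids ≤ 30 μm |

Boundary semantics follow the rule wording: a shape factor of exactly
0.85 is included for L and 0.9 for O, a 300 μm² nucleus is excluded, a
30 μm centroid gap is retained (exclusion requires strictly greater),
and 20 px spacing is retained. Nucleus spacing is natively in pixels
and areas/centroids in μm; when a caller supplies spacing in μm, an
explicit `um_per_pixel` calibration is required — the pixel size of a
binned 10× acquisition is instrument-specific and deliberately has no
default.

## EPI–MES scoring

Tumor log2 expression is z-scored per gene across tumors with the
sample (n−1) standard deviation; zero-variance genes and genes with
missing values cannot be z-scored and are dropped with a warning rather
than silently zero-filled. Signature refinement keeps list members
whose z profile has Pearson r > 0.5 (strict) with the unweighted mean z
of the full list, the candidate gene included. A tumor's score is the
mean z over the refined epithelial genes minus the mean z over the
refined mesenchymal genes; list-level aggregation uses the mean rather
than the sum so the score is invariant to list size. Tumors are sorted
by score (stable sort, so ties preserve input order) and split into
five contiguous rank quintiles — equal-count by construction, balanced
to within one tumor — labelled H-MES, L-MES, Ambig, L-EPI, H-EPI from
most mesenchymal to most epithelial.

The packaged gene lists reproduce the curated epithelial (26 printed
entries, 25 unique — one keratin symbol is printed twice and the loader
de-duplicates while preserving order), mesenchymal (15) and breast
cancer subtype-marker (9) lists. Marker-correlation panels report raw
Pearson r and two-sided p per stratum with no multiplicity adjustment
(the convention is to plot raw p against a 0.05 reference); strata with
fewer than 3 tumors are marked not-computable. Correlation matrices are
clustered by average linkage on Manhattan (city-block) distances
between rows, with the tree cut into a requested number of groups.
Comparative-Ct quantitation returns fold change 2^(−ΔΔCt), percent
remaining (× 100) and relative mRNA (−ΔΔCt).

## Micropattern geometry

For a disc the maximum inter-point distance is the diameter
2·√(area/π): 37.4 μm at 1100 μm² and 29.9 μm at 700 μm². Under
isotropic scaling of any fixed shape, linear dimensions grow with the
square root of area, so moving from 700 to 1100 μm² lengthens every
chord by (√(1100/700) − 1) × 100 ≈ 25% regardless of shape. The
elongated-triangle maximum chord is not computed from area alone — its
aspect ratio is defined by the micropattern vendor and is not
derivable — so only the scaling ratio is reproduced for "L".

## What the synthetic data does and does not emulate

The cohort generator draws per-cell kinetics log-uniformly from
group-specific ranges. Defaults encode the study conditions: 61 frames
at 30 s with the agonist at the tenth frame; a constant pre-stimulus
baseline of 100 a.u. (a raw baseline level is needed for ΔF/F₀ to be
defined; the exact value is immaterial because ΔF/F₀ is scale-
invariant); decay time constants of 30–150 s for round cells and
200–800 s for elongated cells, encoding the observation that elongated
cells decay more slowly; rise-rate gaps τ_Δ of 0.01–0.1 s⁻¹ (rise
times of tens of seconds, consistent with responses that peak within a
few frames); amplitudes b of 50–200 and c of 20–100 a.u. on the 100
a.u. baseline, giving peak ΔF/F₀ of roughly 1–3; i.i.d. Gaussian frame
noise of sd 2 a.u.; and a 10% non-responder fraction emitting baseline
plus noise only. Gaussian i.i.d. noise is the weakest assumption
sufficient for least-squares fitting; real indicator noise is
signal-dependent and temporally correlated (photobleaching, drift),
none of which is modelled, so passing tests demonstrate correctness of
the computations, not robustness to every real-data artifact. No
dose-response coupling is modelled: concentration is carried as
metadata and cells are assigned to doses round-robin.

The object-table generator plants each QC violation in isolation
(doublet nuclei, out-of-window shape factors, close nuclei, oversized
nuclei, mismatched centroids) plus optional exact-boundary records, and
computes ground-truth inclusion by evaluating the five rules directly
on the emitted numbers — so truth matches a brute-force oracle by
construction rather than by intent, even if a random draw lands on a
rule boundary.

The expression generator gives every tumor a standard-normal latent
EPI↔MES coordinate; epithelial signature genes load positively on it,
mesenchymal genes negatively (magnitudes uniform in 0.8–1.5 log2
units), subtype markers and filler genes carry no structure, and
i.i.d. Gaussian noise (default sd 0.5 log2 units) is added. Real tumor
expression has correlated structure beyond one axis (subtype programs,
purity, batch), so the generator validates the scoring arithmetic and
its monotone relation to a known axis, not biological discovery.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed and is
bit-reproducible. The test and acceptance workloads use the sizes the
analyses were designed around: 500 transients for the PCA variance
check, 100 cells for parameter recovery (fitted twice, noise-free and
at 5% noise), 1000 synthetic records for the QC oracle comparison, 500
label permutations for the MANOVA calibration, and 300 tumors for the
EPI–MES round trip.

## Known limitations

- Single-transient model only: oscillatory or multi-peak responses are
  outside the model family and will fit poorly (by design, such cells
  are usually screened out by the peak-position criterion).
- The fit is per-cell; no information is shared across cells.
- Decay times approaching the 30 s frame interval are weakly
  identified at realistic noise (see the Cramér–Rao discussion above).
- The rank-sum responsiveness test assumes exchangeable frames within
  each window; strong drift during the baseline violates it.
- Quintile labels are relative to the analyzed cohort, not absolute
  calibrations of EPI/MES state.
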