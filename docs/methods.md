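# Methods

This note documents the models implemented in `allokin`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions.

## Coupled-assay kinetics

ADP release by the kinase is regenerated by pyruvate kinase with
stoichiometric NADH oxidation by lactate dehydrogenase, so the reaction is
read as an absorbance decrease at 340 nm. Conversion to product uses
Beer–Lambert with ε(NADH, 340 nm) = 6220 M⁻¹cm⁻¹ and a 1 cm path length;
both are configurable (`AssayTrace.epsilon_nadh`, `path_length`). The
coupled system is treated as instantaneously coupled (no lag correction).

**Initial-rate window.** The initial velocity is the least-squares slope of
the longest early window that (a) stays below 10% substrate conversion and
(b) passes a linearity criterion: the quadratic term of a second-order fit
must contribute less than 5% of the linear term over the window span. The
5% curvature tolerance is a package convention ("linear portion" admits no
unique definition); both knobs are arguments of `initial_rate`.

**Michaelis–Menten fit.** `curve_fit` on `v = vmax·S/(KM+S)` with
initialisation `vmax₀ = 1.2·max(v)` and `KM₀` = interpolated [S] at
half-`vmax₀` — robust for any saturating design. Non-physical estimates
raise a `FitError` with the initialisation in the message. When the largest
assayed [S] is below the fitted K_M the result carries a `non_saturating`
flag: the design cannot pin down `vmax`, the situation in which weakly
active constructs are reported as "ND".

**Table rounding.** Catalytic efficiencies are additionally reported with
the summary-table convention: one significant figure, except two when the
leading digit is 1 (a single figure would halve the resolution exactly
where relative steps are largest). Thus 67039 → 7×10⁴ but 18605 → 1.9×10⁴.
Fold changes round to the nearest integer at ≥ 3 and to one decimal below
(2.49-fold reads 2.5-fold, not 2-fold).

## Four-state autoactivation model

States (e₀₀, e₁₀, e₀₁, e₁₁) index (loop, IN-box) phosphorylation; relative
specific activities default to a = (0.01, 0.10, 0.05, 1.00), the measured
1% / 10% / 5% / 100% relative initial rates of the four forms at high
substrate. Activities are treated as reference-condition constants (their
substrate dependence is unknown; the partially phosphorylated forms have
different K_M, so the activity numbers are tied to the 600 µM assay
condition at which they were measured).

Rate laws, with catalytic pool `C = E_tot · Σ aᵢⱼ eᵢⱼ` (M):

    de₀₀/dt = −(k_cis + k_loop_trans·C)·e₀₀ − k_trans·C·e₀₀
    de₁₀/dt = +(k_cis + k_loop_trans·C)·e₀₀ − k_trans·C·e₁₀
    de₀₁/dt = +k_trans·C·e₀₀ − (k_cis + k_loop_trans·C)·e₀₁
    de₁₁/dt = +k_trans·C·e₁₀ + (k_cis + k_loop_trans·C)·e₀₁

Weighting the trans channels by the donors' relative activity encodes
"a partially active or fully active enzyme can phosphorylate another
molecule" without introducing per-donor-state rate constants; whether the
trans IN-box step requires a particular donor state is not established, so
the activity-weighted pool is a modelling choice. ATP is held saturating
(assays use 1–5 mM), all steps are pseudo-first/second order in enzyme
only, and there are no dephosphorylation terms (no phosphatase present), so
the activity-weighted fraction is nondecreasing. Substrate turnover is
`dP/dt = E_tot·kcat_ref·(Σ aᵢⱼeᵢⱼ)·S/(KM_ref+S)` with the all-P reference
constants kcat_ref = 12 s⁻¹, KM_ref = 179 µM.

**Default rate constants.** The experiments constrain the mechanism
(slow intramolecular loop step, faster intermolecular IN-box step) but
print no rate constants, so the defaults are chosen to reproduce the
qualitative record: k_cis = 5×10⁻⁴ s⁻¹ gives loop-phosphorylation
half-times of ~20–30 min at any concentration; k_trans = 5×10² M⁻¹s⁻¹
makes the trans step ~12× faster than cis at the 12 µM preincubation
concentration yet negligible at the 25–100 nM assay concentrations over the
first assay minutes (the basis for freezing the state distribution after
dilution in `preincubation_assay`). With a much faster trans constant the
half-activation times from the unphosphorylated and IN-box-only starting
pools collapse onto each other (both become cis-limited); the chosen value
preserves the observed ordering t½(no-P) > t½(IN-P) > t½(loop-P) with
clear separation. `k_loop_trans` defaults to 0 (pure-cis loop step), an
opt-in channel, because the concentration-normalization test shows the
loop step to be concentration independent at assay concentrations.

**Integration.** `solve_ivp` with LSODA, rtol 10⁻⁸, atol 10⁻¹⁰ (rate
constants can span decades). State-fraction conservation and mass balance
P + S = S₀ hold to 10⁻⁶ at every output time and are asserted in tests.

**Cis/trans diagnostic.** Product curves at ≥ 2 enzyme concentrations are
interpolated to a common grid and divided by concentration. The lag window
is all times before the fastest curve reaches 20% of its final normalized
product; the statistic is the maximum over the window of
(max − min)/mean across concentrations. Label "cis" below a 5% spread,
"trans" when the spread exceeds it and the normalized curves increase
monotonically with concentration, "mixed" otherwise. The 20% lag fraction
and 5% spread threshold are package conventions, exposed as arguments. The
diagnostic is informative only when activation proceeds appreciably within
the observation window (450 min by default): the validated operating range
at 25–100 nM is roughly k_cis ∈ [2×10⁻⁵, 2×10⁻³] s⁻¹ and
k_trans ∈ [2.5×10³, 2.5×10⁵] M⁻¹s⁻¹, the two-decade grids used in the
classifier tests. Note that the pure-cis overlap is exact only while
substrate consumption is negligible — at fixed S₀ a higher enzyme
concentration depletes substrate sooner, which separates even
concentration-independent normalized curves late in the reaction.

**Parameter estimation.** `fit_autoactivation` does multi-start
least squares in log-rate space with activities held fixed, and reports
delta-method standard errors and a condition-number flag instead of raising
on unidentifiable designs.

## Differential HDX-MS

**Normalization.** `MaxUptake = max(N − P − 2, 0)` (N residues, P
prolines); the more common N − P − 1 is available via
`convention="n-p-1"`. Exchange-competent deuterium is
`MaxUptake · f_D2O` with f_D2O = 0.95 (a 1:20 dilution into D₂O buffer,
`deuterium_fraction`). Back-exchange is handled only through the
fully-deuterated-control normalization mode; no per-residue intrinsic-rate
correction is attempted.

**Significance.** A difference is called significant only when *both*
|ΔD%| > 5% and the (1 − α) confidence interval for ΔD (Da) excludes zero.
The CI uses a global pooled replicate SD across all peptides and
timepoints, `CI = ± t(1−α/2, Σ(nᵢ−1)) · s_pooled · √(1/n_a + 1/n_b)` —
the pooled-variance approach standard in differential HDX software. With
fewer than two replicates the threshold rule decides alone, with a warning.
The 5% rule is applied per timepoint; the cumulative (butterfly) ΔHDX is
reported separately. Exposure sets default to {3, 10, 30, 90} min; a
300 min point is accepted on input but excluded from the default butterfly
set.

**EX1/EX2 classification.** Envelopes are centroided spectra normalized to
unit sum. One- and two-component Gaussian mixtures are fit by
expectation–maximisation on the intensity-weighted mass grid (intensities
as fractional counts; five starts, the first moment-based). Model selection
is by BIC with an effective ion count (default 1000) as the sample size;
the bimodal model is accepted only if it also separates its means by
≥ 2 Da and keeps both weights above 1%. At late exposures a fully unfolded
peptide is legitimately unimodal; `ex1_fraction_series` maps unimodal
classifications to fraction 0 or 1 by the nearer reference centroid before
the rate fit `f(t) = 1 − exp(−k_op t)`. Rate ratios between states carry a
delta-method CI on the log scale.

## Trajectory analysis

Superposition is Kabsch (SVD) onto an iterated mean structure (two
passes), all particles by default and restrictable to a group; no scaling
and no mass weighting (toy particles have unit mass; a switch exists for
real topologies). RMSF densities are built from non-overlapping blocks
(default 50 frames) because a distribution, not a single number, is the
informative comparison between phosphorylation states; block size is
configurable. PCA is the eigendecomposition of the 3N×3N positional
covariance of the aligned coordinates; eigenvalue sum equals total
positional variance and back-projection reconstructs the centered
coordinates to 10⁻⁸, both asserted in tests.

**Cosine content** uses the discrete form
`cᵢ = (2/T)(Σ cos(iπt/T)·p(t))² / Σ p(t)²` on the mean-centered
projection, clamped to [0, 1]. Values near 1 flag random-diffusion-like
(unconverged) motion; near 0, genuine concerted oscillation. The
0.5–0.9 band quoted for diffusive dynamics is an emergent property of PC1
projections — PCA of mean-centered Brownian motion converges to the cosine
Karhunen–Loève basis — not of raw 1-D walks (whose mean c₁ is ≈ 0.45).
The test-suite realization is PC1 of single diffusing-particle
trajectories, giving an ensemble mean ≈ 0.67.

**Open-close / twist.** Open-close is the mean-centered inter-lobe
centroid distance. Twist is the rotation angle of the C-lobe's leading
principal axis about the inter-centroid axis relative to frame 1
(mean-centered, degrees) — a convention, since the shearing motion has no
unique quantitative definition; the measured amplitude is a projection of
the applied rotation, not an identity. Basin counting smooths the 2-D
occupancy histogram (Gaussian, σ = 1 bin) and counts local maxima above a
prominence threshold; it is meaningful for metastable-state hopping, not
for continuous oscillation (a Lissajous ring has many spurious maxima).

## Synthetic data

All generators take a `SyntheticConfig(seed, noise_sd, time_grid,
replicate_count)` and are bit-reproducible under a fixed seed; with
`noise_sd = 0` the ground truth is recovered exactly by the matching
analysis stage (asserted as round-trip tests per stage). Observation noise
is additive i.i.d. Gaussian — the simplest model that supports
confidence-interval recovery tests; real instrument noise is neither
reported nor emulated in structure (no drift, no heteroscedasticity).
Envelopes are Gaussian components on a regular mass grid (centroided
abstraction; no isotopic fine structure, no profile-mode peaks, no
chromatographic dimension). The two-lobe trajectory is two rigid
pseudo-atom blobs with sinusoidal open-close/twist/loop modes at
incommensurate periods plus an optional per-particle random walk; it
emulates the geometry of collective kinase motions, not their energetics.
Passing tests on these generators therefore demonstrate correctness of the
analysis algorithms under the stated statistical assumptions, not
instrument-level fidelity.

Default study conditions baked into the generators: assay enzyme
concentrations 25/50/100 nM with 600 µM substrate and 450 min continuous
monitoring (Dodson test); 12 µM preincubation; HDX exposures
{3, 10, 30, 90} min at f_D2O = 0.95 with three replicates.

## Problem sizes

The test suite and acceptance script run at desk scale by choice: ODE
grids of 200–800 points, 20+20 classifier draws, tens of Monte-Carlo null
simulations, 10⁴-frame trajectories for closed-form RMSF/PCA checks. All
statistical assertions state coverage (e.g. 3-SE Monte-Carlo coverage ≥
80% at df = 3) rather than single-draw luck.

## Known limitations

- Rate constants of the autoactivation model are order-of-magnitude
  choices consistent with the qualitative record, not measured values.
- The activity-weighted trans pool is one defensible reading of the
  mechanism; donor-state-specific trans constants are not identifiable
  from the emulated data and are not modelled.
- No global progress-curve fitting of K_M, no inhibitor or phosphatase
  models, no spatial phosphorylation gradients.
- HDX: no peptide identification, retention-time alignment, overlapping-
  peptide deconvolution to residue resolution, or charge deconvolution
  (envelopes are assumed mass-domain).
- Trajectory: no force-field energetics, solvent, or hydrogen-bond
  analysis; the twist coordinate is a convention and cosine-content bands
  from real simulations depend on sampling length.
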