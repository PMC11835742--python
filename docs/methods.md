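# Methods

This note documents the models, numerical choices and limitations behind
`neuroturb`. Symbols: N regions, T volumes, TR repetition time, λ the
inverse-distance scale of the spatial kernel (per mm), G the global coupling
of the whole-brain model, `a` the Hopf bifurcation parameter.

## Model-free pipeline

**Preprocessing.** Regional BOLD is demeaned per region and band-pass
filtered with a zero-phase (forward–backward) 2nd-order Butterworth filter.
The default band is 0.008–0.08 Hz, the conventional narrowband for
resting-state phase analyses; both edges are configurable and validated
against the Nyquist frequency 1/(2·TR). Instantaneous phases come from the
analytic (Hilbert) signal; 10 volumes are trimmed from each edge afterwards
(`n_trim`, configurable) because the Hilbert transform of a finite series is
unreliable near its ends.

**Local order parameter.** For each region j and time t,
`R_j(t) e^{iθ_j(t)} = Σ_k w_jk e^{iφ_k(t)} / Σ_k w_jk` with
`w_jk = exp(−λ d_jk)`. The self term is included (w_jj = 1) and the sum is
normalized by the kernel mass, so full synchrony gives R = 1 exactly and R is
bounded in [0, 1] (values a few ulp above 1 are clipped). Two limits are
tested as properties: λ → large recovers R → 1 (self-weight dominates) and
λ → 0 recovers the global Kuramoto order parameter in every region.

**Scale grid.** The default grid is λ ∈ {0.01, 0.03, 0.06, 0.09, …, 0.30},
spanning characteristic lengths 1/λ from ~100 mm down to ~3.3 mm. Group
statistics and classifier features are reported at the three largest scales
(λ = 0.01, 0.03, 0.06), where long-range coordination lives.

**Measures.** All standard deviations are sample SDs (n−1), matching the
MATLAB lineage of this analysis family. Turbulence pools all N·T′ entries of
R; node metastability is the per-region SD over time. The cascade flow
between adjacent scales correlates R at the finer scale (larger λ) at time t
with R at the next coarser scale at t + 1 volume, over all (region, time)
pairs; the information cascade is the plain average of the flows over the
grid's adjacent pairs. Correlations of constant fields are an error, never a
silent NaN.

**Information transfer.** Pairwise correlations over time of the R rows are
binned by Euclidean distance (2 mm bins) and the statistic is the negative
slope of the OLS fit of log(mean bin correlation) against log(bin center),
restricted to a fit range of 10–75 mm (an inertial-subrange stand-in,
configurable) and to bins with positive mean correlation (the log requires
it; non-positive bins are excluded rather than clipped). The sign convention
— positive = faster spatial decay — is recorded on the profile object because
the opposite convention also appears in the literature. Fewer than 5 usable
bins is an error.

## Hopf whole-brain model

Each region is a Stuart–Landau oscillator with additive white noise,
diffusively coupled through the anatomical matrix C:

    dx_j = [(a_j − x_j² − y_j²) x_j − ω_j y_j + G Σ_k C_jk (x_k − x_j)] dt + σ√dt ξ
    dy_j = [(a_j − x_j² − y_j²) y_j + ω_j x_j + G Σ_k C_jk (y_k − y_j)] dt + σ√dt ξ′

Defaults: a = −0.02 (noisy fixed point near criticality), σ = 0.01,
dt = 0.1 s, Euler–Maruyama integration, 20 s transient discarded, x recorded
at the output TR. The integrator is validated against closed forms (orbit
radius √a and cycle frequency ω/2π for a > 0, subcritical decay for a < 0,
agreement with a dense-step deterministic reference) rather than against
another stochastic integrator. Intrinsic frequencies are estimated per region
from the Welch periodogram peak inside the analysis band; synthetic cohorts
draw them once from Uniform(0.04, 0.07) Hz — the upper half of the band,
where resting-state spectral peaks typically sit — and share them across
subjects (group-averaged node frequencies).

**Coupling matrix.** `C_jk = exp(−0.18 · d_jk)` (the exponential distance
rule with the decay rate conventional for this model family), merged with an
optional normalized connectome by elementwise maximum — long-range fibers
act as exceptions "on top of" the EDR. C is symmetric, hollow and bounded by
1.

**Fitting G.** The empirical target is the subject-averaged FC-vs-distance
curve (full-series Pearson correlations averaged in 5 mm distance bins over
5–80 mm). For each G on the grid the model curve is averaged over `n_reps`
seeds and scored by the mean squared difference across bins; ties break
toward the smaller G (closer to subcritical). The error norm is a choice —
the analysis names the quantity fitted, not the metric — and a KS-style
alternative can be swapped in by comparing the binned curves differently.
Because adjacent grid points (ΔG = 0.1) produce expected curves that differ
by little more than the sampling noise of a 300-volume run, the
parameter-recovery experiments in the test suite and acceptance script
estimate curves from long stationary runs (3600 s, i.e. 1800 volumes at
TR = 2 s) with 10 empirical subjects; at those sizes the recovery of a
planted G* = 1.2 lands within one grid step reliably (verified over
independent replicate seeds).

## In-silico perturbation

Per trial, every region's bifurcation parameter is shifted by an independent
draw Δa_j ~ Uniform(0, Δa_max) (positive shifts — toward supercriticality —
by default; a symmetric option exists). The perturbed and unperturbed
networks are integrated with the same noise seed (paired design, a pure
variance-reduction device; an unpaired option exists) and the readout is the
difference of the spatiotemporal means of R at λ = 0.01, the scale most
sensitive to group structure. Susceptibility is the trial mean of |Δ|, the
information encoding capability the trial SD of |Δ|; the modulus is taken
per trial before aggregation (the alternative — modulus after averaging —
differs only when shifts change sign, which positive perturbations of this
model do not produce).

**Saturation caveat.** With a = −0.02 a shift of order 0.05–0.1 drives most
regions deep into the oscillatory regime, where the mean local order
parameter approaches its ceiling and the readout stops discriminating: the
dose–response curve rises steeply up to Δa_max ≈ 0.05 and is flat beyond
(replicate means 0.269 / 0.3816 / 0.3804 over Δa_max ∈ {0.05, 0.1, 0.2} on a
60-region network at G = 1.3 — the last step is flat to slightly negative,
inside replicate noise). Susceptibility is a linear-response concept, so
**group contrasts are probed at Δa_max = 0.02**, inside the linear regime;
there the model fitted to the higher-coupling (responder-like) group shows
the larger susceptibility and information capability, and at saturated probe
strengths that ordering inverts because higher-coupling models start closer
to the ceiling.

## Group inference

The group test is a two-sided permutation test on the Wilcoxon rank-sum
statistic (1000 label permutations by default) with the add-one convention
p = (1 + #extreme)/(1 + n_perm), so the smallest attainable p is
1/(n_perm + 1); its type-I error at α = 0.05 is verified to sit in
[0.03, 0.07] over 500 null replicates. Effect sizes are Cohen's d with the
pooled (n₁ + n₂ − 2) SD. Multiplicity is controlled by Benjamini–Hochberg
FDR within each comparison family (the seven scalar measures for group
pairs; the N nodes for the node-level analysis). In the node-level analysis,
"selected" nodes are FDR-significant nodes whose raw p falls in the bottom
30% quantile; the quantile is computed over the significant nodes by default
(an `all`-nodes mode exists, since either reading is defensible), and the
selected nodes are tallied by resting-state network.

## Treatment-response classifier

Exactly seven baseline features per patient: turbulence and information
transfer at λ ∈ {0.01, 0.03, 0.06} and the information cascade. The learner
is an RBF-kernel SVM (C = 1; kernel width from the median pairwise distance
of the standardized training fold — the analysis names the kernel, not the
hyperparameters). Evaluation balances the classes by subsampling the larger
class to 32 (clipped with a warning when the smaller class is smaller),
splits 90/10 stratified, standardizes with training statistics only, and
repeats 100 times; AUC comes from decision values per repetition and is then
averaged (matching the mean ± SD presentation). A 10-fold stratified
cross-validation mode exists because both protocols appear in this
literature; repeated balanced splits are the default. Significance comes
from re-running the identical procedure on label-shuffled data (add-one p;
the strict-inequality count is a switch). Null calibration — approximate
uniformity of the permutation p-values over replicate structureless
datasets — doubles as the leakage test: any standardization or tuning
outside the training fold would shift it.

## Synthetic cohorts

The generator emulates the study design: three groups (controls, responders,
non-responders) of parcellated BOLD at TR = 2 s, 300 volumes, with group
differences planted **through the coupling G** — the same mechanism the
model-based analysis fits — rather than by adding signal. Default group
couplings (1.28, 1.55, 1.23) mirror the fitted optimal working points of the
three groups. Geometry is dart-thrown inside a brain-sized ellipsoid
(140 × 170 × 120 mm, ≥ 3 mm spacing) with k-means clusters standing in for
eight resting-state networks; the connectome is the EDR kernel with 40
random long-range (> 40 mm) pairs boosted to Uniform(0.5, 1.0). Outcome
scores (HAMD6 percent change) are produced by a Gaussian copula on the rank
of each patient's baseline turbulence at λ = 0.01, hitting a target
population correlation (default 0.4) without assuming a score distribution;
baselines are plausibility-only (Uniform(8, 14) for patients on the 0–22
HAMD6 range).

What the generator does **not** emulate: scanner and physiological noise
spectra, head motion, preprocessing residuals, hemodynamic convolution,
spatial autocorrelation of measurement noise, or any empirical HAMD6
distribution. Passing tests therefore demonstrate that the estimators
recover structure planted through the model's own mechanism at realistic
sizes — not that the effects exist, or have these sizes, in clinical data.

## Problem sizes and determinism

Tests and the acceptance script run 60-region networks (300-volume cohorts
of 20 subjects per group; 1800-volume runs for coupling recovery), which
preserve every qualitative regime of the 1000-region analyses at desk scale.
Every stochastic component takes an explicit seed; child seeds derive from a
master seed via `numpy.random.SeedSequence`, so cohorts, fits and
perturbation reports are bit-reproducible. Degenerate inputs (constant
series, empty scale grids, too-short series, non-finite cells, asymmetric
connectomes, unsatisfiable spacing) raise typed errors naming the offending
stage, file location or subject.

## Known limitations

- Euler–Maruyama at dt = 0.1 s has O(dt) weak error; the limit-cycle radius
  carries a ~ω²dt/2 relative bias (0.4% at 0.03 Hz), well inside the 1%
  verification band but visible at higher frequencies or coarser steps.
- The FC-vs-distance objective is shallow near its optimum at clinical run
  lengths; group-level G estimates from 300-volume cohorts are only accurate
  to ±1–2 grid steps (0.1–0.2 in G).
- The perturbation readout saturates for large bifurcation shifts (see
  above); susceptibility comparisons are only meaningful in the
  linear-response regime.
- A single template connectome is shared by all subjects; there are no
  individual structural models.
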