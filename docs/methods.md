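# Methods

This note documents the models and procedures implemented in `omskit`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic-data generator does and does
not emulate.

## Diagonal design

**Model.** A calibration experiment for k components is laid out on an
integer grid of *conditional coordinates* in [−L, L]^k, where L is the
number of spiral positions. Position p (p = 1…L) places a centrally
symmetric pair of samples {+p·v, −p·v} on one main diagonal of the
hypercube, identified by a unit direction vector v ∈ {−1, +1}^k. Because
position p occupies levels ±p of *every* factor, the Latin hypercube
condition (each level of each factor occupied by exactly one sample)
holds by construction for any diagonal assignment, and every scheme is
centrally symmetric (coordinates sum to the zero vector), which pins all
factor means to the center of the experimental space.

**Diagonal enumeration.** The 2^(k−1) diagonals are enumerated by sign
patterns with the first component fixed at +1: vector j has component
i ≥ 1 equal to −1 iff bit i−1 of j is set. The default sequence cycles
j = (p−1) mod 2^(k−1). For k = 2 this is the "rule of the cross": odd
positions on the main diagonal, even positions on the anti-diagonal. For
k = 3 position 1 yields (1,1,1)/(−1,−1,−1) and position 2 yields
±2·(1,−1,1) = {(2,−2,2), (−2,2,−2)}.

**Designations.** A design is named `d{k}{DS}v{VS}{N}`: k factors, N
samples, DS and VS the IDs of the first training and test samples. The
grammar fixes k, DS, VS to single digits (all standard designs comply);
multi-digit variants are rejected loudly rather than guessed. The center
sample always has ID 0 and position p contributes IDs 2p−1 and 2p, so N
odd ⟺ the center is included ⟺ min(DS, VS) = 0. For VS = 0 the center is
a *test* sample; the spiral test positions then start at 3 rather than 1,
because a test pair at position 1 would sit on levels adjacent to the
center and violate the adjacency rule below.

**Built-in test set.** Test samples are the pairs at every `step`-th
(default third) spiral position starting from `start_position`, except
the maximal position (edge samples stay in the training set, since the
hull of the training set must still cover the test samples). Two rules
are re-verified after selection and reported as a warning on violation:
no two test samples on adjacent levels of any factor, and no test sample
at the edge. Removing the test subset leaves every diagonal represented
and keeps all column means at zero, so the training-only model is not
biased by the split.

**Diagnostics.** `validate_scheme` reports (a) the Latin-hypercube flag
by exhaustive level occupancy; (b) pairwise Pearson correlations of the
coordinate columns — population form Σxy/√(Σx²Σy²), exact because the
means are identically zero; (c) coverage as the convex-hull volume of
the samples divided by (2L)^k (Qhull; the shoelace value 528/576 ≈ 0.917
for the standard 25-sample two-factor design); (d) per-diagonal sample
counts.

**Sequence optimization (k ≥ 4).** Beyond three factors the filling is no
longer invariant to the diagonal order. The optimizer exhaustively scores
all permutations of the 2^(k−1) diagonals applied cyclically and returns
the sequence minimizing the maximum absolute pairwise factor correlation
(computed in closed form from position-weighted sign products, so the
8! = 40320 candidates for k = 4 evaluate in well under a second). The
max-|r| objective is our choice; no canonical criterion exists. Instances
with more than `max_positions` (default 10) positions, or k > 4, raise an
explicit "too large" error recommending the default sequence.

## Synthetic data

The generator produces every input class the other modules need; all
generators are pure functions of (parameters, seed).

- **Mixture spectra.** Beer–Lambert forward model A = C·E + baseline +
  noise, with pure-component absorptivities E as sums of Gaussian bands
  and the default axis 400–1100 nm at 1 nm (the visible/short-NIR window
  of low-cost LED analyzers). The scatter baseline is a·(λ/λ_min)^(−p)
  with a particle-size proxy in [0, 1] that raises both amplitude and
  exponent — the simplest monotone background whose shape responds to a
  homogenization-like variable. It is an emulation, not Mie/Rayleigh
  physics.
- **Hierarchical noise.** Batch/sample/position effects are scalar
  offsets shared by the whole spectrum of the group; replicate noise is
  per-channel i.i.d. Gaussian. This makes a one-channel ANOVA recover the
  configured sds exactly in expectation, which the tests exploit. Real
  heteroscedastic, wavelength-correlated instrument noise is *not*
  emulated, so passing tests demonstrate correctness of the estimators,
  not robustness to every real noise structure.
- **Process series** multiply each time point's noiseless spectrum by
  exp(N(0, σ²)) — the total-intensity turbulence of fluidized-bed
  processes that time-domain smoothing is designed to remove.
- **Two-class spectra** add an extra Gaussian band of configurable
  amplitude to class 1 with the sample → position → replicate hierarchy
  present, so segmented CV by position or sample is meaningful.
- **Dissolution batches** share the material constant m while k varies
  uniformly over a configured range, and expose a noiseless feature
  linearly linked to k, standing in for the spectral quantity a process
  calibration would predict.

## Preprocessing

- Reference normalization: A = −log₁₀(I/I_ref); any non-positive
  intensity is an error naming the measurement and channel.
- Internal (reference-free) normalization divides each measurement by its
  own comparison-channel intensity and takes log₁₀, landing in optical-
  density-like units; the output is exactly invariant to per-measurement
  multiplicative gain. Ratio-then-log is our formula choice.
- Time-domain moving average uses shrinking symmetric windows at the
  series edges (no padding — fabricating data at process start/end is
  worse than a locally smaller window), so window 1 is the identity and
  interior white-noise variance falls as 1/W. The window is always an
  explicit parameter: published uses employ different widths (e.g. 15,
  47, 101 points) for different purposes, so no default is safe.
- SNV uses the sample (n−1) standard deviation; derivatives are
  Savitzky–Golay with explicit order/window/degree and a guard that
  refuses windows wider than the channel count (the few-channel case
  where spectral smoothing is inapplicable).
- Block augmentation concatenates same-measurement blocks column-wise,
  keeping block provenance per column; "unit total variance" scaling
  divides each block by the square root of its summed column variances.
  If the concatenated axis is not strictly monotone (different methods,
  overlapping ranges), a synthetic column index axis is substituted.
- The combinatorial search evaluates every candidate pipeline under one
  injected validator (same model settings, same split) and ranks by
  error with deterministic tie-breaking; pipelines that violate guards
  rank last with infinite error rather than aborting the search.

## Channel model and genetic algorithm

A channel is (center, width, weight shape); the response is the
weight-normalized mean Σw·x/Σw on the axis grid, linear in the spectrum.
Width is the full width for boxcar/triangular weights and the FWHM for
gaussian weights, matching how LED emissions are specified
(maximum / half-height width). Channels may overlap freely unless a
minimum center separation is configured.

The GA (the literature specifies the two-loop structure but no
operators) uses tournament selection of size 2, uniform crossover over
center-sorted channel loci, Gaussian mutation of centers (sd = 5 % of
the axis span) and widths (sd = 20 % of the width range) clipped to
constraints, add/remove-channel moves within the count bounds, elitism
of 1, and an inner stop after the generation budget or 20 stagnant
generations. Discrete candidate grids (e.g. an LED inventory) replace
the Gaussian moves by resampling from the grid. Infeasible offspring are
repaired by re-mutation and, failing that, replaced by fresh feasible
chromosomes, so no evaluated individual ever violates the constraints.
The outer loop runs `n_restarts` independent populations; each converged
inner solution is scored by the injected cross-validation (LOOCV by
default — the outer validator is deliberately pluggable because no
canonical choice exists) and the global best by RMSECV is returned, with
the per-restart best-fitness traces (monotone non-increasing) attached.
Preprocessing co-optimization adds one integer locus indexing a finite
catalogue of pipelines applied to the full spectra before reduction;
processed training sets are cached per index.

## Calibration and validation

MLR is ordinary least squares with an intercept and a hard rank check
(collinear channels raise with advice to use PLS or drop channels). PLS
extracts latent variables by NIPALS on centered data — *no autoscaling*
by default, since optimized channels share units and autoscaling
amplifies noise channels; at full rank its predictions coincide with
OLS. Cross-validation folds are whole segments in sorted label order,
so results are bit-reproducible; singleton segments reduce SCV exactly
to LOOCV. The hierarchy must nest (each finer label within one coarser
label) and every level needs at least two segments. LV selection scans
1…max_lv against the built-in test set and takes the smallest count
whose RMSEP is within 5 % of the curve minimum (a parsimony rule of
ours; the test set is the selection instrument, the 5 % band the knob).

PLS-DA regresses the 0/1 class coding and assigns class 1 at predicted
values ≥ 0.5. Confusion percentages follow %Sn = 100·TP/(TP+FN),
%Sp = 100·TN/(FP+TN), %Ac = 100·(TP+TN)/total; displayed integers are
rounded half-up (the convention is not standardized; raw values are
retained), and a zero denominator yields an explicit undefined marker,
never 0. Slope-and-bias transfer fits the least-squares line mapping
slave predictions onto reference values and returns the corrector
ŷ ↦ slope·ŷ + bias.

## Dissolution kinetics

φ(t; m, k) = 100·k·(e^{(m+k)t} − 1)/(m + k·e^{(m+k)t}), evaluated in the
overflow-free form 100·k·(1 − e^{−(m+k)t})/(m·e^{−(m+k)t} + k): φ(0) = 0,
strictly increasing, asymptote 100 %. Units: m and k are inverse time in
whatever unit t carries; rescaling t by c rescales both estimates by 1/c.
Fitting is nonlinear least squares in (log m, log k) — positivity by
construction — from a 4×4 multi-start grid of offsets {−3, −1.5, 0, 1.5}
around (0.1, 0.1); the reported covariance is σ²(JᵀJ)⁻¹ in log-parameter
space at the optimum. A prior contributes a Gaussian penalty on log m
(MAP); the diffuse prior is the flat limit, i.e. batch 1 of the
sequential chain is a plain NLS fit. Successive Bayesian estimation
chains only m (the material constant) through the batches while k is
re-estimated freely each time, matching the physical roles of the two
constants; the posterior precision on m accumulates across batches. A
change of coating material should reset the chain — the chain operates
on whatever batch list the caller passes, so a reset is a new call.

## Trajectory monitoring

The trajectory is the projection of time-ordered measurements onto PCA
scores of completed normal batches (or onto calibration-model
predictions, one per axis). The normal region is delimited by a Hotelling
T² limit — a(n²−1)/(n(n−a)) F₁₋α(a, n−a) for a components and n training
samples — plus a residual (Q) limit at the training residual quantile.
Each limit is taken at (1+c)/2 so that the combined false-alarm rate of
the two tests is bounded by 1 − c (Bonferroni); this is what the
in-distribution alarm-rate test checks. Scores are optionally smoothed
by a centered moving average before classification (noisy process
trajectories are read smoothed; raw scores are kept in the output), an
alarm is the first excursion, and the end-point flag latches when the
smoothed point enters a user-supplied box in score or prediction space.
Acceptable-quality regions for raw material and product are
application-defined and enter only as such boxes.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed (a single seed drives a
whole pipeline run, giving identical artifact hashes). The test suite
uses deliberately small instances — 25-sample designs, 141-channel
spectra, GA populations of 16–24 over ≤ 30 generations, 10⁴-point
Monte-Carlo checks, 100-seed repetition studies — chosen so each
statistical property is resolvable with comfortable margins at these
sizes. The demo pipeline completes in a couple of seconds on one CPU.

## Known limitations

- No physical scattering, fluorescence EEM, or instrument-specific line
  shapes in the generator; conclusions about real matrices (milk,
  granulates, tissue) require real spectra.
- MCR-based unmixing, iPLS-style interval baselines, D-optimal and other
  non-diagonal designs, and cloud/global model hosting are out of scope.
- The diagonal-sequence optimizer is exhaustive-only (k = 4, small L);
  larger instances need heuristics that are deliberately not provided.
- The GA is a stochastic optimizer: equivalence with exhaustive search
  is guaranteed only with enough restarts relative to the search space
  (the tests pin instances where coverage is near-certain).
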