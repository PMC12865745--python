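# Methods

This note documents the models, statistical procedures, parameter
defaults, numerical choices, and limitations of `adcfmri`. Everything
stated here is computed by the package's tests or by
`scripts/acceptance.py`; nothing is asserted from outside sources.

## Stimulation paradigm and acquisition

The default paradigm is a visual block design: 24 s initial rest followed
by 12 epochs of 16 s stimulation + 24 s rest (504 s total). Flash
frequency (1 or 25 Hz) and flash duration (10 ms) are carried as metadata
only — regressors model whole blocks, not individual flashes. Sample `i`
of a series with repetition time `tr` covers `[i·tr, (i+1)·tr)`, and a
sample is "stimulation" when its start time lies in a block; this is
exact for trigger-locked acquisitions and makes every derived quantity
(boxcar mass, epoch windows) integer arithmetic.

Two acquisition contrasts share the geometry and the 1-s TR: a BOLD
series (all volumes unweighted) and a diffusion-weighted series strictly
alternating b = 200 and b = 1000 s/mm² (b-low first by default; the order
is a config field). Dummy volumes are a property of real data ingestion
(`n_dummies`, stripped on read); the phantom emits post-dummy series.

## Phantom signal model

Per voxel, with region-wise parameters,

    S(b, t) = s0 · (1 + a_v·r_v(t)) · [ (1 − f(t))·e^(−b·D(t)) + f(t)·e^(−b·D*) ]
    D(t) = d0 · (1 + a_d·r_d(t)),   f(t) = f0 · (1 + a_f·r_f(t)), clipped to [0, 1)

where each `r_x` is a unit response waveform (peak 1) locked to the
stimulation blocks. The three mechanisms are independently switchable:

- **Multiplicative BOLD** `a_v` — a T2/T2*-like gain. It cancels exactly
  in the ADC ratio (below), which is the design premise of the
  acquisition.
- **Diffusivity modulation** `a_d` — negative `a_d` (ADC decrease)
  encodes excitatory activity, following the association of activity with
  cell swelling and reduced extracellular diffusivity.
- **IVIM contamination** `a_f` — vascular contribution enters through the
  perfusion fraction `f`, not through `D`, making "residual vascular
  contribution" a separable mechanism. With `f0 > 0` the biexponential
  makes the measured ADC increase with `f`, producing the positive,
  BOLD-shaped ADC responses seen in well-vascularized regions.

Response waveforms are either `block` (boxcar smoothed by a first-order
exponential, τ = 2.5 s by default — rodent hemodynamics are fast) or
`double_peak` (Gaussian "novelty" peaks of width 2 s at block onset and
offset over a plateau, the shape seen at high flicker frequencies; the
parameterization is this package's own, since only the qualitative shape
is established). Waveforms are normalized to unit peak so the peak
modulation equals the configured amplitude exactly.

**Pair-constant physiology.** For the interleaved contrast the
physiological waveforms are sampled at 2-s pair resolution and held
constant across the two volumes of each b-value pair. Real alternating
acquisitions violate this: T2 changes between successive volumes and
leaks into the ADC at response transients (a known limitation of
alternating-b designs). The phantom deliberately idealizes it away; with
per-volume sampling the multiplicative factor would not cancel (a 2.2%
BOLD block produces a spurious −1.5% ADC transient at onset) and the
cancellation property would be unattainable by any analysis.

**Noise and drift.** Magnitude (Rician) noise: `sqrt((S+g1)² + g2²)` with
two independent Gaussian draws of width `noise_sigma` per volume
(Gaussian noise is a config option for analytic tests). Default
`noise_sigma = 1.5` at `s0 = 1000` (image SNR ≈ 670). This default is
deliberately high — it was fixed by a power analysis so that
single-subject voxelwise detection of the weakest planted response
(−0.5% ADC) is near-ceiling: the phantom's default regime verifies
pipeline *logic*, not statistical power, and the knob can be lowered to
emulate realistic rodent acquisitions (tSNR 50–150). A multiplicative
sinusoidal drift (0.5%, 300-s period, random phase per region) emulates
slow scanner drift and is removed by the high-pass filter.

**Presets.** Six conditions encode the reported rat visual-system
response amplitudes as ground truth, planting the response in one region
of the default seven-region label map (mSC, lSC, DLGn, V1, CC, Hipp,
RSC on a 32×32×4 grid, 0.38×0.38×1.5 mm voxels — desk-scale stand-in for
an atlas segmentation):

| preset | BOLD peak | ADC peak | ADC mechanism |
|---|---|---|---|
| mSC_1Hz | +2.2% | −0.5% | diffusivity (excitatory) |
| lSC_1Hz | +1.5% | +0.7% | perfusion fraction (vascular) |
| CC_1Hz | 0 | −0.3% | diffusivity |
| mSC_25Hz | +2.2% (double-peak) | −0.2% | diffusivity |
| lSC_25Hz | +1.2% (double-peak) | +0.6% | perfusion fraction |
| CC_25Hz | 0 | −0.2% | diffusivity |

Amplitudes (`a_v`, `a_d` or `a_f`) are calibrated by scalar root-finding
(Brent) on the *noise-free pipeline output* — the epoch-averaged,
baseline-normalized peak of the model time course, including the
biexponential nonlinearity and the six-sample baseline convention — so
the configured peaks are recovered exactly (tests assert ±0.02
percentage points). Vascular presets use `f0 = 0.05`; excitatory presets
`f0 = 0`.

## ADC construction

`split_interleaved` separates the alternating series into b200 and b1000
series of half length at doubled TR, retaining original volume indices.
`compute_adc` evaluates `ADC(t) = ln(S_low/S_high) / (b_high − b_low)`,
algebraically identical to `1/(b1−b2)·ln(S_b2/S_b1)` but without a
negative denominator. Voxels with any nonpositive sample are flagged in a
validity mask (and set to NaN) rather than clipped or raised on: Rician
noise at low SNR legitimately produces near-zero magnitudes, and such
voxels must be excluded from inference, not silently altered.

`interpolate_pairwise_adc` builds a 1-s series for plotting: each
b-value series is linearly interpolated to the 1-s grid and the ADC is
formed from one measured and one interpolated value per time point.
Output length is `2n − 1`; endpoints beyond a series' first/last
measurement use the nearest measurement (a declared convention — the
handling of endpoints is not otherwise constrained). Interpolated ADC is
never used for GLM inference, only for epoch-average plots.

**High-pass filter (100-s cutoff).** Drift removal regresses out a
cosine *and* sine basis at half-cycle frequencies with periods ≥ cutoff
and restores the temporal mean. Both quadratures matter: a
cosine-only basis leaves ~24% of an off-grid drift sinusoid, both
quadratures leave < 1e-7, while the 40-s epoch frequency passes ≥ 95%.
Basis regression has no phase distortion and handles short series
exactly; series shorter than the cutoff pass through with a warning.

## Statistical mapping

**Boxcar GLM** (BOLD): per-voxel OLS on `[intercept, stimulus boxcar]`;
z = signed t mapped through exact tail probabilities
(`t.logsf` → `ndtri_exp`, capped at |z| = 40).

**FIR GLM** (ADC): the stimulus boxcar convolved with 4 lag-bin
indicators spanning a 16-s window, plus intercept; an omnibus F-test that
all FIR coefficients vanish, mapped to a one-sided positive z. The
F-test is sign-blind by construction, which is why response polarity is
recovered downstream from the response shapes instead.

**Cluster-extent correction.** Supra-threshold voxels (|z| > 2.3 by
default; one-sided for FIR) are grouped by 26-connectivity (stated
because it is otherwise a silent convention). Cluster extent p-values
come from a permutation null of the maximum cluster extent, computed by
recomputing the GLM under random time permutations of the *full-model
residuals* (Freedman–Lane). Two design points deserve emphasis:

1. *Residuals, not data.* Permuting the raw series would scatter any true
   response into the null; with a periodic block design even circular
   shifts stay partially aligned with the stimulus-locked subspace at
   every lag (the design repeats every 40 s), which measurably corrupts
   the null in either direction. Full-model residuals are signal-free by
   construction.
2. *Augmented residualization for the boxcar.* The boxcar statistic
   deliberately under-models the smoothed response, so its own residuals
   retain block-edge transients; residualizing with the FIR design (which
   spans response-shaped signal of any polarity) removes them while the
   statistic itself remains the boxcar t.

Time permutation assumes temporally white noise after drift removal —
true of the phantom and consistent with leaving autocorrelation
(prewhitening) out of scope. Measured null family-wise error over 200
null phantoms at |Z| > 2.3, α = 0.05: within [0.01, 0.10] (slightly
conservative, 1–3%). A cluster survives at extent p < α with
`p = (1 + #{null ≥ extent}) / (n_perm + 1)`; default `n_perm = 500`,
minimum 100 enforced.

**Group level.** Subject z maps (synthetic subjects share the grid,
standing in for template registration) are combined by a one-sample t
across subjects, mapped back to z; zero-variance voxels are capped at
|z| = 8. Cluster correction at the group level uses a sign-flipping
permutation null (valid under the symmetric-null assumption), with
default cluster-forming threshold 1.5 or 2.3.

## Response classification

Voxels in surviving clusters are summarized by their epoch-averaged
fractional-change response: each 40-s epoch window (starting 6 samples
before onset) is divided by the mean of its *first six samples* and 1 is
subtracted, then windows are averaged. "First six volumes" is
interpreted at each stream's native sampling (6 s of baseline for BOLD,
12 s for native ADC) and as *pre-onset* samples — the window placement
(default `pre_onset_samples = 6`) is exposed as a parameter because the
convention is not fixed by the procedure itself; pre-onset baselines
match how such responses are plotted.

Pooled responses (rows = voxels, across subjects) are clustered with
Euclidean K-means, k = 10, k-means++ initialization, 10 restarts, fixed
seed (deterministic). Euclidean distance rather than time-warping
metrics is appropriate because responses are trigger-locked; clustering
epoch-averaged responses rather than full time courses makes rows
comparable across subjects with independent noise. Each cluster's
polarity is the sign of its centroid mean over the stimulation-window
samples; voxels inherit their cluster's polarity, and centroids with
|mean| < 1e-12 join neither pool (logged). k = 10 is kept even when the
phantom plants fewer archetypes — surplus clusters are harmless after
polarity pooling.

Regional average responses follow the strict order: voxel average →
per-epoch baseline normalization → epoch average → mean ± SD across
runs.

## Problem sizes and determinism

Default phantom: 32×32×4 grid, 504 volumes, 6 subjects (each subject a
fresh seed), 500 permutations — the full pipeline runs in well under ten
minutes on one CPU, and the test suite's calibration checks use 200 null
phantoms with 199 permutations each. Every stochastic step takes an
explicit seed; the pipeline manifest records versions, seeds, parameters
and content hashes, and reruns are hash-identical.

## Limitations

- The phantom idealizes the acquisition: pair-constant physiology (no
  within-pair T2 transients), no motion, distortion, ghosting, or
  multi-coil artifacts, no realistic anatomy, and temporally white noise.
  Passing tests therefore validate the analysis logic and its statistical
  calibration under the stated model — not robustness to the
  preprocessing problems real data carry (denoising, unringing,
  distortion and motion correction, registration are upstream of this
  package).
- The default SNR is verification-grade; at realistic rodent tSNR,
  single-subject voxelwise detection of sub-percent ADC responses is not
  near-ceiling and group pooling carries the inference.
- Temporal autocorrelation is not modeled; the permutation null relies on
  exchangeability of time points after drift removal.
- IVIM parameters (`f`, `D*`) are simulated, never estimated; tensor or
  multi-shell diffusion modeling is out of scope.
- The group model is a one-sample test on z maps, a stand-in for a full
  mixed-effects analysis.
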