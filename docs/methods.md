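# Methods

This note documents the models implemented in `erpsnn`, the defaults and why
they are what they are, what the synthetic data do and do not emulate, and
the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic oddball-ERP cohorts (`erpsnn.simulate`)

**Task schedule.** The generator reproduces a 4-tone auditory oddball: two
blocks, each with 90 standard tones and 18 noise bursts, targets and
distractors (288 events, 62.5% standards, 12.5% each rare kind), event order
shuffled per block, inter-stimulus interval drawn uniformly from
1100 ± 100 ms. Composition is exact by construction; only order and timing
are random.

**Averaged ERP samples.** One channels × time matrix (62 × 1300 at 1 kHz,
stimulus onset at sample 0) per participant × time point × stimulus.
Each sample is a sum of component templates with additive Gaussian sensor
noise (default SD 0.5 µV, the residual noise level of an averaged ERP; an
AR(1) coefficient is available but off by default, so temporal
autocorrelation of the noise is deliberately absent at default):

| component | latency | width (2σ) | amplitude | topography |
|---|---|---|---|---|
| N100 | 100 ms | 30 ms | −8 µV | frontocentral |
| N200 | 200 ms | 40 ms | −6 µV | frontocentral |
| late positivity (target) | 340 ms | 120 ms | +9 µV | occipitoparietal-maximal |
| late positivity (distractor) | 320 ms | 120 ms | +9 µV | anterior-maximal |

Topography gains are smooth functions of the anterior–posterior scalp
coordinate, kept below 0.65 so planted multipliers never clip at the ±1
gain bound. Each component carries an event-locked oscillatory burst (a
cosine carrier under the same Gaussian envelope; 40 Hz at 1.5× the envelope
for the late positivity). The burst is essential to the pipeline's physics:
a purely monophasic bump of realistic width changes millisecond-scale first
differences by ~0.15 µV, far below any sensible spike-encoding threshold, so
without the burst, amplitude structure would never reach the spike domain.
With it, component gain translates monotonically into spike density — the
quantity the reservoir statistics consume.

**Planted effects (the recovery targets).**

- `frontal_gain_delta` (default 1.0): frontal-channel late-positivity gain
  is multiplied by `1 + delta` for experimental-group samples at every time
  point after T1. The default doubles the frontal late positivity — a large
  training effect, commensurate with the near-doubling of frontal weights
  the method is meant to detect.
- A per-participant latent `z ~ N(0,1)` scales right-frontal late-positivity
  gain by `1 + 0.3 z` (`rf_gain_sd`).
- Psychometrics: FFMQ is coupled to `z` with correlation
  `psychometric_coupling` (default 0.6); BDI and the three DASS scales are
  coupled negatively. The generative latent is exposed as `latent_rf_gain`
  in the psychometric table as ground truth for recovery tests.

**What the generator does not emulate:** single trials, blinks or other
artefacts, volume-conduction correlations between channels, reaction times,
non-stationary noise, or distinct T2 vs T3 distributions (both are
"post-training" for the experimental group). Passing tests therefore show
that the pipeline recovers planted amplitude/topography/coupling structure
from averaged, independently-noisy epochs — not that it handles raw EEG.

## Spike encoding (`erpsnn.encoding`)

Threshold-based representation: `s(t) = sign(Δx(t))` when `|Δx(t)| > θ`,
else 0; the first sample never spikes and ties produce no spike (strict
inequality). `θ` is either absolute or `α · SD(Δx)` with α = 1.5, giving
~13% spike density on noise-dominated differences — sparse enough that the
reservoir integrates rather than saturates. Under `sd_scaled` the scope is
**global** by default (one θ pooled over the sample's channels): a
per-channel θ normalises every channel to the same spike count, which erases
exactly the between-channel amplitude differences the connectivity analysis
is designed to detect. Per-channel scope remains available
(`threshold_scope="per_channel"`) for channel-normalised dialects.

## Reservoir (`erpsnn.reservoir`)

**Geometry.** The packaged grid is a synthetic stand-in: exactly 1471 sites
on a 1 cm lattice filling a brain-proportioned ellipsoid in a
Talairach-like frame (the published atlas grid is not redistributable; only
its site count and spacing are reproduced). The 62-channel montage uses
standard 10-05 scalp coordinates in the same frame; CB1/CB2 take the
PO9/PO10 positions. Each channel maps to its nearest unclaimed grid neuron
(montage order breaks ties), which is injective for the packaged fixtures.
`NeuronGrid.subsample(n)` draws a uniform random subset of sites for
scaled-down runs; the reduced lattice is coarser, so reduced-grid runs use a
wider wiring radius (40 mm at 200 sites vs 25 mm at 1471).

**Wiring.** `p(i→j) = p₀ exp(−d²/r²)` with a hard cutoff at `d = r`
(defaults r = 25 mm, p₀ = 0.15), no self-edges, at most one edge per
ordered pair. Initial weights are uniform on (0, 1]; a randomly chosen 20%
of neurons are inhibitory and negate their outgoing weights.

**Dynamics.** Discrete 1 ms steps, one-step axonal delay:
`u ← λu + Σ w·s + inj`, fire when `u > θ_f`, reset to 0, refractory.
Defaults: λ = 0.5, θ_f = 1.2, refractory 1 step. These were chosen from
measured transduction curves (region weight vs controlled input density):
long membrane memory lets the alternating ± spikes of an ERP burst cancel,
and a long refractory period caps input-neuron firing inside the burst —
either one flattens the response to exactly the density differences the
statistics need. The defaults give a monotone response. The firing log
records (neuron, step, sign of the net drive at the firing step).

**Plasticity.** Nearest-spike additive STDP with one-step pairing
resolution: on each firing, incoming edges whose presynaptic neuron fired
strictly earlier are potentiated by `A₊ e^(−Δt/τ)` and outgoing edges whose
postsynaptic neuron fired strictly earlier are depressed by
`A₋ e^(−Δt/τ)`; simultaneous spikes are not paired. Excitatory weights are
clipped to [0, w_max]; inhibitory updates act on the magnitude, mirrored
into [−w_max, 0]. Defaults A₊ = 0.02, A₋ = 0.01 (2:1 so sustained drive
yields net strengthening), τ = 10 ms, w_max = 2. One pass per sample by
default (configurable).

**Condition models share one initial network.** For the region-weight /
ANOVA / correlation path, every per-participant model is trained from the
same deterministic initial wiring (weights reset per sample). Re-drawing
wiring per model adds ±0.04 initialisation noise to region means — larger
than typical planted effects — while a shared prestructured network makes
between-model weight differences reflect the data alone. Leave-one-out
classification instead re-initialises per fold with a seed keyed to the
held-out sample id (so results are independent of sample ordering).

## deSNN classification (`erpsnn.desnn`)

Rank-order initialisation `w_r = mod^order(r)` (mod = 0.9; order of r's
first spike, ties broken by neuron index, never-firing neurons get 0) plus
`drift = 0.25` per subsequent spike; Euclidean kNN with k = 1; vote ties
break by smaller mean distance, then alphabetical class order. Per fold:
fresh reservoir, unsupervised STDP on the n−1 training samples (in
canonical sample-id order), then each training sample and the held-out
sample are re-passed through the frozen trained reservoir to form output
neurons. Baselines flatten samples to vectors and use fixed
hyperparameters: MLP with one hidden layer of 20, RBF SVM at default
regularisation, and one-vs-rest linear regression with argmax labelling.

**Known limitation — familiarity shift.** The unsupervised STDP pass
strengthens exactly the pathways each training sample drives, so a
training sample's re-passed firing log rides an enhanced response while the
held-out sample's does not. At desk scale this systematically depresses
leave-one-out accuracy (disabling STDP raises 3-class accuracy from ~0.27
to ~0.53 on the synthetic cohort); together with the by-design identity of
the T2 and T3 distributions (ceiling ≈ 2/3), synthetic classification
accuracies are modest. The protocol is kept as published; the chance-level
control (permuted labels) is unaffected because predictions are independent
of the label assignment.

## Connectivity statistics (`erpsnn.connectivity`, `erpsnn.stats`)

Reservoir neurons are assigned to scalp regions by Voronoi partition over
the input neurons; a connection belongs to its presynaptic neuron's region
(postsynaptic and midpoint attribution available). Cells report mean |w| —
absolute, so inhibitory edges do not cancel excitatory ones; a signed
variant is available. Midline-assigned connections are excluded from
hemispheric cells but included in per-model totals. Cells with no member
connection are flagged missing rather than reported as zero. The FIN
(feature interaction network) counts, for each ordered cluster pair, spikes
emitted in one cluster and delivered along existing edges into the other.

The mixed repeated-measures ANOVA is the classical univariate design: any
crossed within-subject factors, one optional between factor, subjects
nested in groups, balanced complete data required (missing cells are named
in the error). Each within effect is evaluated through orthonormal
contrasts of the within-cell means; its error stratum is the
effect-by-subject interaction; Greenhouse–Geisser ε comes from the
contrast-space error covariance with the 1/df floor, and ε = 1 exactly for
single-df effects. Effect size is partial η². The implementation agrees to
machine precision with textbook sums of squares and with independent
implementations on shared designs (see `tests/test_stats.py`). Note the GG
correction is guaranteed conservative (larger p) only when F > 1.
Correlations are Kendall tau-b with two-sided p; constant inputs are
flagged undefined; an optional Benjamini–Hochberg column is off by default,
matching the uncorrected reporting convention of the analysis it mirrors.

## Problem sizes and determinism

Full-scale runs (1471 neurons, 1300-step epochs) take ~30 ms per sample
model. The test and acceptance suites use reduced sizes chosen as package
defaults for desk-scale validation: 200-neuron subsampled lattices for
recovery statistics, 80–100 neurons and 200–600-step epochs for
leave-one-out protocols. Every random draw derives from an explicit seed
(`numpy.random.SeedSequence` with stable stage/sample keys), so cohorts,
reservoirs and whole experiment runs are byte-identical across reruns with
the same configuration.
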