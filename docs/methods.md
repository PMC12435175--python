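# Methods

`ppgbp` is a desk-scale benchmarking pipeline for estimating blood
pressure (BP) from the raw photoplethysmogram (PPG). It reproduces the
*methodology* of large PPG→BP benchmark studies — calibration-scenario
splits, joint SBP/DBP deep regression, label-shift importance
weighting, and an agreement/bootstrap evaluation suite — on synthetic
multi-site cohorts small enough to run on one CPU in minutes. It makes
no claim about absolute error levels on real recordings; the synthetic
cohorts exist so that every qualitative claim of the methodology can be
exercised and tested end to end.

## The regression problem

Each sample is a univariate PPG segment x ∈ ℝ^L sampled at 125 Hz
(L = 1250, 625 or 262 for 10 s, 5 s and 2.1 s sites), labeled with the
segment's systolic and diastolic pressure (SBP, DBP, mmHg). A network
f_θ maps a segment to a joint prediction (ŜBP, D̂BP); training
minimizes the summed per-output squared error

  ℒ(θ) = (1/n) Σᵢ [ w⁽ˢ⁾ᵢ (ŜBPᵢ − SBPᵢ)² + w⁽ᵈ⁾ᵢ (D̂BPᵢ − DBPᵢ)² ],

with unit weights by default and importance weights under label-shift
adaptation (below). Optimization uses AdamW (decoupled weight decay
0.01), learning rate 10⁻³, 50 epochs, and an effective batch of 512
assembled by gradient accumulation from micro-batches; accumulation is
exact (micro-losses are scaled by micro/effective before backprop), so
results are identical to true large-batch steps. After each epoch the
validation score — the mean of the SBP and DBP validation MAEs — is
computed and the best-scoring parameter snapshot is kept. The
"validation score" is not further specified in the benchmark protocol
this follows; MAE is the primary metric, so selecting on it is the
most faithful reading. No learning-rate schedule or early stopping is
used; a one-pass range-test learning-rate finder is provided for the
state-space model.

All architectures (LeNet-style CNN, two bottleneck XResNet1d depths,
an InceptionTime-style network, and a simplified diagonal state-space
stack) end in global average pooling over time followed by a 2-output
linear head, so a model trained at one segment length runs unchanged
on any other length ≥ 64 samples (the deepest stride stack needs at
least one time step before pooling). A global `scale` knob multiplies
channel widths; desk-scale experiments use `scale=0.5` or `0.25`. The
state-space layer computes its long convolution kernel as a learned
mixing of a fixed bank of damped cosines (the impulse responses of a
diagonal recurrence with log-spaced decays); it is a deliberately
simplified member of the structured state-space family, not a full
NPLR/HiPPO implementation, and claims no equivalence to it.

The network stack itself (reverse-mode autodiff over numpy arrays,
conv/batch-norm/pooling layers, AdamW) lives in `ppgbp.nn`; every
primitive's gradient is verified against central finite differences in
the test suite.

Two training-protocol details are the package's own choices:

* **Per-segment z-scoring** (mean 0, SD 1) is applied inside the model
  before the first convolution. Raw-segment preprocessing is rarely
  reported in this literature; z-scoring is the conservative choice,
  and it is the reason the synthetic generator encodes BP in shape
  rather than amplitude (below).
* **Output-bias initialization at the train-label means.** Adam's
  per-parameter step is bounded by the learning rate, so reaching an
  absolute offset of ~120 mmHg from zero would consume thousands of
  updates; starting the head bias at the label means lets the short
  desk-scale budgets spend their steps on the signal, not the offset.
  It changes nothing asymptotically and is on by default.

## Synthetic cohorts

A cohort is a set of *sites* (datasets). Each site has a label
distribution (SBP/DBP mean ± SD, drawn jointly with correlation 0.7 so
that the pulse-pressure floor SBP − DBP ≥ 15 mmHg rejects almost
nothing and the published marginals are preserved), a subject count,
segments per subject, segment length, sensor bandwidth (low-pass
cutoff), noise level and heart-rate distribution. Six presets carry the
published label statistics of the emulated datasets (two large clinical
sources at 10 s segments and four external sets at 5 s / 2.1 s); their
subject counts can be scaled down for desk runs. A two-component
mixture (`tail_boost`: core normal + SD×2.5 tail component) emulates
device-validation populations that emphasize BP extremes.

Each subject has BP *setpoints* plus within-subject segment-to-segment
variability (6/4 mmHg SD for SBP/DBP), a heart rate, and random
morphology offsets (below). Each beat of a segment is the sum of two
Gaussian pulses — a systolic peak at fraction μ₁/T = 0.15 of the beat
period with width 0.08 T, and a reflected wave of width 0.12 T.
BP is encoded in three **normalization-invariant shape features**:

* reflected-wave delay Δ/T = 0.30 − 0.0010·(SBP − 120), strictly
  decreasing in SBP;
* systolic upstroke steepness: the left width of the systolic pulse is
  multiplied by clip(1 − 0.003·(SBP − 120), 0.5, 1.5), so higher SBP
  gives a steeper upstroke (a well-known qualitative property of real
  pulse waves);
* reflected/systolic amplitude ratio r = clip(0.30 + 0.004·(DBP − 60),
  0.10, 0.80), strictly increasing in DBP.

Subject-level random effects on Δ (SD 0.01 T) and r (SD 0.03) make
subjects distinguishable: they create an error floor for models that
have never seen a subject, which is exactly what gives the Calib
scenario its memorization advantage. Segments additionally receive
per-beat heart-rate jitter (SD 2% of the period), additive white noise,
0.2 Hz baseline wander, and zero-phase low-pass filtering at the site's
cutoff (zero-phase so the sensor model cannot corrupt the timing code).
All constants are arbitrary but fixed; the tests rely on the monotone,
invertible structure of the maps, never on the specific values.

**Identifiability.** `decode_bp` is a brute-force inverse of the
generator: it estimates the beat period from the autocorrelation,
least-squares-fits the periodic two-pulse template (with an affine
amplitude transform as free parameters) and inverts the monotone maps.
On a noiseless cohort (noise, wander, jitter, subject effects and
sensor filtering all off) it recovers SBP and DBP to well under 2 mmHg,
before and after z-scoring — certifying that the learning problem posed
to the networks is actually solvable from shape alone. It shares no
code path with the trained models.

**What the generator does *not* emulate:** real PPG morphology and its
physiologic diversity, motion artifacts, sensor-specific waveform
distortions, demographic covariates, or any temporal structure within a
subject (segments are exchangeable). Passing tests therefore certify
the *pipeline machinery and its qualitative claims*, not clinical
accuracy on real data.

## Scenario splits

* **calib** — each subject's segments are partitioned at random across
  train/val/calib/test, so every test subject was seen in training.
  The per-subject partition is random rather than chronological because
  synthetic segments carry no time axis; real-data users should
  override this.
* **calibfree** — subjects are partitioned (defaults ≈ 80% train, 6%
  val, 3% calib, 10% test subjects, mirroring the emulated benchmark's
  proportions); all segments follow their subject.
* **aami** — subject-disjoint, with test subjects greedily selected in
  randomized order until tail quotas hold: by default ≥ 5% of test
  segments with SBP ≤ 100 mmHg, ≥ 5% with SBP ≥ 160, ≥ 20% with
  SBP ≥ 140. The thresholds mirror the device-validation population
  pattern and are configurable; unsatisfiable quotas raise with the
  fractions actually achieved. Zero quotas reduce exactly to calibfree.

The calibration subset is constructed and stored for structural
fidelity but consumed by no in-scope experiment. `verify_split` checks
disjointness, the scenario's subject semantics and the quotas by
direct counting and is run on every constructed split in the tests.

## Label-shift importance weighting

Source and target label distributions are summarized as normalized
histograms on a shared grid (5 mmHg bins over 20–260 mmHg; the width
balances density-ratio stability against resolution and is
configurable). A training sample in bin i receives

  wᵢ = max(τ, h_target,i / h_train,i)  if h_train,i > 0,  else τ,

with τ = 1 by default, so weighting only ever *up*-weights
underrepresented regions and no sample is effectively discarded.
Weights are computed separately from the SBP and DBP distributions and
applied to the corresponding output losses. Out-of-range labels clip
into the edge bins so every weight is defined; the h_train = 0 branch
cannot trigger for actual training samples (their bin is nonempty by
construction) but is implemented as stated for diagnostic evaluation at
arbitrary values. Weights are used as given — the rule has no
normalization step — with an optional mean-1 renormalization flag, off
by default. Only the target *label distribution* ever enters; the API
accepts a label sequence or a pre-built histogram and never pairs
target labels with target samples.

Dataset similarity is measured by the earth mover's distance between
SBP histograms: for uniform bins this is the 1-D Wasserstein-1
distance, computed exactly as Σ|CDF_a − CDF_b|·width. Non-uniform bins
raise (documented) rather than silently approximating.

## Evaluation

* **MAE** (primary): (1/n) Σ|pred − ref|.
* **Bland–Altman**: bias = mean(pred − ref); limits of agreement =
  1.96 × sample SD (ddof = 1) of the differences.
* **Paired bootstrap**: 1000 resamples of the test indices, the same
  multiset applied to both models; percentile 95% interval of
  MAE(other) − MAE(reference). "Significantly worse" means the interval
  lies strictly above zero — the conventional reading; percentile
  rather than BCa intervals because the choice is otherwise
  unconstrained and percentile is the simplest seed-controlled option.
  Coverage is verified by simulation (≈ 95% for equal-skill models).

## Desk-scale experiment definitions

`ppgbp.experiments` freezes the concrete study conditions used by the
test suite and `scripts/acceptance.py` (identical code paths). All use
2.1 s segments, a `scale=0.5` LeNet-style model, effective batch 64,
micro batch 32, learning rate 3·10⁻³ (the small-budget protocol), and
Vital-like label statistics unless stated:

* **Identifiability**: 12 subjects × 3 segments, all nuisances off;
  inversion MAE < 2 mmHg raw and z-scored.
* **Learning gate**: 60 subjects × 8 segments, noise SD 0.01, subject
  morphology effects off, subject-disjoint split, 60 epochs; test MAE
  must be < 50% of the median-baseline MAE for both outputs.
* **Calib vs CalibFree**: strong subject effects (Δ SD 0.03 T, r SD
  0.10), 30 subjects, 30 epochs, 10 seeds; the calib split must win
  (lower mean MAE) in ≥ 7/10 seeds.
* **Label-shift adaptation**: source site vs a target site identical
  except SBP mean +20 mmHg; noise SD 0.05, subject effects on, 10
  paired seeds; weighted training must lower target SBP MAE in ≥ 7/10.
* **EMD/OOD correlation**: one model, five targets with SBP shifts
  0–32 mmHg; Spearman ρ(EMD, OOD MAE) > 0.
* **Bootstrap calibration**: 200 replicates of two equal-skill
  predictors on 200 segments, 1000 bootstrap iterations; CI covers 0
  in 95% ± 4%.
* **End-to-end benchmark**: two sites (source + 20 mmHg-shifted
  target), calibfree, weighted and unweighted, 3 seeds; completes in
  minutes and shows ID MAE < OOD MAE in the majority of seeds.

These problem sizes are the package's chosen desk-scale conditions;
they keep the full suite in the minutes range on a single CPU while
leaving comfortable margins on every gate.

## Numerical and degenerate-input choices

Labels are float64 mmHg and subject/site IDs strings throughout, with
exact HDF5 round-trips (one group per site avoids ragged storage;
signals are stored unnormalized so the store remains a faithful data
record). Networks run in float32. Empty histograms are flagged rather
than erroring; empty stores round-trip; `select` accepts duplicate
indices (bootstrap); median of an even count interpolates; the
learning-rate finder returns the maximum rate with a warning when no
explosion is observed. All randomness flows through seeded
`numpy.random.Generator` instances: cohorts, splits, training shuffles
and bootstrap are bit-reproducible given their seeds.

## Known limitations

The generator's shape-coding is far cleaner than real PPG physiology,
so absolute MAEs here are optimistic; only orderings and qualitative
effects transfer. The simplified state-space layer has a frozen
spectrum. The AAMI-style quotas approximate a validation-population
pattern, not the certification standard itself. Bootstrap intervals
are percentile, which slightly undercovers at small test sizes.
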