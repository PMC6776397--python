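# Methods

This note documents the measurement conventions, the model behind the
synthetic-data generator, the numerical choices, and the known limits of
what the test suite demonstrates.

## Measurement conventions

The primary literature on CN intrinsic excitability states *what* each
measure is but rarely *how* to compute it robustly from sampled, noisy
sweeps. The following conventions are fixed package-wide:

- **Units.** mV, nA, seconds internally; ms and MΩ at the reporting
  surface. All unit conversion happens in `cnephys.io` on read/write.
- **Junction correction.** Raw traces are shifted once by the junction
  potential (default −11 mV, K-gluconate electrodes) before any
  measurement, so absolute potentials (RMP, AP peak, AHP) are reported
  corrected while differential quantities are unaffected. A flag on the
  series makes double correction impossible.
- **Steady state** is the mean over the final 10% of the step — long
  enough to average noise, short relative to every sag time constant in
  range.
- **R_in** uses hyperpolarizing sweeps whose steady-state deflection is at
  most 15 mV ("just below rest"), with an intercept in the line fit so a
  small rest-estimate offset cannot bias the slope.
- **τ_m** is a three-parameter single-exponential least-squares fit over
  [onset, onset + min(5·τ_init, half the step)] on sweeps with 2–10 mV
  peak deflections; τ_init comes from the 1−1/e crossing of a 1-ms-smoothed
  trace (the raw crossing is noise-advanced and destabilizes the window).
  Fits are averaged across qualifying sweeps weighted by squared
  deflection, and a fit that runs into its upper bound (a quarter of the
  step) is discarded. Multi-exponential fitting is deliberately out of
  scope.
- **Sag.** B/A is (V_ss − rest)/(V_peak − rest) with the peak taken on a
  5-ms boxcar-smoothed trace (otherwise the noise extremum biases B/A low,
  badly so when the deflection is only a few mV). τ_h is fit from the
  deflection peak to the step end on the sweep whose steady state lies
  nearest −80 mV (window ±10 mV); if no relaxation is resolvable
  (B/A ≈ 1, or the cell cannot be held near −80 mV — true of real
  cartwheel/pyramidal cells and of our cartwheel archetype) the measure is
  missing with a recorded reason.
- **Spike detection**: upward dV/dt crossing of 20 mV/ms whose following
  local maximum — the search ends at the falling-phase dV/dt crossing, so
  a close follower in a fast train is never mistaken for the same event —
  rises ≥ 15 mV above rest; events within 1 ms merge. The criterion sits
  safely below the steepest templates in range and above baseline noise.
- **AP shape** comes from the first spike of the lowest suprathreshold
  sweep. Both conventions found in the literature are computed: the
  rest-relative height and the absolute peak/AHP potentials; the absolute
  values are what enter the classifier.
- **Adaptation** is evaluated on the second-lowest spiking sweep
  (threshold-level trains are uninformative); with a single spiking sweep
  the code falls back to it and flags the provenance.
- **ISI CV** uses the sweep with the most spikes and needs ≥ 4 intervals,
  which naturally yields "missing" for onset-only bushy cells.
- **Rebound** counts spikes within 100 ms (configurable) after the offset
  of hyperpolarizing steps, maximized over sweeps.
- **f–I slope** is the least-squares slope of (count/step duration) vs
  current over the three lowest spiking levels; two levels give a flagged
  two-point slope.
- Any measure that cannot be computed becomes a missing value with its
  reason in the per-cell provenance record; a cell is never dropped for a
  single failed measure.

## The synthetic cohort generator

Two tiers, both anchored to per-class mean profiles for the six principal
classes (shipped, human-editable, in `src/cnephys/data/archetypes.yaml`).

**Feature-level sampling** draws each class's cells from a Gaussian copula
with mean-exact margins: normal for unbounded measures, lognormal for
strictly positive ones, logit-normal (numerically mean-corrected by
Gauss–Hermite quadrature) for B/A on (0,1) and the adaptation index on
(−1,1). Only means are published for the class profiles, so the
within-class spread is this package's choice: SD = 0.4 × the between-class
SD of the six class means, per measure. The only default correlation is
R_in–τ_m at ρ = 0.5 (larger cells have both lower resistance and, with
roughly common specific capacitance, shorter time constants would argue
for a positive membrane-level coupling; we keep one minimal, physiologically
motivated term). Bushy ISI CV is emitted missing. Default per-class counts
(18, 31, 32, 38, 12, 31) give a 162-cell cohort.

**Trace-level simulation** is phenomenological, not conductance-based: the
claims under test concern measures and classification, not channel
mechanisms. The subthreshold response to a step of amplitude I is

    D(t) = A(I) · (1 − e^(−t/τ)) · (b + (1 − b) e^(−t/τ_h)),

a charging curve multiplied by a sag relaxation, decaying back with τ
after offset. Hyperpolarizing drive is linear, A = I·R_pk; depolarizing
drive saturates at 12 mV above rest via tanh — a stand-in for the
rectification that keeps real cells from depolarizing linearly at 4 nA,
and what keeps interspike baselines below the spike detector's height
criterion. Two kernel parameters are *calibrated* rather than set to the
targets: because the rise is not instantaneous, the measured B/A of the
raw kernel exceeds b and the fitted τ_m underestimates τ (by up to 60%
when τ_h/τ_m is small), so the generator root-finds (b, τ) such that the
package's own extraction returns the targets on a noiseless kernel. This
keeps the closed loop honest: extraction is never adjusted to the
generator, the generator is adjusted to the measurement definitions.

Suprathreshold sweeps insert stereotyped action-potential templates — a
Gaussian spike lobe whose amplitude and width are solved per spike from
the local baseline so the absolute peak and the half-width measured at
rest + height/2 hit their targets, plus a delayed alpha-function AHP lobe
that cannot begin before the falling phase crosses the half-height level
(otherwise it narrows the measured half-width). Spike times follow the
class program: onset-only cells fire ≤ 3 spikes centered so the adaptation
index is exact; the first two spiking levels of sustained cells use the
quantiles of an exponentially decaying rate profile whose decay is solved
from the adaptation target (bounded density, so intervals never collapse);
higher levels are gamma-renewal trains with a refractory floor, rescaled
to an exact count so the f–I slope is deterministic, with the gamma shape
set from the ISI-CV target. Rebound spikes are inserted at 8 ms spacing
after the deepest hyperpolarizing step. Firing rates are r₀ + I_rate·ΔI
above threshold, capped at 350 spikes/s (real cells saturate; the cap also
bounds template overlap). Additive Gaussian noise, default σ = 0.3 mV —
a typical whole-cell baseline — is configurable.

The per-cell protocol adapts to the cell, as real protocols do: small
hyperpolarizing steps sized for 1.5–9 mV steady-state deflections, one
step solved to reach −80 mV steady state, a deep −1 nA step carrying the
rebound program, and graded depolarizing levels from threshold (set at
1.2 × the saturation scale over R_pk) in 0.1 nA increments up to 4 nA.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: channel noise and non-stationary drift,
electrode artifacts and bridge errors, true spike-shape variability within
a train (templates are stereotyped), bursting microstructure beyond a
high-CV renewal process, K_ir rectification of DCN cells, and any
correlation structure beyond the single R_in–τ_m term. Two archetype
targets are physically unreachable within the design and are reported as
the recordings would give them: the cartwheel τ_h (its −80 mV sweep
deflects only ~5 mV, leaving a sub-noise sag — the same limitation real
pyramidal/tuberculoventral protocols hit) and the cartwheel AHP, whose
target sits 21 mV above rest while interspike baselines saturate 12 mV
above rest.

## Classification choices

- z-scores use the sample-SD convention (ddof = 1), fixed repo-wide
  because it changes third-decimal results.
- LDA axes come from `eigh(S_b, S_w)`; a singular within-class scatter
  falls back to ridge shrinkage (εI with ε = 10⁻⁸·tr(S_w)/p, floored for
  the all-zero case) and is flagged on the model. Components = classes − 1;
  variance-explained fractions are the positive eigenvalues normalized to
  sum to 1.
- Prediction is nearest centroid in discriminant space; equal priors by
  default, empirical priors optional (adds a log-prior term).
- The PCA comparison scores the same nearest-centroid rule on the top-5
  principal-component scores of the standardized table, under the same CV
  protocol — the primary analyses this package follows did not state which
  classifier was scored in PCA space, so this is a documented stand-in.
- Cross-validation folds are stratified by class (with only 12 cartwheel
  cells, unstratified folds can lose a class from a training split) and
  refit standardization and imputation per training fold; fold shuffling is
  seeded.
- The subset search scores each of the C(12, k) measure subsets with 5
  repeated stratified 80/20 splits shared across subsets of a run, so
  subset comparisons are paired.
- η² is SS_between/SS_total on standardized values; p-values from the
  one-way F test; FDR adjustment is Benjamini–Hochberg across the 12
  measures simultaneously.

## Problem sizes

Defaults are desk-scale: the 162-cell cohort sizes above; recovery checks
run 6 archetypes × 20 seeds of full sweep series at 20 kHz (≈ 10 s);
the exhaustive subset search over sizes 1–4 (793 subsets × 5 splits)
takes well under a minute.

## Known limitations

- The generator's trace realism is exactly as deep as the measures it is
  asked to reproduce; it is unsuitable for studying spike-shape dynamics,
  threshold adaptation, or channel kinetics.
- At the default dispersion the six synthetic classes are more separable
  than a real mixed-strain cohort: cross-validated LDA accuracy is ~0.98,
  and the PCA-space comparison performs equally well, so the synthetic
  cohort does not reproduce the large LDA-over-PCA gap seen on real data
  where class overlap is substantial.
- Bushy f–I slopes are quantized by onset spike counts (an onset cell's
  rate barely changes with current), so the recovered I_rate for onset
  cells is accurate only to a few spikes/s/nA in absolute terms.
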