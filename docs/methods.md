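# Methods

## Model

The core of the package is a two-neuron Matsuoka oscillator used as a model
of a sensory-driven spinal pattern generator at the ankle.  Neuron 1 drives
the soleus (SOL, plantarflexor, stance muscle), neuron 2 the tibialis
anterior (TA, dorsiflexor, swing muscle).  Each neuron has an inner state
`x_i`, a rectified output `y_i = max(0, x_i)` interpreted as the muscle's
activation (EMG envelope), and a slow self-inhibitory adaptation state
`f_i`:

    ẋ_i + x_i = a_self·y_i + a_mut·y_j + s_i − b_i·f_i      (j ≠ i)
    T_i·ḟ_i + f_i = y_i
    y_i = max(0, x_i)

The connection weights are symmetric by construction (a11 = a22 = `a_self`
≥ 0, a12 = a21 = `a_mut` < 0), so mutual inhibition lets only one neuron
dominate at a time, and the adaptation (`b_i`, `T_i`) lets dominance switch
— the mechanism behind flexor/extensor alternation.  The membrane time
constant is taken as 1 s, so all dynamics are expressed in seconds; any
rescaling of that choice is absorbed by the fitted parameters.

There is no tonic descending input: the oscillator is driven purely by
sensory afferents, namely the body-weight-normalized vertical load `F` and
the hip flexion/extension angle `HA` [rad], each first-order smoothed:

    s_i = m_i·p + n_i·ṗ + w_i·q + v_i·q̇
    ṗ = r1·(F − p),     q̇ = r2·(HA − q)

`ṗ` and `q̇` inside `s_i` are the analytic lag expressions, not numerical
differences — exact, smooth, and consistent with the ODE system.  The 16
free constants are `a_self, a_mut, b1, b2, T1, T2, m1..v2, r1, r2`.

A practical note on expressiveness: with a 1 s membrane constant the inner
state is a heavily smoothed copy of the drive, so sharp within-stride
bursts are not produced by the load magnitude alone.  The four drive terms
(`p`, `ṗ`, `q`, `q̇`) form a filtered basis with staggered phases, and the
fitted weights reconstruct burst timing from that basis; the rate terms
therefore often carry large weights in good fits, which is expected and
not a pathology.

## Numerical integration

`simulate` integrates the 6-state system with an adaptive Dormand–Prince
5(4) stepper (numba-compiled; drives linearly interpolated between
samples), integrating segment-by-segment so the trajectory is evaluated
exactly on the drive timebase.  Default tolerances are rtol = 1e-8,
atol = 1e-10: the rectification `max(0, x)` is a kink the error estimator
cannot see across a step, and looser tolerances (1e-6) leave residual
errors of order 3e-5 against a dt = 1e-4 fixed-step reference, while the
tighter setting reaches ~1e-6 agreement at essentially no extra cost
(~1 ms per 7 s trial).  On step underflow or a non-finite state the
simulation falls back to the implicit Radau method (small `T2` makes the
system stiff in corners of parameter space); if both fail, a
simulation-diverged error names the time reached.

Initial conditions follow a steady-state-consistent convention: `x_i(0)`
is the first conditioned-EMG sample of the corresponding muscle,
`f_i(0) = y_i(0)`, `p(0) = F(0)`, `q(0) = HA(0)`.  This minimizes the
startup transient; the first stride is discarded from all fitting and
correlation anyway because the output becomes oscillatory only after it.

## Preprocessing

* **EMG conditioning**: centre (subtract the whole-trial mean), rectify,
  then low-pass with an order-5 Butterworth at 40 Hz.  The filter is
  applied forward–backward by default (zero phase; effective order
  doubles): the fit aligns model output to EMG timing, and a causal pass
  would lag every burst by several milliseconds and bias all
  timing-sensitive parameters.  A `zero_phase=False` flag restores the
  single causal pass.  Low-passing a rectified signal can undershoot
  slightly below zero, so the envelope is clamped at 0.
* **Force**: negative insole readings are clamped to zero (pressure
  insoles cannot pull), then divided by body weight.
* **Common timebase**: channels arrive at 2000 Hz (EMG), 200 Hz (force)
  and 100 Hz (hip angle) and are linearly interpolated onto a uniform
  200 Hz timebase — the force rate, which preserves the lowest-rate
  dynamic content while keeping each ODE evaluation cheap.
* **Stride detection**: heel strike / toe off are upward / downward
  crossings of 0.05 body weights, with 50 ms debouncing and a 0.4 s
  minimum stride; strides without a swing interval are rejected.  All
  three values are standard force-plate contact heuristics and are
  configurable.

## Fitting

Both muscles are fitted simultaneously: the residual vector concatenates
`(y1 − SOL)` and `(y2 − TA)` over all samples from the second stride
onward, optionally weighted per muscle (default 1:1).  Optimization is
trust-region-reflective bounded least squares; the box bounds encode the
sign structure (`a_mut < 0`, `a_self ≥ 0`, `T, r > 0` with a 1e-3 floor,
`b ≥ 0`, input weights free in ±50).  Termination is a relative
SSE-change threshold of 0.001 between iterations ("relative deviation"
read as relative change in the scalar cost — scale-free and standard);
an iteration cap and seeded randomized restarts (default 5) guard against
bad starts, and the best restart by final SSE wins.  A diverged simulation
inside the optimizer returns finite large-penalty residuals instead of
raising, so the trust region can retreat.

Fit quality is the Pearson correlation `R` per muscle between model output
and EMG envelope over the concatenated samples from stride 2 onward, plus
their arithmetic mean `R_ave`.  A degenerate fit whose output channel is
flat has no defined correlation; `fit_trial` reports `R = 0` for it rather
than failing the trial (the strict `correlation` function still raises).

## Gait components and statistics

Per stride: stance % (contact duration over stride period; swing % is its
complement by definition), hip ROM (max − min hip angle), maximum
normalized force, and IEMG (trapezoidal integral of each envelope over the
stride, exact for piecewise-linear envelopes).  IEMG units are arbitrary
(envelope·s); across conditions each muscle's condition means are divided
by their maximum so the largest mean is 1.00 exactly and the rest are
expressed relative to it.

Each gait component and fitted parameter is compared across conditions
with classical one-way ANOVA (between/within decomposition, F with
(k−1, N−k) df) followed by Tukey HSD on the studentized range, using the
Tukey–Kramer harmonic adjustment for unequal group sizes (trial counts
per condition are unbalanced after exclusions).  α defaults to 0.05.  No
multivariate omnibus test is run before the per-variable ANOVAs, and no
multiple-testing correction is applied across variables.

## Synthetic data

No recordings ship with the package; a seeded generator produces the study
conditions:

* five conditions (3.5, 4.0, 4.5 km/h, self-selected ~4.8 km/h, and
  exaggerated "silly" walking), six consecutive steady-state strides per
  trial, three trials per condition, native rates 2000/200/100 Hz,
  body weight 749.6 N;
* per-condition defaults follow the expected speed trends: stance fraction
  0.666 → 0.650 (silly 0.633), hip half-amplitude 0.335 → 0.385 rad
  (silly 0.420), force peak 1.11 → 1.26 BW, per-stride IEMG targets
  0.47 → 0.55 (SOL) and 0.42 → 0.53 (TA) with silly largest (0.69/0.65);
  stride durations 1.16 → 1.03 s (silly 1.25 s) are generator choices in
  the normal range for treadmill walking at those speeds;
* **force**: per stride, a double-peaked stance profile (two flat-topped
  raised-cosine bumps at 25%/75% of stance over a 0.15 plateau) and
  exactly zero force in swing.  Contact starts and ends discontinuously
  at the true stance boundaries so threshold-crossing detection lands
  within one sample of the truth, and the flat bump apex makes the sampled
  maximum equal the nominal peak exactly;
* **hip angle**: a sinusoid at stride frequency, range 2×half-amplitude,
  peak flexion 5% of a stride before heel strike, around a 0.10 rad
  offset;
* **EMG**, two modes.  `template` paints raised-cosine bursts (SOL
  spanning 20–60% of the stride, TA 55–105%) whose per-stride integrals
  match the IEMG targets exactly with jitter off.  `oscillator`
  forward-simulates `GROUND_TRUTH_PARAMS`, a fixed documented set found
  once by matching the model to template bursts and then frozen; it
  produces stable SOL-stance / TA-swing alternation under every default
  condition and gives recovery tests an exactly attainable truth.
  Optional Gaussian envelope noise (fraction of peak) is clamped at zero;
  the silly condition carries three-fold stride-to-stride amplitude
  jitter.
* raw-level trials synthesize surface EMG as the envelope modulating a
  zero-mean Gaussian carrier at 2000 Hz, so the conditioning chain is
  exercised realistically (the recovered envelope is the rectified mean,
  ≈0.80× the true one — an overall scale the fit absorbs).

What the generator does **not** emulate: electromechanical delay, ECG and
motion artifacts, electrode crosstalk, double support asymmetries,
stride-duration variability, or any musculoskeletal dynamics.  Passing
tests therefore show that the pipeline recovers what this generator
encodes — alternating bursts, speed-trending components, a recoverable
oscillator truth — not that the model explains real EMG.

## Problem sizes and determinism

Default analyses run 15 trials (5 conditions × 3), ~7.5 s each at 200 Hz;
a full pipeline run takes tens of seconds on one core, dominated by the
per-trial fits (each fit costs `(16+1) × iterations` simulations of
~1 ms).  Every random draw flows from a single seed through
`numpy.random.default_rng` / `SeedSequence`, so a rerun with the same
config reproduces `stats.json` byte for byte; per-trial fit seeds are
derived by offsetting the global seed with the trial index.

## Known limitations

* The oscillator parameters are not globally identifiable from two
  envelopes; different parameter vectors can produce near-identical
  outputs (recovery is asserted on output behaviour `R`, and the sign of
  `a_mut`, not on parameter equality).
* The trust-region fit is local; restarts mitigate but do not remove
  dependence on the initial guess.
* Stance and swing percentages always sum to 100 by construction here;
  analyses that measure them independently can report sums slightly off
  100, so comparisons with such tables should use the stance row.
* The statistics pool trials (and limbs) as independent observations;
  no random subject effect is modelled.
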