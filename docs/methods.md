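# Methods

## The neuron model

Cells are simulated as one or two isopotential compartments. The soma carries
a leak conductance and a hyperpolarisation-activated (HCN) conductance with
first-order gating

    dm/dt = (m∞(V) − m) / τ(V),     m∞(V) = 1 / (1 + exp((V − V½)/k)),

and current I_h = g_hcn·m·(V − E_h) with E_h = −30 mV. τ(V) is a logistic
interpolation between `hcn_tau_min` and `hcn_tau_max`; the defaults
(900–1100 ms, i.e. nearly voltage-flat around 1 s) are discussed below. The
optional lumped dendrite (capacitance `cm_dend`, leak `g_leak_dend`, coupling
`g_c`) hosts the synapses: bi-exponential AMPA and NMDA conductances, the
latter scaled by the magnesium block 1/(1 + [Mg]·(1/3.57)·exp(−0.062·V)) with
[Mg] = 1 mM. Action potentials are threshold events (−45 mV default) that
paste a stereotyped 1.35-ms waveform (upstroke ≈ 230 V/s, peak +35 mV) and
reset to −55 mV with a 2-ms refractory period — enough structure for the
dV/dt-based AP detector to be tested against the simulator's own spike
markers, with no pretence of Hodgkin–Huxley realism.

Integration is exponential Euler on the gating variable and forward Euler on
the voltages at dt = 0.025 ms, decimated to the 20 kHz recording rate. The
shortest membrane time constant in any preset (~1 ms on the dendrite) is 40×
the step, and the integrator aborts with a diagnostic if |V| exceeds 200 mV.
Voltage clamp is modelled through a series resistance (default 2 MΩ,
representing residual access after compensation), which produces a physical
capacitive transient and defines the recorded pipette current. Recording
noise is additive Gaussian on the recorded channel (defaults 0.2 mV / 2 pA),
applied after integration; trial-to-trial biological variability in the
train protocol comes from per-trial stimulus efficacy jitter and Poisson
background synaptic bombardment instead.

## Why τ(V) is flat and the activation fit is conductance-based

The I_h protocol measures each step's amplitude as steady-state minus
"instantaneous" current, the latter a 10–60 ms post-step window mean. Any
relaxation already completed inside that window is lost; with a
voltage-dependent τ the lost fraction would vary across steps and shift the
fitted midpoint. With τ ≈ 1 s the loss is a few percent and essentially
uniform, so it rescales the fitted plateau without moving V½ — and 5-s steps
still settle to within 1 %. The cost is that sag develops only partially
within a 500-ms current step; the preset HCN conductance is calibrated for
the sag this protocol actually measures.

Fitting the raw current amplitudes with I_max/(1+exp((V−V½)/k)) cannot
recover the gating midpoint: the driving force (V − E_h) keeps growing after
the conductance saturates, and numerically this biases the midpoint by
5–11 mV hyperpolarised over the −50…−120 mV range. `fit_activation`
therefore divides the amplitudes by |V − E_h| (the conductance activation
curve) before fitting; with this convention the full simulate → extract → fit
round trip recovers midpoints across −80…−100 mV to ≤ 0.7 mV noiselessly.
The raw-current fit remains available (`driving_force_correction=False`) and
is used in tests whose expected values are exact Boltzmann samples.

## Impedance estimation

|Z(f)| is estimated as the magnitude of the Gaussian-smoothed (σ = 0.05
decade in log-frequency) cross-spectrum ⟨V·I*⟩ divided by the smoothed
stimulus power ⟨|I|²⟩, with 4× zero-padding, restricted to the chirp band.
The naive |FFT(V)|/|FFT(I)| ratio carries ripple from the chirp onset
transient that displaces the argmax of these intentionally shallow resonance
curves by ~0.3 Hz; the cross-spectral estimator reduces the error to
≤ 0.04 Hz on the reference membranes. A spectral-occupancy check rejects
sweeps whose stimulus is not actually a chirp. Q is defined as
|Z(f_res)|/|Z(f_min)| — the protocol gives no other normalisation point —
and equals 1 exactly for a low-pass (passive) membrane.

The reference resonant membrane used for validation is the small-signal
equivalent of a slow restorative conductance: R‖C in parallel with an R_L–L
branch. `design_resonant_membrane` fixes R = 250 MΩ, C = 400 pF, R_L = R and
solves for L by bracketed root-finding so the closed-form |Z| peaks at a
requested frequency (Q ≈ 1.3–1.6 at 0.8–1.1 Hz); C here is a tuning choice
that sharpens the peak enough for reliable argmax recovery, not a claim
about L4 SC capacitance.

## Measurement windows and conventions

* Step steady state: mean of the final 100 ms of a 500-ms step; sag peak
  search: first 200 ms. These windows are not dictated by the protocol and
  are config knobs; sag is floored at 0 (passive charging can leave the
  200-ms peak marginally above the later steady level) and is invariant to
  baseline shifts by construction.
* AP onset: first sample with dV/dt > 20 V/s followed by a 0 mV crossing
  within 3 ms; refractory 2 ms.
* AMPA uEPSC: 0.5-ms mean at the within-10 ms extremum, minus the 5-ms
  pre-event baseline; NMDA: 20–50 ms post-event mean at +40 mV. Repetitions
  (≥3 in the protocol) are averaged sample-wise before measurement, so the
  effective noise floor for silent-spine classification is 3·SD/√n_rep.
* Silent spine: AMPA below and NMDA above the noise floor; both below is
  "unresponsive" and excluded from ratio statistics. Genuinely weak spines
  near the floor inflate the silent fraction slightly above the generative
  probability (visible in the wild-type preset, ~0.10 called vs 0.064 true);
  this is a property of any floor-based call, not a bug, and the acceptance
  check budgets for it.
* Ensemble summation: peak over 20 ms from the first photolysis marker;
  counts whose sweeps fire an AP are excluded from slope fits (the spike
  truncates the subthreshold peak) but kept for the spines-to-AP statistic,
  which is right-censored at the largest tested count when nothing fires.
* mEPSC detection: criterion threshold 3 (the sliding-fit scale over
  residual SD), amplitude floor 3× the 5-ms baseline SD, refractory
  7.5 ms (−70 mV) / 25 ms (+40 mV) keeping the higher-criterion event.
  Performance on the synthetic recordings: 100 % recall at 5× noise SD with
  sub-millisecond timing, < 0.1 Hz false positives on pure noise.

## Statistics

`hierarchical_compare` fits statsmodels MixedLM with genotype (optionally
drug and interaction) as fixed effects and random intercepts for litter,
animal and slice (litter as the top grouping, animal and slice as variance
components); levels with < 2 groups are dropped, and singular fits trigger
simplification in the order slice → litter, never animal. Significance is a
likelihood-ratio test (ML fits) against the model without genotype. The
log-normal and gamma families are handled as LMMs on log-values — statsmodels
has no nested-random-effects GLMM — and the transformation is recorded in the
result metadata. Null calibration at the reference design (10 animals × 5
cells per genotype, animal-level ICC 0.2): rejection rate 0.05 at α = 0.05
over 200 simulations. Family selection compares maximised log-likelihoods of
normal, log-normal and gamma fits (two free parameters each, so ML ordering
equals AIC ordering). Fisher's exact test is two-sided by the
point-probability rule; the test suite verifies exact agreement with an
independent combinatorial enumeration on 2×2 tables up to n = 200.

## What the generator emulates — and what it does not

Preset anchors (uEPSC means 6.9/9.8 pA, silent fractions 6.4/17.6 %,
activation midpoints −86/−92 mV, MIS incidence 7.2/20.5 %, mEPSC rates and
amplitudes, morphology means, spines-to-AP 8.8/6.6, 10-Hz train spike
probability 0/0.55) are the two genotypes' group values; the remaining biophysics
(g_leak 3 nS, g_hcn 1.9 nS, k = 10 mV, dendritic coupling 2.5 nS, per-spine
conductance scales, the per-pA-per-nS calibration constant 24.5) were fixed
once so the simulated protocols land near those anchors, and are not tuned
thereafter. Multi-innervated spines are modelled as a doubled per-contact
conductance with preset incidence; knockout NMDA enrichment as a 1.3×
conductance ratio. Litter/animal-level log-normal factors induce the
intra-class correlation the mixed models rely on.

Known departures from the real system:

* The sag reduction produced by shifting V½ alone (11.5 % → 10.3 % at
  −125 pA) is milder than the measured genotype contrast (10.9 % → 7.6 %);
  with the channel complement held fixed, a −6 mV gating shift in a point
  conductance cannot remove a third of the sag. The direction is preserved
  and is what the cohort-fidelity check asserts.
* Summation-dependent EPSP decay sharpening does not emerge: in a lumped
  model, larger ensembles deactivate HCN slightly (lengthening decay) and
  the NMDA tail dominates, so the decay-vs-summation trend is positive
  regardless of HCN. Reproducing the sharpening likely requires spatially
  distributed I_h along a cable. The decay machinery is validated on its
  oracles (passive τ equality, exponential fit vs log-linear tail
  regression), and the model does reproduce the ZD direction measured on
  first EPSPs: blocking HCN prolongs decay at every ensemble size.
* The knockout's *higher* resonant frequency is not reproduced by the
  conductance presets (less resting I_h lowers f_res in this model); the
  resonance-recovery checks therefore run on the linearised membrane with
  analytically placed peaks, where ground truth is exact.
* Passing tests show the measurement code is correct on data whose
  generating process is known; they do not validate the biological model
  against real recordings, for which no public dataset exists.

## Problem sizes

Default cohorts are 3 animals × 2 cells per genotype with 8 sequential and
10 multi-protocol spines per cell, 60-s mEPSC records, and 10 train trials
per frequency — deliberately smaller than a real experiment's cell counts but large
enough that every genotype contrast is resolved and the nested models are
estimable. The statistical calibration harness uses 10 animals × 5 cells.
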