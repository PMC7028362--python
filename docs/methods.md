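# Methods

`locustolf` simulates the chain of odor processing in the locust olfactory
system — antennal lobe (AL), mushroom-body Kenyon cells (KCs) and
mushroom-body output neurons (MBONs) — and the analysis of how separable
two odors are from the MBONs' point of view.  This note records the model
equations as implemented, the free parameters and how their defaults were
chosen, the numerics, and what the package's synthetic inputs do and do
not emulate.

## Odor input (`stimulus`)

An odor is a Gaussian profile of DC input amplitudes over the PN (and LN)
index: the peak position is the odor's identity, the width sigma (a
fraction of the index range; 0.2 / 0.25 / 0.35 in the standard
experiments) is its concentration — a wider profile recruits more
neurons, as higher concentrations do.  The profile is thresholded to
exactly zero below 5% of the peak, and lives on a circular index space so
that a peak shift (5 index units for a "similar" odor, 20 for a
"distinct" one) changes nothing but the identity.  The temporal envelope
is a half-cosine rise over 60 ms, a 1000 ms plateau, and an exponential
decay with a 200 ms time constant; during the stimulus the per-neuron
input is multiplied by `1 + 0.075 * N(0,1)` independently per integration
step (the middle of the 5-10% noise band).  The peak input amplitude is
not a measured quantity; the default (7 nA at the profile peak, with LNs
receiving 0.6 of the PN profile) was calibrated once so that strongly
driven PNs fire 3-5 spikes per oscillation cycle and the network
oscillates near 20 Hz, and was not revisited afterwards.

Neuron indices are a labelling device: adjacency is random, so index
proximity implies input-profile similarity only, not connectivity.

## Antennal lobe (`al_network`)

Single-compartment Hodgkin-Huxley-style neurons.  PNs carry transient
sodium (m^3 h), delayed-rectifier potassium (n^4), transient A-type
potassium (m^4 h) and two leaks (gL = 0.15 uS to -55 mV, gKL = 0.05 uS to
-95 mV); gNa = 50, gK = 10, gA = 10 uS with ENa = +50, EK = EA = -95 mV.
LNs replace Na/A by a transient calcium current (m^2 h, gCa = 2 uS,
ECa = +140 mV) and a calcium-dependent potassium current
(m = [Ca]/([Ca]+2), tau = 100/([Ca]+2) ms, EKCa = -90 mV) whose build-up
produces spike-frequency adaptation; LNs fire Ca spikelets rather than Na
spikes.  Calcium follows d[Ca]/dt = -A j_Ca - ([Ca] - 2.4e-4)/5 ms with
A = 5.2e-4 mM cm^2/(uA ms) acting on the Ca current *density*
(cell area 1.43e-4 cm^2, the area implied by Cm = 1.43e-4 uF at
1 uF/cm^2).  Na/K rate functions are Traub-style; the activation and
inactivation pairs are internally consistent only on the shifted voltage
V2 = V + 55, so the Na activation rate is
alpha_m = 0.32 (-(V+42)) / (exp(-(V+42)/4) - 1) (half-activation near
-30 mV), with beta_m = 0.28 (V+15)/(exp((V+15)/5) - 1), and the K-current
rates alpha_n = 0.02 (-(30+V))/(exp(-(30+V)/5) - 1),
beta_n = 0.5 exp(-(35+V)/40).  Removable singularities of these
expressions are evaluated by their analytic limits.

One deliberate departure from the printed LN parameter set: gKCa
defaults to 1.2 uS rather than 0.3 uS.  At 0.3 uS the LN possesses a
stable depolarized equilibrium near -18 mV (the Ca window current exceeds
the maximal KCa current there) and latches after its first spikelet;
1.2 uS is the smallest value restoring the relaxation-oscillation
spikelets with adaptation that the circuit requires.

Synapses are first-order kinetic schemes, d[O]/dt = alpha(1-[O])[T] -
beta[O], with I = g [O] (V - E).  Nicotinic synapses (PN->LN and a
50-of-350 excitatory PN subset -> PN; E = 0 mV, alpha = 10, beta =
0.2 ms^-1) see a square transmitter pulse [T] = 0.5 for 0.3 ms after each
presynaptic spike.  Fast GABA_A synapses (LN->PN, LN->LN; E = -70 mV,
alpha = 10, beta = 0.16 ms^-1) see graded release, a sigmoid of the
presynaptic voltage centred at -20 mV with 1.5 mV slope.  Connectivity is
Bernoulli with p = 0.5 per projection type, sampled from a seed.
Per-type conductances are *totals* per postsynaptic cell, divided by the
expected fan-in, so behaviour is comparable across network sizes; the
defaults (nACh PN->LN 0.15, PN->PN 0.1, GABA LN->PN 1.5, LN->LN 0.3 uS)
were calibrated once against three qualitative constraints — a
reciprocally coupled PN-LN pair oscillates near 20 Hz under DC, the full
network's odor-evoked LFP peaks near 20 Hz at all three sigmas, and
zeroing the GABA conductances abolishes that peak.  The oscillation
emerges from PN->LN excitation, fast feedback inhibition and KCa-paced LN
recovery; the two-cell demonstration uses per-connection conductances
g_GABA = 1.0 and g_nACh = 0.3 uS with DC (9, 6) nA, giving a 49.5 ms
period.

### Numerics

Exponential-Euler updates at dt = 0.02 ms for every state variable:
V, each gate, [Ca] and each open fraction obey equations that are linear
in their own state over a step, so each is advanced by its exact
exponential relaxation toward the instantaneous target.  This is
unconditionally stable despite the stiff sodium conductance
(gNa/Cm ~ 350 ms^-1), where an explicit Runge-Kutta step at the same dt
would sit at the edge of its stability region.  The scheme is first
order: halving dt changes spike times by < 0.5 ms over the first 250 ms
of a two-cell trial (tested), with slow spike-phase drift (~0.3% per
firing cycle) accumulating beyond that horizon.  Spikes are
upward threshold crossings (-20 mV for PN Na spikes with a 2 ms
refractory; -40 mV for LN spikelets with 5 ms), which separates the two
spike types without a height criterion.  A compiled (numba) kernel and a
pure-numpy loop implement the identical scheme; they agree to float
precision over short horizons (tested) and differ beyond only through
chaotic amplification of rounding, so any single backend is bit-exactly
reproducible from its seeds.  Integration aborts with a diagnostic if
|V| exceeds 200 mV.

## LFP, phase, and the integration window (`lfp_gating`)

The LFP is the mean PN membrane potential.  It is low-pass filtered at
40 Hz (4th-order Butterworth, forward-backward so zero-phase), the slow
stimulus-locked baseline (5 Hz low-pass) is subtracted, and the Hilbert
transform of the residual gives the instantaneous phase.  Cycle
boundaries are the phase-wrap points (troughs), detected only inside the
analysis window — from 200 ms after stimulus onset (skipping the onset
transient) to the end of the plateau.  A spike's within-cycle phase is
the analytic-signal angle measured from the preceding trough, in
[0, 2 pi).

Gating emulates the cyclic feedback inhibition KCs receive from the giant
GABAergic neuron without modelling that neuron: all PN spikes whose
within-cycle phase exceeds a threshold phi are deleted, so phi *is* the
window of integration and directly controls downstream sparseness.
Spikes outside the detected oscillatory epoch (before the first or after
the last trough) are retained ungated; this touches only stimulus onset
and offset.  Retained sets are nested in phi by construction (tested as
exact set inclusion).

## Mushroom body (`mb_network`)

KCs and MBONs are two-variable map neurons in the regular-spiking
regime: a fast variable x iterated through the piecewise map
(alpha/(1-x) + u while x <= 0; plateau alpha + u on the upstroke; reset
to -1 after the peak) with alpha = 3.65, and a slow variable
y_{n+1} = y_n - mu (x_n + 1) + mu (sigma_dc + sigma_e I_n), mu = 0.0005.
One iteration is 0.5 ms, so a 50 ms LFP cycle spans 100 iterations.  The
bias sigma_dc = -2.0 keeps cells silent at rest with a robust margin;
synaptic input I enters the fast equation (u = y + I) *and*, scaled by
sigma_e = 1, the slow one.  The slow-equation term matters: with
fast-only input the slow variable cancels any sustained drive on a
~1 s timescale, and KC spike counts then *fall* as the integration
window widens — the opposite of the gating logic.  With the input in
both equations sustained drive produces sustained spiking, and KC counts
grow with phi (small residual adaptation can produce reversals of a few
percent between adjacent phi values, which the tests tolerate).

Synaptic currents decay geometrically (factor gamma = 0.9 per iteration,
~5 ms) and each presynaptic spike adds g (x_rp - x_post) w; with
x_rp = 2.0, above the spike peak, the increment is depolarizing over the
whole subthreshold range.  (x_rp at the spike threshold itself would
shunt input to zero exactly when the cell is about to fire, which again
inverts the phi trend.)  The driving force is saturated to [0, 6]: it is
zero during the one-iteration spike plateau and bounded after deep
hyperpolarizing swings, removing a positive feedback loop between the
orbit and the current that can otherwise diverge under dense input
volleys; inside the normal operating range the saturation is inactive.

Each KC samples each PN with p = 0.1; PN->KC weights are 1/fan-in, so a
KC's drive is the spiking fraction of its sampled PNs and the one gain
g_KC = 0.3 applies at every scale.  Sparse sampling is what gives
individual KCs odor selectivity here: at the package's network sizes,
50% sampling makes every KC's input statistically identical and the
population responds all-or-none, carrying no identity information.  Each
MBON reads a random 60% of the KCs through plastic weights w in [0, 2]
(initial value 1.0 unless stated); MBON drive is normalised by the
connected-KC count with gain g_MBON = 12.  Both gains were calibrated
once to the qualitative targets — sparse KC responses graded in phi and
sigma, and MBON binary patterns that saturate at high concentration and
wide windows — and then frozen.

## STDP (`plasticity`)

Trace-based pair STDP with weight-dependent (soft-bound) amplitudes at
the KC->MBON synapse.  Each KC spike increments its presynaptic trace x
by a+ = 1 (decay tau+ = 20 ms) and depresses its synapses by
w eta- y_post; each MBON spike increments its trace y by a- = 1 (tau- =
20 ms) and potentiates its synapses by (W_max - w) eta+ x_pre; eta+ =
eta- = 0.01, W_max = 2, w_min = 0.  Depression therefore dominates near
W_max and potentiation near zero, and symmetric pre/post pairing has a
unique stable fixed point at W_max eta+ a+ / (eta+ a+ + eta- a-) = 1,
which is why median weights from high (1.4) and low (0.6)
initialisations converge toward each other (the convergence, not the
exact asymptote, is the tested property).  Traces decay once per map
iteration (0.5 ms, exact exponential); within an iteration presynaptic
updates are applied before postsynaptic ones, so coincident pairs count
as pre-before-post.  All-to-all spike interaction via accumulating
traces; only synapses on each MBON's 60% mask exist.  Traces reset
between presentations (inter-trial intervals are long against 20 ms).
Snapshots of the weight matrix are taken every few presentations; the
median trajectory is computed over the synapses that changed at all,
since sparse KC activity leaves most weights untouched.

## Odor-separation analysis (`coding_analysis`)

MBON spike trains are binarised per LFP cycle (1 if the cell spiked in
the cycle), giving an MBON x cycle 0/1 matrix per trial.  The distance
between two trials is the Hamming distance between these matrices —
identical to the squared Euclidean distance on 0/1 entries (both
computed and asserted equal) — after truncating to the shared cycle
count (noise moves trough positions by a cycle).  The distance-vs-phi
curve runs the full downstream pipeline per phi and averages over all
cross-odor trial pairs; its argmax phi* is the optimal integration
window.  Ties in the argmax resolve to the lowest phi.  For the
classification read-out, pairwise trial distances are embedded in 2-D by
metric MDS (seeded) and a linear discriminant is fit on the plane; the
reported number is the raw misclassified-trial count.  The pre/post
learning comparison collects per-trial-pair distances at the
pre-training phi* for three odor pairs at each concentration and applies
a two-sided paired t-test.

## Experiments, scales and problem sizes

`experiments` wires these stages into three seeded runs (CLI:
`locustolf al-demo | phi-sweep | stdp-run`): the AL demonstration with
LFP spectrum, the phi x sigma sweep with the uniform-weight variant
(weights 0.1-0.9), and the STDP run (two weight initialisations, 60
shuffled presentations of two similar odors and one distinct odor,
pre/post distance curves, paired test, MDS + discriminant).  A master
seed spawns every child seed, and identical configs regenerate
byte-identical artifacts (tested).

Two presets: `reference` (350 PN / 100 LN / 15,000 KC / 100 MBON,
1000 ms plateau) and `ci` (100 PN / 30 LN / 1,500 KC / 20 MBON, 600 ms
plateau), the package's desk-scale working point.  The test suite runs
everything except the LFP-frequency check at the `ci` preset with two
trials per odor and a 40-presentation training schedule; the
LFP-frequency check and the acceptance script's t1 use the full
`reference` antennal lobe.  Training during the STDP experiment gates PN
spikes at phi = pi (a mid-range window at which the high-concentration
odors drive both KCs and MBONs), and the same antennal-lobe trials are
reused across presentations with shuffled order — the variability across
presentations comes from the per-trial input noise realisations.

## What the synthetic inputs do and do not emulate

The Gaussian-profile DC input stands in for olfactory receptor input: it
captures identity as *which* neurons are driven and concentration as
*how many*, plus amplitude noise.  It does not model receptor-neuron
transduction or adaptation, plume dynamics or temporal odor structure,
and the circular index space is a statistical convenience with no
anatomical meaning.  Consequently, passing tests show that the model
circuitry transforms, sparsens and separates representations as
described — not that any real odor pair would yield these distances.
Absolute spike counts and distances at the `ci` scale are not
comparable to the full-size system; only orderings and trends are, which
is what the tests assert.

## Known limitations

- No explicit GGN/feedback-inhibition dynamics: phi is an external sweep
  parameter, never an emergent quantity.
- No lateral-horn pathway, no GABA_B, no lateral inhibition between
  MBONs, no reward/neuromodulator signals.
- The printed parameter set required three restorations (Na activation
  shift, Ca-influx units, gKCa scale) to produce the described
  behaviours; all three are documented above and remain configurable.
- Map-neuron adaptation leaves percent-level non-monotonicities in KC
  counts versus phi; trend assertions carry matching tolerances.
- The MDS embedding is a stress minimiser with a seeded random start;
  misclassification counts can shift by a trial for unlucky seeds.
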