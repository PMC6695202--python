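# Methods

`stellate` asks a single quantitative question: at a weak thalamocortical
synapse, does the physiological postsynaptic conductance maximise the
information transmitted per ATP spent on postsynaptic ion pumping?  The
package answers it in silico with four interlocking pieces: a compartmental
Hodgkin-Huxley model of a layer-4 spiny stellate (L4SS) cell, stochastic
synaptic bombardment, a shuffle-corrected transfer-entropy estimator, and an
ATP budget for the resulting ion fluxes.

## The cell model

**Geometry.** No reconstruction is shipped; `morphology.generate_morphology`
builds a stylised stellate tree that reproduces the target summary
statistics: soma area 757 um^2 (one isopotential sphere-equivalent
compartment), total dendritic area 11,885 um^2 (matched exactly by a global
diameter rescaling), ~360 compartments with a maximum length of 21 um and a
mean near 14.6 um.  Six primary dendrites branch dichotomously over four
branch orders (default lengths 33/47/58/66 um per order with a seeded
lognormal jitter, diameter taper 0.7), giving path distances out to ~200 um.
Path distance uses the midpoint convention — soma centre to compartment
midpoint along the tree, the soma contributing no length — which is the
symmetric choice for compartmental models.  Morphologies serialise to SWC
with synthetic coordinates so a real reconstruction can be substituted.

**Membrane.** Passive parameters: Cm 1.5 uF/cm^2, Rm 16,000 Ohm cm^2, Ra
100 Ohm cm, rest -70 mV.  The capacitance is the standard 1 uF/cm^2 raised
50% to absorb spine membrane; the source value is printed in per-um^2 units
that are dimensionally implausible, and this reading is the recorded
interpretation (overridable in `MembraneParams`).  Active conductances: fast
Na (E=+70), delayed-rectifier K and slow non-inactivating K (E=-77), at
300/30/100 mS/cm^2 on the soma and 3/1/1 mS/cm^2 on dendrites, plus a
uniform L-type Ca conductance of 0.03 pS/um^2 with a fixed reversal of
+120 mV (a GHK flux equation is deliberately not used; the current is
negligible for voltage dynamics).

**Gating kinetics** are not dictated by the published parameter set, so they
are this package's own frozen choice (`channels.py`): Traub-type Na and Kdr
rate functions with a threshold shift v_T = -55 mV, and a slow K gate with
sigmoid steady state (midpoint -25 mV, slope 5 mV) and a voltage-independent
600 ms time constant.  The slow K parameterisation matters: at 100 mS/cm^2
somatic density it must stay nearly silent below threshold (so the cell's
input resistance and EPSP sizes are set by the leak) while integrating
depolarisation slowly enough to act as spike-frequency adaptation rather
than a sub-threshold brake.  A conventional muscarinic-type parameterisation
(lower midpoint, fast tau at depolarised voltages) makes the cell fire at
most ~0.5 Hz regardless of drive; the frozen choice yields sustained regular
spiking under current steps and ~4 Hz under nominal bombardment, which is
the operating regime the analysis requires.

**Calcium** is bookkeeping faithful to the stated parameters: a 0.1 um
submembrane pool per compartment fed by the L-type current, a 3 uM buffer
(Kd 1 uM), a two-step membrane pump (10^-13 mol/cm^2, k1..k4 as configured)
and longitudinal diffusion at 0.6 um^2/ms between neighbouring compartments.
It has no feedback on the voltage beyond the (tiny) Ca current itself;
removing it changes sub-threshold EPSPs by well under 5%.

**Numerics.** One numba kernel advances everything.  The cable equation is
solved implicitly on the tree in Hines order (parents precede children; one
elimination sweep and one back-substitution per step).  Time stepping is
Crank-Nicolson implemented as a backward-Euler half step at dt/2 followed by
linear extrapolation, with Rush-Larsen exponential gating updates staggered
at the step boundaries; rate functions are pre-tabulated on a 0.05 mV grid
and linearly interpolated.  dt defaults to 0.025 ms for single-event
measurements and 0.05 ms for long bombardment runs (halving dt moves a
somatic EPSP peak by <1%).  The resting state is made an exact equilibrium
by solving the per-compartment leak reversal against the standing active
currents at -70 mV.  Spikes are detected online at a 0 mV upward crossing
with a 3 ms lockout (models overshoot reliably; the lockout matches the
analysis bin).  Divergence (|Vm| > 200 mV) raises an error naming the
failure time.

## Synaptic input

Double-exponential conductance kernels, peak-normalised so the configured
value is the peak conductance of one event: tc/cc tau 0.3/1.7 ms at E=0 mV
(g_tc = g_syn = 1 nS, g_cc = 0.8 nS), inhibition tau 1/10 ms at E=-75 mV
(g_inh = 0.5 nS).  One lumped synapse of each class sits on every dendritic
compartment; event rates are set by spine counts times per-spine rates
(1870 x 0.45 Hz cc, 460 x 0.09 Hz inh, 470 x 4 Hz tc), apportioned by
compartment area — for tc additionally weighted by a Gaussian in path
distance (mean 83.6 um, s.d. 28.3 um, truncated at zero).  Surface densities
quoted alongside the counts are treated as descriptive.  Backgrounds are
independent homogeneous Poisson processes (no correlation structure, no
plasticity, depression or failures).

The **axon of interest** makes three synchronous contacts on one dendritic
lineage as close as achievable to 60/78/96 um, using tc parameters.  Its
spike train is a 25 s renewal process (3 ms dead time + exponential,
mean 4.3 Hz) repeated five times — 125 s standing in for a recorded relay
cell response.  A user-supplied spike file (one time per line, seconds)
replaces the synthetic block.  The dimensionless **gain** multiplies the
peak conductances of the tc class and the axon of interest together, leaving
cc/inh and all event times untouched, so scale-then-sample and
sample-then-scale commute by construction.

**Calibration.** With nominal rates the model fires slightly below 4 Hz, so
(as in the original protocol) the corticocortical rates — cc and inh
together, never tc — carry a single multiplicative scale found by bisection
until a 20 s calibration run fires at 4 +- 0.3 Hz.  At the defaults the
scale lands near 1.2, i.e. a slight adjustment.

## Information

Both trains are binarised in 3 ms bins (1 = at least one spike).  Transfer
entropy from input to output is the plug-in estimate over words of k = l =
10 contiguous bins with a frame shift u scanned over 0..10 bins (ties
towards smaller u); u lags the source word relative to the predicted output
bin.  Counting is exact: joint words are integer-encoded and tallied, so the
estimator is vectorised yet agrees with brute-force enumeration to 1e-12 on
small inputs.  The word-length bias of the raw estimate is removed by
subtracting a noise floor: the same statistic with the input sequence
permuted (30 permutations, bin-wise by default; non-overlapping k-bin block
permutation as the alternative, remainder left in place), which preserves
spike counts exactly.  Corrected TE may be negative on noise-dominated data
and is reported unclipped, because clipping biases averages across seeds.
Entropy rates use the conditional block entropy H(n) - H(n-1) with a length
guard against plug-in collapse.  Rates are per bin divided by 3 ms.

## Energy

Every inward charge at excitatory synapses and through Na channels is
treated as Na+ to be extruded at 3 Na+ per ATP: ATP = Q / 3e.  Charges are
accumulated at full time resolution during the run (the recorded traces are
subsampled); the public `charge_to_atp` integrates the inward part of a
current trace with the trapezoidal rule.  Inhibitory Cl- flux and the
calcium pump are excluded from the signalling budget by design (the budget
names excitatory synaptic currents and action potentials); the
action-potential cost integrates the Na-channel current over the whole
trace, which is parameter-free and correct to within the negligible resting
window current.  Efficiency is bits/s divided by ATP/s.  Two denominators
are reported: the axon of interest alone (`eff_syn`) and the total
signalling budget (`eff_total` <= `eff_syn` always).

## The gain scan

For each seed, one background realisation is drawn and reused across all
gains (common random numbers), so gain contrasts are paired.  Each (gain,
seed) cell runs the full model, estimates TE and tabulates the energy
budget; rows persist to CSV as they finish so interrupted scans resume.
Peak finding takes the argmax of the mean efficiency over the gain grid with
ties broken toward the lower gain (conservative for the efficiency claim),
and reports the s.e.m. at and beside the peak so flat maxima are visible.

## Dynamic-clamp emulation

The experimental arm is emulated in software: a recorded EPSC trace converts
to conductance via g = I/(Vm - Vrev) after stimulus artefacts are blanked by
holding the last pre-artefact sample; background noise conductances come
from `lump_to_soma`, which relocates all excitatory synapses to the soma and
superposes their kernels (inhibition deliberately omitted).  The composite
gain*(g_syn + g_tc) + g_cc is injected at the soma with the
instantaneous-voltage current law I(t) = g(t)(Vm(t) - Vrev), per-channel
charges are accounted separately, and sustained depolarisation above -30 mV
without spikes is flagged as depolarising block (the regime that capped
experimental gains at 3).

## Study sizes and what the desk-scale checks show

Default verification sizes, chosen to keep a complete run on a laptop CPU:
single-event sweeps over all ~359 dendritic placements at dt 0.025 ms;
calibration and bombardment at dt 0.05 ms; the with-inhibition efficiency
peak on the reduced grid {0.6, 0.8, 1, 1.2, 1.6} with 3 seeds and 60 s
trains; the no-inhibition scan on the full 12-point grid [0 ... 9.6] with
3 seeds and 60 s trains.  With 60 s trains and 3 seeds the TE standard error
at gain 1 is roughly 0.1 bits/s, so peak locations are resolved only up to
one grid step; the 125 s / ~6-seed configuration sharpens them.

The synthetic data emulate Poisson background and a refractory renewal input
train; they do not emulate input correlations, oscillatory states,
short-term plasticity or a real reconstruction's electrotonic detail.
Passing tests therefore show that the method — model, estimator, budget,
scan — reproduces the published quantitative picture under its stated
assumptions, not that those assumptions hold in tissue.

## Position of the efficiency optimum in this configuration

With the synthetic substrate the reproduction is quantitative but not exact:
at the calibrated operating point the model measures ~3.7 Hz output,
TE_raw ~0.9-1.3 bits/s and corrected TE ~0.4-0.7 bits/s at gain 1, with
run-to-run spread ~0.2 bits/s at 125 s — all consistent with the published
simulation values.  The information-versus-gain sigmoid, however, sits
slightly to the right of the published one: the axon of interest couples a
little more weakly here (0.72 mV mean somatic EPSP per contact instead of
~0.8, surrogate gating kinetics, and a renewal input train without the
burst structure of a recorded relay-cell response), so the measured
bits-per-ATP optimum lands one to two grid steps above the physiological
gain (argmax 1.2-1.6 with inhibition, ~1.2 without) rather than exactly at
1 and 0.8.  The qualitative structure — efficiency rises to a maximum near
the physiological conductance and falls on both sides, and removing
inhibition shifts the optimum to lower gains relative to the
with-inhibition curve's plateau — is reproduced.  Likewise the paired
TE increase from gain 1 to 1.2 is positive as published, but its
run-to-run spread at desk scale (tens of percentage points even with
common random numbers) is far wider than the published point estimates
of ~16%/~8%.

## Known limitations

* Gating kinetics are a surrogate for the original model's channels; absolute
  firing thresholds and AP costs inherit that choice, which is why the
  background calibration step exists.
* The stylised morphology is electrotonically more uniform than a real
  reconstruction: somatic EPSPs vary ~0.55-0.85 mV across tc placements
  rather than the broader experimental range, which tightens (not biases)
  placement-related spread.
* The plug-in TE estimator is biased upward at k = 10 on 125 s of data; all
  reported TE values rely on the scramble subtraction, and the residual
  bias of the difference is not separately corrected.
* Calcium dynamics use one submembrane shell and a non-volume-weighted
  longitudinal exchange; adequate for bookkeeping, not for Ca-dependent
  channels (none are modelled).
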