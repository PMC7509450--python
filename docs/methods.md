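# Model and methods

## Scope

`ca1ach` simulates the somatic response of a CA1 pyramidal neuron to
acetylcholine acting on M1 muscarinic receptors.  The cell is reduced to a
three-section cable — one somatic compartment (20 µm × 20 µm), the first
200 µm of the apical trunk (ten 20 µm cylinders, 2 µm diameter), and an
electrical-only axonal compartment for spike initiation — coupled to an
intracellular reaction network in the soma and trunk.  The network contains
the Gq cascade (receptor, G protein, PLC), PIP2 hydrolysis into IP3 and DAG,
IP3 turnover (IP 5-phosphatase and the calcium-gated IP3 3-kinase),
phosphoinositide resynthesis, ER calcium storage and release (SERCA, leak,
IP3 receptors, calreticulin), cytosolic buffering and extrusion (calbindin,
the OGB-1 indicator when enabled, PMCA), store-operated calcium entry, and
longitudinal diffusion of free calcium and IP3.  M4/presynaptic modulation,
spines, mitochondria and network interactions are out of scope.

## Units and state

Time ms, voltage mV, concentration mM, current pA, conductance nS (densities
mS/cm²), length µm.  The ER is a well-mixed 10 % sub-volume of each
chemistry compartment (cytosol 90 %); SERCA, leak and IP3R are direct
volume-to-volume fluxes with the 9:1 volume correction, and SOCE adds
calcium to the ER lumen only.  Membrane signalling species (receptor,
G protein, PLC, the lipids) are dimensionless surface densities normalised
to resting PIP2 = 1; hydrolysed PIP2 is converted to cytosolic IP3 with a
per-compartment scale proportional to the surface-to-volume ratio
(≈20 µM per PIP2 unit at the soma, ten-fold higher in the 2 µm trunk).
Two further geometric scalings are sublinear: the IP3R flux capacity grows
as (S/V)^0.4 (tubular ER packs more release membrane per volume in thin
processes) and the PMCA extrusion capacity as (S/V)^0.3 (thin dendrites
clear calcium faster than the soma, but not in full proportion to their
membrane area).  Together these make distal compartments reach higher IP3,
release earlier and peak higher, reproducing the trunk-to-soma calcium wave
from geometry alone, while dendritic AP transients still decay faster than
somatic ones.

The electrical and chemical equations form one stiff ODE system (≈530
states) integrated monolithically with BDF; no operator splitting.  The
Jacobian is evaluated by grouped finite differences on the known sparsity
pattern (21 structurally orthogonal column groups).  Default tolerances are
rtol 1e-4 with per-block absolute tolerances (1e-3 mV, 1e-6 for gates,
1e-9 mM); a dedicated test verifies that tightening them changes a
subthreshold response by well under 0.1 mV.  Stimulus edges split the
integration interval, and somatic spikes are located exactly by solver
events (0 mV upward crossings, 2 ms refractory).  Small tolerance-level
negative concentrations are tolerated; sustained negativity aborts the run.

The resting state is pinned exactly: the leak reversal absorbs the standing
channel currents at −65 mV, and a constant background calcium influx
balances resting PMCA extrusion net of resting VGCC influx.  The ER resting
balance is *not* pinned — it is owned by the stage-1 calibration, so the
SERCA/leak balance genuinely defines the 175 µM rest point.

## Channels

Transient Na (m³h), delayed-rectifier K, A-type K, Kv7 (M-current), SK,
a lumped high-voltage-activated Ca channel, a low-threshold Ca channel, HCN
and leak, with Boltzmann steady states and bell/sigmoid time constants.
Kinetics are smooth re-parameterisations rather than copies of any published
morphology files; densities are free parameters fixed by the excitability
calibration.  Three choices deserve comment:

* **A-type K with slow inactivation** (τ_b = 150 ms).  With a fast-
  inactivating A-current the reduced cable had a type-II f–I curve whose
  onset rate was ≈30 Hz, so no current could drive steady 10 Hz firing as
  the driven protocols require.  Slow inactivation (the classical
  low-frequency-firing mechanism) opens a continuous low-rate window;
  rheobase-level drives then produce ≈8–12 Hz.
* **HCN.**  The printed pair of cholinergic excitability effects — a ≈40 %
  rheobase drop and a ≈39 % input-resistance rise — could not be met with
  one Kv7 density alone: the M-current that is strong enough near threshold
  to control rheobase overshoots the subthreshold resistance change.  Ih
  contributes resting conductance that disappears on depolarisation and is
  absent near threshold, which decouples the two measures.  It is also a
  real and prominent CA1 conductance.
* **Kv7–PIP2 coupling** is an instantaneous Hill function of membrane PIP2
  relative to rest, deliberately steep and centred high (half-saturation
  0.64× rest, coefficient 5): ≈90 % available at rest, closed at full
  depletion, and — crucially — still mostly closed while PIP2 is only
  partially resynthesised.  The steepness is what lets the
  post-transient depolarization persist even though the lipid cycle itself
  is fast (see the calibration trade-off below).  SK is an instantaneous
  Hill function of cytosolic calcium (half 0.7 µM, coefficient 4.8),
  denser at the soma than in the trunk.

## Cascade kinetics

The receptor topology follows the published Gq scheme: ACh binding (the
association rate is derived from a configurable receptor EC50, default
0.65 µM), receptor–G-protein precoupling, nucleotide exchange on the
receptor-bound G protein, PLC binding of Gα-GTP, GTPase acceleration while
PLC-bound, and reassociation.  The three documented modifications are
explicit factors: PLC association and dissociation ×10 and the hydrolysis
rate constant r_PLC ×100, which move IP3 production from a ≈2 s peak (the
unmodified kinetics, reproducible by setting the factors to 1) to being
largely complete within 2 s of a 50 ms pulse.

Two inactivation rates were retuned relative to the source values.  With a
lone-Gα GTPase of ≈0.026 s⁻¹ the active G protein integrates for tens of
seconds and even 10 nM pulses eventually trigger full calcium release,
contradicting the observed dose thresholds (negligible release below
0.1 µM, hyperpolarization EC50 ≈0.5 µM).  The shipped model uses
k_hyd = 0.6 s⁻¹ for free Gα-GTP and k_gap = 4.5 s⁻¹ for the PLC-bound form,
which confines amplification to the window the dose–response data imply.

IP3 is degraded by an IP 5-phosphatase Michaelis path and by IP3 kinase
that must bind two calcium ions before accepting IP3; IP2 and IP4 are
terminal sinks.  DAG is produced but inert.  The lipid cycle
PI → PI4P → PIP2 (with the reverse phosphatase steps) is constrained so the
configured resting pools are an exact fixed point: k5P and k4K are derived
from (k5K, k4P) and the pool sizes.  The stage-4 calibration therefore
scales the four rates jointly, setting the resynthesis speed (and with it
the decay of spike acceleration) without moving the rest point.

## IP3 receptor

A sequential-binding scheme: R + IP3 ⇌ R·IP3; R·IP3 + Ca ⇌ open;
open + Ca ⇌ inactivated.  The steady-state open fraction is increasing in
IP3 and biphasic in calcium.  Gating does not consume measurable ligand.
Release flux is g_IP3R · open · [Ca]_ER, proportional to store content so
that release terminates as the store empties — the mechanism behind the
non-monotone inhibition duration: higher ACh produces more IP3, opens more
receptors and drains the store faster, so the calcium transient (and the
spike inhibition it causes) is *shorter* at high concentrations, with the
longest inhibition at an intermediate dose.

## Store-operated entry

dCa_ER/dt = g_SOCE · ln(1+e^(vm−v_init)) · e^(−(Ca_ER−Ca_d)·k_SOCE), with
Ca_d = half the resting ER concentration and k_SOCE multiplying inside the
exponent (the printed expression is ambiguous on this point; the multiplying
form is adopted and exposed in config).  The softplus reference v_init sits
5 mV above the resting potential (−60 mV): with the reference at rest, the
depletion gate dominates and a depleted store refills almost as fast in a
quiescent cell as in a spiking one, erasing the depolarisation requirement
the mechanism exists to express.  With the elevated reference the resting
flux is far below 1 % of the resting SERCA throughput and refilling
genuinely needs depolarisation.  The mechanism never touches cytosolic
calcium.  In the repeated-pulse experiment (two 100 µM pulses 15 s apart)
the second hyperpolarization recovers essentially nothing of the first at
rest, ≈60 % with interposed 10 Hz spiking, and nothing again when SOCE is
removed; the test thresholds (<25 %, ≥45 %, ablated < half of driven) are
the package's own.

## Staged calibration

`CholinergicCA1Model.fit()` runs four stages in a fixed order, each freezing
its result (later stages never touch earlier parameters):

1. **ER store** (g_SERCA, kf_leak): for each trial leak rate the SERCA flux
   is re-derived from the resting balance (including resting SOCE), making
   the 175 µM rest exact by construction; a deterministic log-space secant
   on the leak rate then meets the 59 s refill time constant.  The refill
   protocol resets free ER calcium to 20 % of rest with calreticulin
   re-equilibrated, holds the cell at rest and fits a + b·e^(−t/τ).
2. **AP transient** (VGCC soma/trunk, PMCA density): targets are indicator
   ΔF/F peak and decay after one evoked spike, with OGB-1 present and
   calbindin at 20 % of its regular concentration.  The study's targets are
   figure-based; the shipped numeric targets (soma ≈1.2 %, trunk ≈1.9 %,
   decay ≈0.5 s) are config entries reproducing the qualitative pattern
   (trunk larger than soma, sub-second-scale decay).  The absolute
   amplitudes are small because the VGCC densities are jointly constrained
   by the excitability calibration (per-spike calcium also paces the SK
   rhythm of the driven protocols).
3. **Release** (g_IP3R): constraints — cytosolic peak > 1 µM, transient
   resolving in 1–3 s, spike inhibition starting within 200 ms of a 100 µM
   pulse in the driven cell.  With the PLC factors reset to 1 the constraint
   set is infeasible (a long weak release instead of a short strong one),
   which is reported as such.
4. **Lipid cycle** (joint rate scale): the instantaneous firing rate must
   peak within 1–3 s of the pulse and return to within 10 % of baseline on
   a 10–25 s horizon.  The resynthesis rate is the one place where two
   constraints pull against each other: the tonic rheobase half-maximal
   concentration scales with the resynthesis rate (a slower cycle makes
   steady low-dose hydrolysis accumulate and shifts the tonic threshold to
   lower concentrations), while the firing-rate peak moves earlier as the
   cycle speeds up.  The shipped rates favour the tonic half-max (≈8 nM,
   the dose–response quantity), placing the firing-rate peak at ≈1.9 s —
   just under the 2–3 s a slower cycle would give — with the rate back at
   baseline by ≈15 s.

The hand-tuning of the original workflow is replaced by bounded
deterministic searches from fixed starting points, so the calibration is
bit-for-bit reproducible.  The shipped defaults are the output of this
workflow; re-running `fit()` verifies rather than changes them.

## Protocol definitions

Baselines for peak hyper/depolarization are the mean somatic potential over
the 500 ms before the stimulus.  Spike threshold is 0 mV with a 2 ms
refractory.  The 10 Hz drive current is found by bracketing plus secant on
the steady rate (0.2 Hz tolerance, rate measured after a 1 s transient).
Rheobase is a binary search on 200 ms pulses to 1 pA from the protocol's
steady state.  Input resistance is the regression slope of the steady
deflection at {−100, 0, +100} pA, measured in the 600–800 ms window of an
800 ms step (all slow conductances have settled; longer probes can trigger
late spikes under saturating ACh, which would invalidate the measurement).
Inhibition duration is the longest inter-spike interval ending after pulse
onset.  Dose grids are log-spaced at 4 points per decade over 1 nM–100 µM
(config-exposed); EC50s come from 4-parameter Hill fits in log-dose space.
Tonic excitability is measured from a 90 s adaptation under sustained ACh
with the bath still present during probes.

## Problem sizes

The shipped protocols use the durations above: 180 s for the ER refill fit,
10 s phasic windows, 90 s tonic adaptation, 8–25 s post-pulse windows for
the driven runs, and 6–8 concentrations per sweep.  These resolve every
fitted quantity (the refill fit R² exceeds 0.99; doubling sweep density
moves the EC50 estimates by far less than the fit tolerance).

## What the model does and does not show

All quantitative statements are about this calibrated reduced model, not
about new data: the virtual experiments regenerate the modelled cell's
behaviour deterministically.  The reduced cable has a smaller total membrane
area than a full reconstruction, so absolute input resistance and drive
currents are not directly comparable to in-vitro values even though the
*relative* cholinergic changes are calibrated; channel kinetics are
idealised re-parameterisations; the IP3 receptor scheme is a compact
stand-in for the (unavailable) original gating model, chosen for its
qualitative fingerprint (IP3-gated, calcium-biphasic, store-limited); and
bath ACh is a clamped concentration, not synaptic release.  Behaviour that
depends on dendritic branch geometry, spines or nicotinic receptors is
outside what passing tests can support.

## Known limitations

* The phosphoinositide pools are lumped per compartment with no lateral
  lipid diffusion and no PIP2 oscillations.
* ER lumenal calcium does not diffuse between compartments.
* The axon is a single compartment tuned only for reliable spike initiation.
* Hill fits assume a single sigmoid; strongly threshold-like dose–response
  curves make the fitted EC50 sensitive to grid placement near the
  transition (the shipped grids place two points per factor ~1.8 there).
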