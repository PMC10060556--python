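# Methods

`cranioflow` simulates the interaction of three lumped-parameter
(zero-dimensional, Windkessel-type) models: a cardiocerebral artery
network, an intracranial pressure (ICP) compartment, and per-territory
cerebral microcirculation models whose compliance pressures constitute a
simulated photoplethysmogram (PPG). This note records the model structure,
the physical reasoning behind the calibrated constants, the numerical
choices, and the known limitations.

## Circuit engine

All three parts are expressed in one hydraulic-circuit formalism (pressure
as voltage, volumetric flow as current; SI units internally, mmHg/ml only
at I/O boundaries, 1 mmHg = 133.3 Pa). Element kinds are resistors
(viscous loss), inductors (blood inertia), capacitors (vessel or tissue
compliance, constant or pressure-dependent), smoothed diodes and composite
*valves* (a series resistance plus diode solved as one scalar monotone
law), and pressure/flow sources, including unity-gain trackers that copy a
node pressure without drawing flow.

The state vector holds capacitor transmural pressures and inductor flows.
Nonlinear capacitors use the differential form `q = C(P) dP/dt`, the
standard convention in the Windkessel literature, so the state stays a
pressure. At assembly, node pressures are classified as *resolved*
(reachable from ground through sources and capacitor states) or as
*junctions*, which are obtained from a small linear Kirchhoff solve at each
derivative evaluation. Diodes interpolate between an off-conductance
(1e-14 SI) and an on-conductance (1e-6 SI) over a +-1 Pa band with a
quintic smoothstep: C2-smooth for the implicit integrator, yet exactly at
the off-conductance outside the band, so reverse leakage is bounded by
`g_off * |dP|`. Integration uses the SciPy BDF solver (relative tolerance
1e-6; absolute tolerance 1e-8 m^3/s for flows and 1e-5 Pa for pressures;
the structural Jacobian sparsity is exploited through grouped finite
differences). The model contains no randomness: repeated runs are
bit-identical.

## Artery network

Twenty-two intermediate segments (ascending aorta to the Circle of Willis)
each form a three-element Windkessel: series resistance and inertance with
the compliance at the segment midpoint. Eleven outlets (33 segments in
total) are three-element terminals; the five extracranial ones drain to a
5 mmHg venous source, the six cerebral ones are ICP-coupled once the model
is assembled. Segment R, L, C derive from vessel length and radius
(`R = 8*mu*l/(pi r^4)`, `L = rho*l/(pi r^2)`, `C = 3*pi*r^3*l/(2Eh)`, with
mu = 4 mPa.s, rho = 1050 kg/m^3 and an exponential wall-stiffness law);
terminal resistances are sized so that textbook regional flow fractions
reproduce a 92 mmHg mean arterial pressure at 5.6 L/min cardiac output.
Two tables ship (`scenario1`, default, and `scenario2`, a variant anatomy
with narrower, longer vessels) as versioned CSVs with per-row provenance.

Ageing enters only through two pressure-dependent compliances. The aorta
follows `C(P) = Amax*L / (pi*P1*(1 + ((P-P0)/P1)^2))` with
`P0 = 76 - 0.98*age` and `P1 = 57 - 0.44*age` (mmHg; valid ages 20-70;
`Amax` = 5.8 cm^2 for male adults), distributed over the three aortic
segments by length. The common carotid follows
`C(P) = a*exp(-b*P) * (1.3 - 0.012*(age-20))` with a = 3.14 ml/mmHg and
b = 0.018 /mmHg, anchored at the reference pressure 100 mmHg (the
reference capacitance is the exponential law evaluated there — the only
reading that keeps both printed forms consistent). Both laws stiffen with
age, which is what raises pulsatility indices in older subjects. The
cardiac inflow is a half-sine ejection (period 0.8 s, stroke volume 75 ml,
systolic fraction 0.35): smooth enough that no artificial high-frequency
content reaches the microcirculation, and integrating exactly to one
stroke volume per beat.

## ICP compartment

The craniospinal circuit has proximal and distal arterial beds (R1/Ci_1,
R2/Ci_2, plus a small capillary compliance Ci_c, all referenced to the ICP
node so each beat pumps an arterial volume excursion into the CSF space), a
CSF formation route (Rf + one-way valve, capillary node to ICP node), an
outflow route (Ro + one-way valve, ICP node to the venous sinus), and a
venous chain (Rpv, Rdv, Rve with compliances Cvi, Cue) ending at the
central venous pressure (5 mmHg). The bed is driven by the pressures at
the distal internal-carotid and basilar compliance nodes through equal
resistive taps fed by pressure trackers (the bed re-represents the same
vasculature, so it must not draw additional flow from the network).

The intracranial tissue compliance on the ICP node is the piecewise law

    C(ICP) = 7.502e-9 * ratio_cd                ICP in [0, 666.5) Pa
    C(ICP) = (5e-6 / ICP) * ratio_cd            ICP >= 666.5 Pa

continuous at the 666.5 Pa (5 mmHg) knot; `ratio_cd <= 1` emulates
pathological capacitance loss (0.25 = 75 % decrease).

**Why reduced capacitance elevates the measured mean ICP.** In any
periodic steady state the capacitance integrates to zero net flux, so a
flux balance alone cannot make the mean ICP depend on `ratio_cd`. The
mechanism here is a controlled transient: every run starts with the CSF
space at venous pressure (5 mmHg) and charges toward its CSF flux-balance
point through Rf/Ro. Above the knot the pressure-volume curve is
exponential (`V ~ 5e-6 * ratio_cd * ln(ICP)`), so the relaxation rate
scales with `1/ratio_cd`: at the 10 s measurement a normal brain has
reached ~10.5 mmHg while brains with 50 % and 75 % capacitance loss have
climbed to ~17 and ~24 mmHg on the same trajectory. Two requirements
pinned the calibration: the effective capacitance of the ICP node must be
dominated by the `ratio_cd`-scaled tissue term (hence small bed
compliances and the venous compliance referenced to ground), and the
normal-capacitance relaxation time must be of the order of the 10 s
run-in. This makes the CSF turnover far faster than physiological
(formation/outflow fluxes of order 0.1 ml/s rather than 0.006 ml/s) — a
deliberate time-scale compression that leaves the pressure landscape
intact; the mean ICP is insensitive to age (< 0.2 mmHg spread) because the
CSF fluxes, not the arterial pulse, set it.

## Microcirculation and PPG

Each probed territory (left ACA, MCA, PCA by default) replaces its
terminal's lumped distal branch with an arteriole-capillary-venule chain:
RA1-RA2 (equal halves of the arteriole share), RC, RV2-RV1 (equal venule
halves) plus a small drainage resistor, with compliances CC at the
capillary-venule junction and CV1/CV2 (equal) down the venule. The chain
resistances sum exactly to the terminal's distal resistance and the three
compliances to the terminal's capacitance (default split: arteriole 55 %,
capillary 25 %, venule 20 % of resistance; capillary 20 % of capacitance).
An arteriovenous-anastomosis resistance (10x the arteriole resistance)
bridges the arteriole and venule midpoints. The drainage resistor exists
because an ideal source would otherwise pin the most distal compliance
algebraically.

The chain drains into, and its compliances are referenced to, a
*microvascular reference* node carrying a divided-down copy of the ICP
signal (resistive divider toward the venous source, fraction ~0.08, with a
light smoothing compliance). This is the one place where the design had to
be found rather than chosen: if the chain sees ICP at full scale as a
subtractive boundary, every transmural pressure is proportional to
(prearteriole - ICP), forcing the PPG cycle mean to fall by
`dICP/(pre - ICP)` — more than 10 % over the condition grid — which is
arithmetically incompatible with shape features (PI = amplitude/mean)
staying within 2 %. Transmitting a fraction of ICP — mean shift and pulse
alike — to the territory outlet reproduces the observed structure: the
value features (maximum, minimum, mean) fall strictly and monotonically as
ICP rises, while min-to-max time, PI, RI and MMR move by < 1 % across
conditions. Unprobed (right-side) cerebral terminals keep their outlet
source tracking the ICP node at full scale.

The simulated PPG is the summed transmural pressure across CC, CV1 and CV2
(volume-proportional under fixed compliance, matching the volumetric origin
of a PPG signal; unit Pa, not an optical unit); a capillary-only probe is
available as `ppg_mode: capillary`. Territory contrast comes from terminal
compliance sizing (per-territory time constants MCA 1.6 s > ACA 1.05 s >
PCA 0.95 s): the MCA territory, largest and most compliant, is the most
damped, giving it the lowest PI/RI/MMR at every age; the PCA territory is
fed through the vertebrobasilar route, which bypasses the large carotid
compliance, giving it the highest.

## Measurement

Every simulation runs 30 s at a 1 kHz output rate; all features are
measured on the first cardiac cycle after 10 s (window [10 s, 10.8 s)).
Extrema use the half-open window with first-sample tie-breaking; the mean
is the trapezoidal integral over the closed cycle divided by the period;
min-to-max time measures the rising limb and wraps modulo the period when
the sampled cycle's maximum precedes its minimum. PI = (max-min)/mean,
RI = (max-min)/max, MMR = max/mean, so PI = RI*MMR identically. Initial
pressures are uniform: 80 mmHg arterial, 5 mmHg CSF/venous, with a graded
25-5 mmHg ramp down the microcirculation chains.

## Calibration

The free constants (the tables above) were fixed once against the printed
physiological bands — normal-condition mean ICP in 10-15 mmHg, mean
arterial pressure 70-110 mmHg, mean ICP above 15 mmHg at 50 % capacitance
reduction and above 20 mmHg at 75 %, within-cycle ICP amplitude below
5 mmHg, and territory ordering MCA < ACA/PCA — and committed to the data
files. `cranioflow calibrate` re-runs a deterministic bounded coordinate
search (CSF formation/outflow resistances, stroke volume, global terminal
scale; fixed step ladder, no randomness) on a compact probe grid and
reports before/after values; on the shipped tables it terminates
immediately with zero violation.

## What the synthetic conditions do and do not show

The scenario grid is the study's synthetic data: idealized male-adult
anatomy, a fixed heart rate, no autoregulation, no respiration, no
measurement noise. Passing tests therefore demonstrate the internal
consistency of the coupled model and the direction and rough magnitude of
its responses — not performance on real recordings. Specific limitations:
ICP waveforms carry one or two peaks per beat, not the clinical
P1/P2/P3 morphology (the venous system is a simple unidirectional chain);
the mean-ICP elevation is a transient mechanism with compressed CSF time
constants, so the 30 s tail of a run (all conditions converging toward the
same flux-balance point) is not physiologic; the ICP-to-microvasculature
transmission fraction is a modelling device calibrated to the waveform
claims, not a measured quantity; optical sensor physics, scalp
contamination and contact pressure are out of scope, as are vessel
occlusion and patient-specific anatomy.
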