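# Intracranial-pressure circuit elements (SI hydraulic units).
# Resistances Pa.s/m3, compliances m3/Pa, pressures mmHg.
# Provenance: structure and relative magnitudes follow the classic
# intracranial hydrodynamics analogues (proximal/distal arterial beds, CSF
# formation/outflow through one-way routes, venous pathway); absolute values
# calibrated so that, starting from the venous pressure level, the CSF
# space charges toward its flux-balance point with a relaxation rate
# inversely proportional to the intracranial capacitance, placing the 10-s
# measurement near 10.5 mmHg at normal capacitance, ~17 mmHg at 50 %
# reduction and ~24 mmHg at 75 % reduction, with within-cycle ICP
# pulsation below 5 mmHg everywhere.
r1_1: 2.67e+8     # proximal arterial bed, upstream half (2.0 mmHg.s/ml)
r1_2: 2.67e+8     # proximal arterial bed, downstream half
ci_1: 5.0e-11     # proximal arterial bed compliance (to ICP node)
r2_1: 2.67e+8     # distal arterial bed, upstream half
r2_2: 2.67e+8     # distal arterial bed, downstream half
ci_2: 5.0e-11     # distal arterial bed compliance (to ICP node)
ci_c: 2.5e-11     # capillary compliance (to ICP node; small but nonzero)
cvi: 3.7e-9       # intracranial venous compliance (to ground)
cue: 1.5e-8       # extracranial venous compliance (to ground)
rpv: 2.13e+8      # proximal venous resistance (1.6 mmHg.s/ml)
rdv: 2.4e+8       # distal venous resistance (lacunae / bridge veins)
rve: 6.5e+7       # extracranial venous pathway resistance
rf: 8.0e+9        # CSF formation resistance (capillary node -> ICP)
ro: 2.6e+10       # CSF outflow resistance (ICP -> sinus node)
pcv_mmhg: 5.0     # central venous pressure
r_tap: 2.0e+7     # equal coupling taps from ICA-L/ICA-R/basilar junctions
r_ref_a: 1.15e+9  # microvascular reference divider, ICP-side resistance
r_ref_b: 1.0e+8   # microvascular reference divider, venous-side resistance
c_ref: 3.0e-10    # smoothing compliance of the reference node
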