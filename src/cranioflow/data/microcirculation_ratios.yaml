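# Partition of a cerebral outlet terminal's distal resistance and
# capacitance over the territory microcirculation chain.
# Resistance fractions sum to 1; capacitance fractions sum to 1.
# Provenance: arteriole-dominant resistance and venule-dominant compliance,
# consistent with measured cerebral microvascular pressure profiles.
r_arteriole: 0.55       # split equally over RA1, RA2
r_capillary: 0.25       # RC
r_venule: 0.20          # split over RV2, RV1 and a small drainage resistor
c_capillary_frac: 0.20  # CC; the rest is split equally over CV1, CV2
rava_multiplier: 10.0   # R_AVA as a multiple of total arteriole resistance
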