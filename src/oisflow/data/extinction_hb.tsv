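# Hemoglobin extinction coefficients at the three LED wavelengths.
# Units: mM^-1 cm^-1 (decadic-style coefficients used directly in the
# exponential attenuation model; concentration outputs inherit the mM label).
# Values rounded from compiled whole-blood spectrophotometry tables;
# user-overridable -- the concentration scale of all outputs follows
# whatever table is supplied.
# columns: wavelength_nm	eps_hbo	eps_hbr
525	33.20	33.80
590	14.70	27.00
625	0.74	5.89
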