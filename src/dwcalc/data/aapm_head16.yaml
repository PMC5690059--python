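# Conversion factors k(D_W) referenced to the 16-cm head PMMA phantom.
# Exponential fit k = a * exp(-b * D_W), D_W in cm.
phantom: head16
a: 1.874799
b: 0.03871313
valid_range: [6.0, 45.0]
provenance: >
  Public exponential-fit coefficients from AAPM Report 204 (16-cm phantom
  fit), as adopted for water-equivalent diameter by AAPM Report 220.
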