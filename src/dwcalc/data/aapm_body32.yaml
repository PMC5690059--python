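# Conversion factors k(D_W) referenced to the 32-cm body PMMA phantom.
# Exponential fit k = a * exp(-b * D_W), D_W in cm.
# Users may replace this file with their own table (coefficients or an
# `entries: [[dw_cm, k], ...]` node list).
phantom: body32
a: 3.704369
b: 0.03671937
valid_range: [6.0, 55.0]
provenance: >
  Public exponential-fit coefficients from AAPM Report 204 (Table 1D,
  normalized-data fit, 32-cm phantom), as adopted for water-equivalent
  diameter by AAPM Report 220.
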