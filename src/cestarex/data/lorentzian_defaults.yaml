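# Starting values (sv) and bounds (lb, ub) for the multi-pool Lorentzian
# background fit of Z-spectra: amplitude A (unitless dip depth), linewidth
# sigma (FWHM, ppm) and centre offset (ppm) per background component.
#
# threepool_sym  = Water + NOE_-3.5 + MT_symmetric  (high-power protocol)
# fourpool_asym  = Water + NOE_-3.5 + NOE_-1.6 + MT_asymmetric (low-power protocol)
components:
  Water:
    A:      {lb: 0.02, ub: 1.0,  sv: 0.9}
    sigma:  {lb: 0.3,  ub: 10.0, sv: 1.4}
    center: {lb: -1.0, ub: 1.0,  sv: 0.0}
  NOE_-3.5:
    A:      {lb: 0.0,  ub: 0.6,  sv: 0.02}
    sigma:  {lb: 0.5,  ub: 10.0, sv: 3.0}
    center: {lb: -4.0, ub: 0.0,  sv: -2.0}
  NOE_-1.6:
    A:      {lb: 0.0,  ub: 0.2,  sv: 0.001}
    sigma:  {lb: 0.0,  ub: 1.5,  sv: 1.0}
    center: {lb: -2.0, ub: -1.0, sv: -1.5}
  MT_symmetric:
    A:      {lb: 0.0,  ub: 1.0,   sv: 0.1}
    sigma:  {lb: 10.0, ub: 100.0, sv: 25.0}
    center: {lb: -4.0, ub: 4.0,   sv: 0.0}
  MT_asymmetric:
    A:      {lb: 0.0,  ub: 1.0,   sv: 0.1}
    sigma:  {lb: 10.0, ub: 100.0, sv: 25.0}
    center: {lb: -4.0, ub: 4.0,   sv: -2.0}
models:
  threepool_sym: [Water, "NOE_-3.5", MT_symmetric]
  fourpool_asym: [Water, "NOE_-3.5", "NOE_-1.6", MT_asymmetric]
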