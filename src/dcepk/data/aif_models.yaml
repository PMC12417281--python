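# Named population arterial-input-function coefficient sets.
# Time unit: minutes after bolus onset; concentrations in mM.
#
# mixed_gaussian_sigmoid: two Gaussian bolus passes plus a sigmoid-gated
# exponential washout (Parker-style population AIF; a1/a2 in mmol·min,
# sigma/t in min, alpha in mmol, beta in min^-1, s in min^-1, tau in min).
mixed_gaussian_sigmoid:
  a1: 0.809
  a2: 0.330
  t1: 0.17046
  t2: 0.365
  sigma1: 0.0563
  sigma2: 0.132
  alpha: 1.050
  beta: 0.1685
  s: 38.078
  tau: 0.483

# biexponential: Weinmann-style decay without a first-pass peak; amplitudes in
# mM per (mmol/kg) dose units, rates in min^-1, dose in mmol/kg.
biexponential:
  dose: 0.1
  a1: 3.99
  a2: 4.78
  m1: 0.144
  m2: 0.0111
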