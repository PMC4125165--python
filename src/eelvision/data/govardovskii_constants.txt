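# Visual-pigment absorbance template constants (A1 retinal / A2 3,4-didehydroretinal).
#
# Alpha band: S(x) = 1 / ( exp[A(a - x)] + exp[B(b - x)] + exp[C(c - x)] + D ),
# with x = lambda_max / lambda.  The exponent 'a' depends on lambda_max:
#   A1: a = a0 + a1 * exp( -(lambda_max - a2)^2 / a3 )
#   A2: a = a0 + a1 * exp( (lambda_max - a2) / a3 )
# For A2 the constant A also depends on lambda_max:
#   A = A0 + A1 * exp( (lambda_max - A2) / A3 )
# Beta band: S_beta(lambda) = A_beta * exp( -((lambda - lm_beta) / b_beta)^2 ),
#   lm_beta = lm0 + lm1 * lambda_max ;  b_beta = bb0 + bb1 * lambda_max
#
# Format: <chromophore>.<key> = <value>

a1.A = 69.7
a1.B = 28.0
a1.C = -14.9
a1.D = 0.674
a1.b = 0.922
a1.c = 1.104
a1.a0 = 0.8795
a1.a1 = 0.0459
a1.a2 = 300.0
a1.a3 = 11940.0
a1.beta_amp = 0.26
a1.beta_lm0 = 189.0
a1.beta_lm1 = 0.315
a1.beta_bb0 = -40.5
a1.beta_bb1 = 0.195

a2.A0 = 62.7
a2.A1 = 1.834
a2.A2 = 625.0
a2.A3 = 54.2
a2.B = 20.85
a2.C = -10.37
a2.D = 0.5343
a2.b = 0.9101
a2.c = 1.1157
a2.a0 = 0.875
a2.a1 = 0.0268
a2.a2 = 665.0
a2.a3 = 40.7
a2.beta_amp = 0.37
a2.beta_lm0 = 216.7
a2.beta_lm1 = 0.287
a2.beta_bb0 = 150.5
a2.beta_bb1 = 0.0064
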