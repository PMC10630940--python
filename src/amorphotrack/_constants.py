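"""Physical constants and package-wide conventions."""

#: vacuum permittivity [F/m]
EPS0 = 8.8541878128e-12

#: molar gas constant [J/(mol K)]
R_GAS = 8.31446261815324

#: relaxation time defining the dielectric glass transition, tau_alpha(Tg) [s]
TAU_REF_TG = 100.0

#: coupling-model crossover time default [s] (field convention, overridable)
T_C_DEFAULT = 2e-12
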