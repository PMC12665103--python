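"""Unit conversion factors.

All internal computation uses CGS-derived working units (cm, s, cm^3) for
geometry and conductances and SI (m^2/s) only where diffusivities enter from
configuration; every factor that crosses that boundary is defined here and
nowhere else, so the conversion table can be audited in one place.
"""

# length
UM_TO_CM = 1e-4
CM_TO_UM = 1e4
M_TO_CM = 1e2
CM_TO_M = 1e-2

# area
M2_TO_CM2 = 1e4
CM2_TO_M2 = 1e-4

# volume
UL_TO_CM3 = 1e-3
CM3_TO_UL = 1e3

# flow rate
UL_MIN_TO_CM3_S = 1e-3 / 60.0

# diffusivity
M2S_TO_CM2S = 1e4

# viscosity: 1 Pa.s = 10 g/(cm.s) (poise)
PAS_TO_POISE = 10.0

# time
MIN_TO_S = 60.0
H_TO_S = 3600.0
S_TO_H = 1.0 / 3600.0

# pressure
PA_TO_DYNE_CM2 = 10.0
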