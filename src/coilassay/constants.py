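"""Physical constants and unit conversions (SI internally)."""

import math

#: Vacuum permeability, H/m.
MU0 = 4.0e-7 * math.pi

#: Copper resistivity at 20 °C, Ω·m.
COPPER_RESISTIVITY = 1.68e-8

#: 1 V/m expressed in μV/cm.
V_PER_M_TO_UV_PER_CM = 1.0e4
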