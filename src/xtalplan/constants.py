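"""Physical constants and unit-conversion factors.

Internal canonical units are mg, ml, µm and h.  Millimetres and microlitres
are accepted at API boundaries and converted exactly once, through the
factors below, so no conversion is ever duplicated inline.
"""

#: Avogadro's number (mol^-1).
AVOGADRO = 6.02214e23

#: Cubic ångströms per cubic millimetre (1 mm = 1e7 Å).
A3_PER_MM3 = 1e21

#: Millilitres per cubic micrometre (1 ml = 1 cm^3 = 1e12 µm^3).
ML_PER_UM3 = 1e-12

#: Cubic millimetres per millilitre.
MM3_PER_ML = 1e3

#: Microlitres per millilitre.
UL_PER_ML = 1e3

#: Micrometres per millimetre.
UM_PER_MM = 1e3

#: Milligrams per gram.
MG_PER_G = 1e3

#: Seconds per hour.
S_PER_H = 3600.0

#: Metres per millimetre.
M_PER_MM = 1e-3
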