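"""Published constants of the OGIS insulin-sensitivity index (2-h variant,
samples at 0, 90 and 120 min), transcribed from the original publication.

The formula operates in the original units — glucose mg/dl, insulin mU/l,
oral glucose dose g/m^2, volumes ml/m^2 — and returns ml min^-1 m^-2.
Version the table rather than editing in place if a re-transcription ever
changes a value; a dual-transcription test locks the current values.
"""

OGIS_CONSTANTS_VERSION = "2h-v1"

P1 = 289.0  # mg/dl per (g/m^2) — dose scaling
P2 = 270.0  # mU/l — insulin offset
P3 = 14000.0  # (mg/dl)^2-scaled fasting term numerator
P4 = 440.0  # dimensionless gain
P5 = 637e-6  # (mg/dl)^-1 — glucose-dependent clearance slope
P6 = 117.0  # ml min^-1 m^-2 — glucose-effectiveness clearance

V_GLUCOSE = 1e4  # ml/m^2 — glucose distribution volume
G_CLAMP = 90.0  # mg/dl — reference (clamp) glucose

# unit conversions used when feeding SI-unit MMTT data into the formula
MGDL_PER_MMOLL = 18.016  # glucose, from molar mass 180.16 g/mol
PMOLL_PER_MUL = 6.945  # insulin, 1 mU/l = 6.945 pmol/l
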