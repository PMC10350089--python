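"""Measured photophysical parameter sets for the two oligo-complex designs.

These are the characterization results for the Atto488-labeled external
(end-labeled, "ext.") and internal ("int.") oligo-complex configurations:
two-component fluorescence decays, FCS correlation parameters, molecular
brightness and rotational times. They serve as simulation ground truth for
recovery studies and as inputs to the worked examples.
"""

from __future__ import annotations

from .photophysics import DecayParams, FcsParams

__all__ = [
    "EXT_DECAY", "INT_DECAY", "EXT_FCS", "INT_FCS",
    "EXT_BRIGHTNESS_KHZ", "INT_BRIGHTNESS_KHZ",
    "EXT_ROTATIONAL_TIME_PS", "INT_ROTATIONAL_TIME_PS",
    "G_FACTOR", "OMEGA_0", "INTENSITY_FOLD_INT_VS_EXT",
]

# Two-lifetime decay fits (amplitude fraction, lifetime in ns)
EXT_DECAY = DecayParams(((0.57, 4.0), (0.43, 0.76)))
INT_DECAY = DecayParams(((0.68, 4.0), (0.32, 0.92)))

# FCS correlation fits: N, diffusion time (ms), dark-state fractions and
# times (fast in us, slow in ms); omega0 calibrated with Rhodamine 110.
EXT_FCS = FcsParams(n=0.49, t_diff=0.71, omega=4.73, g_inf=0.0,
                    a_t1=0.28, a_t2=0.13, t_t1=2.4, t_t2=0.19)
INT_FCS = FcsParams(n=0.50, t_diff=0.59, omega=4.73, g_inf=0.0,
                    a_t1=0.26, a_t2=0.082, t_t1=0.9, t_t2=0.088)

# Molecular brightness (kHz per bright molecule)
EXT_BRIGHTNESS_KHZ = 8.1
INT_BRIGHTNESS_KHZ = 13.5

# Rotational correlation times (ps) and detection calibration
EXT_ROTATIONAL_TIME_PS = 280.0
INT_ROTATIONAL_TIME_PS = 350.0
G_FACTOR = 1.04
OMEGA_0 = 4.73

# Steady-state intensity fold change of the int. vs ext. complex in solution
INTENSITY_FOLD_INT_VS_EXT = 6.0
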