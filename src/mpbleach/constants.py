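"""Physical constants and instrument-level defaults.

Unit conventions used throughout the package (chosen to match how multiphoton
photophysics values are tabulated in the literature):

* lengths in cm, areas in cm^2
* one-photon cross sections in cm^2, two-photon cross sections in GM
  (1 GM = 1e-50 cm^4 s) externally and cm^4 s internally
* photon flux in photons / cm^2 / s, average power in W
* photon energies via hc = 1239.841984 eV nm
"""

#: hc in eV nm (CODATA exact, from h and c exact values)
HC_EV_NM = 1239.841984

#: 1 eV in joules (exact)
EV_J = 1.602176634e-19

#: 1 GM (Goeppert-Mayer) in cm^4 s
GM_CM4S = 1e-50

# ---------------------------------------------------------------------------
# Defaults describing the colony-on-agar bleaching instrument: an 80 MHz
# femtosecond oscillator focused by a low-NA objective into an E. coli colony
# (~200 um thick, refractive index of water).
# ---------------------------------------------------------------------------

#: pulse repetition rate of the imaging oscillator (Hz)
DEFAULT_REP_RATE_HZ = 80e6

#: pulse duration at the sample, transform-limited anchor at 1100 nm (s)
DEFAULT_PULSE_DURATION_S = 109e-15

#: colony thickness (cm); colonies measure 150-240 um, 200 um is typical
DEFAULT_COLONY_THICKNESS_CM = 200e-4

#: refractive index of the aqueous colony interior
DEFAULT_COLONY_N0 = 1.33

#: beam waist radius at focus (cm); the instrument's waist varies between
#: 3.5 and 5.5 um across wavelength, 4.5 um is the mid-band value
DEFAULT_WAIST_CM = 4.5e-4

# ---------------------------------------------------------------------------
# The 1 kHz regenerative-amplifier solution-bleaching setting used for the
# homogeneous-beam cross-check.  The amplifier delivers a spatially uniform
# ~3 mm beam; its effective rectangular pulse duration at the sample is an
# assumption of this package (see docs/methods.md).
# ---------------------------------------------------------------------------

AMPLIFIER_REP_RATE_HZ = 1e3
AMPLIFIER_PULSE_DURATION_S = 350e-15
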