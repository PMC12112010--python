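"""Shared physical constants and unit conventions.

Conventions used throughout the package:

- frequency ``f`` in MHz
- depth ``z`` in cm
- attenuation slopes in dB/(MHz·cm); exponentials convert to nepers
- backscatter coefficients in 1/(cm·sr)
- transducer geometry (pitches, extents) in mm
"""

#: dB per neper (20 / ln 10); all dB→Np conversions use this single constant.
DB_PER_NEPER = 8.6859

#: Assumed sound speed of soft tissue used for image geometry (m/s).
#: Axial pixel pitch of a beamformed frame is c / (2 * sampling_rate).
ASSUMED_SOUND_SPEED_M_S = 1540.0

#: Two-way propagation factor for attenuation of *power* in dB:
#: power decays as exp(-4 * alpha_Np * f * z).
TWO_WAY_POWER_FACTOR = 4.0


def db_to_neper(alpha_db: float) -> float:
    """Convert an attenuation value from dB units to nepers."""
    return alpha_db / DB_PER_NEPER
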