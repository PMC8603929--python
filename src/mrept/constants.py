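"""Physical constants and field-strength helpers.

All internal math is SI (metres, radians, seconds, S/m).  Voxel spacing is
carried in millimetres on the containers (the convention of NIfTI headers)
and converted to metres at the point of differentiation.
"""

import numpy as np

#: Vacuum permeability, H/m.
MU0 = 4.0e-7 * np.pi

#: Proton gyromagnetic ratio, Hz/T.
GYROMAGNETIC_RATIO_HZ_PER_T = 42.577e6


def larmor_frequency_hz(b0_tesla: float) -> float:
    """Proton Larmor frequency f = γ·B0 in Hz.

    At 9.4 T this evaluates to 400.22 MHz, the operating frequency of a
    9.4 T small-animal scanner.
    """
    if b0_tesla <= 0:
        raise ValueError(f"B0 must be positive, got {b0_tesla}")
    return GYROMAGNETIC_RATIO_HZ_PER_T * b0_tesla


def rhs_constant(larmor_hz: float) -> float:
    """The source term 2·μ₀·ω of the conductivity equation, rad·S⁻¹·m⁻¹...

    For a phase map in rad and lengths in metres, σ = ∇²ϕ / (2μ₀ω) comes out
    in S/m.  At 400 MHz, 2μ₀ω = 6316.5.
    """
    if larmor_hz <= 0:
        raise ValueError(f"Larmor frequency must be positive, got {larmor_hz}")
    return 2.0 * MU0 * (2.0 * np.pi * larmor_hz)
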