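"""Physical constants and unit conventions.

Momentum-transfer variable: ``s = sin(theta)/lambda`` in 1/Angstrom
everywhere in this package.  Radial Fourier transforms use the kernel
``q = 4*pi*s``.  Resolution ``d`` relates to ``s`` by ``s = 1/(2d)``.
"""

from __future__ import annotations

import math

import scipy.constants as _sc

#: Bohr radius in Angstrom, used to convert Slater exponents from atomic units.
BOHR_ANGSTROM: float = _sc.physical_constants["Bohr radius"][0] * 1e10

#: Mott-Bethe prefactor  C = m0 e^2 / (8 pi eps0 h^2), expressed in Angstrom
#: so that  f_e(s) = C * (Z - f_x(s)) / s**2  with s in 1/Angstrom gives an
#: electron scattering amplitude in Angstrom.
MOTT_BETHE_C: float = (
    _sc.m_e * _sc.e**2 / (8.0 * math.pi * _sc.epsilon_0 * _sc.h**2)
) * 1e-10

FOUR_PI = 4.0 * math.pi
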