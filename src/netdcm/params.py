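"""Parameter containers shared by the simulator and the forward model.

Conventions
-----------
Spectra are two-sided densities over frequency f in Hz, with the power-law
shape written in angular frequency, ``S(f) = amplitude * (2*pi*f) ** -exponent``
so that integrating a density over (-Nyquist, Nyquist) with measure df yields
a variance.  ``exponent = 0`` is white noise, ``exponent = 1`` the classic
1/f spectrum of slow endogenous activity.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FluctuationParams:
    """Power-law spectral density ``amplitude * omega**-exponent`` (omega in rad/s).

    Used twice: once for the endogenous neuronal fluctuations that drive the
    dynamics, once for additive observation noise (white by default).
    ``amplitude`` has units of variance * s; ``exponent`` is dimensionless.
    """

    amplitude: float = 0.01
    exponent: float = 1.0

    def __post_init__(self):
        if not self.amplitude >= 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not self.exponent >= 0:
            raise ValueError(f"exponent must be >= 0, got {self.exponent}")


@dataclass(frozen=True)
class HemodynamicParams:
    """Constants of the linearized balloon observation model.

    signal_decay and feedback (1/s) govern the vasodilatory signal, transit (s)
    the venous transit time, stiffness the vessel stiffness exponent and
    extraction the resting oxygen extraction fraction.  The defaults are
    canonical literature values and yield a kernel peaking near 5 s.
    """

    signal_decay: float = 0.64
    feedback: float = 0.32
    transit: float = 2.0
    stiffness: float = 0.32
    extraction: float = 0.4

    def __post_init__(self):
        for name in ("signal_decay", "feedback", "transit", "stiffness", "extraction"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")


#: Default endogenous fluctuation spectrum: 1/f with modest amplitude.
DEFAULT_NEURAL_FLUCT = FluctuationParams(amplitude=0.01, exponent=1.0)

#: Default observation noise: white, amplitude set for a realistic SNR of a
#: region eigenvariate (roughly 4:1 signal-to-noise in standard deviation
#: given the default endogenous spectrum and hemodynamics).
DEFAULT_OBS_NOISE = FluctuationParams(amplitude=0.5, exponent=0.0)

DEFAULT_HEMO = HemodynamicParams()
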