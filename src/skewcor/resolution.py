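"""Resolving-power model: which fine-structure species merge into one peak.

Orbitrap resolving power (FWHM definition) is quoted at a reference m/z
and falls off as the inverse square root of m/z; FT-free analyzers keep a
constant resolving power.  Two species are called resolved when their m/z
difference exceeds ``separation_coefficient`` times the peak FWHM; the
default coefficient of 1.66 is where two equal Gaussian peaks become
baseline-separable.  All comparisons are made in neutral-mass units, so
the m/z window is multiplied by the charge.

A third mode, ``nominal``, reproduces the classical low-resolution
behaviour in which everything within half a nominal mass unit merges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: FWHM multiples at which two equal Gaussian peaks are baseline-separated.
DEFAULT_SEPARATION_COEFFICIENT = 1.66

_SCALINGS = ("orbitrap", "constant", "nominal")


@dataclass(frozen=True)
class ResolutionModel:
    """Instrument resolving power and the resulting merge criterion.

    Parameters
    ----------
    resolution:
        Resolving power (m/z over FWHM) at ``mz_ref``.
    mz_ref:
        Reference m/z at which ``resolution`` is specified (Orbitraps are
        commonly quoted at m/z 200).
    scaling:
        ``'orbitrap'`` (inverse square root of m/z, the default),
        ``'constant'``, or ``'nominal'`` (low-resolution unit-mass
        merging; ``resolution`` and ``mz_ref`` are ignored).
    separation_coefficient:
        Multiplier on the FWHM required to call two species resolved.
    """

    resolution: float = 60000.0
    mz_ref: float = 200.0
    scaling: str = "orbitrap"
    separation_coefficient: float = DEFAULT_SEPARATION_COEFFICIENT

    def __post_init__(self) -> None:
        if self.scaling not in _SCALINGS:
            raise ValueError(
                f"scaling must be one of {_SCALINGS}, got {self.scaling!r}"
            )
        if self.scaling != "nominal" and (self.resolution <= 0 or self.mz_ref <= 0):
            raise ValueError("resolution and mz_ref must be positive")
        if self.separation_coefficient <= 0:
            raise ValueError("separation_coefficient must be positive")

    @classmethod
    def nominal(cls) -> "ResolutionModel":
        """Unit-mass-resolution model (classical nominal merging)."""
        return cls(scaling="nominal")

    def resolving_power_at(self, mz: float) -> float:
        """Effective resolving power at an arbitrary m/z."""
        if mz <= 0:
            raise ValueError("mz must be positive")
        if self.scaling == "constant":
            return self.resolution
        if self.scaling == "orbitrap":
            return self.resolution * math.sqrt(self.mz_ref / mz)
        return mz / 0.5  # nominal: FWHM is half a mass unit by construction

    def min_separable_mass_diff(self, mz: float, charge: int = 1) -> float:
        """Smallest resolvable neutral-mass difference at *mz* (Da).

        ``separation_coefficient x FWHM`` in m/z units, converted to
        neutral mass by multiplying with the charge.  In nominal mode the
        window is a fixed 0.5 Da of neutral mass.
        """
        if charge < 1:
            raise ValueError("charge must be >= 1")
        if self.scaling == "nominal":
            return 0.5
        fwhm = mz / self.resolving_power_at(mz)
        return self.separation_coefficient * fwhm * charge

    def is_unresolved(
        self, shift_a: float, shift_b: float, mz: float, charge: int = 1
    ) -> bool:
        """True when two neutral-mass shifts merge into one observed peak."""
        return abs(shift_a - shift_b) < self.min_separable_mass_diff(mz, charge)
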