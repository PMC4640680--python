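"""Optodes, optical properties and time gating.

Internal units are mm, mm^-1 and ps throughout; configuration files that
state coefficients in cm^-1 (the usual tissue-optics convention) are
converted at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Speed of light in vacuum, mm/ps.
C_MM_PER_PS = 0.299792458


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous tissue optical properties (mm^-1 internally).

    Parameters
    ----------
    mu_a : absorption coefficient (mm^-1), >= 0
    mu_s_prime : reduced scattering coefficient mu_s * (1 - g) (mm^-1), > 0
    g : scattering anisotropy (mean cosine), 0 <= g < 1
    n_refr : refractive index, >= 1
    """

    mu_a: float
    mu_s_prime: float
    g: float
    n_refr: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if self.mu_s_prime <= 0:
            raise ValueError("mu_s_prime must be > 0")
        if not (0.0 <= self.g < 1.0):
            raise ValueError("g must be in [0, 1)")
        if self.n_refr < 1.0:
            raise ValueError("n_refr must be >= 1")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s' / (1 - g) (mm^-1)."""
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s

    @classmethod
    def from_cm(cls, mu_a_cm: float, mu_s_prime_cm: float, g: float, n_refr: float):
        """Build from coefficients stated in cm^-1."""
        return cls(mu_a_cm / 10.0, mu_s_prime_cm / 10.0, g, n_refr)


@dataclass(frozen=True)
class Optode:
    """A point source or point detector on the mesh boundary."""

    position: np.ndarray
    direction: np.ndarray
    kind: str  # "source" | "detector"

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        d = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError("optode direction must be nonzero")
        object.__setattr__(self, "direction", d / nrm)
        if self.kind not in ("source", "detector"):
            raise ValueError("kind must be 'source' or 'detector'")


@dataclass(frozen=True)
class TimeGating:
    """Uniform temporal gates: ``n_gates`` bins of ``gate_width`` ps from t0."""

    gate_width: float = 50.0
    n_gates: int = 40
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.gate_width <= 0:
            raise ValueError("gate_width must be > 0")
        if self.n_gates < 1:
            raise ValueError("n_gates must be >= 1")

    @property
    def t_max(self) -> float:
        return self.t0 + self.gate_width * self.n_gates

    def centers(self) -> np.ndarray:
        return self.t0 + self.gate_width * (np.arange(self.n_gates) + 0.5)
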