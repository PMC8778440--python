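"""SAXS curve container with its experimental-design labels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScatteringCurve"]


@dataclass
class ScatteringCurve:
    """One absolute-scale SAXS curve and its four curve parameters.

    q [Å^-1] strictly increasing within [0.005, 1]; I = dΣ/dΩ [cm^-1];
    sigma [cm^-1] > 0.  Each curve is labeled by protein w/v
    concentration ``c0`` [g L^-1] at T°, temperature ``T`` [K],
    cosolvent id ``G`` (or None) and cosolvent molarity ``C_G0`` [M] at
    T°.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    c0: float
    T: float
    G: str | None = None
    C_G0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise ValueError("q, I and sigma must share a length")
        if len(self.q) < 20:
            raise ValueError("a curve needs at least 20 points")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.q[0] < 0.005 or self.q[-1] > 1.0:
            raise ValueError("q must lie within [0.005, 1] Å^-1")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if self.G is None:
            self.C_G0 = 0.0

    @property
    def N_q(self) -> int:
        return len(self.q)

    @property
    def curve_params(self) -> tuple[float, float, str | None, float]:
        """(c°, T, G, C_G°) labels used by the regularization neighbor map."""
        return (self.c0, self.T, self.G, self.C_G0)
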