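"""Effective connectivity: the directed coupling matrix of the neuronal model.

Orientation convention (fixed globally): ``matrix[i, j]`` is the influence of
source region j on the *rate of change* of target region i, in Hz.  Row =
target, column = source.  Diagonal entries are self-connections and must be
strictly negative (self-inhibition) for the dynamics to be dissipative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import RegionSet


class StabilityError(ValueError):
    """Raised when a coupling matrix has an eigenvalue with nonnegative real part."""


@dataclass(frozen=True)
class EffectiveConnectivity:
    matrix: np.ndarray  # (n, n), Hz; row = target, column = source
    regions: RegionSet

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        n = self.regions.n
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} regions")
        if not np.all(np.isfinite(m)):
            raise ValueError("coupling matrix contains non-finite entries")
        if np.any(np.diag(m) >= 0):
            bad = [self.regions.labels[i] for i in np.flatnonzero(np.diag(m) >= 0)]
            raise ValueError(
                f"self-connections must be strictly negative (self-inhibition); "
                f"offending regions: {bad}"
            )

    @property
    def n(self) -> int:
        return self.regions.n

    def max_real_eigenvalue(self) -> float:
        return float(np.max(np.linalg.eigvals(self.matrix).real))

    def is_stable(self) -> bool:
        return self.max_real_eigenvalue() < 0

    def assert_stable(self) -> "EffectiveConnectivity":
        ev = np.linalg.eigvals(self.matrix)
        worst = ev[np.argmax(ev.real)]
        if worst.real >= 0:
            raise StabilityError(
                f"coupling matrix is unstable: eigenvalue {worst:.4g} has "
                f"nonnegative real part"
            )
        return self


def stable(matrix: np.ndarray) -> bool:
    """Stability test for a raw coupling matrix (all eigenvalues in left half-plane)."""
    return float(np.max(np.linalg.eigvals(np.asarray(matrix, float)).real)) < 0
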