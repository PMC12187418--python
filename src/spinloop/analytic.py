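"""Closed-form results: critical coupling and efficiency divergence laws.

The square-lattice Ising model has its continuous phase transition at
sinh(2*beta*Jc) = 1, i.e. Jc = ln(1 + sqrt(2)) / (2*beta) ~ 0.4407 at
beta = 1.  Thermodynamic efficiency diverges there as |J - Jc|^(-1) with
prefactor ln(1 + sqrt(2))/2; the mean-field (Curie-Weiss) model shows the
same |theta - theta_c|^(-1) divergence in temperature with branch-dependent
prefactors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CriticalPoint",
    "onsager_critical_coupling",
    "ising_efficiency_asymptote",
    "curie_weiss_efficiency",
    "ISING_ASYMPTOTE_PREFACTOR",
]

#: ln(1 + sqrt(2)) / 2 = arcsinh(1) / 2: both the critical coupling at
#: beta = 1 and the prefactor of the efficiency asymptote.
ISING_ASYMPTOTE_PREFACTOR = math.log(1.0 + math.sqrt(2.0)) / 2.0


@dataclass(frozen=True)
class CriticalPoint:
    """Critical coupling Jc at inverse temperature beta: sinh(2*beta*Jc) = 1."""

    Jc: float
    beta: float


def onsager_critical_coupling(beta: float = 1.0) -> CriticalPoint:
    """Exact critical coupling of the square-lattice Ising model."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    return CriticalPoint(Jc=math.asinh(1.0) / (2.0 * beta), beta=beta)


def ising_efficiency_asymptote(J: float, beta: float = 1.0) -> float:
    """Divergence law of efficiency near criticality on the square lattice.

    eta(J) = [ln(1 + sqrt(2)) / 2] * |J - Jc|^(-1), valid as J -> Jc on
    either side.

    Raises
    ------
    ValueError
        At J = Jc, where the efficiency diverges.
    """
    Jc = onsager_critical_coupling(beta).Jc
    if J == Jc:
        raise ValueError(f"efficiency diverges at the critical coupling Jc={Jc}")
    return ISING_ASYMPTOTE_PREFACTOR / abs(J - Jc)


def curie_weiss_efficiency(theta: float, theta_c: float, kB: float = 1.0) -> float:
    """Efficiency of the fully connected (Curie-Weiss) ferromagnet.

    Branches in temperature theta around the critical temperature theta_c:

    * theta < theta_c:  -theta_c / (2*kB) * (theta - theta_c)^(-1)  (> 0)
    * theta > theta_c:   1 / (kB * (theta - theta_c))               (> 0)

    Both diverge as |theta - theta_c|^(-1).
    """
    if theta_c <= 0:
        raise ValueError("theta_c must be positive")
    if theta == theta_c:
        raise ValueError("efficiency diverges at the critical temperature")
    if theta < theta_c:
        return -theta_c / (2.0 * kB) / (theta - theta_c)
    return 1.0 / (kB * (theta - theta_c))
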