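"""Enthalpy–entropy decomposition of the solute–solvent interaction free energy.

The interaction free energy of an end-point explicit-solvent ensemble splits
into the mean interaction energy (the interaction enthalpy) and an
exponential-average fluctuation term (the interaction-entropy term):

    dH_int       = <E>
    -T*dS_int    = kT * ln < exp(beta * dE) >,   dE = E - <E>
    dG_int       = dH_int + (-T*dS_int)

with beta = 1/(k_B T). By Jensen's inequality the entropy term is
non-negative — forming the solute–solvent contact always costs entropy — and
it vanishes exactly when the interaction energy does not fluctuate. The
exponential average is evaluated with log-sum-exp so that large fluctuations
(beta*dE in the thousands) stay finite instead of overflowing.

All averages run over a single solution-ensemble trajectory; dE is measured
against the full-series mean (two-pass), not a running mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .nonbonded_energy import EnergySeries

__all__ = [
    "BOLTZMANN_KCAL",
    "DEFAULT_TEMPERATURE",
    "ThermoDecomposition",
    "interaction_enthalpy",
    "interaction_entropy_term",
    "decompose",
    "block_convergence",
]

#: Boltzmann constant, kcal/(mol·K).
BOLTZMANN_KCAL = 0.0019872041

#: Default temperature (K); the ensemble temperature of the reference protocol.
DEFAULT_TEMPERATURE = 298.0


@dataclass(frozen=True)
class ThermoDecomposition:
    """Interaction enthalpy, entropy term and free energy for one solute (kcal/mol)."""

    dH_int: float
    minus_TdS_int: float
    dG_int: float
    temperature: float
    beta: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.minus_TdS_int < 0:
            raise ValueError("entropy term must be non-negative")
        if abs(self.dG_int - (self.dH_int + self.minus_TdS_int)) > 1e-12 * max(
            1.0, abs(self.dG_int)
        ):
            raise ValueError("dG_int must equal dH_int + minus_TdS_int")


def interaction_enthalpy(series: EnergySeries) -> float:
    """Mean total interaction energy over frames, kcal/mol."""
    if series.n_frames < 1:
        raise ValueError("energy series is empty")
    return float(series.e_total.mean())


def interaction_entropy_term(series: EnergySeries,
                             temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Entropy-loss term kT·ln⟨exp(β ΔE)⟩ ≥ 0, kcal/mol.

    Invariant under adding any constant to all frame energies; exactly zero
    for a constant series (including the single-frame degenerate case).
    """
    if series.n_frames < 1:
        raise ValueError("energy series is empty")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    e = series.e_total
    if not np.isfinite(e).all():
        raise ValueError("energy series contains non-finite entries")
    if np.ptp(e) == 0.0:  # constant series: exactly zero, no roundoff from the mean
        return 0.0
    beta = 1.0 / (BOLTZMANN_KCAL * temperature)
    de = e - e.mean()
    # kT * [ logsumexp(beta*dE) - ln n ]; >= 0 by Jensen, clamp roundoff.
    val = (logsumexp(beta * de) - np.log(e.size)) / beta
    return float(max(val, 0.0))


def decompose(series: EnergySeries,
              temperature: float = DEFAULT_TEMPERATURE) -> ThermoDecomposition:
    """Full enthalpy/entropy/free-energy decomposition of an energy series."""
    dh = interaction_enthalpy(series)
    ts = interaction_entropy_term(series, temperature)
    return ThermoDecomposition(
        dH_int=dh,
        minus_TdS_int=ts,
        dG_int=dh + ts,
        temperature=float(temperature),
        beta=1.0 / (BOLTZMANN_KCAL * temperature),
        n_frames=series.n_frames,
    )


def block_convergence(series: EnergySeries, temperature: float = DEFAULT_TEMPERATURE,
                      n_blocks: int = 4) -> list[ThermoDecomposition]:
    """Decomposition per contiguous equal block (remainder goes to the last block).

    A convergence diagnostic for the exponential average: scattered block
    values flag insufficient sampling of the energy fluctuations.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    n = series.n_frames
    if n_blocks > n:
        raise ValueError(f"n_blocks ({n_blocks}) exceeds n_frames ({n})")
    size = n // n_blocks
    out = []
    for b in range(n_blocks):
        lo = b * size
        hi = n if b == n_blocks - 1 else lo + size
        block = EnergySeries(e_ele=series.e_ele[lo:hi], e_vdw=series.e_vdw[lo:hi])
        out.append(decompose(block, temperature))
    return out
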