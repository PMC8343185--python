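"""Wetting criterion for a gel particle at a dextran/PEG interface.

A particle sits at the liquid-liquid interface when neither phase wets it
strongly enough to pull it in completely: |gamma_p,PEG - gamma_p,dex| <
gamma_dex,PEG. Otherwise it is engulfed by whichever phase offers the
cheaper contact. Boundary equality counts as engulfment (the interface
condition is a strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = ["TensionTriple", "ParticleLocation", "particle_location"]


@dataclass(frozen=True)
class TensionTriple:
    """The three pairwise interfacial tensions, all in N/m."""

    gamma_particle_peg: float
    gamma_particle_dex: float
    gamma_dex_peg: float

    def __post_init__(self) -> None:
        for name in ("gamma_particle_peg", "gamma_particle_dex", "gamma_dex_peg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


class ParticleLocation(str, Enum):
    INTERFACE = "interface"
    ENGULFED_IN_DEXTRAN = "engulfed_in_dextran"
    ENGULFED_IN_PEG = "engulfed_in_peg"


def particle_location(t: TensionTriple) -> ParticleLocation:
    """Classify where the particle resides from its tension triple."""
    diff = t.gamma_particle_peg - t.gamma_particle_dex
    if abs(diff) < t.gamma_dex_peg:
        return ParticleLocation.INTERFACE
    # PEG contact is expensive -> the particle buries itself in dextran
    return (
        ParticleLocation.ENGULFED_IN_DEXTRAN
        if diff >= 0
        else ParticleLocation.ENGULFED_IN_PEG
    )
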