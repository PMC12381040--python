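"""Theoretical osmolarity of treatment buffers.

Tonicity treatments are NaCl-modulated phosphate-buffered saline: only the
NaCl concentration differs between conditions (hypertonic 175 mM, isotonic
137 mM, hypotonic 75 mM).  Osmolarity is computed under ideal full
dissociation — each solute contributes concentration x particle count, with
no osmotic coefficients — which is the convention behind the quoted ~313 /
~190 / ~390 mOsm/L values.

The remaining PBS solutes use the standard 1x recipe (2.7 mM KCl, 10 mM
Na2HPO4, 1.8 mM KH2PO4), the usual assumption when a recipe is not printed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ValidationError

__all__ = ["Solute", "BufferComposition", "theoretical_osmolarity", "pbs", "PBS_PRESETS"]


@dataclass(frozen=True)
class Solute:
    name: str
    concentration_mM: float
    particles: int  # ideal dissociation particle count

    def __post_init__(self) -> None:
        if self.concentration_mM < 0:
            raise ValidationError(f"negative concentration for {self.name}")
        if self.particles < 1:
            raise ValidationError(f"particle count must be >= 1 for {self.name}")


@dataclass(frozen=True)
class BufferComposition:
    label: str
    solutes: tuple[Solute, ...]


def theoretical_osmolarity(buffer: BufferComposition) -> float:
    """Sum of concentration x ideal particle count over solutes, in mOsm/L."""
    return float(sum(s.concentration_mM * s.particles for s in buffer.solutes))


def pbs(nacl_mM: float, label: str = "PBS") -> BufferComposition:
    """1x PBS with the stated NaCl concentration (ideal dissociation counts:
    NaCl and KCl -> 2, Na2HPO4 -> 3, KH2PO4 -> 2)."""
    return BufferComposition(
        label=label,
        solutes=(
            Solute("NaCl", nacl_mM, 2),
            Solute("KCl", 2.7, 2),
            Solute("Na2HPO4", 10.0, 3),
            Solute("KH2PO4", 1.8, 2),
        ),
    )


PBS_PRESETS = {
    "hypertonic": pbs(175, "hypertonic PBS"),
    "isotonic": pbs(137, "isotonic PBS"),
    "hypotonic": pbs(75, "hypotonic PBS"),
}
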