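"""Physicochemical annotations for the fluorescent labels under study.

The adhesion of labelled double-stranded DNA to the aluminum aperture
surface is driven by the dye, not the DNA: positively charged, moderately
hydrophobic rhodamine/carbopyronine labels (Atto 550, Atto 647N) promote
sticking while net-negative hydrophilic labels (Alexa Fluor 546/647) do
not.  Hydrophobicity is summarized by logD, the octanol/water distribution
coefficient (positive = hydrophobic).

Lifetimes are intensity-weighted averages in nanoseconds: the confocal
reference value, the value inside a well-passivated 110 nm aperture, and —
where adhesion occurs — the value inside an uncoated aperture where metal
quenching shortens the decay further.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DyeProperties", "DYE_PRESETS"]


@dataclass(frozen=True)
class DyeProperties:
    name: str
    net_charge_after_labelling: int  # sign of the net charge once conjugated
    logD: float
    lifetime_confocal_ns: float
    lifetime_zmw_ns: float          # passivated aperture (no adhesion artefact)
    lifetime_zmw_uncoated_ns: float | None = None  # differs only for sticky dyes

    def __post_init__(self) -> None:
        if self.lifetime_confocal_ns <= 0 or self.lifetime_zmw_ns <= 0:
            raise ValueError("lifetimes must be positive")

    @property
    def hydrophobic(self) -> bool:
        return self.logD > 0

    @property
    def sticky(self) -> bool:
        """Whether this label promotes surface adhesion on bare aluminum."""
        return self.net_charge_after_labelling > 0 and self.hydrophobic


DYE_PRESETS: dict[str, DyeProperties] = {
    "Alexa546": DyeProperties("Alexa546", -1, -1.43, 3.5, 1.78),
    "Alexa647": DyeProperties("Alexa647", -1, -4.26, 1.4, 0.68),
    "Atto550": DyeProperties("Atto550", +1, 6.41, 3.4, 1.39, 1.02),
    "Atto647N": DyeProperties("Atto647N", +1, 3.26, 4.0, 1.74, 1.41),
}
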