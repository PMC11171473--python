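"""Treatment-stage vocabulary of the staged fentanyl/naloxone protocol.

A measurement session on one aortic strip walks through eleven stages:
a post-adaptation control, a cumulative fentanyl series (10^-9 ... 10^-6 M),
a 30-min wash-out, a 10-min naloxone (10^-6 M) pre-treatment, and the
fentanyl series repeated in the continued presence of naloxone.  At every
stage the strip is loaded with four suspended ring masses in increasing
order, so one stage contributes four (pressure, f0, E') observations.
"""

from __future__ import annotations

import enum


class TreatmentStage(str, enum.Enum):
    """Ordered stage labels; the member order is the protocol order."""

    CONTROL = "control"
    FE_9 = "Fe-9"
    FE_8 = "Fe-8"
    FE_7 = "Fe-7"
    FE_6 = "Fe-6"
    WASHOUT30 = "washout30"
    NAL10 = "nal10"
    FE_9_NAL = "Fe-9+Nal"
    FE_8_NAL = "Fe-8+Nal"
    FE_7_NAL = "Fe-7+Nal"
    FE_6_NAL = "Fe-6+Nal"

    def __str__(self) -> str:  # stable labels in file outputs
        return self.value

    @property
    def slug(self) -> str:
        """Filesystem-safe form of the label (lower case, '+' -> '_')."""
        return self.value.lower().replace("+", "_")

    @classmethod
    def from_label(cls, label: str) -> "TreatmentStage":
        for member in cls:
            if member.value == label:
                return member
        raise ValueError(
            f"unknown treatment stage label {label!r}; known labels: "
            + ", ".join(m.value for m in cls)
        )


#: Protocol order as plain labels (convenient for configs and file outputs).
STAGE_LABELS: tuple[str, ...] = tuple(s.value for s in TreatmentStage)

#: Stages during which fentanyl alone is present (cumulative series).
FENTANYL_STAGES: tuple[str, ...] = ("Fe-9", "Fe-8", "Fe-7", "Fe-6")

#: Fentanyl series repeated under naloxone.
FENTANYL_NAL_STAGES: tuple[str, ...] = ("Fe-9+Nal", "Fe-8+Nal", "Fe-7+Nal", "Fe-6+Nal")

GROUPS: tuple[str, ...] = ("sham", "pin")
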