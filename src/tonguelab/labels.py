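"""Class labels for the three tongue colours and the two cascade stages."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

__all__ = ["TongueColor", "Stage1Label", "FinalLabel", "ABSTAIN"]


class TongueColor(str, Enum):
    """The three diagnostic tongue-body colours."""

    LIGHT_RED = "light_red"
    RED = "red"
    DEEP_RED = "deep_red"

    def __str__(self) -> str:  # manifest-friendly
        return self.value


class Stage1Label(str, Enum):
    """Coarse first-stage (SVM) outcome."""

    DEEP_RED = "deep_red"
    RED_OR_LIGHT_RED = "red_or_light_red"

    def __str__(self) -> str:
        return self.value


#: Sentinel returned by the chromatic-only ablation rule when neither or
#: both chromatic boxes match.
ABSTAIN = "abstain"


@dataclass(frozen=True)
class FinalLabel:
    """Final cascade decision with provenance.

    ``stage`` records which stage decided (1 = SVM, only for DEEP_RED;
    2 = colour-range rules, only for RED / LIGHT_RED) and ``rule_path``
    which branch fired (``"stage1"``, ``"red_box"``, ``"light_red_box"``,
    ``"fallback_low_L"``, ``"fallback_high_L"``).
    """

    value: TongueColor
    stage: int
    rule_path: str

    def __post_init__(self) -> None:
        if self.stage == 1 and self.value is not TongueColor.DEEP_RED:
            raise ValueError("stage 1 can only decide DEEP_RED")
        if self.stage == 2 and self.value is TongueColor.DEEP_RED:
            raise ValueError("stage 2 never decides DEEP_RED")
        if self.stage not in (1, 2):
            raise ValueError(f"stage must be 1 or 2, got {self.stage}")
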