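"""Second-stage rule classifier: red versus light red by Lab colour range.

Red and light-red tongues look alike to the naked eye; their chromatic
values overlap but their luminance separates them.  The rule set boxes
each class in (L*, a*, b*):

====== ========== ============== ==============
class  L*         a*             b*
====== ========== ============== ==============
red    L* < 56    32 <= a* <= 39  6 <= b* <= 10
light  L* >= 56   23 <= a* <= 27  15 <= b* <= 19
====== ========== ============== ==============

A colour matching all three red ranges is red; all three light-red
ranges, light red.  Anything outside both boxes (the chromatic gaps)
falls back to luminance alone: L* below the threshold (56, the only
luminance boundary the ranges define) is red, otherwise light red.
The rule is total — every finite Lab point gets exactly one label.

The colour classified is by convention the mean Lab colour of the
red/light-red (max-distance) identifier cluster, not the whole-tongue
mean; the pipeline exposes that choice.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .labels import ABSTAIN, FinalLabel, TongueColor

__all__ = [
    "ClassRange",
    "RangeRuleSet",
    "classify_range",
    "chromatic_only_classify",
    "range_statistics",
]


@dataclass(frozen=True)
class ClassRange:
    """One class's box: an L* bound plus inclusive a*/b* intervals."""

    a_min: float
    a_max: float
    b_min: float
    b_max: float

    def __post_init__(self) -> None:
        if self.a_min > self.a_max or self.b_min > self.b_max:
            raise ValueError("range bounds out of order")

    def chromatic_match(self, a: float, b: float) -> bool:
        return self.a_min <= a <= self.a_max and self.b_min <= b <= self.b_max


@dataclass(frozen=True)
class RangeRuleSet:
    """The red / light-red colour ranges plus the luminance fallback.

    ``L_split`` is shared: red requires L* strictly below it, light red
    L* at or above it, and the fallback reuses it, so the two full
    boxes are disjoint and the cascade order cannot matter for in-box
    points.
    """

    red: ClassRange = field(
        default_factory=lambda: ClassRange(a_min=32, a_max=39, b_min=6, b_max=10)
    )
    light_red: ClassRange = field(
        default_factory=lambda: ClassRange(a_min=23, a_max=27, b_min=15, b_max=19)
    )
    L_split: float = 56.0
    fallback_L_threshold: float = 56.0

    def to_dict(self) -> dict:
        return {
            "red": asdict(self.red),
            "light_red": asdict(self.light_red),
            "L_split": self.L_split,
            "fallback_L_threshold": self.fallback_L_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RangeRuleSet":
        return cls(
            red=ClassRange(**d["red"]),
            light_red=ClassRange(**d["light_red"]),
            L_split=float(d.get("L_split", 56.0)),
            fallback_L_threshold=float(d.get("fallback_L_threshold", 56.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RangeRuleSet":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def classify_range(color, rules: RangeRuleSet | None = None) -> FinalLabel:
    """Label a Lab colour red or light red.

    Full-range match first (red box, then light-red box — the boxes are
    disjoint in L*, so the order is immaterial for in-box points), then
    the luminance fallback for everything else.
    """
    rules = rules or RangeRuleSet()
    L, a, b = (float(v) for v in np.asarray(color, dtype=np.float64))

    if L < rules.L_split and rules.red.chromatic_match(a, b):
        return FinalLabel(TongueColor.RED, stage=2, rule_path="red_box")
    if L >= rules.L_split and rules.light_red.chromatic_match(a, b):
        return FinalLabel(TongueColor.LIGHT_RED, stage=2, rule_path="light_red_box")
    if L < rules.fallback_L_threshold:
        return FinalLabel(TongueColor.RED, stage=2, rule_path="fallback_low_L")
    return FinalLabel(TongueColor.LIGHT_RED, stage=2, rule_path="fallback_high_L")


def classify_range_batch(colors: np.ndarray, rules: RangeRuleSet | None = None):
    """Vectorised :func:`classify_range` over an ``(n, 3)`` colour array.

    Returns ``(labels, rule_paths)`` as object arrays of
    :class:`~tonguelab.labels.TongueColor` values and branch names.
    Same cascade, evaluated with array masks; agrees with the scalar
    rule point for point.
    """
    rules = rules or RangeRuleSet()
    c = np.asarray(colors, dtype=np.float64)
    L, a, b = c[:, 0], c[:, 1], c[:, 2]
    red_box = (
        (L < rules.L_split)
        & (rules.red.a_min <= a) & (a <= rules.red.a_max)
        & (rules.red.b_min <= b) & (b <= rules.red.b_max)
    )
    light_box = (
        (L >= rules.L_split)
        & (rules.light_red.a_min <= a) & (a <= rules.light_red.a_max)
        & (rules.light_red.b_min <= b) & (b <= rules.light_red.b_max)
    )
    fallback_red = ~red_box & ~light_box & (L < rules.fallback_L_threshold)
    fallback_light = ~red_box & ~light_box & ~fallback_red

    labels = np.empty(len(c), dtype=object)
    paths = np.empty(len(c), dtype=object)
    for mask, label, path in (
        (red_box, TongueColor.RED, "red_box"),
        (light_box, TongueColor.LIGHT_RED, "light_red_box"),
        (fallback_red, TongueColor.RED, "fallback_low_L"),
        (fallback_light, TongueColor.LIGHT_RED, "fallback_high_L"),
    ):
        labels[mask] = label
        paths[mask] = path
    return labels, paths


def chromatic_only_classify(color, rules: RangeRuleSet | None = None):
    """Ablation rule using a*/b* only (ignores luminance entirely).

    Returns :data:`~tonguelab.labels.ABSTAIN` when the chromatic point
    lies in neither box or in both (the defaults' boxes are disjoint,
    but a user-edited rule set may overlap).
    """
    rules = rules or RangeRuleSet()
    _, a, b = (float(v) for v in np.asarray(color, dtype=np.float64))
    in_red = rules.red.chromatic_match(a, b)
    in_light = rules.light_red.chromatic_match(a, b)
    if in_red and not in_light:
        return TongueColor.RED
    if in_light and not in_red:
        return TongueColor.LIGHT_RED
    return ABSTAIN


def range_statistics(colors: np.ndarray, labels) -> pd.DataFrame:
    """Per-class min/max/percentiles of cluster mean colours.

    A helper for practitioners re-deriving colour ranges from their own
    labelled corpora (the shipped defaults were derived once from a
    clinical corpus; this reports the raw statistics, it does not fit
    ranges automatically).
    """
    df = pd.DataFrame(np.asarray(colors, dtype=float), columns=["L", "a", "b"])
    df["label"] = [str(l) for l in labels]
    stats = df.groupby("label").agg(
        ["min", lambda s: s.quantile(0.05), "median", lambda s: s.quantile(0.95), "max"]
    )
    stats.columns = [
        f"{ch}_{name}"
        for ch, name in zip(
            [c[0] for c in stats.columns],
            ["min", "p05", "median", "p95", "max"] * 3,
        )
    ]
    return stats
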