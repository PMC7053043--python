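"""BI-RADS (4th edition) density categories and the dense/non-dense split.

The 4th-edition categories are quartile-like 25-point bands of percent
density. Bands are right-closed — (0,25] → A, (25,50] → B, (50,75] → C,
(75,100] → D, with 0 mapping to A — so that the dichotomy "dense ⇔
percent > 50" coincides exactly with C ∪ D.
"""

from __future__ import annotations

from dataclasses import dataclass

_BANDS = (("A", 25.0), ("B", 50.0), ("C", 75.0), ("D", 100.0))


@dataclass(frozen=True)
class BiradsCategory:
    label: str  # "A" | "B" | "C" | "D"
    dense_flag: bool

    def __post_init__(self) -> None:
        if self.label not in "ABCD" or len(self.label) != 1:
            raise ValueError(f"invalid BI-RADS label {self.label!r}")
        if self.dense_flag != (self.label in ("C", "D")):
            raise ValueError("dense_flag must equal (label in {C, D})")


def classify_birads(percent: float) -> BiradsCategory:
    """Map a percent density in [0, 100] to its BI-RADS 4th-edition band."""
    if not 0 <= percent <= 100:
        raise ValueError(f"percent density {percent} outside [0, 100]")
    for label, upper in _BANDS:
        if percent <= upper:
            return BiradsCategory(label=label, dense_flag=label in ("C", "D"))
    raise AssertionError("unreachable")


def classify_dense(percent: float) -> bool:
    """Dense breast ⇔ percent density strictly greater than 50."""
    if not 0 <= percent <= 100:
        raise ValueError(f"percent density {percent} outside [0, 100]")
    return percent > 50
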