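"""The named-feature container shared by all three extraction families."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class FeatureVector:
    """An ordered mapping of feature name → value with explicit undefined flags.

    Names follow ``FAMILY_Statistic[_dK][_aAAA]`` (e.g. ``GLCM_Correlation_d1_a090``,
    ``GLRLM_GLN_a000``, ``HIST_Percentile90``). A feature whose defining
    expression has a zero denominator or an empty support is stored as 0.0
    and listed in :attr:`undefined` — never as a silent NaN.
    """

    values: dict[str, float] = field(default_factory=dict)
    undefined: set[str] = field(default_factory=set)

    def add(self, name: str, value: float) -> None:
        if name in self.values:
            raise ValueError(f"duplicate feature name {name!r}")
        if value is None or (isinstance(value, float) and math.isnan(value)):
            self.values[name] = 0.0
            self.undefined.add(name)
        elif not math.isfinite(value):
            self.values[name] = 0.0
            self.undefined.add(name)
        else:
            self.values[name] = float(value)

    def add_undefined(self, name: str) -> None:
        self.add(name, float("nan"))

    def extend(self, other: "FeatureVector", suffix: str = "") -> None:
        for name, value in other.values.items():
            new = name + suffix
            if new in self.values:
                raise ValueError(f"duplicate feature name {new!r}")
            if name in other.undefined:
                self.values[new] = 0.0
                self.undefined.add(new)
            else:
                self.values[new] = value

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __len__(self) -> int:
        return len(self.values)

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def as_row(self) -> dict[str, float]:
        """Values with undefined entries rendered as NaN (for tabulation)."""
        return {
            name: (float("nan") if name in self.undefined else value)
            for name, value in self.values.items()
        }
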