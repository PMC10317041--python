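"""Per-region signal time courses."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RegionTimeCourse"]


@dataclass(frozen=True)
class RegionTimeCourse:
    """Mean signal of one region of interest versus reconstruction frame.

    ``corrected`` flags partial-volume-corrected values; ``normalized``
    flags division by the region's own baseline mean (relative units).
    """

    region: str
    values: np.ndarray
    frame_times_s: np.ndarray
    corrected: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        times = np.asarray(self.frame_times_s, dtype=float)
        if values.shape != times.shape or values.ndim != 1:
            raise ValueError("values and frame times must be matching 1D arrays")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "frame_times_s", times)

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, **flags) -> "RegionTimeCourse":
        return replace(self, values=np.asarray(values, dtype=float), **flags)
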