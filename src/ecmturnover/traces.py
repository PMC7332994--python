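"""Per-embryo fluorescence time series and their processing stages.

A trace moves through a fixed sequence of stages: ``raw`` (F_Raw, as
extracted from whole-embryo images), ``background`` (F_NoFP, a
no-fluorophore control), ``subtracted`` (F = F_Raw - mean F_NoFP, the
quantity all fitting operates on) and ``normalized`` (F_n or I_n,
unit-free display quantities).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

STAGES = ("raw", "background", "subtracted", "normalized")


@dataclass
class FluorescenceTrace:
    """A time-stamped intensity series for one embryo and one channel.

    Parameters
    ----------
    embryo_id : str
        Label identifying the embryo.
    time_h : array-like
        Sample times in hours from embryonic stage 15; strictly increasing.
    intensity : array-like
        Fluorescence intensity (arbitrary units), same length as ``time_h``.
    stage : str
        One of ``raw``, ``background``, ``subtracted``, ``normalized``.
    channel : str
        Imaging channel label (e.g. ``gfp``, ``mscarlet``, ``meos_red``).
    metadata : dict
        Free-form genotype / condition annotations.
    """

    embryo_id: str
    time_h: np.ndarray
    intensity: np.ndarray
    stage: str = "raw"
    channel: str = "gfp"
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_h.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("time_h and intensity must be 1-D")
        if len(self.time_h) != len(self.intensity):
            raise ValueError(
                f"time_h (n={len(self.time_h)}) and intensity "
                f"(n={len(self.intensity)}) differ in length"
            )
        if len(self.time_h) > 1 and not np.all(np.diff(self.time_h) > 0):
            raise ValueError("time_h must be strictly increasing")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    def __len__(self) -> int:
        return len(self.time_h)

    def with_values(self, intensity: np.ndarray, stage: str | None = None) -> "FluorescenceTrace":
        """Copy of this trace with new intensity values (and optionally a new stage)."""
        return replace(
            self,
            intensity=np.asarray(intensity, dtype=float),
            stage=self.stage if stage is None else stage,
            metadata=dict(self.metadata),
        )
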