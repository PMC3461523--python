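"""Result containers shared by the listener and coupling analyses."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["EffectEstimate", "EffectCurve"]


@dataclass
class EffectEstimate:
    """A proportion-of-variance effect with permutation inference attached.

    ``r2`` is the raw proportion of explained (or shared generalized)
    variance; ``delta_r2`` is the bias-corrected version (observed minus the
    mean of its group-exchange permutation distribution).  P-values are
    exact permutation p-values; ``p_corrected`` is max-statistic corrected
    across whatever family the estimate belongs to (lags, bins, channels,
    ROI pairs), and equals ``p_uncorrected`` for a family of one.
    """

    r2: float
    delta_r2: float | None = None
    p_uncorrected: float | None = None
    p_corrected: float | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")
        if self.delta_r2 is not None and self.delta_r2 > self.r2 + 1e-12:
            raise ValueError("delta_r2 cannot exceed r2")
        for p in (self.p_uncorrected, self.p_corrected):
            if p is not None and not 0.0 < p <= 1.0:
                raise ValueError("p-values must lie in (0, 1]")


@dataclass
class EffectCurve:
    """An effect size indexed by time lag (or any ordered family).

    ``lags_s`` is strictly increasing; ``peak_lag`` attains the maximal
    bias-corrected effect.
    """

    lags_s: np.ndarray
    r2: np.ndarray
    delta_r2: np.ndarray | None = None
    p_uncorrected: np.ndarray | None = None
    p_corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        if np.any(np.diff(self.lags_s) <= 0):
            raise ValueError("lag grid must be strictly increasing")
        if self.r2.shape != self.lags_s.shape:
            raise ValueError("r2 must match the lag grid shape")

    @property
    def peak_lag(self) -> float:
        values = self.delta_r2 if self.delta_r2 is not None else self.r2
        return float(self.lags_s[int(np.argmax(values))])

    @property
    def peak_value(self) -> float:
        values = self.delta_r2 if self.delta_r2 is not None else self.r2
        return float(np.max(values))

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"lags_s": self.lags_s.tolist(),
                               "r2": self.r2.tolist()}
        for name in ("delta_r2", "p_uncorrected", "p_corrected"):
            val = getattr(self, name)
            out[name] = None if val is None else np.asarray(val).tolist()
        out["peak_lag_s"] = self.peak_lag
        out["peak_delta_r2"] = self.peak_value
        return out
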