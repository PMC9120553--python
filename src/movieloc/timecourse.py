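"""Timecourse: the universal analysis currency.

A :class:`Timecourse` is a length-T vector of BOLD signal sampled once per TR.
Missing entries (NaN) mark artifact timepoints excluded from analysis; every
downstream statistic in this package is missing-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Timecourse", "masked_mean"]


def masked_mean(stack: np.ndarray) -> np.ndarray:
    """Column mean ignoring NaNs; columns with no data stay NaN (quietly)."""
    stack = np.atleast_2d(np.asarray(stack, dtype=float))
    valid = np.isfinite(stack)
    count = valid.sum(axis=0)
    total = np.where(valid, stack, 0.0).sum(axis=0)
    return np.where(count > 0, total / np.maximum(count, 1), np.nan)


@dataclass
class Timecourse:
    """A per-TR signal vector with allowed missing entries.

    Parameters
    ----------
    values : ndarray, shape (T,)
        Signal values; NaN marks a missing (artifact) TR.
    tr_s : float
        Sampling interval in seconds.
    z_scored : bool
        True if the non-missing entries have been standardized to mean 0,
        SD 1 (sample SD, ``ddof=1``).
    """

    values: np.ndarray
    tr_s: float = 2.0
    z_scored: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Timecourse values must be one-dimensional")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.z_scored:
            v = self.values[np.isfinite(self.values)]
            if v.size >= 2:
                if abs(v.mean()) > 1e-8 or abs(v.std(ddof=1) - 1) > 1e-8:
                    raise ValueError("z_scored flag set but values are not standardized")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_trs(self) -> int:
        return self.values.size

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask of missing TRs."""
        return ~np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.values).sum())

    def with_values(self, values: np.ndarray, z_scored: bool | None = None) -> "Timecourse":
        """Copy carrying tr_s/name, replacing the data."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            z_scored=self.z_scored if z_scored is None else z_scored,
        )
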