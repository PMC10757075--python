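"""Empirical distribution summaries of per-node features.

Centrality scores on these networks live on small discrete supports, so the
"PDF" here is the empirical probability mass function over the distinct
observed values and the CDF is its running sum — no binning or smoothing is
applied.  For integer-valued measures whose support is tiny (the H-index
takes only a handful of values on a reaction network) an exact frequency
histogram is the more readable summary and is provided separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["DistributionSummary", "empirical_distribution", "frequency_histogram"]


@dataclass(frozen=True)
class DistributionSummary:
    """Empirical PMF/CDF of a feature over ``n`` observations.

    ``support`` is sorted and distinct; ``pdf[i]`` is the fraction of
    observations equal to ``support[i]`` and ``cdf[i]`` the fraction less
    than or equal to it, so ``cdf`` is nondecreasing with final value 1.
    """

    support: np.ndarray
    pdf: np.ndarray
    cdf: np.ndarray
    n: int

    def cdf_at(self, x: float) -> float:
        """F(x): fraction of observations <= x."""
        idx = np.searchsorted(self.support, x, side="right")
        return 0.0 if idx == 0 else float(self.cdf[idx - 1])

    def tail_count(self, x: float) -> int:
        """Number of observations strictly greater than x."""
        return round(self.n * (1.0 - self.cdf_at(x)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": self.support, "pdf": self.pdf, "cdf": self.cdf}
        )


def empirical_distribution(values: Iterable[float]) -> DistributionSummary:
    """Empirical PMF and CDF of a nonempty collection of numbers."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty collection")
    support, counts = np.unique(arr, return_counts=True)
    pdf = counts / arr.size
    return DistributionSummary(
        support=support, pdf=pdf, cdf=np.cumsum(pdf), n=int(arr.size)
    )


def frequency_histogram(values: Iterable[float]) -> pd.DataFrame:
    """Exact counts per distinct integer value, sorted by value.

    Rejects non-integral inputs: a frequency histogram of a continuous
    feature is a presentation mistake, not a summary.
    """
    arr = np.asarray(list(values))
    if arr.size and not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValueError("frequency_histogram requires integer-valued input")
    support, counts = np.unique(arr.astype(np.int64), return_counts=True)
    return pd.DataFrame({"value": support, "count": counts})
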