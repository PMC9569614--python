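"""Phenotype statistics and extreme-bulk selection.

The study design tests approximate normality of the F2 height distribution
with a moment criterion (|skewness| < 1 and |excess kurtosis| < 1, both in
the SPSS small-sample-corrected convention) and then pools the k shortest
and k tallest plants into two extreme bulks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PhenotypeSummary", "summarize_phenotypes", "select_bulks"]


@dataclass
class PhenotypeSummary:
    n: int
    mean: float
    sd: float
    skewness: float
    kurtosis: float  # excess kurtosis (normal = 0)
    normal_flag: bool


def summarize_phenotypes(heights) -> PhenotypeSummary:
    """Moment summary of the height distribution.

    Skewness is the adjusted Fisher-Pearson sample coefficient
    (g1 * sqrt(n(n-1)) / (n-2)) and kurtosis the bias-corrected excess
    kurtosis; these match the SPSS/SAS descriptive-statistics output.  The
    normality flag applies the |skew| < 1 and |kurtosis| < 1 criterion.
    """
    x = np.asarray(heights, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample with n >= 3")
    if not np.isfinite(x).all():
        raise ValueError("heights must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: moments undefined")
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return PhenotypeSummary(
        n=x.size,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)),
        skewness=skew,
        kurtosis=kurt,
        normal_flag=bool(abs(skew) < 1 and abs(kurt) < 1),
    )


def select_bulks(heights, ids, k: int) -> tuple[list, list]:
    """Pick the k smallest (low bulk) and k largest (high bulk) phenotypes.

    Ties at a bulk boundary are broken by ascending id, so the lower id
    enters the bulk; selection is deterministic and the two sets are
    disjoint.  Returns ``(low_ids, high_ids)``.
    """
    x = np.asarray(heights, dtype=float)
    ids = list(ids)
    if len(ids) != x.size:
        raise ValueError("heights and ids must align")
    if k < 1 or 2 * k > x.size:
        raise ValueError("need 1 <= k and 2k <= n")
    by_low = sorted(range(x.size), key=lambda i: (x[i], ids[i]))
    by_high = sorted(range(x.size), key=lambda i: (-x[i], ids[i]))
    low = [ids[i] for i in by_low[:k]]
    high = [ids[i] for i in by_high[:k]]
    if set(low) & set(high):
        raise ValueError("bulks overlap: ties span more than the sample allows")
    return low, high
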