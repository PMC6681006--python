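"""Upper-quartile normalization to CPM and the mean-CPM expression filter.

The scale factor for a sample is the 75th percentile of its counts, taken
over the genes that are nonzero in at least one sample, divided by the
sample's library size. Factors are centered to geometric mean 1, the
effective library size is library size x centered factor, and CPM is
count / effective library size x 1e6. Percentiles use linear interpolation
between order statistics (numpy's default), so an independent oracle can
match bit-for-bit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .data import CountMatrix, NormalizedExpression

log = logging.getLogger(__name__)

__all__ = ["upper_quartile_normalize", "filter_by_cpm"]


def upper_quartile_scale_factors(counts: pd.DataFrame) -> pd.Series:
    """Centered upper-quartile scale factors, one per sample (geometric mean 1)."""
    lib_sizes = counts.sum(axis=0)
    if (lib_sizes == 0).any():
        bad = list(lib_sizes.index[lib_sizes == 0])
        raise ValueError(f"all-zero samples cannot be normalized: {bad}")
    expressed = counts.loc[(counts > 0).any(axis=1)]
    if expressed.empty:
        raise ValueError("no gene is nonzero in any sample")
    uq = expressed.quantile(0.75, axis=0, interpolation="linear")
    factors = uq / lib_sizes
    factors = factors / gmean(factors)
    return factors


def upper_quartile_normalize(
    cm: CountMatrix, pseudocount: float = 1.0
) -> NormalizedExpression:
    """Normalize integer counts to upper-quartile CPM and log2(CPM + pseudocount).

    Parameters
    ----------
    cm : CountMatrix
        Gene-by-sample counts with metadata.
    pseudocount : float
        Added inside the log2 only; CPM itself is unshifted.
    """
    counts = cm.counts
    factors = upper_quartile_scale_factors(counts)
    effective = counts.sum(axis=0) * factors
    cpm = counts / effective * 1e6
    log2cpm = np.log2(cpm + pseudocount)
    return NormalizedExpression(
        cpm=cpm, log2cpm=log2cpm, scale_factors=factors, meta=cm.meta
    )


def filter_by_cpm(
    ne: NormalizedExpression, threshold: float = 1.0
) -> NormalizedExpression:
    """Keep genes whose mean CPM over all samples is strictly above ``threshold``.

    Both lines are pooled for the mean: the expression criterion is applied
    once per region, not once per line. Gene order is preserved.
    """
    if threshold < 0:
        raise ValueError("CPM threshold must be >= 0")
    keep = ne.cpm.mean(axis=1) > threshold
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("CPM filter (> %g): dropped %d genes, kept %d",
                 threshold, n_dropped, int(keep.sum()))
    return NormalizedExpression(
        cpm=ne.cpm.loc[keep],
        log2cpm=ne.log2cpm.loc[keep],
        scale_factors=ne.scale_factors,
        meta=ne.meta,
    )
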