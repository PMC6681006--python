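"""Network connectivity: leaf culling, per-line connectivity profiles,
hub calls, and line-versus-line connectivity comparisons.

Connectivity k of a gene is the off-diagonal row sum of the weighted
adjacency; intramodular k restricts partners to the gene's module; relative
connectivity rescales intramodular k by the module-wise maximum so every
module spans [0, 1] with its most connected gene at 1. Hubs are the top
decile of intramodular connectivity within their module.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import GREY

log = logging.getLogger(__name__)

__all__ = [
    "cull_network",
    "connectivity_profile",
    "identify_hubs",
    "differential_connectivity",
    "compare_mean_connectivity",
]


def cull_network(k_total: pd.Series, keep_fraction: float = 0.90) -> list[str]:
    """Drop leaf nodes: keep the most-connected genes carrying
    ``keep_fraction`` of total connectivity.

    Genes are sorted by connectivity (descending, stable in input order for
    ties) and the shortest prefix whose summed connectivity reaches
    ``keep_fraction`` of the total is retained.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if (k_total < 0).any():
        raise ValueError("connectivity must be >= 0")
    ordered = k_total.sort_values(ascending=False, kind="stable")
    total = float(ordered.sum())
    if total == 0:
        return list(k_total.index)
    cum = ordered.cumsum()
    n_keep = int(np.searchsorted(cum.to_numpy(), keep_fraction * total) + 1)
    n_keep = min(n_keep, len(ordered))
    return list(ordered.index[:n_keep])


def connectivity_profile(
    adjacency: pd.DataFrame, modules: pd.Series, line: str
) -> pd.DataFrame:
    """Per-gene total, intramodular, and relative connectivity for one line.

    Returns a DataFrame indexed by gene with columns line, module, k_total,
    k_within, k_rel, hub (hub filled by :func:`identify_hubs`). Genes in a
    single-gene module get k_rel 0 with a warning.
    """
    genes = adjacency.index
    missing = [g for g in genes if g not in modules.index]
    if missing:
        raise ValueError(f"modules missing for genes: {missing[:5]}")
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k_total = a.sum(axis=1)
    mod = modules.loc[genes].to_numpy()
    k_within = np.zeros(len(genes))
    for m in pd.unique(mod):
        idx = np.flatnonzero(mod == m)
        k_within[idx] = a[np.ix_(idx, idx)].sum(axis=1)
        if idx.size == 1:
            log.warning("module %r has a single gene; k_rel set to 0", m)
    df = pd.DataFrame(
        {"line": line, "module": mod, "k_total": k_total, "k_within": k_within},
        index=genes,
    )
    max_within = df.groupby("module")["k_within"].transform("max")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["k_rel"] = np.where(max_within > 0, df["k_within"] / max_within, 0.0)
    df["hub"] = False
    return df


def identify_hubs(ct: pd.DataFrame, hub_quantile: float = 0.90) -> pd.DataFrame:
    """Flag hubs: genes at or above the ``hub_quantile`` of intramodular
    connectivity within their module (grey genes never qualify)."""
    ct = ct.copy()
    ct["hub"] = False
    for m, sub in ct.groupby("module"):
        if m == GREY or len(sub) == 0:
            continue
        cutoff = sub["k_within"].quantile(hub_quantile)
        ct.loc[sub.index[sub["k_within"] >= cutoff], "hub"] = True
    return ct


def differential_connectivity(
    ct_high: pd.DataFrame,
    ct_low: pd.DataFrame,
    delta_threshold: float = 0.5,
) -> pd.DataFrame:
    """Genes whose relative connectivity differs between lines by at least
    ``delta_threshold`` (on the [0, 1] relative scale).

    Returns per flagged gene both k_rel values, the absolute difference,
    the direction (which line is higher), and whether the gene is a hub in
    the higher line.
    """
    common = ct_high.index.intersection(ct_low.index)
    skipped = len(ct_high.index.symmetric_difference(ct_low.index))
    if skipped:
        log.info("differential connectivity: %d genes present in only one line",
                 skipped)
    h = ct_high.loc[common]
    l = ct_low.loc[common]
    delta = (l["k_rel"] - h["k_rel"]).abs()
    flagged = delta >= delta_threshold
    higher_is_low = l["k_rel"] > h["k_rel"]
    out = pd.DataFrame(
        {
            "k_rel_high": h["k_rel"],
            "k_rel_low": l["k_rel"],
            "delta": delta,
            "direction": np.where(higher_is_low, "LOW>HIGH", "HIGH>LOW"),
            "hub_in_higher_line": np.where(higher_is_low, l["hub"], h["hub"]),
        },
        index=common,
    )
    return out[flagged].sort_values("delta", ascending=False)


def compare_mean_connectivity(
    ct_high: pd.DataFrame,
    ct_low: pd.DataFrame,
    scope: str = "total",
    gene_subset=None,
) -> tuple[float, float, float]:
    """Compare mean connectivity between the lines over a gene set.

    ``scope`` selects total ("total") or intramodular ("modular")
    connectivity. Returns (mean_high, mean_low, p) with p from a paired
    two-sided Wilcoxon signed-rank test across genes; p is NaN (with a
    warning) when fewer than 10 genes are compared.
    """
    col = {"total": "k_total", "modular": "k_within"}.get(scope)
    if col is None:
        raise ValueError("scope must be 'total' or 'modular'")
    common = ct_high.index.intersection(ct_low.index)
    if gene_subset is not None:
        common = common.intersection(pd.Index(gene_subset))
    h = ct_high.loc[common, col].to_numpy()
    l = ct_low.loc[common, col].to_numpy()
    mean_high, mean_low = float(h.mean()), float(l.mean())
    if len(common) < 10:
        log.warning("only %d genes in the comparison; p-value not reported",
                    len(common))
        return mean_high, mean_low, float("nan")
    if np.allclose(h, l):
        return mean_high, mean_low, 1.0
    p = float(stats.wilcoxon(h, l, alternative="two-sided").pvalue)
    return mean_high, mean_low, p
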