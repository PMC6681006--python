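"""Weighted coexpression networks: per-line Pearson correlation, soft
thresholding, topological overlap, cross-line consensus, and module
detection.

The construction follows the weighted-network lineage standard in
transcriptomics: unsigned adjacency ``a_ij = |r_ij|^beta`` with the soft
power chosen by the scale-free topology criterion; similarity for
clustering is the topological overlap matrix (TOM); the cross-line
consensus is the component-wise minimum of quantile-scaled per-line TOMs;
modules come from average-linkage hierarchical clustering of TOM
dissimilarity with an adaptive cut height steered toward a target module
count. The reserved label ``grey`` marks unassigned genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .data import NormalizedExpression

log = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "ScaleFreeFit",
    "correlation_matrix",
    "adjacency_matrix",
    "tom_matrix",
    "scale_free_fit",
    "pick_soft_power",
    "consensus_network",
    "detect_modules",
    "build_network",
    "MODULE_COLORS",
    "GREY",
]

GREY = "grey"

# color-coded module labels; the names carry no meaning within or across
# networks
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]

DEFAULT_BETAS = tuple(range(2, 21, 2))


@dataclass
class ScaleFreeFit:
    """Goodness of a power-law fit to the connectivity distribution."""

    r_squared: float
    slope: float
    passes: bool
    degenerate: bool = False


@dataclass
class GeneNetwork:
    """Per-line similarity/adjacency matrices with a consensus and modules."""

    gene_ids: list[str]
    corr_by_line: dict[str, pd.DataFrame]
    adjacency_by_line: dict[str, pd.DataFrame]
    consensus: pd.DataFrame
    beta: float
    modules: pd.Series  # gene -> color label; "grey" = unassigned
    fit_by_line: dict[str, ScaleFreeFit] = field(default_factory=dict)
    scale_free_ok: bool = True


def correlation_matrix(
    expr: NormalizedExpression | pd.DataFrame, line: str | None = None
) -> pd.DataFrame:
    """Gene-by-gene Pearson correlation over one line's samples.

    Zero-variance genes are excluded with a logged warning. Requires at
    least 3 samples.
    """
    if isinstance(expr, NormalizedExpression):
        if line is None:
            raise ValueError("a line must be named for NormalizedExpression input")
        x = expr.log2cpm[expr.samples_of(line)]
    else:
        x = expr
    if x.shape[1] < 3:
        raise ValueError(f"need >= 3 samples to correlate, got {x.shape[1]}")
    var = x.var(axis=1, ddof=1)
    keep = var > 0
    if not keep.all():
        dropped = list(x.index[~keep])
        log.warning("excluding %d zero-variance genes: %s%s",
                    len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
        x = x.loc[keep]
    r = np.corrcoef(x.to_numpy())
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=x.index, columns=x.index)


def adjacency_matrix(corr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |r|^beta (unit diagonal)."""
    return np.abs(corr) ** beta


def tom_matrix(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbor similarity on a weighted graph.

    ``T_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu a_uj`` over u != i, j and ``k_i = sum_{j != i} a_ij``;
    the diagonal is 1.
    """
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (l + a) / denom
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=adjacency.index, columns=adjacency.columns)


def _connectivity(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency, dtype=float)
    return a.sum(axis=1) - np.diag(a)


def scale_free_fit(
    adjacency, n_bins: int = 10, fit_threshold: float = 0.8
) -> ScaleFreeFit:
    """Fit log10 P(k) ~ log10 k over binned connectivity.

    Accepts a square adjacency matrix (connectivity = off-diagonal row sums)
    or a 1-D connectivity/degree sequence. Connectivity is discretized into
    ``n_bins`` equal-width bins; the regression of log10 bin frequency on
    log10 mean connectivity per bin gives the fit (empty bins dropped).
    Passing requires r^2 at or above ``fit_threshold`` with a negative
    slope; a connectivity sequence without enough distinct values is
    degenerate and fails with r^2 = 0.
    """
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    arr = np.asarray(adjacency, dtype=float)
    k = _connectivity(arr) if arr.ndim == 2 else arr
    if np.unique(k).size < 3:
        return ScaleFreeFit(0.0, 0.0, passes=False, degenerate=True)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        return ScaleFreeFit(0.0, 0.0, passes=False, degenerate=True)
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = np.polyval([slope, intercept], xs)
    ss_res = float(((np.array(ys) - fitted) ** 2).sum())
    ss_tot = float(((np.array(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return ScaleFreeFit(
        r_squared=r2,
        slope=float(slope),
        passes=bool(r2 >= fit_threshold and slope < 0),
    )


def pick_soft_power(
    corr: pd.DataFrame,
    candidate_betas=DEFAULT_BETAS,
    fit_threshold: float = 0.8,
) -> tuple[float, dict[float, ScaleFreeFit], bool]:
    """Choose the smallest soft power whose scale-free fit passes.

    Returns ``(beta, fits, passed)``; when no candidate passes, the beta
    with the best r^2 is returned with ``passed=False`` and a warning.
    """
    if len(candidate_betas) == 0 or min(candidate_betas) < 1:
        raise ValueError("candidate betas must be non-empty and all >= 1")
    fits: dict[float, ScaleFreeFit] = {}
    for beta in sorted(candidate_betas):
        fits[beta] = scale_free_fit(
            adjacency_matrix(corr, beta), fit_threshold=fit_threshold
        )
        if fits[beta].passes:
            return beta, fits, True
    best = max(fits, key=lambda b: fits[b].r_squared)
    log.warning(
        "no candidate soft power reached scale-free r^2 >= %.2f; "
        "falling back to beta = %s (r^2 = %.3f)",
        fit_threshold, best, fits[best].r_squared,
    )
    return best, fits, False


def _quantile_scale(vectors: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Quantile-normalize each vector to the mean of the sorted vectors."""
    ref = np.mean([np.sort(v) for v in vectors.values()], axis=0)
    out = {}
    for key, v in vectors.items():
        scaled = np.empty_like(v)
        scaled[np.argsort(v, kind="stable")] = ref
        out[key] = scaled
    return out


def consensus_network(adjacency_by_line: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Component-wise minimum of quantile-scaled per-line TOMs.

    Per-line topological overlap matrices are computed from the adjacency
    matrices, their strict-upper-triangle distributions are quantile-scaled
    to a common reference (the mean of the sorted distributions), and the
    consensus entry is the minimum across lines.
    """
    lines = list(adjacency_by_line)
    genes = adjacency_by_line[lines[0]].index
    for line in lines[1:]:
        if not genes.equals(adjacency_by_line[line].index):
            raise ValueError("gene sets differ between lines")
    toms = {line: tom_matrix(adjacency_by_line[line]).to_numpy()
            for line in lines}
    iu = np.triu_indices(len(genes), k=1)
    scaled = _quantile_scale({line: toms[line][iu] for line in lines})
    cons_flat = np.min([scaled[line] for line in lines], axis=0)
    cons = np.ones((len(genes), len(genes)))
    cons[iu] = cons_flat
    cons[(iu[1], iu[0])] = cons_flat
    return pd.DataFrame(cons, index=genes, columns=genes)


def detect_modules(
    consensus: pd.DataFrame,
    min_module_size: int = 30,
    target_module_count: int = 25,
    n_heights: int = 60,
    cohesion_ratio: float = 1.5,
    rescue_quantile: float = 0.05,
) -> pd.Series:
    """Partition genes into modules by clustering TOM dissimilarity.

    A simplified dynamic tree cut: average-linkage hierarchical clustering
    on ``1 - consensus`` is cut at an adaptively chosen height — candidate
    heights spanning the dendrogram are scanned and the cut whose number of
    qualifying modules is closest to ``target_module_count`` wins (ties
    prefer the cut assigning more genes, then the coarser cut). A cluster
    qualifies as a module when it has at least ``min_module_size`` genes
    AND its mean intra-cluster similarity exceeds ``cohesion_ratio`` times
    the global off-diagonal mean (this keeps structureless data from
    collapsing into one giant pseudo-module: such clusters are no denser
    than background and are rejected, leaving the genes grey).

    A final rescue stage (the analog of the PAM stage of dynamic hybrid
    cutting) re-assigns each grey gene to its most similar module when its
    mean similarity to that module reaches the ``rescue_quantile`` of the
    members' own intra-module similarity. Labels are arbitrary colors
    ordered by module size; ``grey`` marks unassigned genes.
    """
    genes = consensus.index
    n = len(genes)
    if n <= min_module_size:
        log.warning("only %d genes (< min module size %d); single module",
                    n, min_module_size)
        return pd.Series([MODULE_COLORS[0]] * n, index=genes)
    C = consensus.to_numpy()
    off_mean = float((C.sum() - np.trace(C)) / (n * (n - 1)))
    d = 1.0 - C
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    merge_h = z[:, 2]
    heights = np.linspace(merge_h.min(), merge_h.max(), n_heights + 2)[1:-1]

    def qualifying(labels: np.ndarray) -> dict[int, np.ndarray]:
        out = {}
        for cid, size in pd.Series(labels).value_counts().items():
            if size < min_module_size:
                continue
            idx = np.flatnonzero(labels == cid)
            sub = C[np.ix_(idx, idx)]
            intra = (sub.sum() - idx.size) / (idx.size * (idx.size - 1))
            if intra >= cohesion_ratio * off_mean:
                out[cid] = idx
        return out

    best = None
    for h in heights:
        labels = fcluster(z, t=h, criterion="distance")
        mods = qualifying(labels)
        if not mods:
            continue
        assigned = int(sum(idx.size for idx in mods.values()))
        score = (abs(len(mods) - target_module_count), -assigned, -h)
        if best is None or score < best[0]:
            best = (score, labels, mods)
    if best is None:
        log.warning("no cut produced a qualifying module (size >= %d, "
                    "cohesion >= %.1fx background); all genes grey",
                    min_module_size, cohesion_ratio)
        return pd.Series([GREY] * n, index=genes)
    _, labels, mods = best

    ordered = sorted(mods, key=lambda cid: -mods[cid].size)
    color_of = {
        cid: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
        for i, cid in enumerate(ordered)
    }
    out = np.array([color_of.get(cid, GREY) for cid in labels], dtype=object)

    # rescue stage: pull near-module grey genes back in
    floors, members = {}, {}
    for cid in ordered:
        idx = mods[cid]
        member_sim = (C[np.ix_(idx, idx)].sum(axis=1) - 1.0) / (idx.size - 1)
        floors[color_of[cid]] = float(np.quantile(member_sim, rescue_quantile))
        members[color_of[cid]] = idx
    grey_idx = np.flatnonzero(out == GREY)
    for i in grey_idx:
        sims = {m: float(C[i, idx].mean()) for m, idx in members.items()}
        best_m = max(sims, key=sims.get)
        if sims[best_m] >= floors[best_m]:
            out[i] = best_m

    result = pd.Series(out, index=genes)
    log.info("detected %d modules (target %d); %d/%d genes assigned",
             len(ordered), target_module_count,
             int((result != GREY).sum()), n)
    return result


def build_network(
    corr_by_line: dict[str, pd.DataFrame],
    beta: float | None = 6.0,
    candidate_betas=DEFAULT_BETAS,
    fit_threshold: float = 0.8,
    min_module_size: int = 30,
    target_module_count: int = 25,
) -> GeneNetwork:
    """Assemble the full consensus network from per-line correlation matrices.

    The default soft power of 6 is the standard operating point for
    unsigned weighted networks; with ``beta=None`` the power is instead
    chosen by the scale-free criterion on the first line's correlation
    matrix and shared across lines (a consensus network needs one power). Per-line soft-threshold adjacencies get scale-free fits
    for reporting; the network-level gate ``scale_free_ok`` is the fit on
    the consensus connectivity distribution — when it fails, the caller is
    expected to keep the modules but skip hub/connectivity analyses for
    this network.
    """
    lines = list(corr_by_line)
    common = corr_by_line[lines[0]].index
    for line in lines[1:]:
        if not common.equals(corr_by_line[line].index):
            shared = common.intersection(corr_by_line[line].index)
        else:
            shared = common
        common = shared
    corr_by_line = {ln: corr_by_line[ln].loc[common, common] for ln in lines}

    if beta is None:
        beta, _, _ = pick_soft_power(
            corr_by_line[lines[0]], candidate_betas, fit_threshold
        )
    adj = {ln: adjacency_matrix(corr_by_line[ln], beta) for ln in lines}
    fits = {ln: scale_free_fit(adj[ln], fit_threshold=fit_threshold)
            for ln in lines}
    cons = consensus_network(adj)
    fits["consensus"] = scale_free_fit(cons, fit_threshold=fit_threshold)
    ok = fits["consensus"].passes
    if not ok:
        log.warning(
            "consensus connectivity does not follow a power law "
            "(r^2 = %.3f); hub/connectivity analyses should be skipped "
            "for this network", fits["consensus"].r_squared,
        )
    modules = detect_modules(cons, min_module_size, target_module_count)
    return GeneNetwork(
        gene_ids=list(common),
        corr_by_line=corr_by_line,
        adjacency_by_line=adj,
        consensus=cons,
        beta=float(beta),
        modules=modules,
        fit_by_line=fits,
        scale_free_ok=ok,
    )
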