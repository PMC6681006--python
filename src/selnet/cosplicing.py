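"""Cosplicing networks from exon-usage profiles.

A gene's splicing state in a sample is its vector of exon-count
proportions (each exon weighted equally). Per gene, samples are compared
by a distance on these vectors (Euclidean by default); per gene pair, the
Mantel correlation — the Pearson correlation of the vectorized strict
upper triangles of the two sample-by-sample distance matrices — plays the
role Pearson correlation plays for coexpression. The resulting gene-gene
Mantel matrix feeds the same soft-threshold / TOM / consensus / module
machinery as coexpression; a network whose connectivity distribution fails
the power-law fit is downgraded to modules-only (no hub or connectivity
analysis), mirroring how a region that fails the fit is handled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .coexpression import DEFAULT_BETAS, GeneNetwork, build_network
from .data import ExonCountTable

log = logging.getLogger(__name__)

__all__ = [
    "ExonUsageProfile",
    "GeneDistanceMatrix",
    "exon_proportions",
    "gene_sample_distance",
    "mantel_correlation",
    "mantel_matrix",
    "cosplicing_network",
]

METRICS = ("euclidean", "manhattan", "canberra")


@dataclass
class ExonUsageProfile:
    """Per-sample exon-proportion vectors for one gene.

    ``proportions`` is exon-by-sample with columns summing to 1; samples
    whose total gene count fell below the floor are flagged in ``mask``
    (True = usable) and carry a uniform placeholder vector.
    """

    gene_id: str
    proportions: pd.DataFrame
    mask: pd.Series

    @property
    def n_exons(self) -> int:
        return self.proportions.shape[0]

    def usable_samples(self) -> list[str]:
        return list(self.mask.index[self.mask])


@dataclass
class GeneDistanceMatrix:
    """Symmetric sample-by-sample splicing distance for one gene."""

    gene_id: str
    D: pd.DataFrame


def exon_proportions(
    ect: ExonCountTable, min_gene_count: int = 10
) -> dict[str, ExonUsageProfile]:
    """Exon-usage proportion profiles for every multi-exon gene.

    Per sample, proportion = exon count / total gene count. Samples with
    total below ``min_gene_count`` are masked and given the uniform vector.
    Single-exon genes are excluded (no usage structure to correlate).
    """
    profiles: dict[str, ExonUsageProfile] = {}
    samples = ect.sample_ids
    n_single = 0
    for gene, sub in ect.table.groupby("gene_id", sort=False):
        counts = sub.set_index("exon_id")[samples].to_numpy(dtype=float)
        if counts.shape[0] < 2:
            n_single += 1
            continue
        totals = counts.sum(axis=0)
        mask = totals >= min_gene_count
        props = np.full_like(counts, 1.0 / counts.shape[0])
        if mask.any():
            props[:, mask] = counts[:, mask] / totals[mask]
        profiles[gene] = ExonUsageProfile(
            gene_id=gene,
            proportions=pd.DataFrame(
                props, index=sub["exon_id"].to_list(), columns=samples
            ),
            mask=pd.Series(mask, index=samples),
        )
    if n_single:
        log.info("excluded %d single-exon genes from cosplicing", n_single)
    return profiles


def gene_sample_distance(
    profile: ExonUsageProfile,
    metric: str = "euclidean",
    samples: list[str] | None = None,
) -> GeneDistanceMatrix:
    """Sample-by-sample distance between exon-proportion vectors.

    Masked samples are excluded. Requires at least 3 usable samples.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    use = [s for s in (samples or list(profile.mask.index))
           if profile.mask[s]]
    if len(use) < 3:
        raise ValueError(
            f"gene {profile.gene_id}: only {len(use)} usable samples (< 3)"
        )
    x = profile.proportions[use].to_numpy().T  # samples x exons
    cityblock = "cityblock" if metric == "manhattan" else metric
    D = squareform(pdist(x, metric=cityblock))
    return GeneDistanceMatrix(
        gene_id=profile.gene_id, D=pd.DataFrame(D, index=use, columns=use)
    )


def mantel_correlation(Da: GeneDistanceMatrix, Db: GeneDistanceMatrix) -> float:
    """Pearson correlation of the strict upper triangles of two distance matrices.

    Returns NaN when either matrix is constant off-diagonal (the statistic
    is undefined there and the gene pair should be excluded).
    """
    if list(Da.D.index) != list(Db.D.index):
        common = [s for s in Da.D.index if s in set(Db.D.index)]
        if len(common) < 3:
            return float("nan")
        a = Da.D.loc[common, common].to_numpy()
        b = Db.D.loc[common, common].to_numpy()
    else:
        a, b = Da.D.to_numpy(), Db.D.to_numpy()
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu], b[iu]
    if va.std() == 0 or vb.std() == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


def _condensed_distances(
    profiles: dict[str, ExonUsageProfile],
    samples: list[str],
    metric: str = "euclidean",
) -> tuple[list[str], np.ndarray]:
    """Stack per-gene condensed distance vectors over a fixed sample list.

    Genes with any masked sample among ``samples`` are dropped (keeps the
    pair set identical across genes so the Mantel matrix is one corrcoef).
    """
    cityblock = "cityblock" if metric == "manhattan" else metric
    genes, rows = [], []
    n_masked = 0
    for gene, prof in profiles.items():
        if prof.n_exons < 2:
            continue
        if not prof.mask[samples].all():
            n_masked += 1
            continue
        x = prof.proportions[samples].to_numpy().T
        rows.append(pdist(x, metric=cityblock))
        genes.append(gene)
    if n_masked:
        log.info("dropped %d genes with masked samples from the Mantel matrix",
                 n_masked)
    return genes, np.array(rows)


def mantel_matrix(
    profiles: dict[str, ExonUsageProfile],
    samples: list[str],
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Gene-by-gene Mantel correlation matrix over one line's samples.

    Genes whose distance vector is constant (no splicing variation) are
    excluded — their Mantel correlation is undefined.
    """
    genes, rows = _condensed_distances(profiles, samples, metric)
    if len(genes) < 2:
        raise ValueError("need >= 2 eligible genes for a cosplicing network")
    sd = rows.std(axis=1)
    keep = sd > 0
    if not keep.all():
        log.info("excluded %d genes with constant splicing distances",
                 int((~keep).sum()))
    genes = [g for g, k in zip(genes, keep) if k]
    m = np.corrcoef(rows[keep])
    m = np.clip(m, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return pd.DataFrame(m, index=genes, columns=genes)


def cosplicing_network(
    profiles: dict[str, ExonUsageProfile],
    meta: pd.DataFrame,
    metric: str = "euclidean",
    beta: float | None = None,
    candidate_betas=DEFAULT_BETAS,
    fit_threshold: float = 0.8,
    min_module_size: int = 30,
    target_module_count: int = 25,
) -> GeneNetwork:
    """Build the consensus cosplicing network across the two lines.

    Per line, distances use that line's samples only. The returned network's
    ``scale_free_ok`` flag is False when a line's adjacency fails the
    power-law fit; callers then keep the modules but skip hub/connectivity
    analyses for this network.
    """
    lines = sorted(meta["line"].unique())
    corr_by_line = {}
    for line in lines:
        samples = list(meta.index[meta["line"] == line])
        corr_by_line[line] = mantel_matrix(profiles, samples, metric)
    return build_network(
        corr_by_line,
        beta=beta,
        candidate_betas=candidate_betas,
        fit_threshold=fit_threshold,
        min_module_size=min_module_size,
        target_module_count=target_module_count,
    )
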