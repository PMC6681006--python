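"""Synthetic two-line RNA-Seq datasets with planted network structure.

Three generators cover the test surface of the pipeline:

* :func:`simulate_count_dataset` — negative-binomial gene counts for two
  selected lines (HIGH / LOW drinkers) with per-module latent factors that
  induce block-correlation, planted differential expression, and planted
  differential wiring (factor loadings attenuated or flipped in one line).
* :func:`simulate_exon_dataset` — multinomial exon counts per gene, with
  line-specific exon-usage vectors for the planted differential-splicing
  genes.
* :func:`simulate_breeding` — a bidirectionally applicable mass-selection
  simulator following the breeder's equation R = h^2 * S, used to validate
  realized-heritability estimation.

Correlation is induced on the log2 scale: gene g in module m has
log-expression ``base_g + lambda * f_m(sample) + eps``, with
``lambda^2 = within_module_corr`` so the latent-scale correlation between
two module genes equals ``within_module_corr`` (counting noise attenuates
the realized correlation slightly). Differential wiring scales the loading
of a planted gene in the HIGH line to ``1 - dw_delta_r / within_module_corr``
(negative values flip the sign), which moves its latent correlation with
every module partner by ``dw_delta_r`` while the per-gene variance is held
at 1 by re-inflating the idiosyncratic noise.

Every generator is driven by a :class:`numpy.random.SeedSequence` spawned
from one seed, with stage-local substreams, so a fixed seed yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountMatrix, ExonCountTable
from .phenotype import SelectionRecords

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_count_dataset",
    "simulate_exon_dataset",
    "simulate_breeding",
]


@dataclass
class SimulationConfig:
    """Parameters of the planted-structure simulators.

    Defaults mirror the study design this package targets: 24 samples per
    selected line per brain region, five correlated modules of 200 genes, a
    planted two-fold-per-line expression difference, edge rewiring of 0.5
    on the unsigned correlation scale (the wiring threshold itself), and an
    exon-usage shift of 0.3 (mean absolute proportion difference per exon).
    Rewiring larger than ``within_module_corr`` is rejected: an unsigned
    edge cannot lose more weight than it has.
    """

    n_genes: int = 1000
    n_modules: int = 5
    module_sizes: list[int] | None = None  # default: equal split of n_genes
    n_samples_per_line: int = 24
    within_module_corr: float = 0.6
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    dw_gene_fraction: float = 0.05
    dw_delta_r: float = 0.5  # matches the pipeline's edge-change threshold
    ds_gene_fraction: float = 0.1
    ds_delta_prop: float = 0.3
    exons_per_gene: tuple[int, int] = (2, 8)
    nb_dispersion: float = 0.05
    library_size_mean: int = 1_000_000
    library_size_sigma: float = 0.2
    base_log2_mean: float = 4.0
    base_log2_sd: float = 1.5
    # True: fixed-design simulation — factor traces standardized and
    # residuals orthogonalized so planted correlations are exact.
    # False: random-design — factor/noise realizations sampled freely, which
    # yields a broader, more data-like connectivity distribution at the cost
    # of O(1/sqrt(n)) scatter around the planted correlations.
    calibrate_correlations: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = [self.n_genes // self.n_modules] * self.n_modules
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} "
                f"> n_genes = {self.n_genes}"
            )
        for name in ("within_module_corr", "de_fraction", "dw_gene_fraction",
                     "dw_delta_r", "ds_gene_fraction", "ds_delta_prop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.exons_per_gene
        if lo < 2 or hi < lo:
            raise ValueError("exons_per_gene must be a range with min >= 2")


@dataclass
class GroundTruth:
    """Planted structure of one simulated dataset."""

    module_labels: pd.Series  # gene_id -> module id (0 = background)
    de_genes: set[str] = field(default_factory=set)
    dw_genes: set[str] = field(default_factory=set)
    ds_genes: set[str] = field(default_factory=set)
    de_log2fc: pd.Series | None = None  # signed planted fold change
    true_h2: float | None = None

    def write(self, path) -> None:
        df = pd.DataFrame(
            {
                "module": self.module_labels,
                "de": [g in self.de_genes for g in self.module_labels.index],
                "dw": [g in self.dw_genes for g in self.module_labels.index],
                "ds": [g in self.ds_genes for g in self.module_labels.index],
            }
        )
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def _meta(config: SimulationConfig) -> pd.DataFrame:
    n = config.n_samples_per_line
    samples = [f"H{i + 1:02d}" for i in range(n)] + [f"L{i + 1:02d}" for i in range(n)]
    return pd.DataFrame(
        {"line": ["HIGH"] * n + ["LOW"] * n, "region": ["SIM"] * 2 * n},
        index=pd.Index(samples, name="sample_id"),
    )


def _module_labels(config: SimulationConfig) -> np.ndarray:
    labels = np.zeros(config.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[start:start + size] = m
        start += size
    return labels


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    # NB with mean mu, variance mu + phi*mu^2
    n = 1.0 / phi
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_count_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate gene-level counts for both lines with planted DE/DW structure.

    Returns the count matrix (genes x 2*n_samples_per_line) and the ground
    truth describing module membership and the planted gene sets.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_params, rng_factors, rng_noise, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    G, n = config.n_genes, config.n_samples_per_line
    genes = [f"gene{g + 1:04d}" for g in range(G)]
    labels = _module_labels(config)
    c = config.within_module_corr
    lam = np.sqrt(c)

    base = rng_params.normal(config.base_log2_mean, config.base_log2_sd, size=G)
    # signed loadings: part of each module correlates negatively with the
    # factor, with signs chosen so the abundance-weighted loading sum is
    # near zero per module. The module signal then cancels out of the
    # library total and survives CPM normalization (the unsigned network
    # uses |r| anyway).
    signs = np.ones(G)
    weights = 2.0**base
    for m in range(1, config.n_modules + 1):
        members = np.flatnonzero(labels == m)
        pos = neg = 0.0
        for g in members[np.argsort(-weights[members])]:
            if pos <= neg:
                pos += weights[g]
            else:
                signs[g] = -1.0
                neg += weights[g]

    # planted DE: evenly spread over all genes, alternating direction
    n_de = int(round(config.de_fraction * G))
    de_idx = rng_params.choice(G, size=n_de, replace=False)
    de_sign = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    shift = np.zeros(G)
    shift[de_idx] = de_sign * config.de_log2fc / 2.0  # +/- half per line

    # planted DW: module genes only, loading rescaled in the HIGH line
    modular = np.flatnonzero(labels > 0)
    n_dw = int(round(config.dw_gene_fraction * G))
    n_dw = min(n_dw, modular.size)
    dw_idx = rng_params.choice(modular, size=n_dw, replace=False)
    # flip and attenuate the loading so the unsigned edge weight |r| with
    # every module partner moves by dw_delta_r in the HIGH line (requires
    # dw_delta_r <= within_module_corr to be realizable on the [0, 1] scale)
    if n_dw and config.dw_delta_r > 0:
        if config.dw_delta_r > c:
            raise ValueError(
                f"dw_delta_r = {config.dw_delta_r} exceeds within_module_corr "
                f"= {c}; an unsigned edge change that large is not realizable"
            )
        alpha = -(1.0 - config.dw_delta_r / c)
    else:
        alpha = 1.0

    # calibrate loadings so the requested correlation is realized on the
    # observed log2 CPM scale: the predictable count-noise variance v_g
    # (dispersion + shot noise at the gene's expected depth) attenuates
    # correlations, so the latent variance budget t_g is inflated to
    # compensate and the residual sd absorbs the remainder per line
    weights = 2.0**base
    mu_expect = config.library_size_mean * weights / weights.sum()
    v_count = (config.nb_dispersion + 1.0 / np.maximum(mu_expect, 1e-9)) \
        / np.log(2.0) ** 2
    t_budget = 1.0 + v_count / max(1.0 - c, 0.05)
    lam_gene = np.sqrt(c * t_budget)

    loading = {"HIGH": signs * lam_gene, "LOW": signs * lam_gene}
    loading["HIGH"][dw_idx] *= alpha
    loading["HIGH"][labels == 0] = 0.0
    loading["LOW"][labels == 0] = 0.0

    expr = np.empty((G, 2 * n))
    for j, line in enumerate(("HIGH", "LOW")):
        factors = rng_factors.normal(size=(config.n_modules + 1, n))
        if config.calibrate_correlations:
            # standardize each factor trace within line so the planted
            # module correlation is realized exactly, not just in
            # expectation (removes module-wide dips from the factor's
            # sampled variance)
            factors = (factors - factors.mean(axis=1, keepdims=True)) \
                / factors.std(axis=1, keepdims=True)
        fac = factors[labels]  # per-gene factor trace (row 0 unused for bg)
        lam_line = loading[line]
        resid_sd = np.sqrt(
            np.clip(t_budget - v_count - lam_line**2, 0.0, None)
        )
        eps = rng_noise.normal(size=(G, n))
        if config.calibrate_correlations:
            # residuals drawn orthogonal to the gene's own factor trace and
            # re-standardized: each gene's planted factor correlation is
            # exact by construction rather than up to O(1/sqrt(n)) alignment
            coef = (eps * fac).sum(axis=1) / n
            eps = eps - coef[:, None] * fac
            eps = (eps - eps.mean(axis=1, keepdims=True)) \
                / eps.std(axis=1, keepdims=True)
        eps = eps * resid_sd[:, None]
        line_shift = shift if line == "HIGH" else -shift
        expr[:, j * n:(j + 1) * n] = (
            base[:, None] + line_shift[:, None] + lam_line[:, None] * fac + eps
        )

    rel = 2.0 ** expr
    rel_norm = (2.0 ** base).sum()
    lib = rng_counts.lognormal(
        np.log(config.library_size_mean), config.library_size_sigma, size=2 * n
    )
    mu = rel / rel_norm * lib[None, :]
    counts = _nb_draw(rng_counts, mu, config.nb_dispersion)

    meta = _meta(config)
    cm = CountMatrix(
        pd.DataFrame(counts, index=genes, columns=meta.index), meta
    )
    gt = GroundTruth(
        module_labels=pd.Series(labels, index=genes),
        de_genes={genes[i] for i in de_idx},
        dw_genes={genes[i] for i in dw_idx},
        de_log2fc=pd.Series(2.0 * shift, index=genes),
    )
    return cm, gt


def _ds_profile_pair(
    E: int, delta: float, rng: np.random.Generator, max_tries: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Two exon-proportion vectors with mean per-exon |difference| = delta.

    The L1 distance between two probability vectors is at most 2, so the
    target ``delta * E`` must not exceed 2 (fewer exons allow larger
    per-exon shifts). Baselines are drawn skewed (uneven exon usage) and
    shifted by blending toward the reversal of the sorted profile — the
    permutation with maximal displacement.
    """
    target = delta * E
    if target > 1.9:
        raise ValueError(
            f"ds_delta_prop = {delta} infeasible for a {E}-exon gene "
            f"(needs L1 distance {target:.2f} > 2)"
        )
    for _ in range(max_tries):
        p = rng.dirichlet(np.full(E, 0.8))
        order = np.argsort(p)
        q = p.copy()
        q[order] = np.sort(p)[::-1]  # most-used exon swaps with least-used
        span = np.abs(q - p).sum()
        if span >= target > 0:
            w = target / span
            return p, (1 - w) * p + w * q
        if target == 0:
            return p, p.copy()
    raise ValueError(
        f"ds_delta_prop = {delta} infeasible for a {E}-exon gene "
        f"(no drawn profile allowed an L1 shift of {target:.2f})"
    )


def simulate_exon_dataset(
    config: SimulationConfig,
) -> tuple[ExonCountTable, GroundTruth]:
    """Simulate exon-level counts with line-specific usage for planted DS genes.

    Per gene, each sample's exon counts are a multinomial draw from that
    line's exon-proportion vector, with the gene's total count drawn
    negative-binomially. Planted DS genes have line-mean proportion vectors
    whose mean absolute per-exon difference equals ``ds_delta_prop``; all
    other genes share one vector across lines.
    """
    ss = np.random.SeedSequence(config.seed).spawn(5)[4].spawn(3)
    rng_params, rng_totals, rng_exons = (np.random.default_rng(s) for s in ss)
    G, n = config.n_genes, config.n_samples_per_line
    genes = [f"gene{g + 1:04d}" for g in range(G)]
    lo, hi = config.exons_per_gene
    n_exons = rng_params.integers(lo, hi + 1, size=G)
    labels = _module_labels(config)
    c = config.within_module_corr

    # the mean per-exon shift delta needs L1 distance delta * E <= 2, so DS
    # genes are planted only where the shift is feasible
    n_ds = int(round(config.ds_gene_fraction * G))
    if config.ds_delta_prop > 0 and n_ds:
        eligible = np.flatnonzero(n_exons * config.ds_delta_prop <= 1.6)
        if eligible.size < n_ds:
            raise ValueError(
                f"ds_delta_prop = {config.ds_delta_prop} infeasible: only "
                f"{eligible.size} genes have few enough exons for {n_ds} "
                "DS genes"
            )
        ds_idx = set(rng_params.choice(eligible, size=n_ds, replace=False).tolist())
    else:
        ds_idx = set(rng_params.choice(G, size=n_ds, replace=False).tolist())

    # splicing-rewired genes: exon usage follows the module's shared trace
    # in the LOW line but a private trace in the HIGH line
    modular = np.flatnonzero(labels > 0)
    n_dw = min(int(round(config.dw_gene_fraction * G)), modular.size)
    dw_idx = set(rng_params.choice(modular, size=n_dw, replace=False).tolist())

    meta = _meta(config)
    total_mean = rng_params.lognormal(np.log(500.0), 0.5, size=G)

    # per-line module splicing traces (standardized), driving the blend
    # between each gene's two usage profiles
    def _std(x: np.ndarray) -> np.ndarray:
        return (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, keepdims=True)

    traces = {
        line: _std(rng_params.normal(size=(config.n_modules + 1, n)))
        for line in ("HIGH", "LOW")
    }

    rows = []
    row_genes = []
    row_exons = []
    share = np.sqrt(c)
    for g in range(G):
        E = int(n_exons[g])
        if g in ds_idx:
            # target: (1/E) * sum_e |pH - pL| = ds_delta_prop
            p_low, p_high = _ds_profile_pair(E, config.ds_delta_prop, rng_params)
        else:
            p_low = rng_params.dirichlet(np.full(E, 0.8))
            p_high = p_low
        # the gene's alternative usage profile: reversal-of-sorted blend
        totals = _nb_draw(
            rng_totals, np.full(2 * n, total_mean[g]), config.nb_dispersion
        )
        # alternative-usage direction (toward the reversal of the sorted
        # profile), shared across lines so the planted line-mean difference
        # is untouched by the splicing-state mixing
        order = np.argsort(p_low)
        rev = p_low.copy()
        rev[order] = np.sort(p_low)[::-1]
        delta_alt = rev - p_low  # sums to 0
        # for DS genes, scale the amplitude so proportions stay positive for
        # every splicing state (|xc| < 0.55): the planted line-mean
        # difference is then exact (no clipping bias). Non-DS genes share
        # one profile across lines, so any clipping bias cancels between
        # lines and the full amplitude is kept.
        nz = delta_alt != 0
        if g in ds_idx and nz.any():
            amp = min(
                float(np.min(p_low[nz] / (0.55 * np.abs(delta_alt[nz])))),
                float(np.min(p_high[nz] / (0.55 * np.abs(delta_alt[nz])))),
            )
            delta_alt = delta_alt * min(1.0, amp)

        block = np.empty((E, 2 * n), dtype=np.int64)
        for j, line in enumerate(("HIGH", "LOW")):
            p = p_high if line == "HIGH" else p_low
            shared = share if labels[g] > 0 else 0.0
            if g in dw_idx and line == "HIGH":
                shared = 0.0
            t = (shared * traces[line][labels[g]]
                 + np.sqrt(1.0 - shared**2) * _std(rng_exons.normal(size=n)))
            x = 1.0 / (1.0 + np.exp(-2.0 * t))  # splicing state in (0, 1)
            xc = x - x.mean()  # centered: line-mean profile stays = p
            pi = p[:, None] + xc[None, :] * delta_alt[:, None]
            pi = np.clip(pi, 1e-6, None)
            pi = pi / pi.sum(axis=0, keepdims=True)
            cols = slice(j * n, (j + 1) * n)
            block[:, cols] = rng_exons.multinomial(
                totals[cols], pi.T
            ).T
        rows.append(block)
        row_genes.extend([genes[g]] * E)
        row_exons.extend([f"exon{e + 1}" for e in range(E)])

    table = pd.DataFrame(np.vstack(rows), columns=meta.index)
    table.insert(0, "exon_id", row_exons)
    table.insert(0, "gene_id", row_genes)
    ect = ExonCountTable(table, meta)
    gt = GroundTruth(
        module_labels=pd.Series(labels, index=genes),
        ds_genes={genes[i] for i in sorted(ds_idx)},
        dw_genes={genes[i] for i in sorted(dw_idx)},
    )
    return ect, gt


def simulate_breeding(
    true_h2: float,
    n_generations: int = 4,
    founder_n: int = 120,
    selected_fraction: float = 26 / 120,
    phenotype_sd: float = 2.0,
    founder_mean: float = 3.0,
    direction: int = 1,
    sampling_noise: bool = True,
    seed: int = 0,
) -> SelectionRecords:
    """Simulate mass selection and return per-generation phenotype records.

    The phenotype is additive-genetic plus environmental,
    ``P = mu + g + e`` with ``var(g) = h2 * sd^2`` and
    ``var(e) = (1 - h2) * sd^2``. Each generation the top (or bottom, for
    ``direction = -1``) ``selected_fraction`` of phenotypes is selected;
    offspring genetic values are drawn about the selected parents' mean
    genetic value with the base genetic variance (a variance-replenishing
    infinitesimal model), so the expected response per generation is exactly
    ``h2 * S``. With ``sampling_noise=False`` offspring means are set to
    their expectations, giving a noise-free response.

    Defaults follow a mass-selection design with a founding population of
    120 and 26 selected per line, phenotyped through four offspring
    generations.
    """
    if not 0.0 <= true_h2 <= 1.0:
        raise ValueError("true_h2 must be in [0, 1]")
    if not 0.0 < selected_fraction < 1.0:
        raise ValueError("selected_fraction must be in (0, 1)")
    n_sel = int(round(selected_fraction * founder_n))
    if n_sel < 2:
        raise ValueError(
            f"founder_n = {founder_n} too small to select "
            f"{selected_fraction:.0%} (needs >= 2 parents)"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sd_g = phenotype_sd * np.sqrt(true_h2)
    sd_e = phenotype_sd * np.sqrt(1.0 - true_h2)

    g = rng.normal(0.0, sd_g, size=founder_n) if sd_g > 0 else np.zeros(founder_n)
    e = rng.normal(0.0, sd_e, size=founder_n) if sd_e > 0 else np.zeros(founder_n)
    pheno = founder_mean + g + e

    recs = []
    for t in range(1, n_generations + 1):
        order = np.argsort(direction * pheno)[::-1]
        sel = order[:n_sel]
        pop_mean = float(pheno.mean())
        sel_mean = float(pheno[sel].mean())
        g_mid = float(g[sel].mean())
        if sampling_noise:
            g = g_mid + (rng.normal(0.0, sd_g, size=founder_n) if sd_g > 0
                         else np.zeros(founder_n))
            e = rng.normal(0.0, sd_e, size=founder_n) if sd_e > 0 else np.zeros(founder_n)
        else:
            # noise-free mode: deterministic quantile spread keeps genetic
            # variance alive so R = h2 * S holds exactly every generation
            from scipy.stats import norm

            spread = norm.ppf((np.arange(founder_n) + 0.5) / founder_n)
            spread = (spread - spread.mean()) / spread.std()
            g = g_mid + sd_g * spread
            e = np.zeros(founder_n)
        pheno = founder_mean + g + e
        recs.append((t, pop_mean, sel_mean, float(pheno.mean())))

    df = pd.DataFrame(
        recs,
        columns=["generation", "population_mean", "selected_parent_mean",
                 "offspring_mean"],
    )
    return SelectionRecords(df, founder_mean=float(df["population_mean"].iloc[0]))
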