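"""scikit-learn-compatible estimator surfaces for the transformer- and
clusterer-shaped pipeline stages.

These wrap the module-level functions so the stages compose with sklearn
pipelines and model selection. Following sklearn convention, X is
samples-by-features (samples x genes) — note this is the transpose of the
genes-by-samples orientation the TSV formats use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .coexpression import DEFAULT_BETAS, consensus_network, detect_modules
from .coexpression import adjacency_matrix, pick_soft_power

__all__ = ["UpperQuartileNormalizer", "ConsensusModuleDetector"]


class UpperQuartileNormalizer(BaseEstimator, TransformerMixin):
    """Upper-quartile CPM transformer.

    fit computes per-sample scale factors (75th percentile of counts over
    genes nonzero somewhere, centered to geometric mean 1); transform
    returns log2(CPM + pseudocount). Because the factors are per sample,
    fit and transform must see the same X (use fit_transform).

    Attributes
    ----------
    scale_factors_ : ndarray of shape (n_samples,)
    effective_library_sizes_ : ndarray of shape (n_samples,)
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = check_array(X, dtype="numeric")
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        lib = X.sum(axis=1)
        if (lib == 0).any():
            raise ValueError("all-zero samples cannot be normalized")
        expressed = X[:, X.sum(axis=0) > 0]
        if expressed.shape[1] == 0:
            raise ValueError("no gene is nonzero in any sample")
        uq = np.quantile(expressed, 0.75, axis=1)
        f = uq / lib
        f = f / np.exp(np.mean(np.log(f)))
        self.scale_factors_ = f
        self.effective_library_sizes_ = lib * f
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_factors_")
        X = check_array(X, dtype="numeric")
        cpm = X / self.effective_library_sizes_[:, None] * 1e6
        return np.log2(cpm + self.pseudocount)


class ConsensusModuleDetector(BaseEstimator, ClusterMixin):
    """Consensus coexpression module detection as an sklearn clusterer.

    fit(X, y) clusters the *genes* (columns of X, samples x genes) using
    per-line Pearson correlation, soft-threshold adjacency, quantile-scaled
    TOM consensus, and average-linkage clustering with an adaptive cut.
    ``y`` carries the per-sample line labels; with y=None all samples form
    one line and the consensus reduces to that line's TOM.

    Attributes
    ----------
    labels_ : ndarray of shape (n_genes,), color labels ("grey" = unassigned)
    beta_ : float, the soft power used
    consensus_ : DataFrame, the consensus TOM
    """

    def __init__(
        self,
        beta: float | None = None,
        candidate_betas=DEFAULT_BETAS,
        fit_threshold: float = 0.8,
        min_module_size: int = 30,
        target_module_count: int = 25,
    ):
        self.beta = beta
        self.candidate_betas = candidate_betas
        self.fit_threshold = fit_threshold
        self.min_module_size = min_module_size
        self.target_module_count = target_module_count

    def fit(self, X, y=None):
        X = check_array(X, dtype="numeric")
        if X.shape[0] < 3:
            raise ValueError("need >= 3 samples")
        genes = pd.Index([f"g{i}" for i in range(X.shape[1])])
        lines = pd.Series(["ALL"] * X.shape[0]) if y is None else pd.Series(y)
        corr_by_line = {}
        for line in lines.unique():
            sub = X[(lines == line).to_numpy()]
            r = np.clip(np.corrcoef(sub.T), -1.0, 1.0)
            np.fill_diagonal(r, 1.0)
            corr_by_line[line] = pd.DataFrame(r, index=genes, columns=genes)
        first = corr_by_line[lines.unique()[0]]
        beta = self.beta
        if beta is None:
            beta, _, _ = pick_soft_power(
                first, self.candidate_betas, self.fit_threshold
            )
        adj = {ln: adjacency_matrix(c, beta) for ln, c in corr_by_line.items()}
        self.consensus_ = consensus_network(adj)
        modules = detect_modules(
            self.consensus_, self.min_module_size, self.target_module_count
        )
        self.beta_ = float(beta)
        self.labels_ = modules.to_numpy()
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_
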