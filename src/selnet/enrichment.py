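"""Module-level gene-set enrichment and protection calls.

Each module is crossed with a flagged gene set (differentially
expressed/wired/spliced genes, or a cell-type marker set) in a 2x2 table
over the network's gene universe; one-tailed Fisher/hypergeometric
p-values are computed in both directions and Bonferroni-corrected by the
number of modules. A module significantly depleted of flagged genes is
called "protected" (from the effects of selection); one significantly
over-represented is "enriched".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentResult",
    "fisher_enrichment",
    "bonferroni_correct",
    "module_selection_impact",
]


@dataclass
class EnrichmentResult:
    """One module x one gene set 2x2 Fisher test.

    Table cells: a = flagged in module, b = unflagged in module,
    c = flagged outside, d = unflagged outside.
    """

    module: str
    set_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_enriched: float
    p_depleted: float
    continuity_corrected: bool = False


def fisher_enrichment(
    module_genes, flagged_genes, universe, module: str = "", set_name: str = ""
) -> EnrichmentResult:
    """Exact one-tailed enrichment and depletion tests for one module.

    Both gene sets are intersected with the universe. ``p_enriched`` is the
    upper hypergeometric tail P(X >= a), ``p_depleted`` the lower tail
    P(X <= a). The odds ratio gets a 0.5 continuity correction only when a
    zero cell would make it undefined (flagged in the result).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    mod = set(module_genes) & universe
    if not mod:
        raise ValueError(f"module {module!r} is empty within the universe")
    flagged = set(flagged_genes) & universe
    N = len(universe)
    K = len(flagged)
    n = len(mod)
    a = len(mod & flagged)
    b = n - a
    c = K - a
    d = N - n - c
    p_enr = float(hypergeom.sf(a - 1, N, K, n))
    p_dep = float(hypergeom.cdf(a, N, K, n))
    if b * c == 0 or a * d == 0:
        # zero cell: apply a 0.5 continuity correction, flagged
        orat = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        cc = True
    else:
        orat = (a * d) / (b * c)
        cc = False
    return EnrichmentResult(
        module=module, set_name=set_name, a=a, b=b, c=c, d=d,
        odds_ratio=float(orat), p_enriched=p_enr, p_depleted=p_dep,
        continuity_corrected=cc,
    )


def bonferroni_correct(p: float, n_modules: int) -> float:
    """Bonferroni correction over modules: min(1, p * n_modules)."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    return min(1.0, p * n_modules)


def module_selection_impact(
    modules: pd.Series,
    flagged_genes,
    universe=None,
    alpha: float = 0.01,
    set_name: str = "flagged",
    include_grey: bool = False,
) -> pd.DataFrame:
    """Per-module enriched/protected/neutral calls for a flagged gene set.

    ``modules`` maps gene -> module label; the universe defaults to all
    genes carrying a module label (the culled network). Both-direction
    Fisher tests are Bonferroni-corrected by the number of modules tested;
    a module is "enriched" when the corrected upper-tail p falls below
    ``alpha``, "protected" when the corrected lower-tail p does.
    """
    if universe is None:
        universe = set(modules.index)
    else:
        universe = set(universe)
    names = [m for m in modules.loc[list(universe & set(modules.index))].unique()
             if include_grey or m != "grey"]
    n_mod = len(names)
    rows = []
    for m in sorted(names):
        genes_m = set(modules.index[modules == m]) & universe
        res = fisher_enrichment(genes_m, flagged_genes, universe,
                                module=m, set_name=set_name)
        p_enr_c = bonferroni_correct(res.p_enriched, n_mod)
        p_dep_c = bonferroni_correct(res.p_depleted, n_mod)
        if p_enr_c < alpha:
            call = "enriched"
        elif p_dep_c < alpha:
            call = "protected"
        else:
            call = "neutral"
        rows.append(
            {
                "module": m, "set_name": set_name,
                "n_module": res.a + res.b, "n_flagged_in_module": res.a,
                "odds_ratio": res.odds_ratio,
                "p_enriched": res.p_enriched, "p_depleted": res.p_depleted,
                "p_enriched_corrected": p_enr_c,
                "p_depleted_corrected": p_dep_c,
                "call": call,
            }
        )
    columns = ["module", "set_name", "n_module", "n_flagged_in_module",
               "odds_ratio", "p_enriched", "p_depleted",
               "p_enriched_corrected", "p_depleted_corrected", "call"]
    return pd.DataFrame(rows, columns=columns).set_index("module")
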