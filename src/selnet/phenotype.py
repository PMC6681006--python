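"""Selection-phenotype arithmetic.

Drug-intake dose (mg/kg), two-bottle preference ratio, realized
heritability from the regression of cumulative selection response on
cumulative selection differential, and relative qPCR expression by the
2^-ddCt method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "DrinkingRecord",
    "SelectionRecords",
    "ma_intake_mg_per_kg",
    "preference_ratio",
    "realized_heritability",
    "ddct_relative_expression",
]


@dataclass
class DrinkingRecord:
    """One animal-day of two-bottle choice drinking.

    Volumes in mL, drug concentration in mg/L, body weight in kg.
    """

    ma_volume: float
    water_volume: float
    ma_concentration: float
    body_weight: float

    def __post_init__(self) -> None:
        if self.ma_volume < 0 or self.water_volume < 0:
            raise ValueError("volumes must be >= 0")
        if self.body_weight <= 0:
            raise ValueError("body weight must be > 0")


@dataclass
class SelectionRecords:
    """Per-generation phenotype means of a selective-breeding study.

    ``table`` has columns generation, population_mean, selected_parent_mean,
    offspring_mean (all in phenotype units, e.g. mg/kg); ``founder_mean`` is
    the unselected founding population's mean, the baseline against which
    response is measured.
    """

    table: pd.DataFrame
    founder_mean: float

    def __post_init__(self) -> None:
        required = {"generation", "population_mean", "selected_parent_mean",
                    "offspring_mean"}
        if not required <= set(self.table.columns):
            raise ValueError(f"records need columns {sorted(required)}")
        self.table = self.table.sort_values("generation").reset_index(drop=True)

    @classmethod
    def read(cls, path) -> "SelectionRecords":
        df = pd.read_csv(path, sep="\t", comment="#")
        rec = cls(df, founder_mean=float(df["population_mean"].iloc[0]))
        return rec

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def ma_intake_mg_per_kg(rec: DrinkingRecord) -> float:
    """Drug consumed per unit body weight: conc (mg/L) x volume (L) / weight (kg)."""
    return rec.ma_concentration * (rec.ma_volume / 1000.0) / rec.body_weight


def preference_ratio(rec: DrinkingRecord) -> float:
    """Drug-solution volume over total fluid volume; NaN (flagged) if no fluid."""
    total = rec.ma_volume + rec.water_volume
    if total == 0:
        log.warning("zero total fluid intake; preference undefined")
        return float("nan")
    return rec.ma_volume / total


def realized_heritability(
    sr: SelectionRecords, fit_intercept: bool = True
) -> tuple[float, float, float]:
    """Realized heritability from a selection study.

    Cumulative response ``R_t = offspring_mean_t - founder_mean`` is
    regressed on the cumulative selection differential
    ``S_t = sum_{i<=t} (selected_parent_mean_i - population_mean_i)``;
    the least-squares slope is the realized h^2.

    Returns ``(h2, intercept, r_squared)``. With ``fit_intercept=False`` the
    regression is constrained through the origin and the intercept is 0.
    """
    t = sr.table
    if len(t) < 2:
        raise ValueError("need >= 2 offspring generations for the regression")
    S = (t["selected_parent_mean"] - t["population_mean"]).cumsum().to_numpy()
    R = (t["offspring_mean"] - sr.founder_mean).to_numpy()
    if np.allclose(S, 0):
        raise ValueError("zero cumulative selection differential; h2 undefined")
    if fit_intercept:
        res = stats.linregress(S, R)
        return float(res.slope), float(res.intercept), float(res.rvalue**2)
    slope = float(np.dot(S, R) / np.dot(S, S))
    fitted = slope * S
    ss_res = float(((R - fitted) ** 2).sum())
    ss_tot = float((R**2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, 0.0, r2


def ddct_relative_expression(
    delta_ct: pd.Series, reference_group: list[str]
) -> pd.Series:
    """Per-sample relative expression by the conventional 2^-ddCt method.

    ``delta_ct`` holds per-sample target Ct minus control-gene Ct; the fold
    value of sample i is ``2 ** -(dCt_i - mean dCt of the reference group)``,
    so a sample one cycle below the reference mean (more transcript) has
    fold 2.

    Note: descriptions of this quantity as "two to the negative power of the
    reference average minus each individual value" invert the sign and would
    assign fold < 1 to higher-expressing samples; this implementation keeps
    the conventional orientation (lower Ct => fold > 1) and logs the choice.
    """
    if len(reference_group) == 0:
        raise ValueError("reference group must be non-empty")
    missing = [s for s in reference_group if s not in delta_ct.index]
    if missing:
        raise ValueError(f"reference samples missing from data: {missing}")
    log.info(
        "ddCt: using conventional sign 2^-(dCt_i - reference mean); "
        "fold > 1 means more transcript than the reference group"
    )
    ref_mean = delta_ct.loc[reference_group].mean()
    return 2.0 ** (-(delta_ct - ref_mean))
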