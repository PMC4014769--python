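"""ANOVA-based strain/time analysis of serum metabolite concentrations.

Concentrations are power-transformed toward normality (a grid of
exponents from 0, meaning the log transformation, to 1, untransformed;
the reference analysis settled on y^0.25).  Strain effects are then
examined with one-way fixed-effects ANOVA within each timepoint and
with a two-way strain + time model in which time is entered first, so
the sums of squares are sequential (Type I).  The fraction of total
variation attributable to strain — the partial R^2, i.e.
SS(strain | time) / SS(total) — serves as an approximate heritability.

Records flagged below the limit of detection are excluded from the
ANOVA (their magnitude is unknown), which mirrors the shrinking sample
sizes at late timepoints for the conjugation metabolites.  Fits go
through ordinary least squares (statsmodels) with sequential ANOVA
tables; the test suite checks them against explicit design-matrix
projections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .data import ConcentrationDataset
from .params import ConfigurationError

__all__ = [
    "AnovaResult",
    "power_transform",
    "select_power_transform",
    "one_way_anova_per_time",
    "two_way_anova",
    "anova_table",
]

DEFAULT_LAMBDA_GRID: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class AnovaResult:
    """One factor's row of an ANOVA summary."""

    factor: str  # "strain" or "time"
    F_statistic: float
    p_value: float
    partial_R2: float
    n: int

    def __post_init__(self) -> None:
        if math.isfinite(self.F_statistic) and self.F_statistic < 0:
            raise ValueError("F must be >= 0")
        if math.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if math.isfinite(self.partial_R2) and not (
            -1e-12 <= self.partial_R2 <= 1.0 + 1e-12
        ):
            raise ValueError("partial R^2 must be in [0, 1]")


def power_transform(values, lam: float) -> np.ndarray:
    """y -> y**lam elementwise, with lam = 0 meaning the natural log.

    The grid convention runs from 0 (log) to 1 (identity); any lam in
    (0, 1] is the plain power.  Strictly monotone for positive data.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    y = np.asarray(values, dtype=float)
    if np.any(y < 0):
        raise ValueError("values must be >= 0")
    if lam == 0.0:
        if np.any(y == 0):
            raise ValueError("log transformation undefined at 0")
        return np.log(y)
    return y**lam


def _quantified(data: ConcentrationDataset, metabolite: str) -> pd.DataFrame:
    df = data.frame
    mask = (df["metabolite"] == metabolite) & (~df["below_lod"])
    return df.loc[mask, ["strain_id", "time_hr", "value_mg_L"]].copy()


def select_power_transform(
    data: ConcentrationDataset,
    grid=DEFAULT_LAMBDA_GRID,
    metabolites=None,
) -> tuple[float, pd.DataFrame]:
    """Pick the grid exponent with the best average fit to normality.

    For each candidate exponent the quantified values of every
    metabolite are transformed and scored with the Shapiro-Wilk W
    statistic; the exponent maximising the mean W across metabolites
    wins, with ties broken toward the smaller exponent.  Returns the
    winner and the per-metabolite score table.
    """
    grid = list(grid)
    if not grid:
        raise ConfigurationError("transform grid is empty")
    metabolites = metabolites or data.metabolites
    records = []
    for lam in grid:
        for met in metabolites:
            values = _quantified(data, met)["value_mg_L"].to_numpy()
            if values.size < 3:
                raise ValueError(
                    f"need >= 3 quantified observations for {met}, have {values.size}"
                )
            w = stats.shapiro(power_transform(values, lam)).statistic
            records.append((lam, met, float(w)))
    scores = pd.DataFrame(records, columns=["lambda", "metabolite", "shapiro_W"])
    mean_w = scores.groupby("lambda")["shapiro_W"].mean()
    # ties -> smaller lambda (sort by (-W, lambda))
    best = min(mean_w.items(), key=lambda kv: (-round(kv[1], 12), kv[0]))[0]
    return float(best), scores


def one_way_anova_per_time(
    data: ConcentrationDataset,
    metabolite: str,
    time: float,
    lam: float = 0.25,
) -> AnovaResult:
    """Strain-factor one-way ANOVA at a single timepoint.

    The partial R^2 is SS(strain)/SS(total) of the transformed values.
    When the design is saturated (zero residual degrees of freedom) the
    F statistic and p-value are undefined and reported as NaN, but the
    R^2 is still returned.
    """
    df = _quantified(data, metabolite)
    df = df[np.isclose(df["time_hr"], time)]
    strains = df["strain_id"].unique()
    n = len(df)
    if len(strains) < 2:
        raise ValueError("need >= 2 strains with data at this timepoint")
    y = power_transform(df["value_mg_L"].to_numpy(), lam)
    work = pd.DataFrame({"y": y, "strain": df["strain_id"].to_numpy()})
    fit = smf.ols("y ~ C(strain)", data=work).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        # saturated designs (df_resid = 0) legitimately yield undefined F
        table = sm.stats.anova_lm(fit, typ=1)
    ss_strain = float(table.loc["C(strain)", "sum_sq"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    ss_total = ss_strain + ss_resid
    r2 = ss_strain / ss_total if ss_total > 0 else float("nan")
    df_resid = float(table.loc["Residual", "df"])
    if df_resid <= 0:
        f_stat, p = float("nan"), float("nan")
    else:
        f_stat = float(table.loc["C(strain)", "F"])
        p = float(table.loc["C(strain)", "PR(>F)"])
    return AnovaResult("strain", f_stat, p, r2, n)


def two_way_anova(
    data: ConcentrationDataset,
    metabolite: str,
    lam: float = 0.25,
) -> dict[str, AnovaResult]:
    """Sequential two-way ANOVA, time entered before strain.

    Returns results for both factors; the strain entry's partial R^2 is
    SS(strain | time)/SS(total), the heritability index.  No interaction
    term is fitted; unbalanced cells are handled by least squares.
    """
    df = _quantified(data, metabolite)
    if df["strain_id"].nunique() < 2 or df["time_hr"].nunique() < 2:
        raise ValueError("both factors need >= 2 levels")
    y = power_transform(df["value_mg_L"].to_numpy(), lam)
    work = pd.DataFrame(
        {
            "y": y,
            "strain": df["strain_id"].to_numpy(),
            "time": df["time_hr"].astype(str).to_numpy(),
        }
    )
    fit = smf.ols("y ~ C(time) + C(strain)", data=work).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    ss_time = float(table.loc["C(time)", "sum_sq"])
    ss_strain = float(table.loc["C(strain)", "sum_sq"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    ss_total = ss_time + ss_strain + ss_resid
    n = len(work)
    results = {}
    for factor, key, ss in (
        ("time", "C(time)", ss_time),
        ("strain", "C(strain)", ss_strain),
    ):
        df_resid = float(table.loc["Residual", "df"])
        if df_resid <= 0:
            f_stat, p = float("nan"), float("nan")
        else:
            f_stat = float(table.loc[key, "F"])
            p = float(table.loc[key, "PR(>F)"])
        r2 = ss / ss_total if ss_total > 0 else float("nan")
        results[factor] = AnovaResult(factor, f_stat, p, r2, n)
    return results


def anova_table(
    data: ConcentrationDataset,
    lam: float = 0.25,
    metabolites=None,
) -> pd.DataFrame:
    """Study-level summary: per-timepoint strain rows plus an "All" row.

    Shaped like the classic strain/time heritability table: for each
    metabolite, one row per timepoint (one-way strain ANOVA) followed by
    an overall row from the sequential two-way model with both factors.
    """
    metabolites = metabolites or data.metabolites
    rows = []
    for met in metabolites:
        for t in data.times:
            sub = _quantified(data, met)
            sub = sub[np.isclose(sub["time_hr"], t)]
            if sub["strain_id"].nunique() < 2 or len(sub) < 3:
                continue
            res = one_way_anova_per_time(data, met, t, lam)
            rows.append(
                (met, f"{t:g}", res.n, res.partial_R2, res.F_statistic,
                 res.p_value, float("nan"), float("nan"))
            )
        try:
            both = two_way_anova(data, met, lam)
        except ValueError:
            continue
        strain, time_res = both["strain"], both["time"]
        rows.append(
            (met, "All", strain.n, strain.partial_R2, strain.F_statistic,
             strain.p_value, time_res.F_statistic, time_res.p_value)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite", "time_hr", "n", "partial_R2",
            "strain_F", "strain_p", "time_F", "time_p",
        ],
    )
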