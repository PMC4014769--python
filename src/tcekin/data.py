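"""Observed-concentration dataset container.

Serum metabolite observations are tabular: one record per (study,
strain, animal, metabolite, time) with a concentration in mg/L, or a
below-LOD flag plus the limit of detection when the analyte was not
quantifiable.  The container is a thin, validating wrapper around a
pandas DataFrame and is the interchange object between the synthetic
generator, the ANOVA stage and the Bayesian fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import MEASURED_METABOLITES

#: canonical column order of the CSV schema (version 1)
DATASET_COLUMNS = (
    "study_id",
    "strain_id",
    "animal_id",
    "metabolite",
    "time_hr",
    "value_mg_L",
    "below_lod",
    "lod_mg_L",
)

INDEX_STRAIN = "B6C3F1/J"


class DatasetError(ValueError):
    """A dataset violates the concentration-record schema."""


@dataclass
class ConcentrationDataset:
    """Validated serum concentration records with censoring flags."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        df = df.loc[:, list(DATASET_COLUMNS)].reset_index(drop=True)
        df["time_hr"] = df["time_hr"].astype(float)
        df["value_mg_L"] = df["value_mg_L"].astype(float)
        df["lod_mg_L"] = df["lod_mg_L"].astype(float)
        df["below_lod"] = df["below_lod"].astype(bool)

        bad_met = ~df["metabolite"].isin(MEASURED_METABOLITES)
        if bad_met.any():
            rows = df.index[bad_met].tolist()
            raise DatasetError(
                f"unknown metabolite in rows {rows}: "
                f"{sorted(df.loc[bad_met, 'metabolite'].unique())}"
            )
        if (df["time_hr"] < 0).any():
            rows = df.index[df["time_hr"] < 0].tolist()
            raise DatasetError(f"negative times in rows {rows}")
        unc = ~df["below_lod"]
        bad_value = unc & ~(df["value_mg_L"] > 0)
        if bad_value.any():
            rows = df.index[bad_value].tolist()
            raise DatasetError(
                f"uncensored records must have value > 0; offending rows {rows}"
            )
        cen = df["below_lod"]
        bad_lod = cen & ~(df["lod_mg_L"] > 0)
        if bad_lod.any():
            rows = df.index[bad_lod].tolist()
            raise DatasetError(
                f"censored records must carry lod > 0; offending rows {rows}"
            )
        object.__setattr__(self, "frame", df)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def strains(self) -> list[str]:
        return sorted(self.frame["strain_id"].unique())

    @property
    def metabolites(self) -> list[str]:
        return [m for m in MEASURED_METABOLITES if m in set(self.frame["metabolite"])]

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_hr"].unique())

    def for_strain(self, strain_id: str) -> "ConcentrationDataset":
        sub = self.frame[self.frame["strain_id"] == strain_id]
        return ConcentrationDataset(sub.copy())

    def censored_fraction(self, metabolite: str | None = None) -> float:
        df = self.frame
        if metabolite is not None:
            df = df[df["metabolite"] == metabolite]
        if len(df) == 0:
            return float("nan")
        return float(df["below_lod"].mean())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationDataset":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - rewrap with context
            raise DatasetError(f"could not read dataset CSV {path}: {exc}") from exc
        return cls(df)
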