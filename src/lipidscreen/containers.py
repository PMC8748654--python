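"""In-memory containers shared across the pipeline.

The central object is :class:`ConcentrationMatrix`, a samples x lipid-species
table of molar concentrations (nmol/mL) with a parallel per-cell provenance
table recording whether each value was measured, imputed, or absent.
Sample metadata travels as a plain :class:`pandas.DataFrame` (the "sample
table") with one row per sample.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: provenance codes for individual concentration cells
MEASURED = "measured"
IMPUTED = "imputed"
ABSENT = "absent"

#: canonical sample-table column names
SAMPLE_COLUMNS = (
    "group",        # T (PDAC case), N (healthy control), Pan (pancreatitis)
    "gender",       # M / F
    "age",          # years
    "stage",        # T1-T4 for cases, "" otherwise
    "site",         # blood collection site label
    "diabetes",     # 0/1 flag
    "ca199",        # CA 19-9 in U/mL
)


@dataclass
class ConcentrationMatrix:
    """Samples x species molar concentrations with per-cell provenance.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per lipid species,
        holding concentrations in nmol/mL.  ``NaN`` marks an absent value.
    provenance
        DataFrame of identical shape holding one of ``"measured"``,
        ``"imputed"`` or ``"absent"`` per cell.  Built automatically from
        ``values`` when omitted (non-NaN -> measured).
    """

    values: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes)}")
        if self.provenance is None:
            prov = pd.DataFrame(
                np.where(self.values.notna(), MEASURED, ABSENT),
                index=self.values.index,
                columns=self.values.columns,
            )
            self.provenance = prov
        else:
            if self.provenance.shape != self.values.shape:
                raise ValueError("provenance shape does not match values")
            self.provenance = self.provenance.reindex(
                index=self.values.index, columns=self.values.columns
            )
        present = self.values.to_numpy(dtype=float)
        if np.nanmin(present, initial=0.0) < 0:
            raise ValueError("negative concentrations are not allowed")

    # -- basic protocol ----------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def species(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(self.values.copy(), self.provenance.copy())

    def subset_samples(self, sample_ids) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            self.values.loc[sample_ids].copy(),
            self.provenance.loc[sample_ids].copy(),
        )

    def subset_species(self, names) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            self.values.loc[:, names].copy(),
            self.provenance.loc[:, names].copy(),
        )

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, values_path: str | Path, provenance_path: str | Path | None = None) -> None:
        self.values.to_csv(values_path, index_label="sample_id")
        if provenance_path is not None:
            self.provenance.to_csv(provenance_path, index_label="sample_id")

    @classmethod
    def from_csv(
        cls,
        values_path: str | Path,
        provenance_path: str | Path | None = None,
    ) -> "ConcentrationMatrix":
        values = pd.read_csv(values_path, index_col="sample_id")
        prov = None
        if provenance_path is not None:
            prov = pd.read_csv(provenance_path, index_col="sample_id")
        return cls(values, prov)


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check a sample table for the columns the pipeline relies on."""
    missing = [c for c in ("group", "gender") if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table lacks required columns: {missing}")
    bad = set(samples["group"].unique()) - {"T", "N", "Pan"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return samples
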