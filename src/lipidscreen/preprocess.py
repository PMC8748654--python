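"""Cohort-level preparation of concentration matrices.

Order of operations mirrors the study protocol: species present in fewer
than 25% of samples are excluded, remaining zero/missing cells are imputed
as 80% of the species' minimum positive value, concentrations are
log-transformed and centered/scaled (unit-variance or Pareto), samples are
split into training and validation sets by the every-6th rule on a seeded
stratified permutation, and models are built per gender.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ABSENT, IMPUTED, MEASURED, ConcentrationMatrix

logger = logging.getLogger(__name__)

DEFAULT_MIN_PRESENCE = 0.25
DEFAULT_IMPUTE_FACTOR = 0.8
TRAINING = "training"
VALIDATION = "validation"


def filter_by_presence(
    m: ConcentrationMatrix,
    min_presence: float = DEFAULT_MIN_PRESENCE,
) -> tuple[ConcentrationMatrix, pd.DataFrame]:
    """Drop species observed (positive, non-missing) in too few samples.

    A species is retained iff its presence fraction is **at least**
    ``min_presence``; species at exactly the boundary stay in.  Returns the
    filtered matrix and an exclusion report (species, presence fraction,
    retained flag).
    """
    if m.shape[0] == 0 or m.shape[1] == 0:
        raise ValueError("empty concentration matrix")
    vals = m.values
    present = vals.notna() & (vals > 0)
    presence = present.sum(axis=0) / len(vals)
    retained = presence >= min_presence
    report = pd.DataFrame(
        {"presence": presence, "retained": retained}, index=vals.columns
    )
    if not retained.any():
        raise ValueError(
            f"all {len(retained)} species fall below presence {min_presence}; "
            "review the threshold"
        )
    kept = m.subset_species(vals.columns[retained])
    logger.info(
        "presence filter: retained %d/%d species at threshold %.0f%%",
        int(retained.sum()),
        len(retained),
        100 * min_presence,
    )
    return kept, report


def impute_zeros(
    m: ConcentrationMatrix,
    factor: float = DEFAULT_IMPUTE_FACTOR,
) -> ConcentrationMatrix:
    """Replace zero/missing cells by ``factor`` x the species' minimum
    positive value across all samples, flagging them as imputed."""
    if not 0 < factor:
        raise ValueError("imputation factor must be > 0")
    values = m.values.copy()
    prov = m.provenance.copy()
    for col in values.columns:
        v = values[col]
        positive = v[v > 0]
        needs = v.isna() | (v <= 0)
        if not needs.any():
            continue
        if positive.empty:
            raise ValueError(
                f"species {col!r} has no positive value to impute from "
                "(presence filtering should have removed it)"
            )
        fill = factor * positive.min()
        values.loc[needs, col] = fill
        prov.loc[needs, col] = IMPUTED
    return ConcentrationMatrix(values, prov)


def normalize_to_nist(
    matrices: dict[str, ConcentrationMatrix],
    nist: pd.DataFrame,
) -> dict[str, ConcentrationMatrix]:
    """Harmonize per-method concentrations via NIST SRM 1950 anchors.

    ``nist`` is a methods x species table of the concentrations each method
    reported for the reference plasma.  Each value is rescaled by
    ``mean_over_methods(NIST) / NIST(method)`` for its species, which
    preserves the nmol/mL scale while removing method-specific bias.
    Species without a positive NIST value for a method pass through with a
    warning.
    """
    out: dict[str, ConcentrationMatrix] = {}
    for method, matrix in matrices.items():
        values = matrix.values.copy()
        if method not in nist.index:
            logger.warning("no NIST row for method %s; passed through", method)
            out[method] = matrix.copy()
            continue
        for col in values.columns:
            if col not in nist.columns:
                logger.warning("species %s lacks NIST coverage; passed through", col)
                continue
            ref = nist.loc[method, col]
            if not np.isfinite(ref) or ref <= 0:
                logger.warning(
                    "non-positive NIST value for %s / %s; species skipped",
                    method,
                    col,
                )
                continue
            col_vals = nist[col]
            anchor = col_vals[np.isfinite(col_vals) & (col_vals > 0)].mean()
            values[col] = values[col] * (anchor / ref)
        out[method] = ConcentrationMatrix(values, matrix.provenance.copy())
    return out


@dataclass
class ScalingParams:
    """Training-set transformation parameters, reusable on new samples."""

    log: bool
    scaling: str                # "uv" | "pareto" | "none"
    means: pd.Series
    scales: pd.Series

    def apply(self, values: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.means.index if c not in values.columns]
        if missing:
            raise ValueError(f"missing species in new data: {missing}")
        x = values[self.means.index].astype(float)
        if self.log:
            if (x <= 0).any().any():
                raise ValueError("log transform requires strictly positive values")
            x = np.log(x)
        return (x - self.means) / self.scales


def transform_scale(
    m: ConcentrationMatrix | pd.DataFrame,
    log: bool = True,
    scaling: str = "pareto",
) -> tuple[pd.DataFrame, ScalingParams]:
    """Log-transform, center, and scale a concentration matrix.

    ``scaling="uv"`` divides each centered column by its standard deviation,
    ``"pareto"`` by the square root of the standard deviation, ``"none"``
    only centers.  Zero-variance columns are centered with scale 1 and a
    warning.  Returns the model-ready matrix and the fitted parameters so
    validation samples can be transformed with training-set statistics.
    """
    values = m.values if isinstance(m, ConcentrationMatrix) else m
    x = values.astype(float)
    if log:
        if (x <= 0).any().any():
            raise ValueError("log transform requires strictly positive values (impute first)")
        x = np.log(x)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    zero_var = ~(sds > 0)
    if zero_var.any():
        logger.warning(
            "%d zero-variance species centered with scale 1: %s",
            int(zero_var.sum()),
            list(sds.index[zero_var][:5]),
        )
    if scaling == "uv":
        scales = sds.where(~zero_var, 1.0)
    elif scaling == "pareto":
        scales = np.sqrt(sds).where(~zero_var, 1.0)
    elif scaling == "none":
        scales = pd.Series(1.0, index=sds.index)
    else:
        raise ValueError(f"unknown scaling {scaling!r} (use 'uv', 'pareto' or 'none')")
    params = ScalingParams(log=log, scaling=scaling, means=means, scales=scales)
    return params.apply(values), params


def split_train_validation(samples: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Assign every 6th sample (within group x gender strata) to validation.

    Samples are permuted within each stratum with a seeded generator, then
    1-based positions 6, 12, 18, ... go to the validation set; the rest form
    the training set.  Deterministic for a fixed seed and sample ordering.
    """
    rng = np.random.default_rng(seed)
    assignment = pd.Series(TRAINING, index=samples.index, name="split")
    strata = samples.groupby(["group", "gender"], sort=True, observed=True)
    for _key, sub in strata:
        ids = sub.index.to_numpy()
        perm = rng.permutation(len(ids))
        ordered = ids[perm]
        validation = ordered[5::6]  # 1-based positions 6, 12, ...
        assignment.loc[validation] = VALIDATION
    return assignment


def stratify_by_gender(
    m: ConcentrationMatrix,
    samples: pd.DataFrame,
) -> dict[str, tuple[ConcentrationMatrix, pd.DataFrame]]:
    """Partition matrix and metadata into male and female strata."""
    genders = samples["gender"]
    unknown = samples.index[~genders.isin(["M", "F"])]
    if len(unknown):
        raise ValueError(f"unknown gender codes for samples: {list(unknown)}")
    out: dict[str, tuple[ConcentrationMatrix, pd.DataFrame]] = {}
    for code, label in (("M", "male"), ("F", "female")):
        ids = samples.index[genders == code]
        if len(ids) == 0:
            logger.warning("gender stratum %s is empty", label)
        out[label] = (m.subset_samples(ids), samples.loc[ids])
    return out
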