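"""Univariate dysregulation statistics and relevance selection.

For each lipid species the case/control contrast is summarized by the
Welch two-sample t-test (unequal variances, two-sided), the fold change of
group mean concentrations, and the VIP from the matching OPLS-DA model.
Species pass the relevance filter when p < 0.05, VIP > 1 and the fold
change is at least 20% (formalized symmetrically as max(r, 1/r) >= 1.2);
Bonferroni-surviving species are additionally flagged as especially
significant.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_VIP_MIN = 1.0
DEFAULT_FC_MIN_PERCENT = 20.0


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test (two-sided).

    Returns (t statistic, Welch-Satterthwaite degrees of freedom, p value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)``."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of tests")
    return np.minimum(1.0, m * p)


def fold_change(mean_t: float, mean_n: float) -> tuple[float, float, str]:
    """Case/control mean ratio with symmetric percent change and direction.

    ``percent_change = (max(r, 1/r) - 1) * 100`` so up- and downregulation
    are treated alike; direction is "down" when the case mean is lower.
    """
    if mean_t <= 0 or mean_n <= 0:
        raise ValueError("group means must be positive")
    ratio = mean_t / mean_n
    percent = (max(ratio, 1.0 / ratio) - 1.0) * 100.0
    direction = "down" if ratio < 1 else "up"
    return ratio, percent, direction


def diff_table(
    matrix_values: pd.DataFrame,
    groups: pd.Series,
    vip: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-species dysregulation statistics for a T vs N contrast.

    ``matrix_values`` holds concentrations (samples x species); ``groups``
    maps each sample to T/N (other labels ignored).  ``vip`` is merged from
    the gender-matched OPLS-DA model when given.
    """
    t_ids = groups.index[groups == "T"]
    n_ids = groups.index[groups == "N"]
    if len(t_ids) < 2 or len(n_ids) < 2:
        raise ValueError("need at least 2 cases and 2 controls")
    rows = []
    for col in matrix_values.columns:
        a = matrix_values.loc[t_ids, col].dropna()
        b = matrix_values.loc[n_ids, col].dropna()
        t_stat, df, p = welch_test(a, b)
        ratio, percent, direction = fold_change(a.mean(), b.mean())
        rows.append(
            dict(
                species=col,
                mean_T=a.mean(),
                mean_N=b.mean(),
                fold_change=ratio,
                percent_change=percent,
                direction=direction,
                t_stat=t_stat,
                df_welch=df,
                p_value=p,
            )
        )
    table = pd.DataFrame(rows).set_index("species")
    table["p_bonferroni"] = bonferroni(table["p_value"].to_numpy(), len(table))
    if vip is not None:
        table["vip"] = vip.reindex(table.index)
    return table


def select_relevant(
    diff: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    vip_min: float = DEFAULT_VIP_MIN,
    fc_min_percent: float = DEFAULT_FC_MIN_PERCENT,
) -> pd.DataFrame:
    """Flag statistically relevant species by the threshold conjunction.

    Relevant iff p < alpha (strict), VIP > vip_min (strict) and the
    symmetric fold change is at least ``fc_min_percent`` (boundary
    inclusive).  Species without a VIP value are flagged non-evaluable.
    """
    out = diff.copy()
    if "vip" not in out.columns:
        raise ValueError("diff table lacks a 'vip' column; merge model VIP first")
    missing_vip = out["vip"].isna()
    if missing_vip.any():
        logger.warning(
            "%d species lack VIP values and are not evaluable", int(missing_vip.sum())
        )
    out["evaluable"] = ~missing_vip
    out["relevant"] = (
        (out["p_value"] < alpha)
        & (out["vip"] > vip_min)
        & (out["percent_change"] >= fc_min_percent)
        & out["evaluable"]
    )
    out["especially_significant"] = out["relevant"] & (out["p_bonferroni"] < alpha)
    return out


def rsd_across_methods(
    matrices: dict[str, "pd.DataFrame | object"],
    species: str,
) -> pd.Series:
    """Per-sample relative standard deviation (%) of one species across
    methods.  Samples present in fewer than two methods get NaN."""
    from .containers import ConcentrationMatrix

    columns = {}
    for method, m in matrices.items():
        values = m.values if isinstance(m, ConcentrationMatrix) else m
        if species in values.columns:
            columns[method] = values[species]
    if not columns:
        raise ValueError(f"species {species!r} absent from all methods")
    wide = pd.DataFrame(columns)
    count = wide.notna().sum(axis=1)
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1)
    rsd = sd / mean * 100.0
    rsd[count < 2] = np.nan
    rsd.name = f"rsd_{species}"
    return rsd


def boxplot_summary(values, whiskers: str = "median") -> dict:
    """Five-number summary with 1.5*IQR whiskers.

    ``whiskers="median"`` spans 1.5*IQR from the *median* (the convention
    used in the study's figures); ``"tukey"`` uses the common from-quartile
    convention.  Whisker bounds are clipped to the data range; points
    outside are reported as outliers.  Quartiles use linear interpolation.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty group")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    if whiskers == "median":
        lo, hi = med - 1.5 * iqr, med + 1.5 * iqr
    elif whiskers == "tukey":
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    else:
        raise ValueError("whiskers must be 'median' or 'tukey'")
    inside = v[(v >= lo) & (v <= hi)]
    lo_clip = inside.min() if inside.size else med
    hi_clip = inside.max() if inside.size else med
    outliers = v[(v < lo) | (v > hi)]
    return dict(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(lo_clip),
        whisker_high=float(hi_clip),
        outliers=outliers.tolist(),
    )


def zscore_heatmap_matrix(matrix_values: pd.DataFrame) -> pd.DataFrame:
    """Samples x species z-scored concentrations for heat-map export."""
    x = matrix_values.astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (x - mu) / sd


def network_table(diff: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge tables for external network rendering.

    Nodes carry the per-species significance and regulation direction;
    edges connect species of the same lipid class (shared metabolism).
    """
    from .lipids import parse_name

    nodes = diff.reset_index()[
        ["species", "p_value", "fold_change", "percent_change", "direction"]
    ].copy()
    nodes["lipid_class"] = [parse_name(s)[0] for s in nodes["species"]]
    edges = []
    for cls, sub in nodes.groupby("lipid_class"):
        names = sub["species"].tolist()
        edges.extend(
            {"source": a, "target": b, "relation": "same_class"}
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        )
    return nodes, pd.DataFrame(edges, columns=["source", "target", "relation"])
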