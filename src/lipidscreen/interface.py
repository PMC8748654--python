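"""Run configuration, CA 19-9 operations, QC monitoring, and orchestration.

`RunConfig` freezes the study's printed operating thresholds (3000-count
peak extraction, 5 mDa matching tolerance, 25% presence rule, 80%-of-
minimum imputation, predicted-Y cut-off 0.5, alpha 0.05, VIP > 1, 20% fold
change, CA 19-9 cut-off 37 U/mL, QC injection after each 40 samples) as
defaults.  `run_pipeline` drives the end-to-end analysis on a synthetic or
user-supplied cohort and writes all report files plus a reproducibility
manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics, diffstats, preprocess
from .containers import ConcentrationMatrix
from .survival import univariate_lipid_survival

logger = logging.getLogger(__name__)

CA199_CUTOFF = 37.0  # U/mL


@dataclass
class RunConfig:
    """Pipeline settings; threshold defaults are the study's printed values."""

    # inputs (either a cohort directory with CSVs, or synthetic generation)
    input_dir: str | None = None
    output_dir: str = "lipidscreen_out"
    synthetic: bool = True

    # quantitation
    intensity_threshold: float = 3000.0   # counts
    mz_tolerance: float = 5.0             # mDa

    # preprocessing
    min_presence: float = 0.25
    impute_factor: float = 0.8
    scaling: str = "pareto"               # "uv" | "pareto"
    log_transform: bool = True

    # modelling / decision rules
    y_cutoff: float = 0.5
    alpha: float = 0.05
    vip_min: float = 1.0
    fc_min_percent: float = 20.0
    max_orthogonal: int = 3
    cv_folds: int = 7

    # clinical comparator
    ca199_cutoff: float = CA199_CUTOFF    # U/mL

    # QC
    qc_cadence: int = 40                  # QC sample after each 40 injections
    qc_mad_k: float = 4.0
    pca_outlier_z: float = 5.0

    seed: int = 0

    def validate(self) -> None:
        for name in (
            "intensity_threshold",
            "mz_tolerance",
            "min_presence",
            "impute_factor",
            "y_cutoff",
            "alpha",
            "vip_min",
            "fc_min_percent",
            "ca199_cutoff",
        ):
            if getattr(self, name) <= 0 and name != "intensity_threshold":
                raise ValueError(f"{name} must be positive")
        if self.scaling not in ("uv", "pareto"):
            raise ValueError("scaling must be 'uv' or 'pareto'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# CA 19-9
# ---------------------------------------------------------------------------

def classify_ca199(value: float, cutoff: float = CA199_CUTOFF) -> str | None:
    """Clinical CA 19-9 call: "PDAC" iff the value is over the cut-off.

    The boundary is strict (a value exactly at the cut-off is negative);
    missing values yield a missing classification (None).
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if value < 0:
        raise ValueError("CA 19-9 cannot be negative")
    return "PDAC" if value > cutoff else "negative"


def combine_with_ca199(
    matrix_values: pd.DataFrame,
    ca199: pd.Series,
) -> pd.DataFrame:
    """Append CA 19-9 as one extra variable to a concentration matrix.

    The raw U/mL values are added as a column named ``CA19-9`` so the
    shared log/scaling transform treats them like any lipid variable.
    Samples with missing CA 19-9 are dropped with a warning; a constant
    CA 19-9 column is dropped (it carries no class information).
    """
    ca = ca199.reindex(matrix_values.index)
    if ca.isna().all():
        raise ValueError("CA 19-9 missing for all samples")
    keep = ca.notna()
    if (~keep).any():
        logger.warning("dropping %d samples without CA 19-9", int((~keep).sum()))
    out = matrix_values.loc[keep].copy()
    ca = ca.loc[keep]
    if ca.nunique() <= 1:
        logger.warning("CA 19-9 is constant; column not added")
        return out
    out["CA19-9"] = ca
    return out


# ---------------------------------------------------------------------------
# QC monitoring
# ---------------------------------------------------------------------------

def qc_drift_monitor(
    intensities: pd.DataFrame,
    qc_positions: list[int] | None = None,
    mad_k: float = 4.0,
) -> pd.DataFrame:
    """Robust signal-drift report per monitored species.

    ``intensities`` has one row per injection (in measurement order) and
    one column per monitored species.  A Theil-Sen line is fit against
    injection order; injections deviating more than ``mad_k`` scaled MADs
    from the trend are flagged.  When QC positions are given, the report
    includes the QC-sample RSD per species.
    """
    if len(intensities) < 10:
        raise ValueError("need at least 10 injections for drift monitoring")
    order = np.arange(len(intensities), dtype=float)
    rows = []
    for col in intensities.columns:
        y = intensities[col].to_numpy(dtype=float)
        slope, intercept, *_ = _theil_sen(order, y)
        resid = y - (intercept + slope * order)
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = 1.4826 * mad if mad > 0 else np.std(resid) or 1.0
        flags = np.nonzero(np.abs(resid - np.median(resid)) > mad_k * scale)[0]
        qc_rsd = np.nan
        if qc_positions:
            qc_vals = y[list(qc_positions)]
            if qc_vals.mean() != 0:
                qc_rsd = float(np.std(qc_vals, ddof=1) / qc_vals.mean() * 100.0)
        rows.append(
            dict(
                species=col,
                slope_per_injection=float(slope),
                intercept=float(intercept),
                percent_drift_per_injection=float(slope / intercept * 100.0)
                if intercept
                else np.nan,
                flagged_injections=flags.tolist(),
                qc_rsd_percent=qc_rsd,
            )
        )
    return pd.DataFrame(rows).set_index("species")


def _theil_sen(x: np.ndarray, y: np.ndarray):
    from scipy.stats import theilslopes

    res = theilslopes(y, x)
    return res.slope, res.intercept


def pca_outlier_flags(
    matrix_values: pd.DataFrame,
    z_threshold: float = 5.0,
) -> pd.Series:
    """Advisory outlier flags from robust z-scores on the first two PCs.

    The matrix must already be preprocessed (log/scaled).  Flags never
    remove samples; the analyst decides.
    """
    X = matrix_values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    scores, _loadings, _evr = chemometrics.fit_pca(Xc, n_components=2)
    flagged = np.zeros(len(X), dtype=bool)
    for j in range(scores.shape[1]):
        s = scores[:, j]
        mad = np.median(np.abs(s - np.median(s)))
        scale = 1.4826 * mad if mad > 0 else (np.std(s) or 1.0)
        flagged |= np.abs(s - np.median(s)) > z_threshold * scale
    return pd.Series(flagged, index=matrix_values.index, name="pca_outlier")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _evaluate_gender_models(
    matrix: ConcentrationMatrix,
    samples: pd.DataFrame,
    split: pd.Series,
    config: RunConfig,
):
    """Per-gender OPLS-DA training and validation; returns reports + tables."""
    strata = preprocess.stratify_by_gender(matrix, samples)
    metrics_rows = []
    vip_tables = {}
    predictions = {}
    pooled: dict[str, dict[str, list]] = {
        "training": {"truth": [], "pred": [], "score": []},
        "validation": {"truth": [], "pred": [], "score": []},
    }
    for label, (m_g, s_g) in strata.items():
        usable = s_g["group"].isin(["T", "N"])
        ids = s_g.index[usable]
        if len(ids) == 0:
            continue
        y = (s_g.loc[ids, "group"] == "T").astype(int)
        train_ids = ids[split.loc[ids] == preprocess.TRAINING]
        valid_ids = ids[split.loc[ids] == preprocess.VALIDATION]
        if y.loc[train_ids].nunique() < 2:
            raise RuntimeError(f"training set for {label} stratum is single-class")
        raw = m_g.values
        X_train, params = preprocess.transform_scale(
            raw.loc[train_ids], log=config.log_transform, scaling=config.scaling
        )
        n_ortho = chemometrics.auto_select_orthogonal(
            X_train.to_numpy(),
            y.loc[train_ids].to_numpy(),
            max_k=config.max_orthogonal,
            k_folds=config.cv_folds,
            seed=config.seed,
        )
        model = chemometrics.fit_opls_da(
            X_train.to_numpy(),
            y.loc[train_ids].to_numpy(),
            n_orthogonal=n_ortho,
            species=list(X_train.columns),
        )
        model.Q2 = chemometrics.crossvalidate_q2(
            X_train.to_numpy(),
            y.loc[train_ids].to_numpy(),
            n_ortho,
            k=config.cv_folds,
            seed=config.seed,
        )
        vip_tables[label] = pd.Series(
            chemometrics.vip(model), index=X_train.columns, name="vip"
        )
        for set_label, set_ids in (("training", train_ids), ("validation", valid_ids)):
            if len(set_ids) == 0:
                continue
            X_set = params.apply(raw.loc[set_ids]).to_numpy()
            y_hat = chemometrics.predict(model, X_set)
            y_cls = (y_hat > config.y_cutoff).astype(int)
            truth = y.loc[set_ids].to_numpy()
            report = chemometrics.classification_metrics(truth, y_cls, label=set_label)
            row = report.as_dict()
            row.update(gender=label, n_orthogonal=model.n_orthogonal, Q2=model.Q2, R2Y=model.R2Y)
            metrics_rows.append(row)
            predictions[(label, set_label)] = pd.Series(y_hat, index=set_ids)
            if truth.sum() and (1 - truth).sum():
                pooled[set_label]["truth"].extend(truth.tolist())
                pooled[set_label]["pred"].extend(y_cls.tolist())
                pooled[set_label]["score"].extend(y_hat.tolist())
    # pooled (both genders) rows
    for set_label, d in pooled.items():
        if d["truth"]:
            rep = chemometrics.classification_metrics(d["truth"], d["pred"], label=set_label)
            row = rep.as_dict()
            _roc, auc = chemometrics.roc_auc(d["score"], d["truth"])
            row.update(gender="pooled", auc=auc)
            metrics_rows.append(row)
    return pd.DataFrame(metrics_rows), vip_tables, predictions


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write artifacts to the output directory.

    Stages: cohort acquisition (synthetic or CSV) -> presence filter ->
    imputation -> every-6th split -> per-gender OPLS-DA with auto
    orthogonal selection -> diagnostics/ROC -> dysregulation statistics ->
    survival analysis -> manifest.  Any stage failure aborts with an error
    naming the stage; artifacts written so far stay on disk and the
    manifest marks the failure.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}
    stage = "setup"

    def _fail(exc: Exception):
        manifest["stages"][stage] = f"failed: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        stage = "cohort"
        if config.synthetic:
            from .synthetic import CohortConfig, generate_cohort, generate_survival, SurvivalParams

            ccfg = CohortConfig(
                seed=config.seed,
                survival_params=SurvivalParams(coefficients={"LPC 18:2": -0.7}),
            )
            matrix, samples = generate_cohort(ccfg)
            samples = generate_survival(samples, matrix, ccfg)
        else:
            if not config.input_dir:
                raise ValueError("input_dir required when synthetic=False")
            indir = Path(config.input_dir)
            for required in ("concentrations.csv", "samples.csv"):
                if not (indir / required).exists():
                    raise FileNotFoundError(f"missing input file: {indir / required}")
            matrix = ConcentrationMatrix.from_csv(indir / "concentrations.csv")
            samples = pd.read_csv(indir / "samples.csv", index_col="sample_id")
            manifest["files"]["input_concentrations_sha256"] = _sha256(indir / "concentrations.csv")
            manifest["files"]["input_samples_sha256"] = _sha256(indir / "samples.csv")
        manifest["stages"][stage] = f"ok: {matrix.shape[0]} samples x {matrix.shape[1]} species"

        stage = "preprocess"
        filtered, report = preprocess.filter_by_presence(matrix, config.min_presence)
        imputed = preprocess.impute_zeros(filtered, config.impute_factor)
        report.to_csv(outdir / "exclusion_report.tsv", sep="\t")
        imputed.to_csv(outdir / "concentrations.csv", outdir / "provenance.csv")
        samples.to_csv(outdir / "samples.csv", index_label="sample_id")
        manifest["stages"][stage] = (
            f"ok: {filtered.shape[1]}/{matrix.shape[1]} species retained"
        )

        stage = "split"
        split = preprocess.split_train_validation(samples, seed=config.seed)
        split.to_frame().to_csv(outdir / "split.csv", index_label="sample_id")
        manifest["stages"][stage] = (
            f"ok: {(split == preprocess.VALIDATION).sum()} validation samples"
        )

        stage = "model"
        metrics, vip_tables, _predictions = _evaluate_gender_models(
            imputed, samples, split, config
        )
        metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
        for label, v in vip_tables.items():
            v.to_csv(outdir / f"vip_{label}.tsv", sep="\t")
        manifest["stages"][stage] = "ok"

        stage = "diffstats"
        diff_tables = {}
        for label, v in vip_tables.items():
            ids = samples.index[samples["gender"] == ("F" if label == "female" else "M")]
            sub = samples.loc[ids]
            dt = diffstats.diff_table(
                imputed.values.loc[ids], sub["group"], vip=v
            )
            dt = diffstats.select_relevant(
                dt,
                alpha=config.alpha,
                vip_min=config.vip_min,
                fc_min_percent=config.fc_min_percent,
            )
            dt.to_csv(outdir / f"difftable_{label}.tsv", sep="\t")
            diff_tables[label] = dt
        manifest["stages"][stage] = "ok"

        stage = "survival"
        if "os_months" in samples.columns and samples["os_months"].notna().any():
            from .lipids import MARKER_SPECIES

            marker_cols = [s for s in MARKER_SPECIES if s in imputed.species]
            forest, _curves = univariate_lipid_survival(
                samples, imputed.values, marker_cols
            )
            forest.to_csv(outdir / "forest.tsv", sep="\t", index=False)
            manifest["stages"][stage] = f"ok: {len(marker_cols)} lipids"
        else:
            manifest["stages"][stage] = "skipped: no survival data"

        stage = "manifest"
        for f in sorted(outdir.iterdir()):
            if f.name != "manifest.json" and f.is_file():
                manifest["files"][f.name] = _sha256(f)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        _fail(exc)
    return manifest
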